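"""Layer tracing, region assignment, gap and summary tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seedmorph import (
    AmbiguousTopologyError,
    CellPolygon,
    InvalidArgumentError,
    assign_regions,
    detect_gaps,
    layer_summary,
    measure_layer,
    trace_layer,
)
from seedmorph.synthetic import ConstantField, LayerSpec, synthesize_layer

from conftest import rotation


class TestTraceLayer:
    def test_abutting_squares_order_and_s(self, abutting_squares):
        tr = trace_layer(abutting_squares)
        assert tr.cell_ids == tuple(f"c{i}" for i in range(10))
        assert tr.total_length == pytest.approx(9.0)
        np.testing.assert_allclose(tr.s, np.arange(10) / 9.0)

    @given(seed=st.integers(0, 500))
    def test_input_order_invariance(self, seed):
        squares = [
            CellPolygon("s0", "l0", f"c{i}", [(i, 0), (i + 1, 0), (i + 1, 1), (i, 1)])
            for i in range(10)
        ]
        rng = np.random.default_rng(seed)
        shuffled = [squares[i] for i in rng.permutation(10)]
        tr = trace_layer(shuffled)
        assert tr.cell_ids == tuple(f"c{i}" for i in range(10))

    def test_start_hint_reverses(self, abutting_squares):
        tr = trace_layer(abutting_squares, start_hint=(9.5, 0.5))
        assert tr.cell_ids[0] == "c9"
        ref = trace_layer(abutting_squares)
        np.testing.assert_allclose(tr.s, 1.0 - ref.s[::-1])

    def test_semicircle_arc_length(self):
        spec = LayerSpec(
            layer_id="l", n_cells=60, midline="arc", arc_radius=100.0,
            arc_span=math.pi, area_field=ConstantField(30.0),
            aspect_field=ConstantField(1.0), orientation_jitter=0.0,
            vertex_noise=0.0, cell_cv=0.0,
        )
        cells, gt = synthesize_layer(spec, np.random.default_rng(0), "s")
        tr = trace_layer(cells, start_hint=gt.start_point)
        assert tr.total_length == pytest.approx(100 * math.pi, rel=0.02)

    def test_rejects_single_cell(self, unit_square):
        with pytest.raises(InvalidArgumentError):
            trace_layer([unit_square])

    def test_rejects_branching(self):
        # T-shaped arrangement: centre cell touches three neighbours
        cells = [
            CellPolygon("s", "l", "c", [(0, 0), (1, 0), (1, 1), (0, 1)]),
            CellPolygon("s", "l", "w", [(-1, 0), (0, 0), (0, 1), (-1, 1)]),
            CellPolygon("s", "l", "e", [(1, 0), (2, 0), (2, 1), (1, 1)]),
            CellPolygon("s", "l", "n", [(0, 1), (1, 1), (1, 2), (0, 2)]),
        ]
        with pytest.raises(AmbiguousTopologyError):
            trace_layer(cells)

    def test_disconnected_needs_hint(self):
        def sq(x, cid):
            return CellPolygon("s", "l", cid, [(x, 0), (x + 1, 0), (x + 1, 1), (x, 1)])

        cells = [sq(0, "a0"), sq(1, "a1"), sq(5, "b0"), sq(6, "b1")]
        with pytest.raises(AmbiguousTopologyError):
            trace_layer(cells)
        tr = trace_layer(cells, start_hint=(0.0, 0.5))
        assert tr.cell_ids == ("a0", "a1", "b0", "b1")

    def test_rigid_motion_leaves_s_invariant(self, abutting_squares):
        tr = trace_layer(abutting_squares)
        theta = 0.7
        moved = [
            CellPolygon(
                c.specimen_id, c.layer_id, c.cell_id,
                c.vertices @ rotation(theta).T + [13.0, -4.0],
            )
            for c in abutting_squares
        ]
        hint = rotation(theta) @ np.array([0.5, 0.5]) + [13.0, -4.0]
        tr2 = trace_layer(moved, start_hint=hint)
        np.testing.assert_allclose(tr2.s, tr.s, atol=1e-9)
        assert tr2.total_length == pytest.approx(tr.total_length, rel=1e-9)


class TestRegions:
    def test_half_open_boundaries(self):
        labels = assign_regions(np.array([0.0, 1 / 3, 0.5, 2 / 3, 1.0]))
        assert list(labels) == [
            "chalazal", "curving_zone", "curving_zone", "micropylar", "micropylar",
        ]

    def test_uniform_201_counts(self):
        s = np.linspace(0, 1, 201)
        labels = assign_regions(s)
        counts = {r: int(np.sum(labels == r)) for r in np.unique(labels)}
        assert counts == {"chalazal": 67, "curving_zone": 67, "micropylar": 67}

    def test_out_of_order_boundaries(self):
        with pytest.raises(InvalidArgumentError):
            assign_regions(np.array([0.5]), boundaries=(0.7, 0.3))

    def test_labels_partition(self, abutting_squares):
        tr = trace_layer(abutting_squares)
        labels = assign_regions(tr)
        assert len(labels) == len(tr)


class TestGaps:
    def test_abutting_layer_no_gaps(self, abutting_squares):
        rep = detect_gaps(trace_layer(abutting_squares), contact_tol=0.0)
        assert rep.gap_fraction == 0.0
        assert rep.gaps == ()

    def test_constructed_gap_fraction(self):
        # 10 unit squares, one 5 µm clearance; midline length 14 µm
        xs = list(range(5)) + [x + 10 for x in range(5)]
        cells = [
            CellPolygon("s", "l", f"c{i}", [(x, 0), (x + 1, 0), (x + 1, 1), (x, 1)])
            for i, x in enumerate(xs)
        ]
        tr = trace_layer(cells, start_hint=(0.0, 0.5))
        rep = detect_gaps(tr, contact_tol=0.0)
        assert rep.total_gap_length == pytest.approx(5.0)
        assert rep.gap_fraction == pytest.approx(5.0 / 14.0)
        (g0, g1, glen) = rep.gaps[0]
        assert glen == pytest.approx(5.0)
        assert g1 > g0

    def test_contact_tol_absorbs_clearance(self):
        cells = [
            CellPolygon("s", "l", "a", [(0, 0), (1, 0), (1, 1), (0, 1)]),
            CellPolygon("s", "l", "b", [(1.3, 0), (2.3, 0), (2.3, 1), (1.3, 1)]),
            CellPolygon("s", "l", "c", [(2.6, 0), (3.6, 0), (3.6, 1), (2.6, 1)]),
        ]
        tr = trace_layer(cells, start_hint=(0.0, 0.5), contact_tol=0.5)
        assert detect_gaps(tr, contact_tol=0.5).gap_fraction == 0.0
        assert detect_gaps(tr, contact_tol=0.0).gap_fraction > 0.0

    def test_generator_gap_recovery_on_arc(self):
        spec = LayerSpec(
            layer_id="l", n_cells=50, midline="arc", arc_radius=120.0,
            area_field=ConstantField(100.0), aspect_field=ConstantField(0.5),
            orientation_jitter=0.0, vertex_noise=0.0, cell_cv=0.08,
            gap_fraction=0.046, gap_region=(0, 1 / 3),
        )
        fracs = []
        for seed in range(20):
            cells, gt = synthesize_layer(spec, np.random.default_rng(seed), "s")
            tr = trace_layer(cells, start_hint=gt.start_point)
            fracs.append(detect_gaps(tr, contact_tol=0.0, region=(0, 1 / 3)).gap_fraction)
        assert np.mean(fracs) == pytest.approx(0.046, abs=0.005)

    def test_gap_fraction_bounds(self, abutting_squares):
        rep = detect_gaps(trace_layer(abutting_squares), contact_tol=0.0)
        assert 0.0 <= rep.gap_fraction < 1.0
        assert rep.total_gap_length <= rep.layer_length


class TestSummary:
    def test_whole_layer(self, abutting_squares):
        summ = layer_summary(trace_layer(abutting_squares))
        assert summ.length == pytest.approx(9.0)
        assert summ.cell_count == 10

    def test_half_mask_counts_boundary_cell(self, abutting_squares):
        summ = layer_summary(trace_layer(abutting_squares), (0.0, 0.5))
        assert summ.cell_count == 6
        assert summ.length == pytest.approx(4.5)

    def test_empty_interval_rejected(self, abutting_squares):
        with pytest.raises(InvalidArgumentError):
            layer_summary(trace_layer(abutting_squares), (0.5, 0.5))


def test_measure_layer_table(abutting_squares):
    df = measure_layer(trace_layer(abutting_squares))
    assert len(df) == 10
    assert df["area"].tolist() == pytest.approx([1.0] * 10)
    assert df["growth_polarity"].tolist() == pytest.approx([1.0] * 10)
    assert set(df["region"]) == {"chalazal", "curving_zone", "micropylar"}
    assert df["s"].is_monotonic_increasing
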