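"""Ordering a cell layer along its proximal-distal axis.

A layer (e.g. the endothelium or the ii1' sub-epidermal layer of the
seed coat) is an approximately one-cell-wide chain of cells following a
curved midline from the chalaza (proximal) to the micropyle (distal).
This module orders the cells into that chain, parametrises each cell by
normalised arc length ``s`` along the centroid polyline, assigns the
chalazal / curving-zone / micropylar region labels, quantifies
discontinuities (gaps) in the chain, and summarises layer size
(length and cell number, optionally restricted to one side).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .errors import AmbiguousTopologyError, InvalidArgumentError
from .geometry import CellPolygon, polygon_centroid, shape_descriptors

__all__ = [
    "REGIONS",
    "LayerTrace",
    "GapReport",
    "LayerSummary",
    "trace_layer",
    "assign_regions",
    "detect_gaps",
    "layer_summary",
    "measure_layer",
]

#: Region labels in proximal -> distal order.
REGIONS = ("chalazal", "curving_zone", "micropylar")

DEFAULT_CONTACT_TOL = 0.5  # µm; absorbs segmentation pixelation
DEFAULT_BOUNDARIES = (1.0 / 3.0, 2.0 / 3.0)


@dataclass(frozen=True)
class LayerTrace:
    """Ordered cells of one layer with midline parametrisation.

    ``midline`` is the polyline of cell centroids (one vertex per cell,
    proximal to distal), ``s`` the normalised cumulative arc length of
    each centroid (``s[0] == 0``, ``s[-1] == 1``) and ``tangents`` the
    unit local layer direction at each cell (central differences of the
    centroid polyline, one-sided at the endpoints).
    """

    specimen_id: str
    layer_id: str
    cells: tuple[CellPolygon, ...]
    midline: np.ndarray
    s: np.ndarray
    tangents: np.ndarray
    total_length: float

    @property
    def cell_ids(self) -> tuple[str, ...]:
        return tuple(c.cell_id for c in self.cells)

    def __len__(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class GapReport:
    """Gaps along one traced layer, optionally restricted to an s-interval.

    ``gaps`` holds ``(s_start, s_end, length_um)`` per detected gap;
    ``gap_fraction == total_gap_length / layer_length`` where
    ``layer_length`` is the midline arc length of the inspected interval.
    """

    specimen_id: str
    layer_id: str
    region: tuple[float, float]
    gaps: tuple[tuple[float, float, float], ...]
    total_gap_length: float
    layer_length: float

    @property
    def gap_fraction(self) -> float:
        return self.total_gap_length / self.layer_length


@dataclass(frozen=True)
class LayerSummary:
    """Length and cell number of a layer or one side of it."""

    specimen_id: str
    layer_id: str
    side: str
    length: float
    cell_count: int


def _chain_components(adj: list[set[int]]) -> list[list[int]]:
    """Split an adjacency structure of degree <= 2 into ordered chains."""
    n = len(adj)
    seen = [False] * n
    chains: list[list[int]] = []
    for i in range(n):
        if seen[i]:
            continue
        comp = {i}
        stack = [i]
        while stack:
            j = stack.pop()
            for k in adj[j]:
                if k not in comp:
                    comp.add(k)
                    stack.append(k)
        ends = sorted(j for j in comp if len(adj[j] & comp) <= 1)
        if not ends:
            raise AmbiguousTopologyError(
                "cells form a closed loop; cannot orient the layer axis"
            )
        order = [ends[0]]
        prev = None
        while True:
            nxt = [k for k in adj[order[-1]] if k != prev and k in comp]
            nxt = [k for k in nxt if len(order) < 2 or k != order[-2]]
            unvisited = [k for k in nxt if k not in order]
            if not unvisited:
                break
            prev = order[-1]
            order.append(unvisited[0])
        for j in comp:
            seen[j] = True
        chains.append(order)
    return chains


def _merge_chains(chains: list[list[int]], centroids: np.ndarray) -> list[int]:
    """Greedily join chain endpoints by nearest centroid distance."""
    chains = [list(c) for c in chains]
    while len(chains) > 1:
        best = None
        for i in range(len(chains)):
            for j in range(i + 1, len(chains)):
                for ei, rev_i in ((chains[i][-1], False), (chains[i][0], True)):
                    for ej, rev_j in ((chains[j][0], False), (chains[j][-1], True)):
                        d = float(np.linalg.norm(centroids[ei] - centroids[ej]))
                        key = (d, i, j, rev_i, rev_j)
                        if best is None or key < best:
                            best = key
        _, i, j, rev_i, rev_j = best
        a = chains[i][::-1] if rev_i else chains[i]
        b = chains[j][::-1] if rev_j else chains[j]
        merged = a + b
        chains = [c for k, c in enumerate(chains) if k not in (i, j)]
        chains.append(merged)
    return chains[0]


def trace_layer(
    cells: list[CellPolygon],
    start_hint: np.ndarray | None = None,
    contact_tol: float = DEFAULT_CONTACT_TOL,
) -> LayerTrace:
    """Order the cells of one layer proximal to distal and parametrise them.

    Cells are chained by adjacency (polygon-to-polygon clearance at most
    ``contact_tol``); a cell touching three or more neighbours raises
    :class:`AmbiguousTopologyError`.  Chains separated by gaps are
    bridged greedily through their nearest endpoints.  The proximal end
    is the chain endpoint nearest ``start_hint`` when given, else the
    endpoint with lexicographically smaller centroid ``(x, y)``.

    Raises :class:`AmbiguousTopologyError` when the layer splits into
    two or more multi-cell components and no ``start_hint`` is supplied.
    """
    if len(cells) < 2:
        raise InvalidArgumentError("trace_layer requires at least 2 cells")
    ids = {(c.specimen_id, c.layer_id) for c in cells}
    if len(ids) != 1:
        raise InvalidArgumentError(
            f"cells span multiple specimen/layer identities: {sorted(ids)}"
        )
    specimen_id, layer_id = next(iter(ids))

    geoms = np.array([c.shapely_polygon for c in cells], dtype=object)
    dist = shapely.distance(geoms[:, None], geoms[None, :])
    np.fill_diagonal(dist, np.inf)
    adj = [set(np.nonzero(dist[i] <= contact_tol)[0].tolist()) for i in range(len(cells))]
    for i, neigh in enumerate(adj):
        if len(neigh) >= 3:
            raise AmbiguousTopologyError(
                f"cell {cells[i].cell_id!r} touches {len(neigh)} neighbours; "
                "layer is branching"
            )

    centroids = np.array([polygon_centroid(c) for c in cells])
    chains = _chain_components(adj)
    if sum(len(c) >= 2 for c in chains) > 1 and start_hint is None:
        raise AmbiguousTopologyError(
            f"{len(chains)} disconnected multi-cell chains; supply start_hint "
            "to fix the proximal end"
        )
    order = _merge_chains(chains, centroids) if len(chains) > 1 else chains[0]

    first, last = centroids[order[0]], centroids[order[-1]]
    if start_hint is not None:
        hint = np.asarray(start_hint, dtype=float)
        if np.linalg.norm(last - hint) < np.linalg.norm(first - hint):
            order = order[::-1]
    elif tuple(last) < tuple(first):
        order = order[::-1]

    midline = centroids[order]
    seg = np.linalg.norm(np.diff(midline, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise InvalidArgumentError("coincident centroids: zero-length midline")
    s = np.concatenate([[0.0], np.cumsum(seg)]) / total
    s[-1] = 1.0

    diffs = np.empty_like(midline)
    diffs[1:-1] = midline[2:] - midline[:-2]
    diffs[0] = midline[1] - midline[0]
    diffs[-1] = midline[-1] - midline[-2]
    tangents = diffs / np.linalg.norm(diffs, axis=1, keepdims=True)

    return LayerTrace(
        specimen_id=specimen_id,
        layer_id=layer_id,
        cells=tuple(cells[i] for i in order),
        midline=midline,
        s=s,
        tangents=tangents,
        total_length=total,
    )


def assign_regions(
    s: np.ndarray | LayerTrace, boundaries: tuple[float, float] = DEFAULT_BOUNDARIES
) -> np.ndarray:
    """Label axis positions as chalazal / curving_zone / micropylar.

    Half-open, distal-inclusive rule: ``s < b1`` chalazal,
    ``b1 <= s < b2`` curving zone, ``s >= b2`` micropylar.
    """
    b1, b2 = boundaries
    if not (0.0 < b1 < b2 < 1.0):
        raise InvalidArgumentError(f"boundaries must satisfy 0 < b1 < b2 < 1, got {boundaries}")
    svals = s.s if isinstance(s, LayerTrace) else np.asarray(s, dtype=float)
    labels = np.where(svals < b1, REGIONS[0], np.where(svals < b2, REGIONS[1], REGIONS[2]))
    return labels


def detect_gaps(
    trace: LayerTrace,
    contact_tol: float = DEFAULT_CONTACT_TOL,
    region: tuple[float, float] | None = None,
) -> GapReport:
    """Quantify discontinuities between consecutive cells of a layer.

    For each consecutive pair the gap length is
    ``max(0, clearance - contact_tol)`` where clearance is the minimum
    polygon-to-polygon distance.  Each positive gap is placed on the
    midline centred between the two cells' ``s`` positions.  With
    ``region=(a, b)`` both the gaps (their overlap) and the layer length
    are restricted to that s-interval, giving the region's
    gap-to-length ratio.
    """
    if len(trace) < 2:
        raise InvalidArgumentError("detect_gaps requires a trace of >= 2 cells")
    if contact_tol < 0:
        raise InvalidArgumentError("contact_tol must be >= 0")
    a, b = (0.0, 1.0) if region is None else region
    if not (0.0 <= a < b <= 1.0):
        raise InvalidArgumentError(f"region must satisfy 0 <= a < b <= 1, got {region}")

    gaps: list[tuple[float, float, float]] = []
    total_in_region = 0.0
    for i in range(len(trace) - 1):
        clearance = float(
            shapely.distance(trace.cells[i].shapely_polygon, trace.cells[i + 1].shapely_polygon)
        )
        gap = max(0.0, clearance - contact_tol)
        if gap <= 0.0:
            continue
        mid = 0.5 * (trace.s[i] + trace.s[i + 1])
        half = gap / (2.0 * trace.total_length)
        g0, g1 = max(0.0, mid - half), min(1.0, mid + half)
        overlap = max(0.0, min(g1, b) - max(g0, a)) * trace.total_length
        if overlap > 0.0:
            gaps.append((g0, g1, gap))
            total_in_region += overlap
    layer_length = (b - a) * trace.total_length
    return GapReport(
        specimen_id=trace.specimen_id,
        layer_id=trace.layer_id,
        region=(a, b),
        gaps=tuple(gaps),
        total_gap_length=total_in_region,
        layer_length=layer_length,
    )


def _occupied_intervals(s: np.ndarray) -> np.ndarray:
    """Each cell occupies the s-interval between midpoints to its neighbours."""
    mids = 0.5 * (s[1:] + s[:-1])
    lo = np.concatenate([[0.0], mids])
    hi = np.concatenate([mids, [1.0]])
    return np.column_stack([lo, hi])


def layer_summary(
    trace: LayerTrace,
    side_mask: tuple[float, float] | None = None,
    side: str = "whole",
) -> LayerSummary:
    """Midline length and cell number of a layer or an s-interval of it.

    A cell is counted when its occupied s-interval (between midpoints to
    its neighbours) intersects the closed mask interval.
    """
    a, b = (0.0, 1.0) if side_mask is None else side_mask
    if not (0.0 <= a < b <= 1.0):
        raise InvalidArgumentError(f"side mask must satisfy 0 <= a < b <= 1, got {side_mask}")
    occ = _occupied_intervals(trace.s)
    count = int(np.sum((occ[:, 0] <= b) & (occ[:, 1] >= a)))
    return LayerSummary(
        specimen_id=trace.specimen_id,
        layer_id=trace.layer_id,
        side=side,
        length=(b - a) * trace.total_length,
        cell_count=count,
    )


def measure_layer(
    trace: LayerTrace,
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES,
    roundness_method: str = "circularity",
) -> pd.DataFrame:
    """Per-cell morphometry table for one traced layer.

    Columns: specimen_id, layer_id, cell_id, area, perimeter, roundness,
    periclinal_length, growth_polarity, gp_degenerate, s, region,
    tangent_angle (radians).
    """
    regions = assign_regions(trace.s, boundaries)
    rows = []
    for i, cell in enumerate(trace.cells):
        desc = shape_descriptors(cell, trace.tangents[i], roundness_method)
        rows.append(
            {
                "specimen_id": cell.specimen_id,
                "layer_id": cell.layer_id,
                "cell_id": cell.cell_id,
                **desc,
                "s": float(trace.s[i]),
                "region": regions[i],
                "tangent_angle": float(
                    np.arctan2(trace.tangents[i, 1], trace.tangents[i, 0])
                ),
            }
        )
    return pd.DataFrame(rows)
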