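"""Synthetic curved-tissue generator with analytic ground truth.

Generates seed-coat-like cell layers — chains of quadrilateral cells
laid along a straight or circular-arc midline — with controllable
gradients in cell area and anticlinal:periclinal aspect ratio along the
normalised proximal-distal axis, optional injected gaps in a chosen
axis region, and group-specific field modifiers.  Because cells are
noisy rectangles, every emitted polygon has an analytic ground truth
(true area, aspect, orientation, axis position), so the whole
measurement pipeline can be validated without imaging data.

The default cohort emulates the study design this package targets:
two groups of 33 and 20 specimens, one endothelium-like layer of 60
cells per specimen whose cell area grows and whose roundness falls from
the chalazal (proximal) to the micropylar (distal) end, and a
mutant-like group effect that enlarges cells and pushes the aspect
ratio above 1 (anticlinal elongation) in a micropylar sub-domain.  A
second, ii1'-like layer can carry injected gaps in its chalazal third
at the few-percent scale reported for the corresponding mutant.

Determinism: one root seed; each specimen's RNG stream is derived from
(root seed, group index, specimen index), so changing cohort size never
reshuffles earlier specimens.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import skimage.draw
import warnings

from .errors import InvalidSpecError, OutOfBoundsError, OverlapWarning
from .geometry import CellPolygon

__all__ = [
    "ConstantField",
    "LinearField",
    "ScaledField",
    "SubdomainField",
    "LayerSpec",
    "GroupEffect",
    "CohortSpec",
    "LayerGroundTruth",
    "Specimen",
    "Cohort",
    "synthesize_layer",
    "synthesize_cohort",
    "render_label_image",
    "default_endothelium_layer",
    "default_ii1prime_layer",
    "default_mutant_effect",
    "default_cohort_spec",
]


# ---------------------------------------------------------------------------
# Axis fields: scalar functions of normalised position s in [0, 1].


@dataclass(frozen=True)
class ConstantField:
    value: float

    def __call__(self, s: float) -> float:
        return self.value


@dataclass(frozen=True)
class LinearField:
    """Linear ramp from ``start`` at s=0 to ``stop`` at s=1."""

    start: float
    stop: float

    def __call__(self, s: float) -> float:
        return self.start + (self.stop - self.start) * s


@dataclass(frozen=True)
class ScaledField:
    base: object
    factor: float

    def __call__(self, s: float) -> float:
        return self.factor * self.base(s)


@dataclass(frozen=True)
class SubdomainField:
    """Override the base field with a constant inside an s-interval."""

    base: object
    interval: tuple[float, float]
    value: float

    def __call__(self, s: float) -> float:
        lo, hi = self.interval
        return self.value if lo <= s <= hi else self.base(s)


def _as_field(x):
    return ConstantField(float(x)) if isinstance(x, (int, float)) else x


# ---------------------------------------------------------------------------
# Specs.


@dataclass(frozen=True)
class LayerSpec:
    """Parametrisation of one generated cell layer.

    ``arc_span`` of None lets the midline length emerge from the cells
    (realistic: bigger cells make a longer layer); a numeric span
    rescales all cells so they fill exactly ``arc_radius * arc_span``.
    ``cell_cv`` is the per-cell lognormal coefficient of variation of
    area and aspect draws; ``vertex_noise`` the Gaussian SD (µm) added
    to each corner.  ``gap_fraction`` is the target ratio of removed
    arc length to region length within ``gap_region`` (an s-interval).
    """

    layer_id: str = "endothelium"
    n_cells: int = 60
    midline: str = "arc"  # "arc" | "straight"
    arc_radius: float = 130.0
    arc_span: float | None = None
    area_field: object = LinearField(40.0, 90.0)
    aspect_field: object = LinearField(0.85, 0.55)
    orientation_jitter: float = 0.03
    vertex_noise: float = 0.15
    cell_cv: float = 0.08
    gap_fraction: float = 0.0
    gap_region: tuple[float, float] = (0.0, 1.0 / 3.0)

    def __post_init__(self):
        if self.n_cells < 2:
            raise InvalidSpecError("n_cells must be >= 2")
        if self.midline not in ("arc", "straight"):
            raise InvalidSpecError(f"unknown midline kind {self.midline!r}")
        if not (0.0 <= self.gap_fraction <= 0.5):
            raise InvalidSpecError("gap_fraction must be in [0, 0.5]")
        lo, hi = self.gap_region
        if not (0.0 <= lo < hi <= 1.0):
            raise InvalidSpecError("gap_region must be an interval within [0, 1]")


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative / override modifiers applied to one layer for group B."""

    area_scale: float = 1.0
    aspect_scale: float = 1.0
    aspect_subdomain: tuple[tuple[float, float], float] | None = None
    gap_fraction: float | None = None
    gap_region: tuple[float, float] | None = None

    def apply(self, spec: LayerSpec) -> LayerSpec:
        area_field = _as_field(spec.area_field)
        aspect_field = _as_field(spec.aspect_field)
        if self.area_scale != 1.0:
            area_field = ScaledField(area_field, self.area_scale)
        if self.aspect_scale != 1.0:
            aspect_field = ScaledField(aspect_field, self.aspect_scale)
        if self.aspect_subdomain is not None:
            interval, value = self.aspect_subdomain
            aspect_field = SubdomainField(aspect_field, tuple(interval), value)
        kwargs = dict(area_field=area_field, aspect_field=aspect_field)
        if self.gap_fraction is not None:
            kwargs["gap_fraction"] = self.gap_fraction
        if self.gap_region is not None:
            kwargs["gap_region"] = tuple(self.gap_region)
        return replace(spec, **kwargs)


@dataclass(frozen=True)
class CohortSpec:
    """Full parametrisation of a two-group synthetic dataset."""

    seed: int = 0
    n_specimens: tuple[int, int] = (33, 20)
    groups: tuple[str, str] = ("wt", "mutant")
    layers: tuple[LayerSpec, ...] = ()
    effects: dict = field(default_factory=dict)  # layer_id -> GroupEffect (group B)
    specimen_area_cv: float = 0.10
    specimen_aspect_cv: float = 0.06

    def __post_init__(self):
        if not self.layers:
            object.__setattr__(self, "layers", (default_endothelium_layer(),))


@dataclass(frozen=True)
class LayerGroundTruth:
    """True per-cell fields and gap structure of one generated layer."""

    specimen_id: str
    layer_id: str
    s: np.ndarray  # true axis position of each cell centre (arc-length frac.)
    area: np.ndarray  # µm², before vertex noise
    aspect: np.ndarray  # anticlinal : periclinal
    orientation: np.ndarray  # cell tangent angle, radians
    periclinal: np.ndarray  # µm
    gap_intervals: tuple[tuple[float, float], ...]  # s-intervals
    gap_fraction: float  # over gap_region
    gap_region: tuple[float, float]
    midline_length: float  # µm, including gaps
    start_point: np.ndarray  # proximal end of the midline, µm


@dataclass(frozen=True)
class Specimen:
    specimen_id: str
    group: str
    layers: dict  # layer_id -> (list[CellPolygon], LayerGroundTruth)


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    specimens: tuple[Specimen, ...]

    def group(self, label: str) -> list[Specimen]:
        return [sp for sp in self.specimens if sp.group == label]


# ---------------------------------------------------------------------------
# Layer synthesis.


def _midline_frame(spec: LayerSpec, t: np.ndarray):
    """Points, tangents and normals of the midline at arc lengths t."""
    if spec.midline == "straight":
        pts = np.column_stack([t, np.zeros_like(t)])
        tan = np.tile([1.0, 0.0], (len(t), 1))
        nor = np.tile([0.0, 1.0], (len(t), 1))
    else:
        r = spec.arc_radius
        phi = t / r
        pts = np.column_stack([r * np.sin(phi), r * (1.0 - np.cos(phi))])
        tan = np.column_stack([np.cos(phi), np.sin(phi)])
        nor = np.column_stack([-np.sin(phi), np.cos(phi)])
    return pts, tan, nor


def _quad(center, tangent, normal, length, height, jitter, noise, rng, cell_id):
    c, s = math.cos(jitter), math.sin(jitter)
    u = c * tangent + s * normal
    v = -s * tangent + c * normal
    base = np.array(
        [
            center - u * length / 2 - v * height / 2,
            center + u * length / 2 - v * height / 2,
            center + u * length / 2 + v * height / 2,
            center - u * length / 2 + v * height / 2,
        ]
    )
    for _ in range(10):
        verts = base + (rng.normal(0.0, noise, (4, 2)) if noise > 0 else 0.0)
        poly = shapely.Polygon(verts)
        if poly.is_valid and poly.area > 0:
            return verts
    raise InvalidSpecError(
        f"cell {cell_id}: vertex noise {noise} too large for cell size"
    )


def synthesize_layer(
    spec: LayerSpec,
    rng: np.random.Generator,
    specimen_id: str = "spec0",
) -> tuple[list[CellPolygon], LayerGroundTruth]:
    """Generate one layer of quadrilateral cells along the midline.

    Cells are returned in shuffled order (to exercise layer tracing);
    the ground truth records the true fields and the injected gap
    intervals in normalised arc-length coordinates.
    """
    n = spec.n_cells
    area_f = _as_field(spec.area_field)
    aspect_f = _as_field(spec.aspect_field)
    u = (np.arange(n) + 0.5) / n
    cv = spec.cell_cv
    area = np.array([area_f(ui) for ui in u])
    aspect = np.array([aspect_f(ui) for ui in u])
    if cv > 0:
        area = area * rng.lognormal(0.0, cv, n)
        aspect = aspect * rng.lognormal(0.0, cv, n)
    if np.any(area <= 0) or np.any(aspect <= 0):
        raise InvalidSpecError("area and aspect fields must be positive")
    length = np.sqrt(area / aspect)  # periclinal extent
    height = aspect * length  # anticlinal extent

    # Gap injection: remove arc length between consecutive cells inside
    # gap_region so that total_gap / (region fraction * midline length)
    # equals the target fraction exactly in arc-length terms.  The
    # midline length is the centroid polyline (half a cell is lost at
    # each end), D0 below.
    gap_after = np.zeros(n - 1)  # gap inserted after cell i
    gl, gh = spec.gap_region
    g = spec.gap_fraction
    if g > 0:
        d0 = float(np.sum(0.5 * (length[:-1] + length[1:])))
        width = gh - gl
        total_gap = g * width * d0 / (1.0 - g * width)
        cum = np.cumsum(0.5 * (length[:-1] + length[1:]))  # boundary positions on polyline
        frac = cum / d0
        margin = 0.05 * width
        eligible = np.nonzero((frac >= gl + margin) & (frac <= gh - margin))[0]
        if len(eligible) == 0:
            raise InvalidSpecError("gap_region too narrow to place any gap")
        k = min(int(rng.integers(1, 3)), len(eligible))
        sites = rng.choice(eligible, size=k, replace=False)
        shares = rng.dirichlet(np.full(k, 4.0)) if k > 1 else np.array([1.0])
        gap_after[sites] = total_gap * shares

    # Arc-length positions of cell centres.
    centers = np.empty(n)
    centers[0] = length[0] / 2.0
    for i in range(1, n):
        centers[i] = (
            centers[i - 1] + length[i - 1] / 2.0 + gap_after[i - 1] + length[i] / 2.0
        )
    total = centers[-1] + length[-1] / 2.0

    if spec.arc_span is not None:
        target = spec.arc_radius * spec.arc_span if spec.midline == "arc" else spec.arc_span
        scale = target / total
        length *= scale
        height *= scale
        area *= scale * scale
        centers *= scale
        gap_after *= scale
        total = target
    if spec.midline == "arc" and total / spec.arc_radius > 2.0 * math.pi:
        raise InvalidSpecError(
            f"cells span {total / spec.arc_radius:.2f} rad > 2*pi: layer self-overlaps"
        )

    pts, tan, nor = _midline_frame(spec, centers)
    jitter = (
        rng.normal(0.0, spec.orientation_jitter, n)
        if spec.orientation_jitter > 0
        else np.zeros(n)
    )
    cells = []
    for i in range(n):
        verts = _quad(
            pts[i], tan[i], nor[i], length[i], height[i], jitter[i],
            spec.vertex_noise, rng, f"c{i:03d}",
        )
        cells.append(
            CellPolygon(
                specimen_id=specimen_id,
                layer_id=spec.layer_id,
                cell_id=f"c{i:03d}",
                vertices=verts,
            )
        )

    # Ground truth in centroid-polyline coordinates (what trace_layer sees):
    # polyline runs from centers[0] to centers[-1].
    d_total = centers[-1] - centers[0]
    s_true = (centers - centers[0]) / d_total
    gap_intervals = []
    for i in np.nonzero(gap_after > 0)[0]:
        mid = 0.5 * (centers[i] + centers[i + 1]) - centers[0]
        half = gap_after[i] / 2.0
        gap_intervals.append(((mid - half) / d_total, (mid + half) / d_total))
    realized_fraction = float(np.sum(gap_after) / ((gh - gl) * d_total)) if g > 0 else 0.0
    orientation = np.arctan2(tan[:, 1], tan[:, 0]) + jitter

    truth = LayerGroundTruth(
        specimen_id=specimen_id,
        layer_id=spec.layer_id,
        s=s_true,
        area=area,
        aspect=aspect,
        orientation=orientation,
        periclinal=length,
        gap_intervals=tuple(gap_intervals),
        gap_fraction=realized_fraction,
        gap_region=(gl, gh),
        midline_length=float(d_total),
        start_point=pts[0].copy(),
    )
    perm = rng.permutation(n)
    return [cells[i] for i in perm], truth


def synthesize_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full two-group dataset with per-specimen variability.

    Group B layers receive the per-layer :class:`GroupEffect` from
    ``spec.effects``.  On top of the per-cell noise, each specimen draws
    one lognormal scale for area and one for aspect (biological
    specimen-to-specimen variation).
    """
    specimens = []
    for gi, (group, n_spec) in enumerate(zip(spec.groups, spec.n_specimens)):
        for si in range(n_spec):
            sid = f"{group}{si:03d}"
            layers = {}
            for layer_spec in spec.layers:
                ls = layer_spec
                if gi == 1 and layer_spec.layer_id in spec.effects:
                    ls = spec.effects[layer_spec.layer_id].apply(layer_spec)
                layer_tag = zlib.crc32(layer_spec.layer_id.encode()) % (2**31)
                rng = np.random.default_rng([spec.seed, gi, si, layer_tag])
                a_scale = (
                    rng.lognormal(0.0, spec.specimen_area_cv)
                    if spec.specimen_area_cv > 0
                    else 1.0
                )
                r_scale = (
                    rng.lognormal(0.0, spec.specimen_aspect_cv)
                    if spec.specimen_aspect_cv > 0
                    else 1.0
                )
                ls = replace(
                    ls,
                    area_field=ScaledField(_as_field(ls.area_field), a_scale),
                    aspect_field=ScaledField(_as_field(ls.aspect_field), r_scale),
                )
                layers[layer_spec.layer_id] = synthesize_layer(ls, rng, sid)
            specimens.append(Specimen(specimen_id=sid, group=group, layers=layers))
    return Cohort(spec=spec, specimens=tuple(specimens))


def shrink_cells(cells: list[CellPolygon], offset: float) -> list[CellPolygon]:
    """Inset every cell boundary by ``offset`` µm (half a wall thickness).

    Emulates the visible separation between neighbouring cell lumina in
    wall-stained images; rasterising shrunk cells gives each label its
    own pixels even where cells abut.
    """
    if offset < 0:
        raise InvalidSpecError("offset must be >= 0")
    out = []
    for c in cells:
        shrunk = c.shapely_polygon.buffer(-offset, join_style="mitre")
        if shrunk.is_empty or shrunk.geom_type != "Polygon":
            raise InvalidSpecError(
                f"cell {c.cell_id!r} vanishes at offset {offset} µm"
            )
        out.append(
            CellPolygon(
                specimen_id=c.specimen_id,
                layer_id=c.layer_id,
                cell_id=c.cell_id,
                vertices=np.asarray(shrunk.exterior.coords)[:-1],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Rasterisation.


def render_label_image(
    cells: list[CellPolygon],
    scale: float,
    shape: tuple[int, int] | None = None,
    origin: tuple[float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Rasterise cells into an integer label mask (background 0).

    ``scale`` is µm per pixel.  Pixel-centre convention with image y
    down: the centre of pixel (row r, col c) lies at
    ``x = x0 + (c + 0.5) * scale``, ``y = y0 + (H - r - 0.5) * scale``
    where (x0, y0) is the returned origin (lower-left corner).  Cells
    are labelled 1..K in input order; overlapping pixels are won by the
    later cell, with an :class:`OverlapWarning`.
    """
    if scale <= 0:
        raise InvalidSpecError("scale must be positive (µm per pixel)")
    if not cells:
        if shape is None:
            shape = (16, 16)
        return np.zeros(shape, dtype=np.int32), origin or (0.0, 0.0)
    allv = np.vstack([c.vertices for c in cells])
    if origin is None:
        origin = (
            float(allv[:, 0].min() - 2 * scale),
            float(allv[:, 1].min() - 2 * scale),
        )
    x0, y0 = origin
    if shape is None:
        w = int(math.ceil((allv[:, 0].max() - x0) / scale)) + 2
        h = int(math.ceil((allv[:, 1].max() - y0) / scale)) + 2
        shape = (h, w)
    h, w = shape
    xmax, ymax = x0 + w * scale, y0 + h * scale
    mask = np.zeros(shape, dtype=np.int32)
    for k, cell in enumerate(cells, start=1):
        v = cell.vertices
        if (
            v[:, 0].min() < x0
            or v[:, 0].max() > xmax
            or v[:, 1].min() < y0
            or v[:, 1].max() > ymax
        ):
            raise OutOfBoundsError(
                f"cell {cell.cell_id!r} falls outside the canvas"
            )
        cc_f = (v[:, 0] - x0) / scale - 0.5
        rr_f = (y0 + h * scale - v[:, 1]) / scale - 0.5
        rr, cc = skimage.draw.polygon(rr_f, cc_f, shape=shape)
        if np.any(mask[rr, cc] != 0):
            warnings.warn(
                f"cell {cell.cell_id!r} overlaps an earlier cell; later wins",
                OverlapWarning,
                stacklevel=2,
            )
        mask[rr, cc] = k
    return mask, origin


# ---------------------------------------------------------------------------
# Default study-condition specs.


def default_endothelium_layer() -> LayerSpec:
    """Endothelium-like layer: area rises and roundness falls distally."""
    return LayerSpec(
        layer_id="endothelium",
        n_cells=60,
        midline="arc",
        arc_radius=130.0,
        arc_span=None,
        area_field=LinearField(40.0, 90.0),
        aspect_field=LinearField(0.85, 0.55),
        orientation_jitter=0.03,
        vertex_noise=0.15,
        cell_cv=0.08,
    )


def default_ii1prime_layer(gap_fraction: float = 0.0) -> LayerSpec:
    """ii1'-like sub-epidermal layer; gaps injectable in its chalazal third."""
    return LayerSpec(
        layer_id="ii1prime",
        n_cells=45,
        midline="arc",
        arc_radius=140.0,
        arc_span=None,
        area_field=LinearField(80.0, 130.0),
        aspect_field=ConstantField(0.5),
        orientation_jitter=0.03,
        vertex_noise=0.15,
        cell_cv=0.08,
        gap_fraction=gap_fraction,
        gap_region=(0.0, 1.0 / 3.0),
    )


#: s-interval of the micropylar sub-domain carrying the mutant aspect shift.
MUTANT_ASPECT_INTERVAL = (0.75, 0.95)
#: Mutant aspect ratio inside that sub-domain (anticlinal elongation, GP > 1).
MUTANT_ASPECT_VALUE = 1.5


def default_mutant_effect() -> dict:
    """Mutant-like group effects: larger cells, anticlinal micropylar
    sub-domain in the endothelium; gaps in the ii1' chalazal third."""
    return {
        "endothelium": GroupEffect(
            area_scale=1.3,
            aspect_subdomain=(MUTANT_ASPECT_INTERVAL, MUTANT_ASPECT_VALUE),
        ),
        "ii1prime": GroupEffect(
            gap_fraction=0.046, gap_region=(0.0, 1.0 / 3.0)
        ),
    }


def default_cohort_spec(
    seed: int = 0,
    with_effect: bool = True,
    with_ii1prime: bool = False,
) -> CohortSpec:
    """The default two-group study design (n = 33 vs n = 20)."""
    layers = [default_endothelium_layer()]
    if with_ii1prime:
        layers.append(default_ii1prime_layer())
    return CohortSpec(
        seed=seed,
        n_specimens=(33, 20),
        groups=("wt", "mutant"),
        layers=tuple(layers),
        effects=default_mutant_effect() if with_effect else {},
    )
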