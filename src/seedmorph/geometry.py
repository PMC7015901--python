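"""Per-cell shape descriptors on simple polygons.

Cells segmented from longitudinal mid-plane sections of curved plant
tissues (here, seed-coat cell layers) are represented as simple 2-D
polygons in micrometres.  This module computes the classical descriptors
used to quantify tissue polarity along a cell layer:

* area and perimeter (shoelace closed forms on the vertex loop),
* roundness, by default the isoperimetric circularity ``4*pi*A / P**2``,
* periclinal length, the caliper extent of the cell along the local
  layer tangent,
* growth polarity ``GP = (P/L - 2) / 2``, which for a cell modelled as a
  rectangle of periclinal side ``L`` and anticlinal side ``a`` equals the
  anticlinal:periclinal aspect ratio ``a/L`` exactly.

``GP > 1`` therefore means a cell elongated across the layer
(anticlinally), ``GP < 1`` a cell elongated along it (periclinally).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely

from .errors import DegenerateShapeWarning, InvalidArgumentError, InvalidPolygonError

__all__ = [
    "CellPolygon",
    "polygon_area",
    "polygon_perimeter",
    "polygon_centroid",
    "roundness",
    "periclinal_length",
    "growth_polarity",
    "shape_descriptors",
]


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class CellPolygon:
    """One segmented cell outline with its identifiers.

    Vertices are in micrometres, implicitly closed, and are reoriented
    counter-clockwise on construction.  A closing duplicate of the first
    vertex and zero-length edges are removed.  Degenerate (fewer than 3
    distinct vertices, zero area) or self-intersecting outlines raise
    :class:`~seedmorph.errors.InvalidPolygonError`.
    """

    specimen_id: str
    layer_id: str
    cell_id: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidPolygonError(
                f"cell {self.cell_id!r}: vertices must be an (n, 2) array"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidPolygonError(f"cell {self.cell_id!r}: non-finite vertex")
        if len(v) >= 2 and np.array_equal(v[0], v[-1]):
            v = v[:-1]
        if len(v) >= 2:  # drop zero-length edges
            keep = np.ones(len(v), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(v, axis=0), axis=1) > 0.0
            v = v[keep]
        if len(v) < 3:
            raise InvalidPolygonError(
                f"cell {self.cell_id!r}: fewer than 3 distinct vertices"
            )
        a = _signed_area(v)
        if a == 0.0:
            raise InvalidPolygonError(f"cell {self.cell_id!r}: zero-area outline")
        if a < 0.0:
            v = v[::-1]
        if not shapely.Polygon(v).is_valid:
            raise InvalidPolygonError(
                f"cell {self.cell_id!r}: self-intersecting outline"
            )
        v = np.ascontiguousarray(v)
        v.flags.writeable = False
        object.__setattr__(self, "vertices", v)

    @property
    def shapely_polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self)

    def key(self) -> tuple[str, str, str]:
        return (self.specimen_id, self.layer_id, self.cell_id)


def polygon_area(poly: CellPolygon) -> float:
    """Shoelace area of the closed vertex loop, in µm²; always positive."""
    return _signed_area(poly.vertices)


def polygon_perimeter(poly: CellPolygon) -> float:
    """Sum of edge lengths including the closing edge, in µm."""
    v = poly.vertices
    edges = np.roll(v, -1, axis=0) - v
    return float(np.linalg.norm(edges, axis=1).sum())


def polygon_centroid(poly: CellPolygon) -> np.ndarray:
    """Area centroid of the polygon, in µm."""
    v = poly.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    cx = float(((x + xn) * cross).sum() / (6.0 * a))
    cy = float(((y + yn) * cross).sum() / (6.0 * a))
    return np.array([cx, cy])


def _moment_axis_ratio(poly: CellPolygon) -> float:
    # minor/major axis ratio of the area-moment-equivalent ellipse
    c = polygon_centroid(poly)
    v = poly.vertices - c
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    ixx = (cross * (y * y + y * yn + yn * yn)).sum() / 12.0
    iyy = (cross * (x * x + x * xn + xn * xn)).sum() / 12.0
    ixy = (cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)).sum() / 24.0
    cov = np.array([[iyy, ixy], [ixy, ixx]]) / a
    lam = np.linalg.eigvalsh(cov)
    if lam[1] <= 0:
        raise InvalidPolygonError(f"cell {poly.cell_id!r}: degenerate moments")
    return float(math.sqrt(max(lam[0], 0.0) / lam[1]))


def roundness(poly: CellPolygon, method: str = "circularity") -> float:
    """Dimensionless roundness of a cell, in (0, 1].

    ``method="circularity"`` (default) is the isoperimetric circularity
    ``4*pi*A / P**2``, equal to 1 only in the circle limit.
    ``method="ellipse"`` is the minor:major axis ratio of the
    moment-equivalent ellipse, provided as an alternative convention.
    """
    if method == "circularity":
        p = polygon_perimeter(poly)
        if p <= 0:
            raise InvalidPolygonError(f"cell {poly.cell_id!r}: zero perimeter")
        return 4.0 * math.pi * polygon_area(poly) / (p * p)
    if method == "ellipse":
        return _moment_axis_ratio(poly)
    raise InvalidArgumentError(f"unknown roundness method {method!r}")


def periclinal_length(poly: CellPolygon, tangent: np.ndarray) -> float:
    """Caliper extent of the cell along the local layer tangent, in µm.

    ``tangent`` is the unit direction of the cell layer at this cell; the
    periclinal length is ``max - min`` of the vertex projections onto it.
    """
    t = np.asarray(tangent, dtype=float)
    norm = np.linalg.norm(t)
    if not np.isfinite(norm) or norm == 0.0:
        raise InvalidArgumentError("tangent must be a nonzero 2-D vector")
    t = t / norm
    proj = poly.vertices @ t
    return float(proj.max() - proj.min())


def growth_polarity(perimeter: float, periclinal: float) -> float:
    """Growth polarity GP = (P/L - 2) / 2.

    ``P`` is the cell perimeter and ``L`` its periclinal length.  For a
    perfect a×L rectangle GP equals the anticlinal:periclinal ratio a/L.
    Requires ``P > 2L`` for the rectangle model to be non-degenerate;
    when ``P <= 2L`` (possible for discretised near-circular cells) the
    value ``<= 0`` is still returned, with a
    :class:`~seedmorph.errors.DegenerateShapeWarning`.
    """
    if not periclinal > 0:
        raise InvalidArgumentError("periclinal length must be positive")
    if not perimeter > 0:
        raise InvalidArgumentError("perimeter must be positive")
    gp = 0.5 * (perimeter / periclinal - 2.0)
    if gp <= 0.0:
        warnings.warn(
            f"P={perimeter:.6g} <= 2L={2 * periclinal:.6g}: rectangle model "
            "degenerate, GP <= 0",
            DegenerateShapeWarning,
            stacklevel=2,
        )
    return gp


def shape_descriptors(
    poly: CellPolygon,
    tangent: np.ndarray | None = None,
    roundness_method: str = "circularity",
) -> dict:
    """All per-cell descriptors as a flat dict.

    When ``tangent`` is None the periclinal length and growth polarity
    are reported as NaN (they require the layer direction).
    """
    area = polygon_area(poly)
    perim = polygon_perimeter(poly)
    out = {
        "area": area,
        "perimeter": perim,
        "roundness": roundness(poly, method=roundness_method),
        "periclinal_length": math.nan,
        "growth_polarity": math.nan,
        "gp_degenerate": False,
    }
    if tangent is not None:
        length = periclinal_length(poly, tangent)
        out["periclinal_length"] = length
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", DegenerateShapeWarning)
            out["growth_polarity"] = growth_polarity(perim, length)
        out["gp_degenerate"] = any(
            issubclass(w.category, DegenerateShapeWarning) for w in caught
        )
    return out
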