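"""Readers and writers for polygon tables, label images and cohorts.

Polygon tables come in two interchangeable on-disk forms:

* CSV with columns ``specimen_id, layer_id, cell_id, vertex_index,
  x_um, y_um`` (one row per vertex, UTF-8, header required);
* GeoJSON with one ``Polygon`` feature per cell carrying the three
  identifiers as properties.

Both round-trip losslessly.  Label images (integer masks, background
0, one label per cell) are converted to polygons by sub-pixel contour
extraction at the 0.5 iso-level followed by simplification at 0.25 px
tolerance; pixel coordinates are converted to µm with a mandatory
µm-per-pixel scale using the pixel-centre convention, image y down
mapped to Cartesian y up.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import skimage.measure

from .errors import SchemaError, SplitLabelWarning, UnsupportedGeometryError
from .geometry import CellPolygon

__all__ = [
    "read_polygons",
    "write_polygons",
    "read_polygons_csv",
    "write_polygons_csv",
    "read_polygons_geojson",
    "write_polygons_geojson",
    "ingest_label_image",
    "write_cohort",
]

CSV_COLUMNS = ["specimen_id", "layer_id", "cell_id", "vertex_index", "x_um", "y_um"]


def write_polygons_csv(cells: list[CellPolygon], path) -> None:
    rows = []
    for c in cells:
        for i, (x, y) in enumerate(c.vertices):
            rows.append((c.specimen_id, c.layer_id, c.cell_id, i, x, y))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_polygons_csv(path) -> list[CellPolygon]:
    df = pd.read_csv(path, dtype={"specimen_id": str, "layer_id": str, "cell_id": str})
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"polygon CSV {path}: missing column {col!r}")
    cells = []
    for key, grp in df.groupby(["specimen_id", "layer_id", "cell_id"], sort=False):
        grp = grp.sort_values("vertex_index")
        cells.append(
            CellPolygon(
                specimen_id=key[0],
                layer_id=key[1],
                cell_id=key[2],
                vertices=grp[["x_um", "y_um"]].to_numpy(dtype=float),
            )
        )
    return cells


def write_polygons_geojson(cells: list[CellPolygon], path) -> None:
    features = []
    for c in cells:
        ring = [[float(x), float(y)] for x, y in c.vertices]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "specimen_id": c.specimen_id,
                    "layer_id": c.layer_id,
                    "cell_id": c.cell_id,
                },
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_polygons_geojson(path) -> list[CellPolygon]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    cells = []
    for feat in data.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise UnsupportedGeometryError(
                f"{path}: unsupported geometry type {geom.get('type')!r} "
                "(only Polygon features are accepted)"
            )
        props = feat.get("properties") or {}
        for key in ("specimen_id", "layer_id", "cell_id"):
            if key not in props:
                raise SchemaError(f"{path}: feature missing property {key!r}")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        cells.append(
            CellPolygon(
                specimen_id=str(props["specimen_id"]),
                layer_id=str(props["layer_id"]),
                cell_id=str(props["cell_id"]),
                vertices=ring,
            )
        )
    return cells


def write_polygons(cells: list[CellPolygon], path, format: str | None = None) -> None:
    fmt = _resolve_format(path, format)
    if fmt == "csv":
        write_polygons_csv(cells, path)
    else:
        write_polygons_geojson(cells, path)


def read_polygons(path, format: str | None = None) -> list[CellPolygon]:
    fmt = _resolve_format(path, format)
    return read_polygons_csv(path) if fmt == "csv" else read_polygons_geojson(path)


def _resolve_format(path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        suffix = Path(path).suffix.lower()
        fmt = {".csv": "csv", ".geojson": "geojson", ".json": "geojson"}.get(suffix)
        if fmt is None:
            raise SchemaError(f"cannot infer polygon format from {path}")
    if fmt not in ("csv", "geojson"):
        raise SchemaError(f"unknown polygon format {fmt!r}")
    return fmt


def ingest_label_image(
    mask: np.ndarray,
    scale: float,
    specimen_id: str = "spec0",
    layer_id: str = "layer0",
    origin: tuple[float, float] = (0.0, 0.0),
    simplify_px: float = 0.25,
) -> list[CellPolygon]:
    """Extract one polygon per label from an integer mask.

    Boundaries are traced at the 0.5 iso-level of each label's binary
    mask (sub-pixel, marching squares), simplified with ``simplify_px``
    pixel tolerance, then scaled to µm (pixel-centre convention, image y
    down converted to Cartesian y up, lower-left at ``origin``).  A
    label split into several connected components yields one polygon
    per component with suffixed cell ids and a
    :class:`SplitLabelWarning`.
    """
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise SchemaError(f"label image must be integer, got dtype {mask.dtype}")
    if scale <= 0:
        raise SchemaError("scale must be positive (µm per pixel)")
    h = mask.shape[0]
    x0, y0 = origin
    cells = []
    for label in np.unique(mask):
        if label == 0:
            continue
        binary = mask == label
        comps, n_comp = skimage.measure.label(binary, return_num=True)
        if n_comp > 1:
            warnings.warn(
                f"label {label} has {n_comp} connected components; splitting",
                SplitLabelWarning,
                stacklevel=2,
            )
        for ci in range(1, n_comp + 1):
            comp = comps == ci
            padded = np.pad(comp.astype(float), 1)
            contours = skimage.measure.find_contours(padded, 0.5)
            if not contours:
                continue
            contour = max(contours, key=len) - 1.0  # undo padding offset
            line = shapely.LinearRing(contour)
            simplified = np.asarray(
                shapely.simplify(line, simplify_px).coords
            )
            rr, cc = simplified[:, 0], simplified[:, 1]
            x = x0 + (cc + 0.5) * scale
            y = y0 + (h - rr - 0.5) * scale
            cell_id = str(label) if n_comp == 1 else f"{label}.{ci}"
            cells.append(
                CellPolygon(
                    specimen_id=specimen_id,
                    layer_id=layer_id,
                    cell_id=cell_id,
                    vertices=np.column_stack([x, y]),
                )
            )
    return cells


def write_cohort(cohort, outdir, format: str = "csv") -> Path:
    """Write a synthetic cohort: one polygon file per specimen, a
    dataset manifest and a ground-truth manifest.

    Returns the path to ``manifest.json`` (loadable by the pipeline).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    truth = {}
    for sp in cohort.specimens:
        fname = f"{sp.specimen_id}.{'csv' if format == 'csv' else 'geojson'}"
        cells = [c for cells, _ in sp.layers.values() for c in cells]
        write_polygons(cells, outdir / fname, format=format)
        hints = {
            layer_id: [float(v) for v in gt.start_point]
            for layer_id, (_, gt) in sp.layers.items()
        }
        entries.append(
            {
                "specimen_id": sp.specimen_id,
                "group": sp.group,
                "path": fname,
                "start_hints": hints,
            }
        )
        truth[sp.specimen_id] = {
            layer_id: {
                "s": gt.s.tolist(),
                "area": gt.area.tolist(),
                "aspect": gt.aspect.tolist(),
                "orientation": gt.orientation.tolist(),
                "periclinal": gt.periclinal.tolist(),
                "gap_intervals": [list(gi) for gi in gt.gap_intervals],
                "gap_fraction": gt.gap_fraction,
                "gap_region": list(gt.gap_region),
                "midline_length": gt.midline_length,
                "start_point": [float(v) for v in gt.start_point],
            }
            for layer_id, (_, gt) in sp.layers.items()
        }
    manifest = {
        "seed": cohort.spec.seed,
        "groups": list(cohort.spec.groups),
        "layers": [ls.layer_id for ls in cohort.spec.layers],
        "specimens": entries,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh)
    return outdir / "manifest.json"
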