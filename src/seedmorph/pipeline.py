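"""End-to-end analysis pipeline over a dataset manifest.

The manifest lists specimens (polygon file or label masks, group
label, optional proximal start hints) plus the analysis parameters:
profile resolution N, region boundaries, contact tolerance, tier
alphas, t-test variant and seed.  The pipeline measures every cell,
traces every layer, quantifies gaps and layer size, builds group
profiles, and runs the two-group and region-wise per-position
comparisons, writing deterministic TSV tables (with the parameter
block as header comments) and optional profile plots.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InvalidArgumentError, SeedmorphError
from .io import ingest_label_image, read_polygons
from .layer import (
    DEFAULT_BOUNDARIES,
    DEFAULT_CONTACT_TOL,
    detect_gaps,
    layer_summary,
    measure_layer,
    trace_layer,
)
from .profiles import aggregate_group, compare_profiles, region_compare, resample_records

logger = logging.getLogger("seedmorph")

__all__ = ["AnalysisParams", "SpecimenEntry", "DatasetManifest", "PipelineResult", "run_pipeline"]

MEASUREMENTS = ("area", "roundness", "growth_polarity")


@dataclass(frozen=True)
class AnalysisParams:
    """Analysis parameters shared by every pipeline stage."""

    n_points: int = 201
    region_n_points: int = 67
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES
    contact_tol: float = DEFAULT_CONTACT_TOL
    alphas: tuple[float, float, float] = (0.05, 0.001, 1e-5)
    welch: bool = False
    adjust: str | None = None
    seed: int = 0
    gynobasal_interval: tuple[float, float] = (0.0, 0.5)
    roundness_method: str = "circularity"

    def __post_init__(self):
        if self.n_points < 2 or self.region_n_points < 2:
            raise InvalidArgumentError("profile resolutions must be >= 2")
        b1, b2 = self.boundaries
        if not (0 < b1 < b2 < 1):
            raise InvalidArgumentError("region boundaries out of order")
        if self.contact_tol < 0:
            raise InvalidArgumentError("contact_tol must be >= 0")

    def as_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "region_n_points": self.region_n_points,
            "boundaries": list(self.boundaries),
            "contact_tol": self.contact_tol,
            "alphas": list(self.alphas),
            "welch": self.welch,
            "adjust": self.adjust,
            "seed": self.seed,
            "gynobasal_interval": list(self.gynobasal_interval),
            "roundness_method": self.roundness_method,
        }


@dataclass(frozen=True)
class SpecimenEntry:
    """One specimen: either a polygon table or one mask per layer."""

    specimen_id: str
    group: str
    path: str | None = None  # polygon CSV / GeoJSON with all layers
    masks: dict = field(default_factory=dict)  # layer_id -> mask path
    scale: float | None = None  # µm per pixel, required with masks
    start_hints: dict = field(default_factory=dict)  # layer_id -> (x, y)


@dataclass(frozen=True)
class DatasetManifest:
    specimens: tuple[SpecimenEntry, ...]
    layers: tuple[str, ...]
    groups: tuple[str, ...]
    params: AnalysisParams = AnalysisParams()
    base_dir: Path = Path(".")

    @classmethod
    def from_json(cls, path, **param_overrides) -> "DatasetManifest":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        params = dict(data.get("params", {}))
        params.update(param_overrides)
        if "seed" in data and "seed" not in params:
            params["seed"] = data["seed"]
        for key in ("boundaries", "alphas", "gynobasal_interval"):
            if key in params and isinstance(params[key], list):
                params[key] = tuple(params[key])
        entries = tuple(
            SpecimenEntry(
                specimen_id=e["specimen_id"],
                group=e["group"],
                path=e.get("path"),
                masks=e.get("masks", {}),
                scale=e.get("scale"),
                start_hints=e.get("start_hints", {}),
            )
            for e in data["specimens"]
        )
        return cls(
            specimens=entries,
            layers=tuple(data["layers"]),
            groups=tuple(data["groups"]),
            params=AnalysisParams(**params),
            base_dir=path.parent,
        )


@dataclass
class PipelineResult:
    outdir: Path
    tables: dict
    skipped: list
    comparisons: dict  # (layer, measurement) -> ComparisonResult
    region_comparisons: dict  # (group, layer, measurement, pair) -> ComparisonResult


def _load_specimen_cells(entry: SpecimenEntry, base_dir: Path):
    if entry.path is not None:
        return read_polygons(base_dir / entry.path)
    if not entry.masks:
        raise SeedmorphError(f"specimen {entry.specimen_id}: no input files")
    if entry.scale is None:
        raise SeedmorphError(f"specimen {entry.specimen_id}: masks need a µm/px scale")
    import tifffile

    cells = []
    for layer_id, mpath in entry.masks.items():
        mask = tifffile.imread(base_dir / mpath)
        cells.extend(
            ingest_label_image(
                mask, entry.scale, specimen_id=entry.specimen_id, layer_id=layer_id
            )
        )
    return cells


def _write_tsv(df: pd.DataFrame, path: Path, params: AnalysisParams) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# seedmorph {__version__}\n")
        for key, value in params.as_dict().items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(
    manifest: DatasetManifest, outdir, plots: bool = False
) -> PipelineResult:
    """Run measurement, tracing, gap, profile and comparison stages.

    Per-specimen failures are logged and skipped; the run completes on
    the remaining specimens and reports what was skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = manifest.params

    morpho_rows: list[pd.DataFrame] = []
    gap_rows = []
    summary_rows = []
    gaps_by_spec_layer: dict[tuple[str, str], list] = {}
    skipped = []

    for entry in manifest.specimens:
        try:
            cells = _load_specimen_cells(entry, manifest.base_dir)
        except Exception as exc:  # noqa: BLE001 - continue on bad specimen
            logger.warning("specimen %s: load failed: %s", entry.specimen_id, exc)
            skipped.append((entry.specimen_id, str(exc)))
            continue
        by_layer: dict[str, list] = {}
        for c in cells:
            by_layer.setdefault(c.layer_id, []).append(c)
        for layer_id in manifest.layers:
            if layer_id not in by_layer:
                continue
            try:
                hint = entry.start_hints.get(layer_id)
                trace = trace_layer(
                    by_layer[layer_id],
                    start_hint=None if hint is None else np.asarray(hint),
                    contact_tol=params.contact_tol,
                )
                records = measure_layer(
                    trace, params.boundaries, params.roundness_method
                )
                records.insert(0, "group", entry.group)
                morpho_rows.append(records)
                report = detect_gaps(trace, params.contact_tol)
                chalazal = detect_gaps(
                    trace, params.contact_tol, region=(0.0, params.boundaries[0])
                )
                gaps_by_spec_layer[(entry.specimen_id, layer_id)] = [
                    (g0, g1) for (g0, g1, _) in report.gaps
                ]
                gap_rows.append(
                    {
                        "specimen_id": entry.specimen_id,
                        "group": entry.group,
                        "layer_id": layer_id,
                        "n_gaps": len(report.gaps),
                        "total_gap_length": report.total_gap_length,
                        "layer_length": report.layer_length,
                        "gap_fraction": report.gap_fraction,
                        "gap_fraction_chalazal": chalazal.gap_fraction,
                    }
                )
                for side, mask in (
                    ("whole", None),
                    ("gynobasal", params.gynobasal_interval),
                ):
                    summ = layer_summary(trace, mask, side=side)
                    summary_rows.append(
                        {
                            "specimen_id": entry.specimen_id,
                            "group": entry.group,
                            "layer_id": layer_id,
                            "side": side,
                            "length": summ.length,
                            "cell_count": summ.cell_count,
                        }
                    )
                logger.info(
                    "specimen %s layer %s: %d cells traced",
                    entry.specimen_id,
                    layer_id,
                    len(trace),
                )
            except Exception as exc:  # noqa: BLE001
                logger.warning(
                    "specimen %s layer %s: %s", entry.specimen_id, layer_id, exc
                )
                skipped.append((f"{entry.specimen_id}/{layer_id}", str(exc)))

    tables: dict[str, Path] = {}
    if not morpho_rows:
        raise SeedmorphError("no specimen could be processed")
    morpho = pd.concat(morpho_rows, ignore_index=True)
    tables["morphometry"] = outdir / "morphometry.tsv"
    _write_tsv(morpho, tables["morphometry"], params)
    tables["gaps"] = outdir / "gaps.tsv"
    _write_tsv(pd.DataFrame(gap_rows), tables["gaps"], params)
    tables["layer_summaries"] = outdir / "layer_summaries.tsv"
    _write_tsv(pd.DataFrame(summary_rows), tables["layer_summaries"], params)

    # Group profiles and two-group comparisons.
    comparisons = {}
    for layer_id in manifest.layers:
        sub = morpho[morpho["layer_id"] == layer_id]
        if sub.empty:
            continue
        for measurement in MEASUREMENTS:
            group_mats = {}
            prof_frames = []
            for group in manifest.groups:
                rows = []
                for spec_id, spec_records in sub[sub["group"] == group].groupby(
                    "specimen_id"
                ):
                    rows.append(
                        resample_records(
                            spec_records,
                            measurement,
                            params.n_points,
                            gaps_by_spec_layer.get((spec_id, layer_id)),
                        )
                    )
                if rows:
                    group_mats[group] = np.array(rows)
                    prof = aggregate_group(group_mats[group], group, measurement)
                    pf = prof.to_frame()
                    pf.insert(0, "measurement", measurement)
                    pf.insert(0, "group", group)
                    prof_frames.append(pf)
            if prof_frames:
                name = f"profiles_{layer_id}_{measurement}"
                tables[name] = outdir / f"{name}.tsv"
                _write_tsv(pd.concat(prof_frames, ignore_index=True), tables[name], params)
            if len(group_mats) == 2:
                ga, gb = manifest.groups[:2]
                result = compare_profiles(
                    group_mats[ga],
                    group_mats[gb],
                    group_a=ga,
                    group_b=gb,
                    measurement=measurement,
                    welch=params.welch,
                    adjust=params.adjust,
                )
                comparisons[(layer_id, measurement)] = result
                name = f"comparison_{layer_id}_{measurement}"
                tables[name] = outdir / f"{name}.tsv"
                _write_tsv(result.to_frame(), tables[name], params)
                name = f"runs_{layer_id}_{measurement}"
                tables[name] = outdir / f"{name}.tsv"
                _write_tsv(result.runs_frame(), tables[name], params)
                if plots:
                    from .plotting import plot_comparison

                    plot_comparison(
                        result, outdir / f"comparison_{layer_id}_{measurement}.png"
                    )

    # Within-group region comparisons (region sub-axes at region_n_points).
    region_results = {}
    region_run_rows = []
    for layer_id in manifest.layers:
        sub = morpho[morpho["layer_id"] == layer_id]
        for group in manifest.groups:
            gsub = sub[sub["group"] == group]
            if gsub.empty:
                continue
            for measurement in MEASUREMENTS:
                results = region_compare(
                    gsub,
                    measurement=measurement,
                    n_points=params.region_n_points,
                    boundaries=params.boundaries,
                    welch=params.welch,
                )
                for pair, res in results.items():
                    region_results[(group, layer_id, measurement, pair)] = res
                    for tier, intervals in res.runs.items():
                        for (i0, i1, s0, s1) in intervals:
                            region_run_rows.append(
                                {
                                    "group": group,
                                    "layer_id": layer_id,
                                    "measurement": measurement,
                                    "region_a": pair[0],
                                    "region_b": pair[1],
                                    "tier": tier,
                                    "s_start": s0,
                                    "s_end": s1,
                                }
                            )
    tables["region_runs"] = outdir / "region_runs.tsv"
    _write_tsv(
        pd.DataFrame(
            region_run_rows,
            columns=[
                "group",
                "layer_id",
                "measurement",
                "region_a",
                "region_b",
                "tier",
                "s_start",
                "s_end",
            ],
        ),
        tables["region_runs"],
        params,
    )

    log = {
        "version": __version__,
        "params": params.as_dict(),
        "n_specimens": len(manifest.specimens),
        "skipped": skipped,
        "tables": {k: str(v.name) for k, v in tables.items()},
    }
    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    return PipelineResult(
        outdir=outdir,
        tables=tables,
        skipped=skipped,
        comparisons=comparisons,
        region_comparisons=region_results,
    )
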