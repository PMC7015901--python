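"""Axis profiles and per-position two-group comparisons.

Per-cell measurements of one specimen are resampled onto N fixed
positions along the normalised proximal-distal axis (the figures in
this field typically use N = 67 for within-genotype region profiles and
N = 201 for genotype-vs-genotype profiles).  Each cell is treated as a
step function of s occupying the interval between midpoints to its
neighbours; a position falling exactly on a boundary belongs to the
distal cell.

Group profiles are per-position arithmetic means with sample standard
deviations over specimens (n per position, since a specimen may not
cover every position, e.g. inside a gap).  Two groups are compared with
an independent two-sample Student's t-test (pooled variance by default,
Welch optional) at every position, tiered at P < 0.05, P < 0.001 and
P < 0.00001, and maximal contiguous runs of significant positions are
reported per tier.  No multiple-testing correction is applied by
default; Benjamini-Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError
from .layer import DEFAULT_BOUNDARIES, REGIONS

__all__ = [
    "TIER_ALPHAS",
    "Profile",
    "ComparisonResult",
    "resample_profile",
    "resample_records",
    "aggregate_group",
    "compare_profiles",
    "region_compare",
]

#: Significance tiers, most to least stringent, keyed by label.
TIER_ALPHAS = {"p05": 0.05, "p001": 0.001, "p00001": 1e-5}


@dataclass(frozen=True)
class Profile:
    """Per-position group mean/SD/n of one measurement along the axis."""

    group: str
    measurement: str
    positions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "mean": self.mean,
                "sd": self.sd,
                "n": self.n,
            }
        )


@dataclass(frozen=True)
class ComparisonResult:
    """Per-position two-group t-test results with tiered significance runs.

    ``tier`` holds one of ``ns``, ``p05``, ``p001``, ``p00001`` per
    position (the most stringent threshold passed).  ``runs`` maps each
    tier label to maximal contiguous runs ``(i0, i1, s0, s1)`` of
    positions with ``p < alpha`` for that tier's alpha — so the p05 runs
    contain the p001 runs, which contain the p00001 runs (nesting).
    """

    group_a: str
    group_b: str
    measurement: str
    positions: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    sd_a: np.ndarray
    sd_b: np.ndarray
    t: np.ndarray
    p: np.ndarray
    tier: np.ndarray
    runs: dict[str, list[tuple[int, int, float, float]]]
    degenerate: np.ndarray

    def tier_positions(self, tier: str) -> np.ndarray:
        """Indices of positions significant at the given tier's alpha."""
        alpha = TIER_ALPHAS[tier]
        with np.errstate(invalid="ignore"):
            return np.nonzero(self.p < alpha)[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "mean_a": self.mean_a,
                "sd_a": self.sd_a,
                "n_a": self.n_a,
                "mean_b": self.mean_b,
                "sd_b": self.sd_b,
                "n_b": self.n_b,
                "t": self.t,
                "p": self.p,
                "tier": self.tier,
            }
        )

    def runs_frame(self) -> pd.DataFrame:
        rows = [
            {"tier": tier, "i_start": i0, "i_end": i1, "s_start": s0, "s_end": s1}
            for tier, intervals in self.runs.items()
            for (i0, i1, s0, s1) in intervals
        ]
        return pd.DataFrame(
            rows, columns=["tier", "i_start", "i_end", "s_start", "s_end"]
        )


def profile_positions(n_points: int) -> np.ndarray:
    """The N equally spaced axis positions j/(N-1), including both ends."""
    if n_points < 2:
        raise InvalidArgumentError("n_points must be >= 2")
    return np.linspace(0.0, 1.0, n_points)


def resample_profile(
    s: np.ndarray,
    values: np.ndarray,
    n_points: int,
    gaps: list[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Sample a per-cell measurement at N fixed axis positions.

    The measurement is a step function of s: cell i occupies the
    interval between the midpoints to its neighbours (first cell from 0,
    last cell to 1), boundaries distal-inclusive.  Positions strictly
    inside a gap interval are returned as NaN (no cell covers them).
    """
    s = np.asarray(s, dtype=float)
    values = np.asarray(values, dtype=float)
    if s.size == 0:
        raise InvalidArgumentError("no records to resample")
    if s.size != values.size:
        raise InvalidArgumentError("s and values must have equal length")
    order = np.argsort(s, kind="stable")
    s, values = s[order], values[order]
    pos = profile_positions(n_points)
    mids = 0.5 * (s[1:] + s[:-1])
    idx = np.searchsorted(mids, pos, side="right")
    out = values[idx]
    if gaps:
        for g0, g1, *_ in gaps:
            out[(pos > g0) & (pos < g1)] = np.nan
    return out


def resample_records(
    records: pd.DataFrame,
    measurement: str,
    n_points: int,
    gaps: list[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Resample one measurement column of a per-cell morphometry table."""
    if measurement not in records.columns:
        raise InvalidArgumentError(f"no column {measurement!r} in records")
    return resample_profile(
        records["s"].to_numpy(), records[measurement].to_numpy(), n_points, gaps
    )


def _column_stats(samples: np.ndarray):
    n = np.sum(np.isfinite(samples), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice nanmean
        mean = np.nanmean(samples, axis=0)
        sd = np.nanstd(samples, axis=0, ddof=1)
    mean = np.where(n >= 1, mean, np.nan)
    sd = np.where(n >= 2, sd, np.nan)
    return mean, sd, n


def aggregate_group(
    samples: np.ndarray, group: str, measurement: str
) -> Profile:
    """Per-position mean, sample SD (n-1) and n over a group's specimens.

    ``samples`` is (n_specimens, N); NaN entries (positions a specimen
    does not cover) are dropped from that position's sample.  Positions
    with fewer than 2 contributing specimens get SD = NaN.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    mean, sd, n = _column_stats(samples)
    return Profile(
        group=group,
        measurement=measurement,
        positions=profile_positions(samples.shape[1]),
        mean=mean,
        sd=sd,
        n=n,
    )


def _runs_of(mask: np.ndarray, positions: np.ndarray):
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((i, j, float(positions[i]), float(positions[j])))
            i = j + 1
        else:
            i += 1
    return runs


def compare_profiles(
    a: np.ndarray,
    b: np.ndarray,
    group_a: str = "A",
    group_b: str = "B",
    measurement: str = "value",
    welch: bool = False,
    adjust: str | None = None,
) -> ComparisonResult:
    """Independent two-sample t-test at every axis position.

    ``a`` and ``b`` are (n_specimens, N) arrays resampled at the same N.
    The classical pooled-variance Student's t-test is used by default
    (``welch=True`` switches to the Welch unequal-variance variant), all
    two-tailed.  Degenerate positions: zero pooled variance with equal
    means gives t = 0, p = 1; with unequal means t = ±inf, p = 0, and
    the position is flagged in ``degenerate``.  ``adjust="bh"`` applies
    Benjamini-Hochberg correction to the p-values before tiering.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise InvalidArgumentError(
            f"groups resampled at different N: {a.shape[1]} vs {b.shape[1]}"
        )
    mean_a, sd_a, n_a = _column_stats(a)
    mean_b, sd_b, n_b = _column_stats(b)
    va, vb = sd_a**2, sd_b**2

    valid = (n_a >= 2) & (n_b >= 2)
    diff = mean_a - mean_b
    with np.errstate(invalid="ignore", divide="ignore"):
        if welch:
            se2 = va / n_a + vb / n_b
            df = se2**2 / (
                (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
            )
        else:
            sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
            se2 = sp2 * (1.0 / n_a + 1.0 / n_b)
            df = n_a + n_b - 2
        t = diff / np.sqrt(se2)

    with np.errstate(invalid="ignore"):
        degenerate = valid & (se2 == 0.0)
        t = np.where(degenerate & (diff == 0.0), 0.0, t)
        t = np.where(degenerate & (diff != 0.0), np.sign(diff) * np.inf, t)
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.where(degenerate & (diff == 0.0), 1.0, p)
    p = np.where(degenerate & (diff != 0.0), 0.0, p)
    t = np.where(valid, t, np.nan)
    p = np.where(valid, p, np.nan)

    if adjust == "bh":
        finite = np.isfinite(p)
        if finite.any():
            p = p.copy()
            p[finite] = stats.false_discovery_control(p[finite], method="bh")
    elif adjust is not None:
        raise InvalidArgumentError(f"unknown adjustment {adjust!r}")

    positions = profile_positions(a.shape[1])
    tier = np.full(a.shape[1], "ns", dtype=object)
    with np.errstate(invalid="ignore"):
        for label, alpha in sorted(TIER_ALPHAS.items(), key=lambda kv: -kv[1]):
            tier[np.nan_to_num(p, nan=1.0) < alpha] = label
    runs = {
        label: _runs_of(np.nan_to_num(p, nan=1.0) < alpha, positions)
        for label, alpha in TIER_ALPHAS.items()
    }
    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        measurement=measurement,
        positions=positions,
        n_a=n_a,
        n_b=n_b,
        mean_a=mean_a,
        mean_b=mean_b,
        sd_a=sd_a,
        sd_b=sd_b,
        t=t,
        p=p,
        tier=np.asarray(tier),
        runs=runs,
        degenerate=degenerate,
    )


def region_compare(
    records: pd.DataFrame,
    measurement: str = "area",
    n_points: int = 67,
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES,
    welch: bool = False,
) -> dict[tuple[str, str], ComparisonResult]:
    """Pairwise per-position comparisons among the three axis regions.

    For each specimen and region, the cells of that region are
    re-parametrised on the region's own normalised sub-axis and
    resampled at ``n_points``; the three region profiles of one group
    are then compared pairwise position by position (same tiering
    machinery as :func:`compare_profiles`).  ``records`` must carry
    specimen_id, s, region and the measurement column.
    """
    b1, b2 = boundaries
    bounds = {
        REGIONS[0]: (0.0, b1),
        REGIONS[1]: (b1, b2),
        REGIONS[2]: (b2, 1.0),
    }
    specimens = sorted(records["specimen_id"].unique())
    matrices: dict[str, np.ndarray] = {}
    for region, (lo, hi) in bounds.items():
        rows = []
        for spec in specimens:
            sub = records[
                (records["specimen_id"] == spec) & (records["region"] == region)
            ]
            if len(sub) == 0:
                rows.append(np.full(n_points, np.nan))
                continue
            s_local = (sub["s"].to_numpy() - lo) / (hi - lo)
            rows.append(
                resample_profile(s_local, sub[measurement].to_numpy(), n_points)
            )
        matrices[region] = np.array(rows)
    out: dict[tuple[str, str], ComparisonResult] = {}
    for i in range(len(REGIONS)):
        for j in range(i + 1, len(REGIONS)):
            ra, rb = REGIONS[i], REGIONS[j]
            out[(ra, rb)] = compare_profiles(
                matrices[ra],
                matrices[rb],
                group_a=ra,
                group_b=rb,
                measurement=measurement,
                welch=welch,
            )
    return out
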