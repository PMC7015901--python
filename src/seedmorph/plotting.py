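"""Profile-panel plots: group mean ± SD with tiered significance bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .profiles import ComparisonResult, Profile

__all__ = ["plot_profiles", "plot_comparison"]

TIER_COLOURS = {"p05": "tab:green", "p001": "tab:orange", "p00001": "tab:red"}


def plot_profiles(profiles: list[Profile], path, title: str | None = None) -> None:
    """Mean ± SD bands of one measurement for one or more groups."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for prof in profiles:
        ax.plot(prof.positions, prof.mean, label=prof.group)
        ax.fill_between(
            prof.positions,
            prof.mean - prof.sd,
            prof.mean + prof.sd,
            alpha=0.2,
        )
    ax.set_xlabel("normalised proximal-distal position s")
    ax.set_ylabel(profiles[0].measurement if profiles else "")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_comparison(result: ComparisonResult, path) -> None:
    """Two-group profile panel with per-tier significance bars on top."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for mean, sd, label in (
        (result.mean_a, result.sd_a, result.group_a),
        (result.mean_b, result.sd_b, result.group_b),
    ):
        ax.plot(result.positions, mean, label=label)
        ax.fill_between(result.positions, mean - sd, mean + sd, alpha=0.2)
    top = ax.get_ylim()[1]
    span = top - ax.get_ylim()[0]
    for k, (tier, colour) in enumerate(TIER_COLOURS.items()):
        y = top + (k + 1) * 0.04 * span
        for (_, _, s0, s1) in result.runs.get(tier, []):
            ax.plot([s0, s1], [y, y], color=colour, lw=3, solid_capstyle="butt")
    ax.set_xlabel("normalised proximal-distal position s")
    ax.set_ylabel(result.measurement)
    ax.set_title(f"{result.group_a} vs {result.group_b}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
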