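"""Figure helpers: gaze-shift rate timecourses, time-magnitude difference
maps, and lateralization overlays. Advisory output only — the numbers live
in the analysis report."""

from __future__ import annotations

import numpy as np

__all__ = [
    "plot_rate_timecourses",
    "plot_magnitude_map",
    "plot_lateralization_overlay",
]


def _ax(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(6, 4))
    return ax


def plot_rate_timecourses(times, rate_toward, rate_away, ax=None):
    """Toward vs away gaze-shift rate (shifts/s) over time."""
    ax = _ax(ax)
    ax.plot(times, rate_toward, color="seagreen", label="toward")
    ax.plot(times, rate_away, color="rebeccapurple", label="away")
    ax.axvspan(200, 600, color="0.9", zorder=0)
    ax.set_xlabel("time after cue (ms)")
    ax.set_ylabel("gaze-shift rate (shifts/s)")
    ax.legend(frameon=False)
    return ax


def plot_magnitude_map(times, mag_bins, diff_map, ax=None, ecc_deg: float = 5.7):
    """Toward-minus-away shift rate over time x magnitude; dashed lines mark
    1 degree and the item eccentricity (100%)."""
    ax = _ax(ax)
    vmax = np.nanmax(np.abs(diff_map)) or 1.0
    im = ax.pcolormesh(
        times, mag_bins, diff_map, cmap="RdBu_r", vmin=-vmax, vmax=vmax, shading="auto"
    )
    ax.axhline(100.0 / ecc_deg, ls="--", color="k", lw=0.8)  # 1 degree
    ax.axhline(100.0, ls="--", color="k", lw=0.8)
    ax.set_xlabel("time after cue (ms)")
    ax.set_ylabel("shift magnitude (%)")
    ax.figure.colorbar(im, ax=ax, label="toward - away (shifts/s)")
    return ax


def plot_lateralization_overlay(times, timecourses: dict, cluster_masks: dict | None = None, ax=None):
    """Overlay alpha-lateralization timecourses (%), one line per condition,
    with optional significant-cluster underlines."""
    ax = _ax(ax)
    colors = {"toward": "seagreen", "none": "0.4", "away": "rebeccapurple",
              "early": "tab:blue", "late": "tab:orange"}
    y0 = min(np.nanmin(v) for v in timecourses.values())
    for i, (name, vals) in enumerate(timecourses.items()):
        ax.plot(times, vals, label=name, color=colors.get(name))
        if cluster_masks and name in cluster_masks and cluster_masks[name] is not None:
            m = np.asarray(cluster_masks[name], dtype=bool)
            y = y0 * (1.05 + 0.05 * i)
            ax.plot(np.asarray(times)[m], np.full(m.sum(), y), ".", ms=2,
                    color=colors.get(name))
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time after cue (ms)")
    ax.set_ylabel("alpha lateralization (%)")
    ax.legend(frameon=False)
    return ax
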