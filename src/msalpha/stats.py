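"""Permutation inference and behavioural statistics.

Implements the study's inferential machinery:

* cluster-based permutation tests over time or time-frequency grids
  (mass-univariate t at a two-sided 0.05 cluster-forming threshold, clusters
  of adjacent same-signed points, cluster mass = sum of t values, null
  distribution of the largest \\|mass\\| from participant-level sign flips or
  condition swaps);
* half-peak latency of a lateralization timecourse with a condition-swap
  permutation test of latency differences;
* behavioural trial trimming (RT > 3000 ms, then per-participant 2.5 SD) and
  class comparisons (repeated-measures ANOVA plus Bonferroni-corrected
  paired t-tests with Cohen's d).

Permutation p-values use the (b+1)/(B+1) convention by default so they are
never exactly zero; the plain proportion is available via ``p_convention``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "LatencyTestResult",
    "cluster_permutation_test",
    "half_peak_latency",
    "latency_permutation_test",
    "trim_behaviour",
    "behaviour_class_stats",
    "UndefinedLatencyError",
]

N_PERMUTATIONS = 10_000
CLUSTER_ALPHA = 0.05


class UndefinedLatencyError(RuntimeError):
    """The timecourse never reaches half of its peak in the search window."""


@dataclass
class Cluster:
    mask: np.ndarray  # boolean over the point grid
    mass: float  # sum of t values (signed)
    p: float

    def to_dict(self) -> dict:
        idx = np.argwhere(self.mask)
        return {
            "n_points": int(self.mask.sum()),
            "extent": [[int(idx[:, k].min()), int(idx[:, k].max())] for k in range(idx.shape[1])],
            "mass": float(self.mass),
            "p": float(self.p),
        }


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    t_threshold: float
    n_permutations: int
    exhaustive: bool = False
    cluster_alpha: float = CLUSTER_ALPHA

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.min_p < alpha

    def to_dict(self) -> dict:
        return {
            "clusters": [c.to_dict() for c in self.clusters],
            "t_threshold": float(self.t_threshold),
            "n_permutations": int(self.n_permutations),
            "exhaustive": bool(self.exhaustive),
            "cluster_alpha": float(self.cluster_alpha),
        }


@dataclass
class LatencyTestResult:
    half_peak_early_ms: float
    half_peak_late_ms: float
    observed_diff_ms: float
    p: float
    n_permutations: int
    n_undefined: int = 0

    def to_dict(self) -> dict:
        return {
            "half_peak_early_ms": float(self.half_peak_early_ms),
            "half_peak_late_ms": float(self.half_peak_late_ms),
            "observed_diff_ms": float(self.observed_diff_ms),
            "p": float(self.p),
            "n_permutations": int(self.n_permutations),
            "n_undefined": int(self.n_undefined),
        }


# --------------------------------------------------------------------------
# cluster-based permutation test


def _t_from_means(means: np.ndarray, msq: np.ndarray, n: int) -> np.ndarray:
    """One-sample t from per-point means, given fixed mean-square E[x^2]."""
    var = (msq - means**2) * (n / (n - 1))
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    degenerate = var == 0
    if np.any(degenerate):
        t = np.asarray(t)
        with np.errstate(invalid="ignore"):
            t[degenerate] = np.sign(means[degenerate]) * np.inf
        t[degenerate & (means == 0)] = 0.0
    return t


def _clusters_from_tmap(
    t_map: np.ndarray, threshold: float
) -> list[tuple[np.ndarray, float]]:
    """Same-signed suprathreshold clusters under 4-neighbour adjacency."""
    out: list[tuple[np.ndarray, float]] = []
    for sign in (1.0, -1.0):
        supra = (sign * t_map) > threshold
        if not supra.any():
            continue
        if t_map.ndim == 1:
            edges = np.flatnonzero(np.diff(np.concatenate(([0], supra.view(np.int8), [0]))))
            for s, e in zip(edges[::2], edges[1::2]):
                mask = np.zeros_like(supra)
                mask[s:e] = True
                out.append((mask, float(t_map[s:e].sum())))
        else:
            structure = ndimage.generate_binary_structure(t_map.ndim, 1)  # no diagonals
            labels, nlab = ndimage.label(supra, structure=structure)
            for lab in range(1, nlab + 1):
                mask = labels == lab
                out.append((mask, float(t_map[mask].sum())))
    return out


def _max_cluster_mass(t_map: np.ndarray, threshold: float) -> float:
    masses = [abs(m) for _, m in _clusters_from_tmap(t_map, threshold)]
    return max(masses, default=0.0)


def cluster_permutation_test(
    data: np.ndarray,
    data_b: np.ndarray | None = None,
    n_permutations: int = N_PERMUTATIONS,
    cluster_alpha: float = CLUSTER_ALPHA,
    seed: int | np.random.Generator | None = 0,
    p_convention: str = "plus_one",
) -> ClusterTestResult:
    """Cluster-based permutation test against zero or between two conditions.

    ``data`` is participants x points (1-D time axis or 2-D time-frequency
    grid). With ``data_b`` given, the paired contrast ``data - data_b`` is
    tested; permutation is then equivalent to swapping condition labels
    within participants. The null distribution collects, per permutation of
    participant-level sign flips, the largest absolute cluster mass; each
    observed cluster's p-value is the proportion of permutations whose
    largest cluster exceeds it (two-sided by construction).

    When ``2**n_participants`` does not exceed ``n_permutations``, all
    distinct sign assignments are enumerated instead (with a notice in the
    result) and the plain-proportion p over the exhaustive set is used.
    """
    X = np.asarray(data, dtype=float)
    if data_b is not None:
        X = X - np.asarray(data_b, dtype=float)
    if X.ndim < 2:
        raise ValueError("data must be participants x points")
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 participants, got {n}")
    shape = X.shape[1:]
    Xf = X.reshape(n, -1)
    if np.isnan(Xf).any():
        raise ValueError("data contain NaN; mask or crop before testing")

    threshold = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, df=n - 1))
    msq = (Xf**2).mean(axis=0)
    t_obs = _t_from_means(Xf.mean(axis=0), msq, n).reshape(shape)
    observed = _clusters_from_tmap(t_obs, threshold)

    exhaustive = 2**n <= n_permutations
    if exhaustive:
        B = 2**n
        flips = (((np.arange(B)[:, None] >> np.arange(n)[None, :]) & 1) * 2 - 1).astype(float)
    else:
        B = n_permutations
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(B, n))

    null_max = np.empty(B)
    chunk = max(1, int(2e7 // max(Xf.shape[1], 1)))
    for lo in range(0, B, chunk):
        F = flips[lo : lo + chunk]
        means = F @ Xf / n
        tmaps = _t_from_means(means, msq, n)
        for k in range(F.shape[0]):
            null_max[lo + k] = _max_cluster_mass(tmaps[k].reshape(shape), threshold)

    clusters = []
    for mask, mass in observed:
        b = int((null_max >= abs(mass)).sum())
        if exhaustive or p_convention == "proportion":
            p = b / B
        else:
            p = (b + 1) / (B + 1)
        p = min(max(p, np.finfo(float).tiny), 1.0)
        clusters.append(Cluster(mask=mask, mass=mass, p=p))
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterTestResult(
        clusters=clusters,
        t_map=t_obs,
        t_threshold=threshold,
        n_permutations=B,
        exhaustive=exhaustive,
        cluster_alpha=cluster_alpha,
    )


# --------------------------------------------------------------------------
# half-peak latency


def half_peak_latency(
    time_ms: np.ndarray,
    values: np.ndarray,
    search_window: tuple[float, float] = (0.0, 1000.0),
    peak_sign: int | None = None,
) -> float:
    """First time a timecourse reaches half of its peak modulation.

    The peak is the extremum of the timecourse within ``search_window`` (by
    default the extremum of largest magnitude; pass ``peak_sign=-1`` to force
    the most negative value, appropriate for contralateral alpha
    attenuation). The crossing time is linearly interpolated between
    samples. Invariant under positive rescaling of the values.
    """
    t = np.asarray(time_ms, dtype=float)
    v = np.asarray(values, dtype=float)
    m = (t >= search_window[0]) & (t <= search_window[1]) & np.isfinite(v)
    if m.sum() < 2:
        raise UndefinedLatencyError("fewer than 2 finite samples in the search window")
    tw, vw = t[m], v[m]
    if peak_sign is None:
        peak = vw[np.argmax(np.abs(vw))]
    elif peak_sign < 0:
        peak = vw.min()
    else:
        peak = vw.max()
    if peak == 0:
        raise UndefinedLatencyError("timecourse is identically zero in the search window")
    half = peak / 2.0
    sign = np.sign(peak)
    reached = sign * vw >= sign * half
    if not reached.any():
        raise UndefinedLatencyError("timecourse never reaches half of its peak")
    i = int(np.argmax(reached))
    if i == 0:
        return float(tw[0])
    # linear interpolation between the last sub-half and first supra-half sample
    v0, v1 = vw[i - 1], vw[i]
    frac = (half - v0) / (v1 - v0) if v1 != v0 else 0.0
    return float(tw[i - 1] + frac * (tw[i] - tw[i - 1]))


def latency_permutation_test(
    early: np.ndarray,
    late: np.ndarray,
    time_ms: np.ndarray,
    n_permutations: int = N_PERMUTATIONS,
    search_window: tuple[float, float] = (0.0, 1000.0),
    peak_sign: int | None = -1,
    seed: int | np.random.Generator | None = 0,
    tail: str = "greater",
    max_undefined_frac: float = 0.05,
    p_convention: str = "plus_one",
) -> LatencyTestResult:
    """Permutation test of the half-peak latency difference (late - early).

    ``early``/``late`` are paired participants x times lateralization
    timecourses. The observed statistic is the difference between half-peak
    latencies of the two grand averages. Each permutation swaps the
    early/late labels within a random subset of participants and recomputes
    the grand-average latency difference. ``tail="greater"`` (default) counts
    permutations with a difference at least as large as observed;
    ``tail="two-sided"`` compares absolute differences. Aborts if the
    half-peak is undefined in more than ``max_undefined_frac`` of
    permutations.
    """
    E = np.asarray(early, dtype=float)
    L = np.asarray(late, dtype=float)
    if E.shape != L.shape:
        raise ValueError(f"early/late misaligned: {E.shape} vs {L.shape}")
    n = E.shape[0]
    hp = lambda ga: half_peak_latency(time_ms, ga, search_window, peak_sign)
    hp_early = hp(E.mean(axis=0))
    hp_late = hp(L.mean(axis=0))
    observed = hp_late - hp_early

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    swaps = rng.random((n_permutations, n)) < 0.5
    count = 0
    undefined = 0
    chunk = max(1, int(2e7 // max(E.shape[1], 1)))
    for lo in range(0, n_permutations, chunk):
        S = swaps[lo : lo + chunk].astype(float)[:, :, None]
        ga_e = (S * L[None] + (1 - S) * E[None]).mean(axis=1)
        ga_l = (S * E[None] + (1 - S) * L[None]).mean(axis=1)
        for k in range(ga_e.shape[0]):
            try:
                d = hp(ga_l[k]) - hp(ga_e[k])
            except UndefinedLatencyError:
                undefined += 1
                continue
            if tail == "two-sided":
                count += abs(d) >= abs(observed)
            else:
                count += d >= observed
    if undefined > max_undefined_frac * n_permutations:
        raise UndefinedLatencyError(
            f"half-peak undefined in {undefined}/{n_permutations} permutations; "
            "widen the search window or reduce noise"
        )
    B = n_permutations - undefined
    p = (count / B) if p_convention == "proportion" else (count + 1) / (B + 1)
    return LatencyTestResult(
        half_peak_early_ms=hp_early,
        half_peak_late_ms=hp_late,
        observed_diff_ms=observed,
        p=min(p, 1.0),
        n_permutations=B,
        n_undefined=undefined,
    )


# --------------------------------------------------------------------------
# behaviour


def trim_behaviour(
    trials: pd.DataFrame,
    rt_col: str = "rt_ms",
    participant_col: str = "participant",
    rt_max_ms: float = 3000.0,
    sd_cutoff: float = 2.5,
) -> pd.DataFrame:
    """Two-step RT trimming: drop RT > 3000 ms, then per-participant outliers
    beyond mean +/- 2.5 SD of the surviving RTs (strict inequalities, so a
    zero SD removes nothing). Applying the procedure twice is a fixed point
    only by re-running it; the steps are deliberately ordered."""
    step1 = trials[trials[rt_col] <= rt_max_ms]

    def keep(g: pd.DataFrame) -> pd.DataFrame:
        mu, sd = g[rt_col].mean(), g[rt_col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return g
        return g[(g[rt_col] > mu - sd_cutoff * sd) & (g[rt_col] < mu + sd_cutoff * sd)]

    out = (
        step1.groupby(participant_col, group_keys=False)[step1.columns]
        .apply(keep)
        .reset_index(drop=True)
    )
    return out


def _cohens_d_paired(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    sd = d.std(ddof=1)
    return float(d.mean() / sd) if sd > 0 else 0.0


def behaviour_class_stats(
    trials: pd.DataFrame,
    measure: str = "error_deg",
    class_col: str = "trial_class",
    participant_col: str = "participant",
    classes: tuple[str, ...] = ("toward", "none", "away"),
) -> dict:
    """Class-wise behavioural comparison across participants.

    Aggregates the measure to participant x class means, runs a one-way
    repeated-measures ANOVA (partial eta squared as effect size) and
    Bonferroni-corrected two-sided paired t-tests with paired Cohen's d.
    Participants missing any class are dropped with a warning.
    """
    import pingouin as pg

    df = trials[trials[class_col].isin(classes)]
    cell = (
        df.groupby([participant_col, class_col], observed=True)[measure]
        .mean()
        .unstack(class_col)
    )
    complete = cell.dropna(subset=list(classes))
    dropped = sorted(set(cell.index) - set(complete.index))
    if dropped:
        warnings.warn(f"participants dropped (missing a trial class): {dropped}")
    if complete.shape[0] < 2:
        raise ValueError("need >= 2 participants with all classes")

    long = complete[list(classes)].reset_index().melt(
        id_vars=participant_col, var_name=class_col, value_name=measure
    )
    aov = pg.rm_anova(
        data=long, dv=measure, within=class_col, subject=participant_col, effsize="np2"
    )
    n_pairs = len(classes) * (len(classes) - 1) // 2
    pairwise = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            t, p = sps.ttest_rel(complete[a], complete[b])
            pairwise[f"{a}_vs_{b}"] = {
                "t": float(t),
                "p_bonferroni": float(min(p * n_pairs, 1.0)),
                "cohens_d": _cohens_d_paired(complete[a], complete[b]),
            }
    return {
        "measure": measure,
        "n_participants": int(complete.shape[0]),
        "class_means": {c: float(complete[c].mean()) for c in classes},
        "anova": {
            "F": float(aov["F"].iloc[0]),
            "p": float(aov["p_unc"].iloc[0]),
            "partial_eta_sq": float(aov["np2"].iloc[0]),
            "ddof1": int(aov["ddof1"].iloc[0]),
            "ddof2": int(aov["ddof2"].iloc[0]),
        },
        "pairwise": pairwise,
    }
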