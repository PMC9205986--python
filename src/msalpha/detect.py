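"""Horizontal gaze-shift (microsaccade) detection and trial classification.

The primary detector follows a deliberately sensitive velocity-threshold
scheme: absolute sample-to-sample velocity of the normalized horizontal gaze,
smoothed with a 7-ms Gaussian-weighted moving average, thresholded at three
times the trial's median velocity. A 100-ms refractory period prevents one
eye movement from being counted multiple times; shift magnitude is the
difference between mean gaze position 50-100 ms after versus 50-0 ms before
the initial threshold crossing, and shifts smaller than 1% of the item
eccentricity (0.057 degrees at 5.7 degrees) are discarded. Trials are
classified by the direction of the first detected shift in the 200-600 ms
post-cue window: toward or away from the cued item's memorised side, or
"none" when no shift is detected there.

A binocular 2-D velocity detector in the style of Engbert & Kliegl is
provided as an alternative for robustness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .preprocess import GazeEpoch

__all__ = [
    "GazeShiftEvent",
    "TrialClass",
    "DetectionDiagnostics",
    "compute_velocity",
    "detect_shifts",
    "label_direction",
    "classify_trial",
    "shift_rate_timecourse",
    "rate_magnitude_map",
    "split_by_latency",
    "detect_engbert_kliegl",
]

CLASSIFICATION_WINDOW_MS = (200.0, 600.0)
MAGNITUDE_FLOOR_PCT = 1.0
REFRACTORY_MS = 100.0
THRESHOLD_MULTIPLIER = 3.0
SMOOTHING_WINDOW_MS = 7.0


@dataclass(frozen=True)
class GazeShiftEvent:
    """A detected gaze shift.

    ``magnitude_pct`` is signed (positive = rightward); ``direction`` is
    "toward"/"away" relative to the cued item's memorised side once labelled.
    """

    onset_ms: float
    magnitude_pct: float
    peak_velocity: float  # %/ms
    direction: str | None = None


@dataclass(frozen=True)
class TrialClass:
    """Microsaccade-based trial class: toward | away | none | unusable."""

    label: str
    first_shift_latency_ms: float | None = None


@dataclass
class DetectionDiagnostics:
    threshold: float = np.nan
    n_crossings: int = 0
    n_refractory_dropped: int = 0
    n_edge_skipped: int = 0
    n_subfloor: int = 0


def _gaussian_kernel(window_samples: int, sd_samples: float) -> np.ndarray:
    half = window_samples // 2
    x = np.arange(-half, window_samples - half)
    k = np.exp(-0.5 * (x / sd_samples) ** 2)
    return k / k.sum()


def compute_velocity(
    epoch: GazeEpoch,
    smoothing_window_ms: float = SMOOTHING_WINDOW_MS,
    trace: np.ndarray | None = None,
) -> np.ndarray:
    """Absolute gaze velocity (%/ms), Gaussian-smoothed over a 7-ms window.

    The velocity at sample i is |x[i] - x[i-1]| / dt (the first sample is
    NaN), smoothed with Gaussian weights (sd = window/5, truncated to the
    window). NaN gaze samples yield NaN velocity across the kernel support.
    Edges of the trace use a shrunken, renormalized kernel.
    """
    x = epoch.position_pct if trace is None else np.asarray(trace, dtype=float)
    if not np.isfinite(x).any():
        raise ValueError("cannot compute velocity: trace contains no finite samples")
    dt = 1000.0 / epoch.sampling_rate
    v = np.empty_like(x, dtype=float)
    v[0] = np.nan
    v[1:] = np.abs(np.diff(x)) / dt

    w = max(3, int(round(smoothing_window_ms / dt)))
    kernel = _gaussian_kernel(w, w / 5.0)
    half = w // 2
    # edge-shrinking convolution: pad with NaN, renormalize over in-bounds taps
    padded = np.concatenate([np.full(half, np.nan), v, np.full(w - 1 - half, np.nan)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, w)
    inb = ~np.isnan(
        np.lib.stride_tricks.sliding_window_view(
            np.concatenate([np.full(half, np.nan), np.zeros_like(v), np.full(w - 1 - half, np.nan)]),
            w,
        )
    )
    num = np.where(inb, windows * kernel, 0.0).sum(axis=1)
    den = (inb * kernel).sum(axis=1)
    smoothed = num / den
    # NaN velocity anywhere under the kernel support propagates
    nan_under = np.isnan(np.where(inb, windows, 0.0)).any(axis=1)
    smoothed[nan_under] = np.nan
    return smoothed


def detect_shifts(
    velocity: np.ndarray,
    epoch: GazeEpoch,
    threshold_multiplier: float = THRESHOLD_MULTIPLIER,
    refractory_ms: float = REFRACTORY_MS,
    magnitude_floor_pct: float = MAGNITUDE_FLOOR_PCT,
    diagnostics: DetectionDiagnostics | None = None,
) -> list[GazeShiftEvent]:
    """Detect gaze shifts from a velocity trace (unlabelled events).

    Steps: (1) trial-based threshold = ``threshold_multiplier`` x median of
    the finite velocity samples; (2) onsets are the first samples of
    supra-threshold runs (runs broken by NaN terminate); (3) an onset within
    ``refractory_ms`` of the previously retained onset is dropped;
    (4) magnitude = mean position in the closed window [onset+50, onset+100]
    minus mean in [onset-50, onset] ms (finite samples only); onsets whose
    windows leave the epoch or contain no finite sample are skipped;
    (5) events with \\|magnitude\\| below ``magnitude_floor_pct`` are discarded.
    """
    v = np.asarray(velocity, dtype=float)
    x = epoch.position_pct
    t = epoch.time_ms
    diag = diagnostics if diagnostics is not None else DetectionDiagnostics()

    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("velocity trace contains no finite samples")
    threshold = threshold_multiplier * float(np.median(v[finite]))
    diag.threshold = threshold

    above = np.zeros(v.size, dtype=bool)
    above[finite] = v[finite] > threshold
    # run starts: above here, not above (or NaN) at the previous sample
    prev = np.concatenate(([False], above[:-1]))
    onset_idx = np.flatnonzero(above & ~prev)
    diag.n_crossings = int(onset_idx.size)

    # run extents for peak velocity
    run_end = {}
    for i in onset_idx:
        j = i
        while j + 1 < v.size and above[j + 1]:
            j += 1
        run_end[i] = j

    events: list[GazeShiftEvent] = []
    last_kept: float | None = None
    for i in onset_idx:
        onset = float(t[i])
        if last_kept is not None and onset - last_kept <= refractory_ms:
            diag.n_refractory_dropped += 1
            continue
        last_kept = onset  # retained for refractory bookkeeping
        if onset - 50.0 < t[0] or onset + 100.0 > t[-1]:
            diag.n_edge_skipped += 1
            continue
        pre = x[(t >= onset - 50.0) & (t <= onset)]
        post = x[(t >= onset + 50.0) & (t <= onset + 100.0)]
        pre, post = pre[np.isfinite(pre)], post[np.isfinite(post)]
        if pre.size == 0 or post.size == 0:
            diag.n_edge_skipped += 1
            continue
        mag = float(np.mean(post) - np.mean(pre))
        if abs(mag) < magnitude_floor_pct:
            diag.n_subfloor += 1
            continue
        peak = float(np.nanmax(v[i : run_end[i] + 1]))
        events.append(GazeShiftEvent(onset_ms=onset, magnitude_pct=mag, peak_velocity=peak))
    return events


def label_direction(events: list[GazeShiftEvent], cued_side: str) -> list[GazeShiftEvent]:
    """Label each shift toward/away relative to the cued item's side.

    Positive magnitudes are rightward, so a negative shift is "toward" when
    the cued item was on the left. Flipping ``cued_side`` flips every label.
    """
    if cued_side not in ("left", "right"):
        raise ValueError(f"cued_side must be 'left' or 'right', got {cued_side!r}")
    toward_sign = -1.0 if cued_side == "left" else 1.0
    out = []
    for e in events:
        if e.magnitude_pct == 0.0:
            raise RuntimeError("zero-magnitude event survived the magnitude floor")
        lab = "toward" if e.magnitude_pct * toward_sign > 0 else "away"
        out.append(replace(e, direction=lab))
    return out


def classify_trial(
    events: list[GazeShiftEvent],
    usable: bool,
    window_ms: tuple[float, float] = CLASSIFICATION_WINDOW_MS,
    dismiss: bool = False,
) -> TrialClass:
    """Classify a trial by its first labelled shift in the selection window.

    Unusable trials (blink/NaN in 0-600 ms) are "unusable" regardless of
    events; ``dismiss`` additionally forces "unusable" (used for the optional
    rule that dismisses trials containing sub-floor shifts). Otherwise the
    class is the direction of the first event with onset inside the closed
    ``window_ms``, or "none" if there is no such event.
    """
    if not usable or dismiss:
        return TrialClass(label="unusable")
    lo, hi = window_ms
    for e in sorted(events, key=lambda e: e.onset_ms):
        if lo <= e.onset_ms <= hi:
            if e.direction not in ("toward", "away"):
                raise ValueError("events must be direction-labelled before classification")
            return TrialClass(label=e.direction, first_shift_latency_ms=e.onset_ms)
    return TrialClass(label="none")


def shift_rate_timecourse(
    events_per_trial: list[list[float]],
    time_ms: np.ndarray,
    window_ms: float = 50.0,
    step_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaze-shift rate (shifts/s) over time via a sliding 50-ms window.

    ``events_per_trial`` holds the onset times of the selected events for
    each trial (empty lists count as trials with no events). The window is
    centred: rate(t) = count of onsets in [t - w/2, t + w/2) / n_trials / w.
    Returns (window centres, rate).
    """
    n_trials = len(events_per_trial)
    if n_trials == 0:
        raise ValueError("events_per_trial must contain at least one trial")
    time_ms = np.asarray(time_ms, dtype=float)
    onsets = np.concatenate(
        [np.asarray(e, dtype=float) for e in events_per_trial if len(e)] or [np.empty(0)]
    )
    t0, t1 = time_ms[0], time_ms[-1]
    edges = np.arange(t0, t1 + step_ms, step_ms)
    counts, _ = np.histogram(onsets, bins=edges)
    w = int(round(window_ms / step_ms))
    kernel = np.ones(w)
    sliding = np.convolve(counts, kernel, mode="valid")  # sum over w consecutive 1-ms bins
    centres = edges[:-1][: sliding.size] + window_ms / 2.0
    rate = sliding / n_trials / (window_ms / 1000.0)
    return centres, rate


def rate_magnitude_map(
    events_per_trial: list[list[tuple[float, float]]],
    time_ms: np.ndarray,
    window_ms: float = 50.0,
    step_ms: float = 1.0,
    mag_bin_lefts: np.ndarray | None = None,
    mag_bin_width: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shift rate resolved over time x magnitude bins.

    Each trial contributes (onset_ms, magnitude_pct) pairs. Magnitude bins
    are 5%-wide and overlapping, with left edges 1..110% in 1% steps; bin b
    covers \\|magnitude\\| in the half-open interval [b, b+5). Returns
    (window centres, bin left edges, rate array of shape (bins, times)).
    """
    n_trials = len(events_per_trial)
    if n_trials == 0:
        raise ValueError("events_per_trial must contain at least one trial")
    if mag_bin_lefts is None:
        mag_bin_lefts = np.arange(1.0, 111.0, 1.0)
    time_ms = np.asarray(time_ms, dtype=float)
    pairs = [p for trial in events_per_trial for p in trial]
    onsets = np.asarray([p[0] for p in pairs], dtype=float)
    mags = np.abs(np.asarray([p[1] for p in pairs], dtype=float))

    t_edges = np.arange(time_ms[0], time_ms[-1] + step_ms, step_ms)
    m_edges = np.arange(mag_bin_lefts[0], mag_bin_lefts[-1] + mag_bin_width + 1.0, 1.0)
    H, _, _ = np.histogram2d(mags, onsets, bins=[m_edges, t_edges])

    w_t = int(round(window_ms / step_ms))
    w_m = int(round(mag_bin_width))

    def moving_sum(a: np.ndarray, w: int, axis: int) -> np.ndarray:
        c = np.cumsum(a, axis=axis)
        c = np.concatenate([np.zeros_like(np.take(c, [0], axis=axis)), c], axis=axis)
        upper = np.take(c, range(w, c.shape[axis]), axis=axis)
        lower = np.take(c, range(0, c.shape[axis] - w), axis=axis)
        return upper - lower  # left-aligned windows of width w

    # width-5 overlapping magnitude bins, 50-ms left-aligned time windows
    M = moving_sum(moving_sum(H, w_m, axis=0), w_t, axis=1)
    M = M[: mag_bin_lefts.size]
    centres = t_edges[: M.shape[1]] + window_ms / 2.0
    rate = M / n_trials / (window_ms / 1000.0)
    return centres, np.asarray(mag_bin_lefts), rate


def split_by_latency(
    latencies_by_participant: dict[int, list[tuple[int, float]]],
) -> dict[int, tuple[list[int], list[int]]]:
    """Median split of toward trials on first-shift latency, per participant.

    Input: per participant, (trial_id, latency_ms) for every toward trial.
    Early = latency strictly below that participant's median, late = strictly
    above; trials tied with the median alternate early/late to balance
    counts. Participants with fewer than 2 toward trials are excluded with a
    warning.
    """
    out: dict[int, tuple[list[int], list[int]]] = {}
    for pid, items in latencies_by_participant.items():
        if len(items) < 2:
            warnings.warn(
                f"participant {pid} excluded from latency split (<2 toward trials)"
            )
            continue
        lat = np.asarray([l for _, l in items], dtype=float)
        med = float(np.median(lat))
        early = [tid for (tid, l) in items if l < med]
        late = [tid for (tid, l) in items if l > med]
        tie_to_early = True
        for tid, l in items:
            if l == med:
                (early if tie_to_early else late).append(tid)
                tie_to_early = not tie_to_early
        out[pid] = (early, late)
    return out


# --------------------------------------------------------------------------
# alternative binocular 2-D detector


def _ek_velocity(x: np.ndarray, dt_ms: float) -> np.ndarray:
    """Five-point moving-average derivative (%/ms); NaN near gaps/edges."""
    v = np.full_like(x, np.nan, dtype=float)
    v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt_ms)
    return v


def _ek_monocular(
    ex: np.ndarray,
    ey: np.ndarray,
    dt_ms: float,
    lam: float,
    min_duration_samples: int,
) -> list[tuple[int, int]]:
    vx, vy = _ek_velocity(ex, dt_ms), _ek_velocity(ey, dt_ms)
    crit = np.zeros(ex.size, dtype=bool)
    finite = np.isfinite(vx) & np.isfinite(vy)
    if not finite.any():
        return []
    eta = []
    for v in (vx, vy):
        vf = v[finite]
        sd = np.sqrt(np.median(vf**2) - np.median(vf) ** 2)
        if sd == 0 or not np.isfinite(sd):
            sd = np.finfo(float).eps
        eta.append(lam * sd)
    r = (vx / eta[0]) ** 2 + (vy / eta[1]) ** 2
    crit[finite] = r[finite] > 1.0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], crit.view(np.int8), [0]))))
    runs = [(s, e - 1) for s, e in zip(edges[::2], edges[1::2])]
    return [(s, e) for s, e in runs if e - s + 1 >= min_duration_samples]


def detect_engbert_kliegl(
    epoch: GazeEpoch,
    lam: float = 6.0,
    min_duration_ms: float = 6.0,
    min_binocular_overlap: int = 1,
    refractory_ms: float = REFRACTORY_MS,
    magnitude_floor_pct: float = MAGNITUDE_FLOOR_PCT,
) -> list[GazeShiftEvent]:
    """Binocular 2-D velocity-threshold detector (Engbert-Kliegl style).

    Per eye, the 2-D velocity from a five-point derivative is compared
    against an elliptic threshold at ``lam`` median-based velocity SDs per
    axis; candidate events must last at least ``min_duration_ms`` and
    temporally overlap between the eyes by ``min_binocular_overlap`` samples.
    Events are mapped into :class:`GazeShiftEvent` using the same
    before/after magnitude windows and magnitude floor as the primary
    detector; retained onsets respect the 100-ms separation invariant.

    Falls back (with a warning) to a monocular criterion on the cyclopean
    trace when per-eye data are unavailable.
    """
    dt = 1000.0 / epoch.sampling_rate
    min_dur = max(1, int(round(min_duration_ms / dt)))
    t = epoch.time_ms
    if epoch.eyes_pct is not None:
        e = epoch.eyes_pct
        runs_l = _ek_monocular(e["lx"], e["ly"], dt, lam, min_dur)
        runs_r = _ek_monocular(e["rx"], e["ry"], dt, lam, min_dur)
        merged: list[tuple[int, int]] = []
        for sl, el in runs_l:
            for sr, er in runs_r:
                s, en = max(sl, sr), min(el, er)
                if en - s + 1 >= min_binocular_overlap:
                    merged.append((s, en))
        runs = sorted(set(merged))
    else:
        warnings.warn("per-eye traces unavailable; Engbert-Kliegl running monocular")
        if epoch.vertical_pct is None:
            raise ValueError("2-D detection requires a vertical gaze channel")
        runs = _ek_monocular(epoch.position_pct, epoch.vertical_pct, dt, lam, min_dur)

    x = epoch.position_pct
    events: list[GazeShiftEvent] = []
    last_kept: float | None = None
    for s, en in runs:
        onset = float(t[s])
        if last_kept is not None and onset - last_kept <= refractory_ms:
            continue
        last_kept = onset
        if onset - 50.0 < t[0] or onset + 100.0 > t[-1]:
            continue
        pre = x[(t >= onset - 50.0) & (t <= onset)]
        post = x[(t >= onset + 50.0) & (t <= onset + 100.0)]
        pre, post = pre[np.isfinite(pre)], post[np.isfinite(post)]
        if pre.size == 0 or post.size == 0:
            continue
        mag = float(np.mean(post) - np.mean(pre))
        if abs(mag) < magnitude_floor_pct:
            continue
        seg = np.abs(np.diff(x[s : en + 1])) / dt
        peak = float(np.nanmax(seg)) if seg.size and np.isfinite(seg).any() else np.nan
        events.append(GazeShiftEvent(onset_ms=onset, magnitude_pct=mag, peak_velocity=peak))
    return events
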