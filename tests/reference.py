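"""Independent brute-force reference implementations used as test oracles.

These deliberately use naive explicit loops and never call into the package's
vectorized code paths, so they can serve as an independent check of the
velocity-threshold detector and the cluster permutation machinery.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_detect(
    velocity: np.ndarray,
    position: np.ndarray,
    time_ms: np.ndarray,
    threshold_multiplier: float = 3.0,
    refractory_ms: float = 100.0,
    magnitude_floor_pct: float = 1.0,
) -> list[tuple[float, float]]:
    """Naive scan implementing the detection rules event-for-event.

    Returns (onset_ms, magnitude_pct) pairs. Rules: threshold = multiplier x
    median of finite velocities; an onset is a sample above threshold whose
    predecessor is not above (NaN breaks a run); onsets within the
    refractory period of the last retained onset are dropped; magnitude is
    mean position over the closed [onset+50, onset+100] window minus the
    closed [onset-50, onset] window (finite samples only); events with
    windows off the epoch, empty windows, or |magnitude| below the floor are
    discarded.
    """
    v = [float(x) for x in velocity]
    finite = sorted(x for x in v if math.isfinite(x))
    if not finite:
        raise ValueError("no finite velocity samples")
    k = len(finite)
    median = finite[k // 2] if k % 2 else 0.5 * (finite[k // 2 - 1] + finite[k // 2])
    thr = threshold_multiplier * median

    events = []
    last_kept = None
    for i in range(len(v)):
        above = math.isfinite(v[i]) and v[i] > thr
        prev_above = i > 0 and math.isfinite(v[i - 1]) and v[i - 1] > thr
        if not (above and not prev_above):
            continue
        onset = float(time_ms[i])
        if last_kept is not None and onset - last_kept <= refractory_ms:
            continue
        last_kept = onset
        if onset - 50.0 < time_ms[0] or onset + 100.0 > time_ms[-1]:
            continue
        pre = [
            position[j]
            for j in range(len(position))
            if onset - 50.0 <= time_ms[j] <= onset and math.isfinite(position[j])
        ]
        post = [
            position[j]
            for j in range(len(position))
            if onset + 50.0 <= time_ms[j] <= onset + 100.0 and math.isfinite(position[j])
        ]
        if not pre or not post:
            continue
        mag = sum(post) / len(post) - sum(pre) / len(pre)
        if abs(mag) < magnitude_floor_pct:
            continue
        events.append((onset, mag))
    return events


def brute_force_clusters(t_map: np.ndarray, threshold: float) -> list[float]:
    """All same-signed suprathreshold cluster masses of a 1-D t map, by
    linear scan."""
    masses = []
    i = 0
    n = len(t_map)
    while i < n:
        if t_map[i] > threshold:
            m = 0.0
            while i < n and t_map[i] > threshold:
                m += t_map[i]
                i += 1
            masses.append(m)
        elif t_map[i] < -threshold:
            m = 0.0
            while i < n and t_map[i] < -threshold:
                m += t_map[i]
                i += 1
            masses.append(m)
        else:
            i += 1
    return masses


def brute_force_sign_flip_test(
    data: np.ndarray, cluster_alpha: float = 0.05
) -> list[tuple[float, float]]:
    """Exhaustive sign-flip cluster test for small n, fully naive.

    Returns (mass, p) per observed cluster, p = proportion of the 2^n sign
    assignments whose largest absolute cluster mass reaches the observed one.
    """
    from scipy import stats as sps

    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    thr = sps.t.ppf(1 - cluster_alpha / 2, df=n - 1)

    def tmap(Y):
        m = Y.mean(axis=0)
        sd = Y.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / (sd / np.sqrt(n))
        return np.where(sd > 0, t, np.where(m != 0, np.sign(m) * np.inf, 0.0))

    observed = brute_force_clusters(tmap(X), thr)
    null_max = []
    for code in range(2**n):
        signs = np.array([1.0 if (code >> k) & 1 else -1.0 for k in range(n)])
        null_max.append(max([abs(m) for m in brute_force_clusters(tmap(signs[:, None] * X), thr)], default=0.0))
    null_max = np.asarray(null_max)
    return [(m, float((null_max >= abs(m)).mean())) for m in observed]
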