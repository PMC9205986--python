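"""Gaze pre-processing: eye averaging, blink masking, calibration-based
normalization into % units, and trial usability flagging.

Normalized horizontal gaze is expressed as a percentage of the memory items'
eccentricity: 0% is the screen centre and +/-100% is the centre of the right
or left item's original location (5.7 degrees by default). The mapping from
raw tracker units is affine, fitted from the seven-point calibration module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import CalibrationRecording, GazeTrial

__all__ = [
    "CalibrationError",
    "CalibrationReference",
    "GazeEpoch",
    "merge_eyes",
    "mask_blinks",
    "build_calibration_reference",
    "normalize_gaze",
    "mark_usable",
    "preprocess_trial",
    "pct_to_deg",
    "deg_to_pct",
    "read_gaze_csv",
    "parse_asc_samples",
]

BLINK_EXTENSION_MS = 100.0
USABILITY_WINDOW_MS = (0.0, 600.0)
CALIBRATION_SUBWINDOW_MS = (500.0, 1000.0)


class CalibrationError(ValueError):
    pass


def pct_to_deg(pct: float | np.ndarray, eccentricity_deg: float = 5.7) -> float | np.ndarray:
    """Convert normalized gaze (% of item eccentricity) to visual degrees.

    With the default 5.7 degree eccentricity, the 1% minimum shift magnitude
    corresponds to 0.057 degrees.
    """
    return pct / 100.0 * eccentricity_deg


def deg_to_pct(deg: float | np.ndarray, eccentricity_deg: float = 5.7) -> float | np.ndarray:
    return deg / eccentricity_deg * 100.0


def merge_eyes(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Average the two eyes samplewise into a cyclopean trace.

    NaN in either eye (blink or tracking loss) propagates to NaN, so partial
    blinks are not silently replaced by monocular data.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError(f"eye traces differ in shape: {left.shape} vs {right.shape}")
    return (left + right) / 2.0


def mask_blinks(
    trace: np.ndarray,
    sampling_rate: float = 1000.0,
    extension_ms: float = BLINK_EXTENSION_MS,
) -> np.ndarray:
    """Widen every maximal NaN run by ``extension_ms`` on each side.

    Residual blink artefacts (lid droop, pupil distortion) surround the NaN
    cluster reported by the tracker, so samples within 100 ms of a cluster
    are rewritten as NaN. Overlapping extensions merge into one run. Apply
    once per trace: extension NaNs are indistinguishable from blink NaNs, so
    a second application would widen the runs further.
    """
    trace = np.asarray(trace, dtype=float).copy()
    isnan = np.isnan(trace)
    if not isnan.any():
        return trace
    pad = int(round(extension_ms * sampling_rate / 1000.0))
    edges = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]  # ends exclusive
    for s, e in zip(starts, ends):
        trace[max(0, s - pad) : min(trace.size, e + pad)] = np.nan
    return trace


@dataclass(frozen=True)
class CalibrationReference:
    """Affine map from raw tracker units to normalized % units.

    ``pct = (raw - offset) / scale * 100`` where ``scale`` is the raw
    displacement corresponding to one item eccentricity, fitted by least
    squares over the seven calibration-point medians.
    """

    offset_x: float
    scale_x: float  # raw units per 100%
    offset_y: float
    scale_y: float
    medians: dict = field(default_factory=dict, compare=False)

    def raw_to_pct(self, raw: np.ndarray, axis: str = "x") -> np.ndarray:
        off, sc = (self.offset_x, self.scale_x) if axis == "x" else (self.offset_y, self.scale_y)
        return (np.asarray(raw, dtype=float) - off) / sc * 100.0

    def pct_to_raw(self, pct: np.ndarray, axis: str = "x") -> np.ndarray:
        off, sc = (self.offset_x, self.scale_x) if axis == "x" else (self.offset_y, self.scale_y)
        return np.asarray(pct, dtype=float) / 100.0 * sc + off


def build_calibration_reference(recording: CalibrationRecording) -> CalibrationReference:
    """Fit the raw-to-% affine map from a seven-point calibration recording.

    Per position, the median gaze in the 500-1000 ms sub-window after point
    onset is taken (the first 500 ms allow the saccade to the new point).
    The horizontal scale is the least-squares slope of raw medians against
    nominal positions in % (lateral points = +/-100%, centre = 0%); the
    vertical axis is fitted the same way from the top/bottom points.
    """
    required = {
        "left-top", "left-middle", "left-bottom",
        "right-top", "right-middle", "right-bottom", "centre",
    }
    seen = set(recording.labels)
    missing = required - seen
    if missing:
        raise CalibrationError(f"calibration positions missing: {sorted(missing)}")

    lo, hi = CALIBRATION_SUBWINDOW_MS
    medians: dict[str, tuple[float, float]] = {}
    ecc = max(abs(s.nominal_deg[0]) for s in recording.segments)
    nominal_pct_x, nominal_pct_y, med_x, med_y = [], [], [], []
    for seg in recording.segments:
        if seg.time_ms[-1] - seg.time_ms[0] < hi - 1:
            raise CalibrationError(
                f"calibration segment {seg.label!r} shorter than {hi} ms"
            )
        m = (seg.time_ms >= lo) & (seg.time_ms <= hi)
        mx = float(np.nanmedian(seg.x[m]))
        my = float(np.nanmedian(seg.y[m]))
        medians[seg.label] = (mx, my)
        nominal_pct_x.append(seg.nominal_deg[0] / ecc * 100.0)
        nominal_pct_y.append(seg.nominal_deg[1] / ecc * 100.0)
        med_x.append(mx)
        med_y.append(my)

    def fit(nominal, med):
        A = np.column_stack([np.asarray(nominal) / 100.0, np.ones(len(med))])
        (slope, intercept), *_ = np.linalg.lstsq(A, np.asarray(med), rcond=None)
        if slope == 0:
            raise CalibrationError("degenerate calibration: zero horizontal scale")
        return float(intercept), float(slope)

    off_x, sc_x = fit(nominal_pct_x, med_x)
    off_y, sc_y = fit(nominal_pct_y, med_y)
    return CalibrationReference(
        offset_x=off_x, scale_x=sc_x, offset_y=off_y, scale_y=sc_y, medians=medians
    )


@dataclass
class GazeEpoch:
    """Normalized, blink-masked horizontal gaze around cue onset.

    ``position_pct`` is in % units (positive = rightward); masked samples are
    NaN and flagged False in ``valid``. ``vertical_pct`` and the per-eye 2-D
    traces are carried only for the binocular 2-D detector.
    """

    time_ms: np.ndarray
    position_pct: np.ndarray
    cued_side: str
    sampling_rate: float = 1000.0
    vertical_pct: np.ndarray | None = None
    eyes_pct: dict | None = None  # {"lx","ly","rx","ry"} normalized per-eye

    def __post_init__(self) -> None:
        dt = np.diff(self.time_ms)
        if dt.size and (dt <= 0).any():
            raise ValueError("time axis must be strictly increasing")

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.position_pct)


def normalize_gaze(
    trace: np.ndarray, reference: CalibrationReference, axis: str = "x"
) -> np.ndarray:
    """Apply the calibration affine map; NaNs pass through unchanged."""
    return reference.raw_to_pct(trace, axis=axis)


def mark_usable(epoch: GazeEpoch, window_ms: tuple[float, float] = USABILITY_WINDOW_MS) -> bool:
    """A trial is usable iff its trace is NaN-free throughout [0, 600] ms.

    The window is closed on both ends (conservative: a NaN exactly at the
    boundary flags the trial unusable).
    """
    lo, hi = window_ms
    if epoch.time_ms[0] > lo or epoch.time_ms[-1] < hi:
        raise ValueError(
            f"epoch [{epoch.time_ms[0]}, {epoch.time_ms[-1]}] ms does not span "
            f"the usability window [{lo}, {hi}] ms"
        )
    m = (epoch.time_ms >= lo) & (epoch.time_ms <= hi)
    return bool(np.isfinite(epoch.position_pct[m]).all())


def preprocess_trial(
    trial: GazeTrial,
    reference: CalibrationReference,
    cued_side: str,
    sampling_rate: float = 1000.0,
    keep_eyes: bool = False,
) -> GazeEpoch:
    """Full pre-processing of one raw binocular trial.

    Eyes are averaged, NaN clusters extended by 100 ms on each side, and the
    result normalized to % units via the calibration reference.
    """
    x = mask_blinks(merge_eyes(trial.lx, trial.rx), sampling_rate)
    y = mask_blinks(merge_eyes(trial.ly, trial.ry), sampling_rate)
    eyes = None
    if keep_eyes:
        eyes = {
            "lx": normalize_gaze(mask_blinks(trial.lx, sampling_rate), reference, "x"),
            "ly": normalize_gaze(mask_blinks(trial.ly, sampling_rate), reference, "y"),
            "rx": normalize_gaze(mask_blinks(trial.rx, sampling_rate), reference, "x"),
            "ry": normalize_gaze(mask_blinks(trial.ry, sampling_rate), reference, "y"),
        }
    return GazeEpoch(
        time_ms=trial.time_ms,
        position_pct=normalize_gaze(x, reference, "x"),
        vertical_pct=normalize_gaze(y, reference, "y"),
        cued_side=cued_side,
        sampling_rate=sampling_rate,
        eyes_pct=eyes,
    )


# --------------------------------------------------------------------------
# readers


def read_gaze_csv(path) -> GazeTrial:
    """Read a raw gaze trial from the documented CSV dialect
    (columns: time_ms, lx, ly, rx, ry; empty cells = NaN)."""
    df = pd.read_csv(path)
    cols = ["time_ms", "lx", "ly", "rx", "ry"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"gaze CSV missing columns: {missing}")
    return GazeTrial(*(df[c].to_numpy(dtype=float) for c in cols))


def parse_asc_samples(path) -> GazeTrial:
    """Minimal EyeLink ASC sample-line parser (binocular recording).

    Only sample lines (leading integer timestamp) are read; event lines
    (ESACC, EBLINK, MSG, ...) are ignored. Missing-data markers ('.') become
    NaN. Expected sample layout: time lx ly lpupil rx ry rpupil [...].
    """
    t, lx, ly, rx, ry = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue
            vals = []
            for tok in parts[1:7]:
                try:
                    vals.append(float(tok))
                except ValueError:
                    vals.append(np.nan)
            while len(vals) < 6:
                vals.append(np.nan)
            t.append(float(parts[0]))
            lx.append(vals[0])
            ly.append(vals[1])
            rx.append(vals[3])
            ry.append(vals[4])
    if not t:
        raise ValueError(f"no sample lines found in {path}")
    return GazeTrial(
        time_ms=np.asarray(t),
        lx=np.asarray(lx),
        ly=np.asarray(ly),
        rx=np.asarray(rx),
        ry=np.asarray(ry),
    )
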