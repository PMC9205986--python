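"""Synthetic covert spatial-attention studies with known ground truth.

Generates, per participant: raw binocular gaze traces with injected
microsaccade-like gaze shifts and blink NaN stretches, a seven-point gaze
calibration recording, per-trial posterior-cluster EEG signals (contra- and
ipsilateral to the cued side) carrying a lateralized alpha modulation, and
behavioural outcomes. Every injected event is recorded in a ground-truth
table so downstream detection and statistics can be validated by parameter
recovery.

The generative model of timing follows a threshold account of the oculomotor
link: each trial draws a latent attentional-selection time from the
microsaccade latency distribution; trials that emit a gaze shift place it at
that time, and the alpha modulation onset trails the selection time by a
fixed lag in *all* trials. Trials without an in-window shift therefore carry
the same programmed modulation, matching the empirical observation that
no-microsaccade trials show intact alpha lateralization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .config import ConfigError, StudyConfig

__all__ = [
    "EyeAffine",
    "ShiftPlan",
    "PlannedShift",
    "GazeTrial",
    "CalibrationSegment",
    "CalibrationRecording",
    "ParticipantData",
    "SyntheticStudy",
    "PlanError",
    "generate_study",
    "generate_gaze_trial",
    "generate_alpha_signals",
    "generate_calibration",
    "save_study",
    "load_study",
]

CALIBRATION_LABELS = (
    "left-top",
    "left-middle",
    "left-bottom",
    "right-top",
    "right-middle",
    "right-bottom",
    "centre",
)


class PlanError(ValueError):
    """Raised for invalid shift plans (overlap, sub-floor magnitudes)."""


@dataclass(frozen=True)
class EyeAffine:
    """Hidden tracker coordinate frame: raw = centre + gain * degrees."""

    cx: float = 0.0
    cy: float = 0.0
    gx: float = 1.0  # raw units per degree, horizontal
    gy: float = 1.0

    def to_raw(self, deg_x: np.ndarray, deg_y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.cx + self.gx * deg_x, self.cy + self.gy * deg_y


@dataclass(frozen=True)
class PlannedShift:
    onset_ms: float
    magnitude_pct: float  # signed; positive = rightward

    def __post_init__(self) -> None:
        if abs(self.magnitude_pct) < 1.0:
            raise PlanError(
                f"planned shift magnitude {self.magnitude_pct}% below the 1% floor"
            )


ShiftPlan = Sequence[PlannedShift]


def _validate_plan(plan: ShiftPlan) -> list[PlannedShift]:
    shifts = sorted(plan, key=lambda s: s.onset_ms)
    for a, b in zip(shifts, shifts[1:]):
        if b.onset_ms - a.onset_ms <= 100.0:
            raise PlanError(
                f"planned shifts at {a.onset_ms} and {b.onset_ms} ms are separated by <= 100 ms"
            )
    return shifts


@dataclass
class GazeTrial:
    """Raw binocular gaze samples on the epoch time axis (ms, cue at 0)."""

    time_ms: np.ndarray
    lx: np.ndarray
    ly: np.ndarray
    rx: np.ndarray
    ry: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.time_ms, "lx": self.lx, "ly": self.ly, "rx": self.rx, "ry": self.ry}
        )


@dataclass
class CalibrationSegment:
    label: str
    nominal_deg: tuple[float, float]
    time_ms: np.ndarray  # relative to calibration-point onset
    x: np.ndarray  # raw units
    y: np.ndarray


@dataclass
class CalibrationRecording:
    segments: list[CalibrationSegment]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]


@dataclass
class ParticipantData:
    participant: int
    affine: EyeAffine
    gaze: list[GazeTrial]
    calibration: CalibrationRecording
    eeg_contra: np.ndarray  # trials x samples
    eeg_ipsi: np.ndarray
    eeg_time_ms: np.ndarray
    trials: pd.DataFrame  # per-trial metadata + ground-truth latent variables


@dataclass
class SyntheticStudy:
    config: StudyConfig
    participants: list[ParticipantData]
    ground_truth: pd.DataFrame = field(default=None)  # one row per injected shift

    @property
    def trial_info(self) -> pd.DataFrame:
        return pd.concat([p.trials for p in self.participants], ignore_index=True)


# --------------------------------------------------------------------------
# primitives


def _minimum_jerk_step(n: int) -> np.ndarray:
    """Unit displacement profile over n samples (smooth monotone step)."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def generate_gaze_trial(
    config: StudyConfig,
    shift_plan: ShiftPlan,
    rng: np.random.Generator,
    affine: EyeAffine | None = None,
    blink_intervals: Sequence[tuple[float, float]] | None = None,
) -> GazeTrial:
    """Simulate one raw binocular gaze trial.

    The horizontal cyclopean trace is built in normalized % units (100% = item
    eccentricity), as drift noise plus one minimum-jerk displacement per
    planned shift, then converted to raw tracker units through ``affine``.
    NaN stretches are written into both eyes for each blink interval.
    """
    shifts = _validate_plan(shift_plan)
    t0, t1 = config.epoch_window
    dt = 1000.0 / config.sampling_rate
    time_ms = np.arange(t0, t1, dt)
    n = time_ms.size

    pct = np.zeros(n)
    if config.drift_noise_sd > 0:
        pct += np.cumsum(rng.normal(0.0, config.drift_noise_sd, n))
    dur = max(2, int(round(config.saccade_duration_ms / dt)))
    profile = _minimum_jerk_step(dur)
    for s in shifts:
        i = int(round((s.onset_ms - t0) / dt))
        if i >= n:
            continue
        j = min(i + dur, n)
        pct[i:j] += s.magnitude_pct * profile[: j - i]
        pct[j:] += s.magnitude_pct

    ecc = config.item_eccentricity_deg
    deg_x = pct / 100.0 * ecc
    deg_y = (
        np.cumsum(rng.normal(0.0, config.drift_noise_sd, n)) / 100.0 * ecc
        if config.drift_noise_sd > 0
        else np.zeros(n)
    )

    eye_sd_deg = config.eye_noise_sd / 100.0 * ecc
    eyes = []
    for _ in range(2):
        ex = deg_x + (rng.normal(0.0, eye_sd_deg, n) if eye_sd_deg > 0 else 0.0)
        ey = deg_y + (rng.normal(0.0, eye_sd_deg, n) if eye_sd_deg > 0 else 0.0)
        eyes.append((ex, ey))

    aff = affine or EyeAffine()
    (lx, ly), (rx, ry) = (aff.to_raw(ex, ey) for ex, ey in eyes)
    lx, ly, rx, ry = (np.asarray(a, dtype=float).copy() for a in (lx, ly, rx, ry))

    for b0, b1 in blink_intervals or ():
        m = (time_ms >= b0) & (time_ms <= b1)
        for arr in (lx, ly, rx, ry):
            arr[m] = np.nan

    return GazeTrial(time_ms=time_ms, lx=lx, ly=ly, rx=rx, ry=ry)


def _one_over_f_noise(
    n: int, exponent: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f**exponent, unit-free
    RMS equal to ``amplitude``."""
    if amplitude == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spectrum = scale * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms * amplitude


def generate_alpha_signals(
    config: StudyConfig,
    modulation_onset_ms: float,
    rng: np.random.Generator,
    depth: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate contra- and ipsilateral posterior-cluster EEG for one trial.

    Both channels carry a 1/f background plus an alpha-frequency oscillation;
    after ``modulation_onset_ms`` the contralateral alpha amplitude ramps
    down linearly over ``alpha_ramp_ms`` to ``(1 - depth)`` of its baseline.
    With zero noise the band-power lateralization contrast therefore
    plateaus at ``((1-d)^2 - 1) / ((1-d)^2 + 1) * 100`` percent.
    """
    t0, t1 = config.epoch_window
    if not t0 <= modulation_onset_ms <= t1:
        raise ConfigError(
            f"modulation_onset_ms {modulation_onset_ms} outside epoch {config.epoch_window}"
        )
    d = config.alpha_modulation_depth if depth is None else depth
    if not 0.0 <= d < 1.0:
        raise ConfigError(f"alpha_modulation_depth must lie in [0, 1), got {d}")

    dt = 1000.0 / config.sampling_rate
    time_ms = np.arange(t0, t1, dt)
    n = time_ms.size

    ramp = np.clip((time_ms - modulation_onset_ms) / max(config.alpha_ramp_ms, dt), 0.0, 1.0)
    phase_c, phase_i = rng.uniform(0, 2 * np.pi, 2)
    carrier = 2 * np.pi * config.alpha_freq * time_ms / 1000.0
    contra = config.alpha_amplitude * (1.0 - d * ramp) * np.sin(carrier + phase_c)
    ipsi = config.alpha_amplitude * np.sin(carrier + phase_i)
    contra = contra + _one_over_f_noise(n, config.noise_exponent, config.eeg_noise_amplitude, rng)
    ipsi = ipsi + _one_over_f_noise(n, config.noise_exponent, config.eeg_noise_amplitude, rng)
    return contra, ipsi


def generate_calibration(
    config: StudyConfig,
    rng: np.random.Generator,
    affine: EyeAffine | None = None,
    segment_ms: float = 1200.0,
    noise_sd_deg: float | None = None,
) -> CalibrationRecording:
    """Simulate the seven-point calibration module.

    The point visits left-top/middle/bottom, right-top/middle/bottom and the
    screen centre in randomized order; lateral points sit at the item
    eccentricity. Each segment holds ``segment_ms`` of fixation samples with
    Gaussian fixation noise.
    """
    ecc = config.item_eccentricity_deg
    nominal = {
        "left-top": (-ecc, ecc),
        "left-middle": (-ecc, 0.0),
        "left-bottom": (-ecc, -ecc),
        "right-top": (ecc, ecc),
        "right-middle": (ecc, 0.0),
        "right-bottom": (ecc, -ecc),
        "centre": (0.0, 0.0),
    }
    sd = config.calibration_noise_sd_deg if noise_sd_deg is None else noise_sd_deg
    aff = affine or EyeAffine()
    dt = 1000.0 / config.sampling_rate
    order = list(CALIBRATION_LABELS)
    rng.shuffle(order)
    segments = []
    for label in order:
        gx, gy = nominal[label]
        t = np.arange(0.0, segment_ms, dt)
        dx = np.full(t.size, gx) + (rng.normal(0.0, sd, t.size) if sd > 0 else 0.0)
        dy = np.full(t.size, gy) + (rng.normal(0.0, sd, t.size) if sd > 0 else 0.0)
        x, y = aff.to_raw(dx, dy)
        segments.append(
            CalibrationSegment(label=label, nominal_deg=(gx, gy), time_ms=t, x=x, y=y)
        )
    return CalibrationRecording(segments=segments)


# --------------------------------------------------------------------------
# study assembly


def _plan_trial_shifts(
    config: StudyConfig,
    selection_time: float,
    cued_side: str,
    rng: np.random.Generator,
) -> tuple[list[PlannedShift], str]:
    """Plan the injected shifts for one trial; returns (plan, true class).

    The first in-window shift sits at the latent selection time with a
    direction biased toward the cued side. Background shifts (unbiased) are
    kept clear of a guard band around the 200-600 ms classification window so
    the window's toward:away ratio reflects ``p_toward_given_shift`` exactly.
    """
    toward_sign = -1.0 if cued_side == "left" else 1.0
    plan: list[PlannedShift] = []
    true_class = "none"
    onsets: list[float] = []

    if rng.uniform() < config.p_shift_in_window:
        toward = rng.uniform() < config.p_toward_given_shift
        sign = toward_sign if toward else -toward_sign
        mag = float(config.magnitude_distribution.sample(rng, 1)[0])
        plan.append(PlannedShift(onset_ms=selection_time, magnitude_pct=sign * mag))
        onsets.append(selection_time)
        true_class = "toward" if toward else "away"
        if rng.uniform() < config.p_second_shift:
            second = selection_time + rng.uniform(120.0, 250.0)
            if second < 600.0:
                mag2 = float(config.magnitude_distribution.sample(rng, 1)[0])
                sign2 = toward_sign if rng.uniform() < 0.5 else -toward_sign
                plan.append(PlannedShift(onset_ms=second, magnitude_pct=sign2 * mag2))
                onsets.append(second)

    # unbiased background shifts outside a guard band around the window
    t0, t1 = config.epoch_window
    n_bg = rng.poisson(config.background_shift_rate)
    for _ in range(n_bg):
        for _attempt in range(20):
            onset = rng.uniform(t0 + 150.0, t1 - 150.0)
            if 150.0 <= onset <= 650.0:
                continue
            if all(abs(onset - o) > 110.0 for o in onsets):
                mag = float(config.magnitude_distribution.sample(rng, 1)[0])
                sign = 1.0 if rng.uniform() < 0.5 else -1.0
                plan.append(PlannedShift(onset_ms=onset, magnitude_pct=sign * mag))
                onsets.append(onset)
                break
    return sorted(plan, key=lambda s: s.onset_ms), true_class


def _draw_blinks(config: StudyConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    t0, t1 = config.epoch_window
    out = []
    for _ in range(rng.poisson(config.blink_rate)):
        dur = rng.uniform(100.0, 300.0)
        onset = rng.uniform(t0, t1 - dur)
        out.append((onset, onset + dur))
    return out


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate a full multi-participant synthetic study.

    Deterministic given ``config.seed``; random streams are split per
    participant and per trial so subsets are reproducible. Cued sides are
    balanced exactly within each participant.
    """
    config.validate()
    root_ss = np.random.SeedSequence(config.seed)
    participant_seeds = root_ss.spawn(config.n_participants)

    beh = config.behaviour_effects
    participants = []
    gt_rows = []
    for p_idx, p_ss in enumerate(participant_seeds):
        trial_seeds = p_ss.spawn(config.n_trials + 2)
        p_rng = np.random.default_rng(trial_seeds[-1])
        affine = EyeAffine(
            cx=512.0 + p_rng.normal(0, 20),
            cy=384.0 + p_rng.normal(0, 20),
            gx=35.0 + p_rng.normal(0, 2),
            gy=35.0 + p_rng.normal(0, 2),
        )
        calibration = generate_calibration(
            config, np.random.default_rng(trial_seeds[-2]), affine=affine
        )

        err_offset = p_rng.normal(0.0, beh["error_participant_sd_deg"])
        rt_offset = p_rng.normal(0.0, beh["rt_participant_sd_ms"])

        sides = np.array(["left", "right"])[
            p_rng.permutation(np.arange(config.n_trials) % 2)
        ]

        gaze_trials = []
        eeg_c, eeg_i = [], []
        rows = []
        time_ms = None
        for t_idx in range(config.n_trials):
            rng = np.random.default_rng(trial_seeds[t_idx])
            cued = str(sides[t_idx])
            selection_time = float(config.latency_distribution.sample(rng, 1)[0])
            plan, true_class = _plan_trial_shifts(config, selection_time, cued, rng)
            blinks = _draw_blinks(config, rng)
            trial = generate_gaze_trial(config, plan, rng, affine=affine, blink_intervals=blinks)
            time_ms = trial.time_ms

            mod_onset = selection_time + config.alpha_onset_lag
            depth = config.alpha_modulation_depth
            if true_class == "away":
                depth *= config.away_modulation_scale
            contra, ipsi = generate_alpha_signals(config, mod_onset, rng, depth=depth)

            err = max(
                0.0,
                rng.normal(beh["error_mean_deg"][true_class] + err_offset, beh["error_sd_deg"]),
            )
            rt = max(150.0, rng.normal(beh["rt_mean_ms"] + rt_offset, beh["rt_sd_ms"]))

            toward_sign = -1.0 if cued == "left" else 1.0
            for s in plan:
                gt_rows.append(
                    {
                        "participant": p_idx,
                        "trial": t_idx,
                        "onset_ms": s.onset_ms,
                        "magnitude_pct": s.magnitude_pct,
                        "direction": "toward" if s.magnitude_pct * toward_sign > 0 else "away",
                        "in_window": 200.0 <= s.onset_ms <= 600.0,
                    }
                )
            rows.append(
                {
                    "participant": p_idx,
                    "trial": t_idx,
                    "cued_side": cued,
                    "true_class": true_class,
                    "selection_time_ms": selection_time,
                    "modulation_onset_ms": mod_onset,
                    "modulation_depth": depth,
                    "n_planned_shifts": len(plan),
                    "blink_intervals": ";".join(f"{a:.1f}:{b:.1f}" for a, b in blinks),
                    "error_deg": err,
                    "rt_ms": rt,
                }
            )
            gaze_trials.append(trial)
            eeg_c.append(contra)
            eeg_i.append(ipsi)

        participants.append(
            ParticipantData(
                participant=p_idx,
                affine=affine,
                gaze=gaze_trials,
                calibration=calibration,
                eeg_contra=np.asarray(eeg_c),
                eeg_ipsi=np.asarray(eeg_i),
                eeg_time_ms=time_ms,
                trials=pd.DataFrame(rows),
            )
        )

    gt = pd.DataFrame(
        gt_rows,
        columns=["participant", "trial", "onset_ms", "magnitude_pct", "direction", "in_window"],
    )
    return SyntheticStudy(config=config, participants=participants, ground_truth=gt)


# --------------------------------------------------------------------------
# persistence


def save_study(study: SyntheticStudy, path: str | Path) -> None:
    """Write a study to HDF5 (groups /participant_i/trial_j/{gaze,eeg}, plus
    calibration and per-trial metadata tables)."""
    import json

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(study.config.to_dict())
        for p in study.participants:
            g = f.create_group(f"participant_{p.participant}")
            g.attrs["affine"] = [p.affine.cx, p.affine.cy, p.affine.gx, p.affine.gy]
            cal = g.create_group("calibration")
            for k, seg in enumerate(p.calibration.segments):
                sg = cal.create_group(f"segment_{k}")
                sg.attrs["label"] = seg.label
                sg.attrs["nominal_deg"] = list(seg.nominal_deg)
                sg.create_dataset("time_ms", data=seg.time_ms)
                sg.create_dataset("xy", data=np.stack([seg.x, seg.y]))
            g.create_dataset("eeg_time_ms", data=p.eeg_time_ms)
            g.create_dataset("eeg_contra", data=p.eeg_contra)
            g.create_dataset("eeg_ipsi", data=p.eeg_ipsi)
            g.create_dataset("gaze_time_ms", data=p.gaze[0].time_ms)
            gz = np.stack(
                [np.stack([t.lx, t.ly, t.rx, t.ry]) for t in p.gaze]
            )  # trials x 4 x samples
            g.create_dataset("gaze", data=gz)
            g.create_dataset(
                "trials_json", data=np.bytes_(p.trials.to_json(orient="split").encode())
            )
        f.create_dataset(
            "ground_truth_json",
            data=np.bytes_(study.ground_truth.to_json(orient="split").encode()),
        )


def load_study(path: str | Path) -> SyntheticStudy:
    import json
    from io import StringIO

    with h5py.File(Path(path), "r") as f:
        config = StudyConfig.from_dict(json.loads(f.attrs["config"]))
        participants = []
        for name in sorted(f.keys(), key=lambda s: (len(s), s)):
            if not name.startswith("participant_"):
                continue
            g = f[name]
            cx, cy, gx, gy = g.attrs["affine"]
            segments = []
            cal = g["calibration"]
            for k in sorted(cal.keys(), key=lambda s: int(s.split("_")[1])):
                sg = cal[k]
                x, y = np.asarray(sg["xy"])
                segments.append(
                    CalibrationSegment(
                        label=str(sg.attrs["label"]),
                        nominal_deg=tuple(sg.attrs["nominal_deg"]),
                        time_ms=np.asarray(sg["time_ms"]),
                        x=x,
                        y=y,
                    )
                )
            gtime = np.asarray(g["gaze_time_ms"])
            gaze = [
                GazeTrial(time_ms=gtime, lx=a[0], ly=a[1], rx=a[2], ry=a[3])
                for a in np.asarray(g["gaze"])
            ]
            trials = pd.read_json(
                StringIO(bytes(np.asarray(g["trials_json"])).decode()), orient="split"
            )
            participants.append(
                ParticipantData(
                    participant=int(name.split("_")[1]),
                    affine=EyeAffine(cx, cy, gx, gy),
                    gaze=gaze,
                    calibration=CalibrationRecording(segments=segments),
                    eeg_contra=np.asarray(g["eeg_contra"]),
                    eeg_ipsi=np.asarray(g["eeg_ipsi"]),
                    eeg_time_ms=np.asarray(g["eeg_time_ms"]),
                    trials=trials,
                )
            )
        gt = pd.read_json(
            StringIO(bytes(np.asarray(f["ground_truth_json"])).decode()), orient="split"
        )
    return SyntheticStudy(config=config, participants=participants, ground_truth=gt)
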