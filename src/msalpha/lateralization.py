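"""Time-frequency power and alpha-band lateralization contrasts.

Spectral power is estimated with a short-time Fourier transform of
Hanning-tapered 300-ms windows (1-50 Hz in 1-Hz steps, window advanced in
50-ms steps, or 1-ms steps in latency-resolution mode). Attentional
lateralization is expressed as the normalized contrast
``((contra - ipsi) / (contra + ipsi)) * 100`` between posterior electrode
clusters contra- and ipsilateral to the memorised item location, averaged
over the 8-12 Hz alpha band. The contrast is scale-invariant, so taper
energy normalization cancels and is omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TFRPower",
    "LateralizationTimecourse",
    "stft_power",
    "lateralization_contrast",
    "band_timecourse",
    "condition_tfr_contrast",
    "alpha_timecourse_by_participant",
    "ALPHA_BAND",
]

ALPHA_BAND = (8.0, 12.0)
STFT_WINDOW_MS = 300.0
FREQS_HZ = np.arange(1.0, 51.0)


@dataclass
class TFRPower:
    """Non-negative spectral power on a frequency x time grid."""

    power: np.ndarray  # (n_freqs, n_times) or (n_trials, n_freqs, n_times)
    freqs: np.ndarray  # Hz
    times: np.ndarray  # window centres, ms


@dataclass
class LateralizationTimecourse:
    times: np.ndarray
    values: np.ndarray  # %, in [-100, 100]
    band: tuple[float, float] = ALPHA_BAND
    condition: str = ""


def stft_power(
    signal: np.ndarray,
    time_ms: np.ndarray,
    sampling_rate: float = 1000.0,
    window_ms: float = STFT_WINDOW_MS,
    step_ms: float = 50.0,
    freqs: np.ndarray = FREQS_HZ,
) -> TFRPower:
    """Short-time Fourier power of Hanning-tapered data.

    ``signal`` may be 1-D (one trial) or 2-D (trials x samples). Windows are
    zero-padded to one second so the frequency axis lands on integer Hz;
    windows extending past the epoch are dropped, not padded. In
    latency-resolution mode pass ``step_ms=1``.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    time_ms = np.asarray(time_ms, dtype=float)
    nwin = int(round(window_ms * sampling_rate / 1000.0))
    if signal.shape[-1] < nwin:
        raise ValueError(
            f"signal of {signal.shape[-1]} samples shorter than the {nwin}-sample window"
        )
    step = int(round(step_ms * sampling_rate / 1000.0))
    taper = np.hanning(nwin)
    nfft = int(round(sampling_rate))  # 1-Hz bins
    fidx = np.asarray(freqs, dtype=int)

    windows = np.lib.stride_tricks.sliding_window_view(signal, nwin, axis=-1)[:, ::step, :]
    spec = np.fft.rfft(windows * taper, n=nfft, axis=-1)
    power = np.abs(spec[..., fidx]) ** 2  # (trials, times, freqs)
    power = np.moveaxis(power, -1, -2)  # (trials, freqs, times)
    starts = np.arange(windows.shape[1]) * step
    centres = time_ms[starts] + window_ms / 2.0
    if power.shape[0] == 1:
        power = power[0]
    return TFRPower(power=power, freqs=np.asarray(freqs, dtype=float), times=centres)


def lateralization_contrast(
    contra_power: np.ndarray, ipsi_power: np.ndarray
) -> np.ndarray:
    """Normalized lateralization contrast ((contra-ipsi)/(contra+ipsi))*100.

    Elementwise on aligned arrays; cells with a zero denominator are flagged
    NaN. Bounded by +/-100 and exactly antisymmetric under swapping the
    inputs.
    """
    c = np.asarray(contra_power, dtype=float)
    i = np.asarray(ipsi_power, dtype=float)
    if c.shape != i.shape:
        raise ValueError(f"power arrays misaligned: {c.shape} vs {i.shape}")
    denom = c + i
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (c - i) / np.where(denom > 0, denom, 1.0) * 100.0, np.nan)
    return out


def band_timecourse(
    contrast_tfr: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    band: tuple[float, float] = ALPHA_BAND,
    condition: str = "",
) -> LateralizationTimecourse:
    """Average a frequency x time contrast over a band (default 8-12 Hz)."""
    freqs = np.asarray(freqs, dtype=float)
    lo, hi = band
    if lo < freqs.min() or hi > freqs.max():
        raise ValueError(f"band {band} outside the frequency axis [{freqs.min()}, {freqs.max()}]")
    rows = (freqs >= lo) & (freqs <= hi)
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(np.asarray(contrast_tfr, dtype=float)[rows], axis=0)
    return LateralizationTimecourse(times=np.asarray(times), values=vals, band=band, condition=condition)


def condition_tfr_contrast(
    contra_trials: np.ndarray,
    ipsi_trials: np.ndarray,
    time_ms: np.ndarray,
    step_ms: float = 50.0,
    sampling_rate: float = 1000.0,
    average: str = "power",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial-set lateralization TFR for one condition.

    ``average="power"`` (default) averages spectral power across trials
    before forming the contrast; ``average="contrast"`` averages per-trial
    contrasts instead. Left- and right-cued trials enter symmetrically
    because channels are already expressed as contra/ipsi relative to the
    cued side. Returns (freqs, times, contrast array).
    """
    tfr_c = stft_power(contra_trials, time_ms, sampling_rate, step_ms=step_ms)
    tfr_i = stft_power(ipsi_trials, time_ms, sampling_rate, step_ms=step_ms)
    pc = tfr_c.power if tfr_c.power.ndim == 3 else tfr_c.power[None]
    pi = tfr_i.power if tfr_i.power.ndim == 3 else tfr_i.power[None]
    if average == "power":
        contrast = lateralization_contrast(pc.mean(axis=0), pi.mean(axis=0))
    elif average == "contrast":
        contrast = np.nanmean(lateralization_contrast(pc, pi), axis=0)
    else:
        raise ValueError(f"average must be 'power' or 'contrast', got {average!r}")
    return tfr_c.freqs, tfr_c.times, contrast


def alpha_timecourse_by_participant(
    contra_by_participant: list[np.ndarray],
    ipsi_by_participant: list[np.ndarray],
    time_ms: np.ndarray,
    step_ms: float = 50.0,
    sampling_rate: float = 1000.0,
    band: tuple[float, float] = ALPHA_BAND,
    average: str = "power",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant alpha-band lateralization timecourses.

    Returns (window centres, array participants x times); the participant
    dimension is what permutation statistics resample.
    """
    rows = []
    times = None
    for c_tr, i_tr in zip(contra_by_participant, ipsi_by_participant):
        freqs, times, contrast = condition_tfr_contrast(
            c_tr, i_tr, time_ms, step_ms=step_ms, sampling_rate=sampling_rate, average=average
        )
        rows.append(band_timecourse(contrast, freqs, times, band=band).values)
    return times, np.asarray(rows)
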