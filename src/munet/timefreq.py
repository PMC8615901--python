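"""Morlet amplitude time-frequency analysis and mu-band suppression scores.

The analysis applies a continuous wavelet transform with Morlet wavelets at
1 Hz steps over 3-20 Hz to every artifact-free trial, takes the modulus of the
complex coefficients (amplitude in µV, not power), and averages across trials.
The first and last 400 ms of the epoch are trimmed to remove wavelet edge
distortion, a scalar baseline (the mean over -600..-100 ms) is subtracted per
channel and frequency, and the mu-suppression score is the mean over the
inclusive 6-9 Hz bins, a named channel cluster, and the 400-800 ms window.
Negative scores index suppression (desynchronisation) relative to baseline.

Wavelets are amplitude-normalised: a unit-amplitude sinusoid at a wavelet's
centre frequency yields modulus 1, so time-frequency values stay in µV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .epochs import EpochSet
from .montage import ElectrodeMontage

__all__ = [
    "TimeFrequencyRep",
    "morlet_kernel",
    "morlet_coefficients",
    "morlet_tfr",
    "trim_edges",
    "baseline_subtract",
    "band_cluster_mean",
    "band_indices",
    "sinusoid_band_response",
    "mu_suppression_table",
]

DEFAULT_N_CYCLES = 5.0
DEFAULT_FREQS = np.arange(3.0, 21.0)  # 3..20 Hz at 1 Hz steps


class TimeFrequencyError(ValueError):
    """Raised for invalid time-frequency parameters or state transitions."""


@dataclass
class TimeFrequencyRep:
    """Trial-averaged amplitude over channels x frequencies x time (µV)."""

    amplitude: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    labels: np.ndarray
    baseline_corrected: bool = False
    trimmed: bool = False

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.amplitude.shape != (
            self.labels.size,
            self.freqs.size,
            self.times_ms.size,
        ):
            raise TimeFrequencyError("amplitude shape does not match axes")


def morlet_kernel(freq: float, fs: float, n_cycles: float = DEFAULT_N_CYCLES) -> np.ndarray:
    """Complex Morlet wavelet, amplitude-normalised and zero-mean.

    The Gaussian envelope has sigma_t = n_cycles / (2*pi*freq); the kernel
    spans +-5 sigma_t.  Normalisation is such that convolving with
    cos(2*pi*freq*t) yields modulus 1, and the kernel mean is removed so a
    constant signal maps to ~0.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t**2) / (2.0 * sigma_t**2))
    w = gauss * np.exp(2j * np.pi * freq * t)
    w = w - w.mean()
    # modulus response of the analytic kernel to a unit cosine at `freq`
    # is 0.5 * sum(gauss) (negative-frequency leakage is negligible)
    return w / (0.5 * gauss.sum())


def sinusoid_band_response(
    f0: float, band_freqs: np.ndarray, n_cycles: float = DEFAULT_N_CYCLES
) -> float:
    """Band-average modulus response to a unit-amplitude sinusoid at ``f0``.

    For the amplitude-normalised Morlet at centre frequency f_b the response
    to a sinusoid at f0 is exp(-(f0-f_b)^2 / (2*sigma_f^2)) with
    sigma_f = f_b / n_cycles; the band response is the mean over the band's
    frequency bins.  Used by the synthetic generator to calibrate injected
    ERD amplitudes.
    """
    band_freqs = np.asarray(band_freqs, dtype=float)
    sigma_f = band_freqs / n_cycles
    return float(np.mean(np.exp(-((f0 - band_freqs) ** 2) / (2.0 * sigma_f**2))))


def morlet_coefficients(
    data: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    n_cycles: float = DEFAULT_N_CYCLES,
) -> np.ndarray:
    """Complex Morlet coefficients of ``data`` (..., n_samples).

    Returns an array of shape ``(..., n_freqs, n_samples)``.  Convolution is
    'same'-mode; edge samples are distorted and should be trimmed downstream.
    """
    data = np.asarray(data, dtype=float)
    out = np.empty((*data.shape[:-1], len(freqs), data.shape[-1]), dtype=complex)
    pad_width = [(0, 0)] * (data.ndim - 1)
    for k, f in enumerate(freqs):
        w = morlet_kernel(float(f), fs, n_cycles)
        half = len(w) // 2
        # reflect-pad so every output sample sees the full (zero-mean) kernel
        padded = np.pad(data, [*pad_width, (half, half)], mode="reflect")
        out[..., k, :] = fftconvolve(
            padded, w[(np.newaxis,) * (data.ndim - 1)], mode="valid", axes=-1
        )
    return out


def morlet_tfr(
    epochs: EpochSet,
    f_min: float = 3.0,
    f_max: float = 20.0,
    f_step: float = 1.0,
    n_cycles: float = DEFAULT_N_CYCLES,
    channels=None,
) -> TimeFrequencyRep:
    """Trial-averaged Morlet amplitude of an epoch set.

    The modulus is taken per trial *before* averaging across trials.
    ``channels`` optionally restricts the computation to a subset of 1-based
    channel numbers.
    """
    nyquist = epochs.fs / 2.0
    if f_max >= nyquist:
        raise TimeFrequencyError(f"f_max={f_max} must be below Nyquist ({nyquist})")
    if n_cycles < 1:
        raise TimeFrequencyError("n_cycles must be >= 1")
    es = epochs if channels is None else epochs.select_channels(channels)
    freqs = np.arange(f_min, f_max + f_step / 2.0, f_step)
    coefs = morlet_coefficients(es.data, es.fs, freqs, n_cycles)
    amplitude = np.abs(coefs).mean(axis=0)  # average modulus across trials
    return TimeFrequencyRep(
        amplitude=amplitude,
        freqs=freqs,
        times_ms=es.times_ms,
        labels=es.labels,
    )


def trim_edges(tfr: TimeFrequencyRep, trim_ms: float = 400.0) -> TimeFrequencyRep:
    """Drop ``trim_ms`` from both ends of the time axis (wavelet edge effects)."""
    if tfr.trimmed:
        raise TimeFrequencyError("time axis already trimmed")
    if trim_ms < 0:
        raise TimeFrequencyError("trim_ms must be nonnegative")
    span = tfr.times_ms[-1] - tfr.times_ms[0]
    if 2 * trim_ms >= span:
        raise TimeFrequencyError("trim exceeds half the epoch")
    if trim_ms == 0:
        return replace(tfr, trimmed=True)
    keep = (tfr.times_ms >= tfr.times_ms[0] + trim_ms) & (
        tfr.times_ms < tfr.times_ms[-1] - trim_ms + 1e-9
    )
    return replace(
        tfr,
        amplitude=tfr.amplitude[:, :, keep],
        times_ms=tfr.times_ms[keep],
        trimmed=True,
    )


def baseline_subtract(
    tfr: TimeFrequencyRep, b_start: float = -600.0, b_end: float = -100.0
) -> TimeFrequencyRep:
    """Subtract the scalar [b_start, b_end) baseline mean per channel x frequency."""
    if tfr.baseline_corrected:
        raise TimeFrequencyError("already baseline corrected")
    mask = (tfr.times_ms >= b_start) & (tfr.times_ms < b_end)
    if not mask.any() or b_start < tfr.times_ms[0] - 1e-9:
        raise TimeFrequencyError("baseline window outside the time axis")
    base = tfr.amplitude[:, :, mask].mean(axis=2, keepdims=True)
    return replace(tfr, amplitude=tfr.amplitude - base, baseline_corrected=True)


def band_indices(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Indices of the inclusive frequency bins of ``band``."""
    lo, hi = band
    idx = np.flatnonzero((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9))
    if idx.size == 0:
        raise TimeFrequencyError(f"band {band} outside computed frequencies")
    return idx


def band_cluster_mean(
    tfr: TimeFrequencyRep,
    montage: ElectrodeMontage,
    cluster: str,
    band: tuple[float, float] = (6.0, 9.0),
    window: tuple[float, float] = (400.0, 800.0),
) -> float:
    """Mean baseline-subtracted amplitude over band bins, cluster, and window.

    Band bins and window endpoints are inclusive.  Requires a
    baseline-corrected representation; negative values index mu suppression.
    """
    if not tfr.baseline_corrected:
        raise TimeFrequencyError("baseline correction required before scoring")
    fidx = band_indices(tfr.freqs, band)
    tmask = (tfr.times_ms >= window[0] - 1e-9) & (tfr.times_ms <= window[1] + 1e-9)
    chans = montage.cluster_channels(cluster)
    lookup = {lab: i for i, lab in enumerate(tfr.labels.tolist())}
    missing = [c for c in chans.tolist() if c not in lookup]
    if missing:
        raise TimeFrequencyError(f"cluster {cluster!r} channels missing: {missing}")
    rows = np.array([lookup[c] for c in chans.tolist()])
    return float(tfr.amplitude[np.ix_(rows, fidx)][:, :, tmask].mean())


def mu_suppression_table(
    tfrs: dict[tuple[str, str, str], TimeFrequencyRep],
    montage: ElectrodeMontage,
    clusters=("C3", "C4", "O"),
    band: tuple[float, float] = (6.0, 9.0),
    window: tuple[float, float] = (400.0, 800.0),
) -> pd.DataFrame:
    """Build the subject x condition x emotion x cluster suppression table.

    ``tfrs`` maps (subject, condition, emotion) to a trimmed,
    baseline-corrected TimeFrequencyRep.  Values are µV; one row per
    subject x emotion x cluster.
    """
    rows = []
    for (subject, condition, emotion), tfr in sorted(tfrs.items()):
        for cluster in clusters:
            rows.append(
                {
                    "subject": subject,
                    "condition": condition,
                    "emotion": emotion,
                    "cluster": cluster,
                    "value": band_cluster_mean(tfr, montage, cluster, band, window),
                }
            )
    return pd.DataFrame(rows)
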