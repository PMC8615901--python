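"""Volume-conduction-resistant functional connectivity: CSD + DWPLI.

Scalp potentials are first transformed to current source density (CSD, the
negative spherical-spline surface Laplacian), a reference-free transform that
sharpens topographies and attenuates volume conduction.  On CSD data, the
debiased weighted phase-lag index (DWPLI) is computed in the 6-9 Hz mu band:
per trial, Morlet cross-spectra are averaged over the band bins and the
post-stimulus analysis window to one complex value per channel pair; across
trials the debiased WPLI-square estimator is

    dwpli = [ (sum_t I_t)^2 - sum_t I_t^2 ] / [ (sum_t |I_t|)^2 - sum_t I_t^2 ]

with I_t the imaginary part of the trial cross-spectrum.  The estimator is
insensitive to zero-lag (volume-conducted) coupling, has expectation ~0 for
independent signals at any trial count, and can be negative at small samples.
One symmetric matrix is produced per subject, per condition, per emotion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet
from .montage import ElectrodeMontage
from .spline import DEFAULT_N_TERMS, DEFAULT_ORDER, DEFAULT_REG, csd_matrix
from .timefreq import DEFAULT_N_CYCLES, band_indices, morlet_coefficients

__all__ = [
    "ConnectivityMatrix",
    "CrossSpectra",
    "csd_transform",
    "band_cross_spectrum",
    "dwpli",
    "save_connectivity",
    "load_connectivity",
]


class ConnectivityError(ValueError):
    pass


@dataclass
class ConnectivityMatrix:
    """Symmetric DWPLI adjacency over channels (zero diagonal, values <= 1)."""

    values: np.ndarray
    labels: np.ndarray
    band: tuple[float, float] = (6.0, 9.0)
    subject: str = "S00"
    condition: str = "dynamic"
    emotion: str = "neutral"
    estimator: str = "dwpli"
    n_zero_denominator: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.labels.size
        if self.values.shape != (n, n):
            raise ConnectivityError("values must be square over labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ConnectivityError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ConnectivityError("diagonal must be zero")
        if np.any(self.values > 1.0 + 1e-12):
            raise ConnectivityError("DWPLI values cannot exceed 1")


@dataclass
class CrossSpectra:
    """Per-trial band-averaged complex cross-spectra, shape (T, n, n)."""

    values: np.ndarray
    labels: np.ndarray
    band: tuple[float, float]
    subject: str
    condition: str
    emotion: str

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def csd_transform(
    epochs: EpochSet,
    montage: ElectrodeMontage,
    order: int = DEFAULT_ORDER,
    n_terms: int = DEFAULT_N_TERMS,
    reg: float = DEFAULT_REG,
) -> EpochSet:
    """Apply the spherical-spline surface Laplacian (CSD) per sample.

    The result is reference-free: adding a constant across channels leaves the
    output unchanged.  Units become Laplacian units (documented as µV per
    squared unit arc on the unit sphere); ``reference_state`` becomes "csd".
    """
    if epochs.reference_state == "csd":
        raise ConnectivityError("data already CSD-transformed")
    if not np.array_equal(np.sort(montage.labels), np.sort(epochs.labels)):
        raise ConnectivityError("montage channels do not match epochs")
    lookup = {lab: i for i, lab in enumerate(epochs.labels.tolist())}
    pos = np.empty((epochs.n_channels, 3))
    for lab, row in zip(montage.labels.tolist(), montage.positions):
        pos[lookup[lab]] = row
    T = csd_matrix(pos, order, n_terms, reg)
    data = np.einsum("ij,tjs->tis", T, epochs.data)
    return epochs.copy(data=data, reference_state="csd")


def band_cross_spectrum(
    epochs: EpochSet,
    band: tuple[float, float] = (6.0, 9.0),
    window: tuple[float, float] = (0.0, 1000.0),
    n_cycles: float = DEFAULT_N_CYCLES,
    require_csd: bool = True,
) -> CrossSpectra:
    """Per-trial complex cross-spectra averaged over band bins and window.

    Uses the same Morlet family as the time-frequency analysis at the band's
    integer bins; cross-products a_i * conj(a_j) are averaged over the band
    bins and the window samples, yielding one complex value per channel pair
    per trial.
    """
    if require_csd and epochs.reference_state != "csd":
        raise ConnectivityError("cross-spectra are computed on CSD data")
    nyq = epochs.fs / 2.0
    if not 0 < band[0] <= band[1] < nyq:
        raise ConnectivityError(f"band {band} outside (0, Nyquist)")
    freqs = np.arange(np.ceil(band[0]), np.floor(band[1]) + 1e-9)
    band_indices(freqs, band)  # validates non-empty
    tmask = (epochs.times_ms >= window[0] - 1e-9) & (epochs.times_ms <= window[1] + 1e-9)
    if not tmask.any():
        raise ConnectivityError(f"window {window} outside the epoch")
    X = np.empty((epochs.n_trials, epochs.n_channels, epochs.n_channels), dtype=complex)
    norm = freqs.size * int(tmask.sum())
    for t in range(epochs.n_trials):
        coefs = morlet_coefficients(epochs.data[t], epochs.fs, freqs, n_cycles)
        a = coefs[:, :, tmask]  # (channels, freqs, window samples)
        X[t] = np.einsum("ifs,jfs->ij", a, np.conj(a)) / norm
    return CrossSpectra(
        values=X,
        labels=epochs.labels.copy(),
        band=band,
        subject=epochs.subject_id,
        condition=epochs.condition,
        emotion=epochs.emotion,
    )


def dwpli(cross: CrossSpectra) -> ConnectivityMatrix:
    """Debiased weighted phase-lag index across trials.

    Channel pairs whose denominator vanishes (e.g. identical signals, all
    imaginary parts zero) are set to 0 and counted in
    ``n_zero_denominator``.
    """
    if cross.n_trials < 2:
        raise ConnectivityError("DWPLI needs at least 2 trials")
    imag = np.imag(cross.values)  # (T, n, n)
    sum_i = imag.sum(axis=0)
    sum_i2 = (imag**2).sum(axis=0)
    sum_abs = np.abs(imag).sum(axis=0)
    num = sum_i**2 - sum_i2
    den = sum_abs**2 - sum_i2
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    n = values.shape[0]
    off = ~np.eye(n, dtype=bool)
    n_zero = int(np.count_nonzero((den <= 0) & off)) // 2
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(
        values=values,
        labels=cross.labels.copy(),
        band=cross.band,
        subject=cross.subject,
        condition=cross.condition,
        emotion=cross.emotion,
        n_zero_denominator=n_zero,
    )


def save_connectivity(conn: ConnectivityMatrix, path) -> None:
    """Plain-text export: one header line, then the square matrix."""
    header = (
        f"# subject={conn.subject} condition={conn.condition} "
        f"emotion={conn.emotion} band={conn.band[0]}-{conn.band[1]} "
        f"estimator={conn.estimator} labels={','.join(map(str, conn.labels))}"
    )
    np.savetxt(path, conn.values, header=header, comments="")


def load_connectivity(path) -> ConnectivityMatrix:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip()
    meta = dict(item.split("=", 1) for item in header.split())
    values = np.loadtxt(path, skiprows=1)
    lo, hi = meta["band"].split("-")
    return ConnectivityMatrix(
        values=values,
        labels=np.array([int(x) for x in meta["labels"].split(",")]),
        band=(float(lo), float(hi)),
        subject=meta["subject"],
        condition=meta["condition"],
        emotion=meta["emotion"],
        estimator=meta.get("estimator", "dwpli"),
    )
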