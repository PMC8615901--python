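"""Artifact rejection and referencing chain for epoched infant EEG.

The chain mirrors standard developmental-EEG practice: zero-phase 0.3 Hz
high-pass, flagging of trial/channel pairs whose absolute signal exceeds
±200 µV (strictly greater — boundary equality is kept), rejection of trials
with more than 15% bad channels, spherical-spline interpolation of the
remaining bad channels within each surviving trial, re-referencing to the
common average, and a minimum of 5 surviving trials per emotion for a subject
to enter the group analysis.

The canonical stage order is highpass -> detect -> reject -> interpolate ->
average reference; :func:`preprocess` runs it and records the order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .epochs import EpochSet
from .montage import ElectrodeMontage
from .spline import DEFAULT_N_TERMS, DEFAULT_ORDER, DEFAULT_REG, interpolation_matrix

__all__ = [
    "ArtifactFlags",
    "highpass",
    "detect_bad",
    "reject_trials",
    "interpolate_channels",
    "average_reference",
    "qc_min_trials",
    "preprocess",
    "qc_report",
]

DEFAULT_THRESHOLD_UV = 200.0
DEFAULT_MAX_BAD_FRACTION = 0.15
DEFAULT_MIN_TRIALS = 5
DEFAULT_HIGHPASS_HZ = 0.3


class PreprocessingError(ValueError):
    pass


@dataclass
class ArtifactFlags:
    """Per-trial/channel bad flags, rejected trials, channels to interpolate."""

    bad: np.ndarray  # (n_trials, n_channels) bool
    rejected_trials: set[int] = field(default_factory=set)
    interpolated: dict[int, set[int]] = field(default_factory=dict)
    unrecoverable: set[int] = field(default_factory=set)

    @property
    def kept_trials(self) -> list[int]:
        dropped = self.rejected_trials | self.unrecoverable
        return [t for t in range(self.bad.shape[0]) if t not in dropped]


def highpass(epochs: EpochSet, cutoff: float = DEFAULT_HIGHPASS_HZ, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth high-pass (forward-backward); removes DC."""
    nyq = epochs.fs / 2.0
    if not 0 < cutoff < nyq:
        raise PreprocessingError(f"cutoff {cutoff} Hz must be in (0, {nyq}) Hz")
    sos = butter(order, cutoff, btype="highpass", fs=epochs.fs, output="sos")
    return epochs.copy(data=sosfiltfilt(sos, epochs.data, axis=-1))


def detect_bad(epochs: EpochSet, threshold: float = DEFAULT_THRESHOLD_UV) -> ArtifactFlags:
    """Flag trial/channel pairs whose absolute amplitude exceeds ``threshold``.

    The comparison is strict (> threshold): a peak exactly at the threshold is
    not flagged.
    """
    if threshold <= 0:
        raise PreprocessingError("threshold must be positive")
    bad = np.max(np.abs(epochs.data), axis=-1) > threshold
    return ArtifactFlags(bad=bad)


def reject_trials(
    flags: ArtifactFlags, max_bad_fraction: float = DEFAULT_MAX_BAD_FRACTION
) -> ArtifactFlags:
    """Reject trials whose bad-channel fraction strictly exceeds the limit.

    Surviving trials' bad channels are queued for interpolation.
    """
    if not 0 < max_bad_fraction < 1:
        raise PreprocessingError("max_bad_fraction must be in (0, 1)")
    n_channels = flags.bad.shape[1]
    rejected: set[int] = set()
    interpolated: dict[int, set[int]] = {}
    for t in range(flags.bad.shape[0]):
        bad_idx = set(np.flatnonzero(flags.bad[t]).tolist())
        if len(bad_idx) / n_channels > max_bad_fraction:
            rejected.add(t)
        elif bad_idx:
            interpolated[t] = bad_idx
    return ArtifactFlags(bad=flags.bad, rejected_trials=rejected, interpolated=interpolated)


def interpolate_channels(
    epochs: EpochSet,
    flags: ArtifactFlags,
    montage: ElectrodeMontage,
    order: int = DEFAULT_ORDER,
    n_terms: int = DEFAULT_N_TERMS,
    reg: float = DEFAULT_REG,
) -> tuple[EpochSet, ArtifactFlags]:
    """Replace each surviving trial's bad channels by spherical-spline estimates.

    Good channels are untouched.  Trials with fewer than 4 good channels
    cannot support the spline and are marked unrecoverable.
    """
    if not np.array_equal(np.sort(montage.labels), np.sort(epochs.labels)):
        raise PreprocessingError("montage channels do not match epochs")
    order_in_epochs = {lab: i for i, lab in enumerate(epochs.labels.tolist())}
    pos = np.empty((epochs.n_channels, 3))
    for lab, row in zip(montage.labels.tolist(), montage.positions):
        pos[order_in_epochs[lab]] = row
    out = epochs.copy()
    unrecoverable = set(flags.unrecoverable)
    cache: dict[frozenset, np.ndarray] = {}
    for t, bad_idx in flags.interpolated.items():
        if t in flags.rejected_trials:
            continue
        good = sorted(set(range(epochs.n_channels)) - bad_idx)
        if len(good) < 4:
            unrecoverable.add(t)
            continue
        key = frozenset(bad_idx)
        if key not in cache:
            cache[key] = interpolation_matrix(
                pos[good], pos[sorted(bad_idx)], order, n_terms, reg
            )
        out.data[t, sorted(bad_idx)] = cache[key] @ epochs.data[t, good]
    new_flags = ArtifactFlags(
        bad=flags.bad,
        rejected_trials=set(flags.rejected_trials),
        interpolated={t: set(v) for t, v in flags.interpolated.items()},
        unrecoverable=unrecoverable,
    )
    return out, new_flags


def average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the common average (per-sample channel mean removed)."""
    if epochs.reference_state != "vertex":
        raise PreprocessingError(
            f"average reference requires vertex-referenced data, "
            f"got {epochs.reference_state!r}"
        )
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy(data=data, reference_state="average")


def qc_min_trials(
    trial_counts: dict[str, int], min_trials: int = DEFAULT_MIN_TRIALS
) -> bool:
    """Subject inclusion rule: every emotion needs >= ``min_trials`` survivors."""
    if min_trials < 1:
        raise PreprocessingError("min_trials must be >= 1")
    if not trial_counts:
        return False
    return all(n >= min_trials for n in trial_counts.values())


def preprocess(
    epochs: EpochSet,
    montage: ElectrodeMontage,
    threshold: float = DEFAULT_THRESHOLD_UV,
    max_bad_fraction: float = DEFAULT_MAX_BAD_FRACTION,
    hp_cutoff: float = DEFAULT_HIGHPASS_HZ,
    log: list | None = None,
) -> tuple[EpochSet, ArtifactFlags]:
    """Run the full chain and return clean, average-referenced epochs.

    Stages run in the canonical order (highpass, detect, reject, interpolate,
    average reference); rejected and unrecoverable trials are dropped from the
    returned EpochSet.  ``log`` (if given) accumulates stage names.
    """
    stages = log if log is not None else []
    es = highpass(epochs, hp_cutoff)
    stages.append("highpass")
    flags = detect_bad(es, threshold)
    stages.append("detect_bad")
    flags = reject_trials(flags, max_bad_fraction)
    stages.append("reject_trials")
    es, flags = interpolate_channels(es, flags, montage)
    stages.append("interpolate_channels")
    kept = flags.kept_trials
    if not kept:
        raise PreprocessingError(
            f"no surviving trials for {epochs.subject_id}/{epochs.emotion}"
        )
    es = es.select_trials(kept)
    es = average_reference(es)
    stages.append("average_reference")
    return es, flags


def qc_report(records: list[dict]) -> pd.DataFrame:
    """Assemble the QC table (one row per subject x condition x emotion).

    Each record needs: subject, condition, emotion, trials_in,
    trials_rejected, channels_interpolated_mean.
    """
    cols = [
        "subject",
        "condition",
        "emotion",
        "trials_in",
        "trials_rejected",
        "channels_interpolated_mean",
    ]
    return pd.DataFrame(records, columns=cols)
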