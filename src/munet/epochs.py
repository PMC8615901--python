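"""Epoched EEG container and I/O.

An :class:`EpochSet` holds the trials of one subject in one experimental
condition (dynamic or static face presentation) for one emotion (happiness,
anger, neutral): an array of shape ``(n_trials, n_channels, n_samples)`` in
microvolts, sampled at 500 Hz over a window from -1000 ms to +1400 ms around
stimulus onset, together with its referencing state.

Containers round-trip through HDF5 (datasets ``data``, ``fs``, ``t0``,
``labels``; attributes ``subject``, ``condition``, ``emotion``,
``reference_state``).  Continuous EDF recordings can be segmented into
EpochSets from a plain-text event table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

CONDITIONS = ("dynamic", "static")
EMOTIONS = ("happiness", "anger", "neutral")
REFERENCE_STATES = ("vertex", "average", "csd")

DEFAULT_FS = 500.0
DEFAULT_T0_MS = -1000.0
DEFAULT_N_SAMPLES = 1200  # 2400 ms at 500 Hz


class EpochError(ValueError):
    """Raised for invalid epoch containers or state transitions."""


@dataclass
class EpochSet:
    """Trials x channels x samples of one subject/condition/emotion, in µV."""

    data: np.ndarray
    fs: float = DEFAULT_FS
    t0_ms: float = DEFAULT_T0_MS
    subject_id: str = "S00"
    condition: str = "dynamic"
    emotion: str = "neutral"
    reference_state: str = "vertex"
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise EpochError("data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[0] < 1:
            raise EpochError("need at least one trial")
        if self.condition not in CONDITIONS:
            raise EpochError(f"condition must be one of {CONDITIONS}")
        if self.emotion not in EMOTIONS:
            raise EpochError(f"emotion must be one of {EMOTIONS}")
        if self.reference_state not in REFERENCE_STATES:
            raise EpochError(f"reference_state must be one of {REFERENCE_STATES}")
        if self.labels is None:
            self.labels = np.arange(1, self.data.shape[1] + 1)
        else:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.size != self.data.shape[1]:
                raise EpochError("labels length must match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs

    def copy(self, **changes) -> "EpochSet":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "labels" not in changes and self.labels is not None:
            out.labels = self.labels.copy()
        return out

    def select_trials(self, keep) -> "EpochSet":
        keep = np.asarray(keep, dtype=int)
        return self.copy(data=self.data[keep])

    def select_channels(self, channels) -> "EpochSet":
        """Restrict to the given 1-based channel numbers (sorted)."""
        channels = sorted(int(c) for c in channels)
        lookup = {lab: i for i, lab in enumerate(self.labels.tolist())}
        rows = np.array([lookup[c] for c in channels], dtype=int)
        return self.copy(data=self.data[:, rows], labels=np.array(channels))


def save_epochs(epochs: EpochSet, path) -> None:
    """Write an EpochSet to the documented HDF5 container layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("fs", data=float(epochs.fs))
        f.create_dataset("t0", data=float(epochs.t0_ms))
        f.create_dataset("labels", data=epochs.labels)
        f.attrs["subject"] = epochs.subject_id
        f.attrs["condition"] = epochs.condition
        f.attrs["emotion"] = epochs.emotion
        f.attrs["reference_state"] = epochs.reference_state


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            t0_ms=float(f["t0"][()]),
            labels=f["labels"][()],
            subject_id=str(f.attrs["subject"]),
            condition=str(f.attrs["condition"]),
            emotion=str(f.attrs["emotion"]),
            reference_state=str(f.attrs["reference_state"]),
        )


def read_event_table(path) -> list[tuple[int, str, str]]:
    """Read a plain-text event table: ``onset_sample<TAB>condition<TAB>emotion``.

    Lines starting with '#' and a header line naming the columns are skipped.
    """
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if parts[0] == "onset_sample":
                continue
            onset, condition, emotion = parts[:3]
            events.append((int(onset), condition, emotion))
    return events


def epochs_from_edf(
    edf_path,
    event_table_path,
    subject_id: str,
    pre_ms: float = 1000.0,
    post_ms: float = 1400.0,
) -> list[EpochSet]:
    """Segment a continuous EDF+ recording into EpochSets.

    Events are grouped by (condition, emotion); one EpochSet is returned per
    group.  Epochs extending past the recording edge are dropped.  Signal
    units are converted to µV (MNE reads EDF in volts).
    """
    import mne

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    fs = float(raw.info["sfreq"])
    n_pre = int(round(pre_ms * fs / 1000.0))
    n_post = int(round(post_ms * fs / 1000.0))
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    for onset, condition, emotion in read_event_table(event_table_path):
        start, stop = onset - n_pre, onset + n_post
        if start < 0 or stop > data_uv.shape[1]:
            continue
        groups.setdefault((condition, emotion), []).append(data_uv[:, start:stop])
    out = []
    for (condition, emotion), trials in sorted(groups.items()):
        out.append(
            EpochSet(
                data=np.stack(trials),
                fs=fs,
                t0_ms=-pre_ms,
                subject_id=subject_id,
                condition=condition,
                emotion=emotion,
                reference_state="vertex",
            )
        )
    return out
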