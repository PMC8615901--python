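"""Electrode montage: geodesic-style sensor layouts and named channel clusters.

The montage is a set of labelled electrode positions on the unit sphere plus
named channel clusters.  The three clusters used throughout the analysis are
the left- and right-central sensorimotor clusters (scalp locations of C3/C4 in
the 10-20 system) and an occipital cluster (O1/Oz/O2), defined as fixed sets
of 1-based channel numbers on a 128-channel geodesic net.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeMontage",
    "build_montage",
    "read_sfp",
    "write_sfp",
    "CLUSTER_C3",
    "CLUSTER_C4",
    "CLUSTER_O",
]

# 1-based channel numbers of the study clusters on the 128-channel net.
CLUSTER_C3 = frozenset({30, 31, 36, 37, 41, 42, 53, 54})
CLUSTER_C4 = frozenset({79, 80, 86, 87, 93, 103, 104, 105})
CLUSTER_O = frozenset({70, 71, 75, 76, 83})

_STUDY_CLUSTERS = {"C3": CLUSTER_C3, "C4": CLUSTER_C4, "O": CLUSTER_O}


class MontageError(ValueError):
    """Raised for invalid montage configurations."""


@dataclass
class ElectrodeMontage:
    """Channel labels, unit-sphere positions and named channel clusters.

    Parameters
    ----------
    labels : array of int
        1-based channel numbers, one per electrode.
    positions : ndarray, shape (n_channels, 3)
        Cartesian positions on the unit sphere (unit norm).
    clusters : dict of str -> frozenset of int
        Named clusters given as sets of channel numbers (subsets of `labels`).
    """

    labels: np.ndarray
    positions: np.ndarray
    clusters: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.labels.size, 3):
            raise MontageError(
                f"positions shape {self.positions.shape} does not match "
                f"{self.labels.size} labels"
            )
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise MontageError("positions must lie on the unit sphere")
        label_set = set(self.labels.tolist())
        for name, members in self.clusters.items():
            missing = sorted(set(members) - label_set)
            if missing:
                raise MontageError(
                    f"cluster {name!r} references missing channels {missing}"
                )

    @property
    def n_channels(self) -> int:
        return self.labels.size

    def cluster_channels(self, name: str) -> np.ndarray:
        """Sorted 1-based channel numbers of a named cluster."""
        if name not in self.clusters:
            raise KeyError(f"unknown cluster {name!r}; have {sorted(self.clusters)}")
        return np.array(sorted(self.clusters[name]), dtype=int)

    def cluster_indices(self, name: str) -> np.ndarray:
        """Sorted 0-based positional indices of a named cluster's channels."""
        chans = self.cluster_channels(name)
        lookup = {lab: i for i, lab in enumerate(self.labels.tolist())}
        return np.array([lookup[c] for c in chans], dtype=int)

    def add_cluster(self, name: str, channels) -> None:
        members = frozenset(int(c) for c in channels)
        missing = sorted(members - set(self.labels.tolist()))
        if missing:
            raise MontageError(
                f"cluster {name!r} references missing channels {missing}"
            )
        self.clusters[name] = members

    def subset(self, channels) -> "ElectrodeMontage":
        """Montage restricted to the given 1-based channel numbers."""
        channels = np.array(sorted(int(c) for c in channels), dtype=int)
        idx = {lab: i for i, lab in enumerate(self.labels.tolist())}
        rows = np.array([idx[c] for c in channels], dtype=int)
        keep = set(channels.tolist())
        clusters = {
            name: frozenset(m & keep)
            for name, m in self.clusters.items()
            if m & keep
        }
        return ElectrodeMontage(channels, self.positions[rows], clusters)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform spherical point layout (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


# Scalp anchors (unit vectors; +z vertex, +x nose) for the study clusters:
# left/right central at 45 deg lateral from the vertex, occipital toward the
# back of the head.  Cluster channel numbers are assigned to the layout points
# nearest these anchors so the clusters are spatially coherent patches, as on
# a physical geodesic net.
_CLUSTER_ANCHORS = {
    "C3": np.array([0.0, -np.sin(np.pi / 4), np.cos(np.pi / 4)]),
    "C4": np.array([0.0, np.sin(np.pi / 4), np.cos(np.pi / 4)]),
    "O": np.array([-np.sin(np.deg2rad(75)), 0.0, np.cos(np.deg2rad(75))]),
}


def build_montage(n_channels: int = 128) -> ElectrodeMontage:
    """Build a deterministic quasi-uniform spherical montage.

    Layout points come from a golden-angle spiral; the study clusters "C3",
    "C4" and "O" are registered from their fixed channel numbers, and those
    channel numbers are mapped to spatially coherent patches around
    left-central, right-central and occipital scalp anchors.  ``n_channels``
    must cover the largest cluster channel number (105).

    Raises
    ------
    MontageError
        If ``n_channels`` is too small, naming the missing channel numbers.
    """
    needed = sorted(set().union(*_STUDY_CLUSTERS.values()))
    missing = [c for c in needed if c > n_channels]
    if missing:
        raise MontageError(
            f"n_channels={n_channels} cannot host study clusters; "
            f"missing channel numbers {missing}"
        )
    labels = np.arange(1, n_channels + 1)
    points = _fibonacci_sphere(n_channels)
    # assign cluster channel numbers to the free points nearest each anchor
    assignment = np.full(n_channels, -1, dtype=int)  # channel index -> point
    free = np.ones(n_channels, dtype=bool)
    for name in ("C3", "C4", "O"):
        members = sorted(_STUDY_CLUSTERS[name])
        arc = np.arccos(np.clip(points @ _CLUSTER_ANCHORS[name], -1.0, 1.0))
        arc[~free] = np.inf
        nearest = np.argsort(arc, kind="stable")[: len(members)]
        for chan, pt in zip(members, nearest):
            assignment[chan - 1] = pt
            free[pt] = False
    rest = np.flatnonzero(assignment < 0)
    assignment[rest] = np.flatnonzero(free)
    return ElectrodeMontage(labels, points[assignment], dict(_STUDY_CLUSTERS))


def register_regions(
    montage: ElectrodeMontage, n_regions: int, prefix: str = "R"
) -> list[str]:
    """Register ``n_regions`` maximally spread single-channel clusters.

    Deterministic farthest-point sampling over the montage positions, used by
    the synthetic generator to place coupled source regions.  Returns the
    cluster names ("R1", "R2", ...).
    """
    if not 1 <= n_regions <= montage.n_channels:
        raise MontageError("n_regions out of range")
    pos = montage.positions
    chosen = [0]
    d = np.arccos(np.clip(pos @ pos[0], -1.0, 1.0))
    for _ in range(n_regions - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.arccos(np.clip(pos @ pos[nxt], -1.0, 1.0)))
    names = []
    for k, row in enumerate(chosen, start=1):
        name = f"{prefix}{k}"
        montage.add_cluster(name, [int(montage.labels[row])])
        names.append(name)
    return names


def write_sfp(montage: ElectrodeMontage, path) -> None:
    """Write an .sfp-style tab-separated "label x y z" file."""
    with open(path, "w") as fh:
        for lab, (x, y, z) in zip(montage.labels, montage.positions):
            fh.write(f"E{lab}\t{x:.10f}\t{y:.10f}\t{z:.10f}\n")


def read_sfp(path, clusters: dict | None = None) -> ElectrodeMontage:
    """Read an .sfp-style file written by :func:`write_sfp`.

    Labels of the form "E<k>" or plain integers are accepted.  Positions are
    re-normalised to the unit sphere to absorb round-off.
    """
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            lab, x, y, z = line.split("\t")
            labels.append(int(lab.lstrip("E")))
            rows.append([float(x), float(y), float(z)])
    pos = np.asarray(rows, dtype=float)
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    montage = ElectrodeMontage(np.asarray(labels), pos, {})
    if clusters:
        for name, members in clusters.items():
            montage.add_cluster(name, members)
    else:
        label_set = set(labels)
        for name, members in _STUDY_CLUSTERS.items():
            if members <= label_set:
                montage.add_cluster(name, members)
    return montage
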