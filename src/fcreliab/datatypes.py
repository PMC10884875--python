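"""Shared in-memory containers for the reliability pipeline.

Frames are rows, units (grayordinates or parcels) are columns, everywhere.
Censor masks are boolean with ``True`` meaning *retained*; masking is purely
logical until frames are extracted for a statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BoldRun",
    "MotionTrace",
    "Parcellation",
    "Connectome",
    "SplitHalfPair",
    "ReliabilityMap",
    "SignalPropertyMap",
    "Partition",
    "ConsensusAssignment",
]


@dataclass
class BoldRun:
    """One fMRI run: a frames x units matrix plus acquisition metadata."""

    data: np.ndarray
    tr_seconds: float
    subject: str
    session: int
    run: int
    state: str
    censor_mask: np.ndarray | None = None
    unit_level: str = "parcel"  # "dense" | "parcel"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BoldRun data must be a 2-D frames x units matrix")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.data.shape[0], dtype=bool)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if self.censor_mask.shape[0] != self.data.shape[0]:
            raise ValueError(
                f"censor_mask length {self.censor_mask.shape[0]} != "
                f"frame count {self.data.shape[0]}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.censor_mask.sum())

    def retained(self) -> np.ndarray:
        """The retained frames only (copy)."""
        return self.data[self.censor_mask]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=np.asarray(data, dtype=float))

    def with_mask(self, mask: np.ndarray) -> "BoldRun":
        return replace(self, censor_mask=np.asarray(mask, dtype=bool))


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per frame, plus optional FD."""

    translations: np.ndarray  # frames x 3, mm
    rotations: np.ndarray  # frames x 3, rad
    fd: np.ndarray | None = None  # frames, mm; fd[0] == 0

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be frames x 3")
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)
            if self.fd.shape[0] != self.translations.shape[0]:
                raise ValueError("fd length must match frame count")
            if np.any(self.fd < 0):
                raise ValueError("fd must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]


@dataclass
class Parcellation:
    """Mapping from units to parcels (1..P) and parcels to network names."""

    unit_to_parcel: np.ndarray  # per unit, parcel labels 1..P
    parcel_networks: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        self.unit_to_parcel = np.asarray(self.unit_to_parcel, dtype=int)
        labels = np.unique(self.unit_to_parcel)
        p = labels.size
        if not np.array_equal(labels, np.arange(1, p + 1)):
            raise ValueError("parcel labels must be contiguous 1..P with no empty parcel")

    @property
    def n_parcels(self) -> int:
        return int(self.unit_to_parcel.max())


@dataclass
class Connectome:
    """Symmetric units x units Pearson correlation matrix.

    The diagonal is stored as 1 and excluded from every statistic.  Units with
    undefined correlations (zero temporal variance) carry NaN in their row and
    column.
    """

    matrix: np.ndarray
    unit_level: str = "parcel"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectome matrix must be square")
        finite = np.isfinite(m)
        if not np.allclose(m[finite & finite.T & np.isfinite(m.T)], m.T[finite & finite.T & np.isfinite(m.T)], atol=1e-12):
            raise ValueError("connectome matrix must be symmetric")
        vals = m[np.isfinite(m)]
        if vals.size and (vals.max() > 1 + 1e-9 or vals.min() < -1 - 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle edge weights (excluding the diagonal)."""
        iu = np.triu_indices(self.n_units, k=1)
        return self.matrix[iu]


@dataclass
class SplitHalfPair:
    """Connectomes from two disjoint, exhaustive session halves."""

    first: Connectome
    second: Connectome

    def __post_init__(self) -> None:
        if self.first.n_units != self.second.n_units:
            raise ValueError("split halves must share the unit space")


@dataclass
class ReliabilityMap:
    """Per-unit FC test-retest correlation (or a derived difference)."""

    values: np.ndarray
    state: str = "rest"
    level: str = "subject"  # "subject" | "group"
    measure: str = "fc_trc"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class SignalPropertyMap:
    """Per-unit tMean / tSD / tSNR at a stated aggregation level."""

    values: np.ndarray
    measure: str  # "tmean" | "tsd" | "tsnr"
    state: str = "rest"
    level: str = "subject"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.measure not in ("tmean", "tsd", "tsnr"):
            raise ValueError(f"unknown measure {self.measure!r}")


@dataclass
class Partition:
    """Community assignment: per-parcel ids 1..K, contiguous."""

    labels: np.ndarray
    objective: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            # relabel to contiguous 1..K preserving order of first appearance
            remap = {old: new for new, old in enumerate(dict.fromkeys(self.labels.tolist()), start=1)}
            self.labels = np.array([remap[v] for v in self.labels], dtype=int)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]


@dataclass
class ConsensusAssignment:
    """Final partition plus the co-assignment probability matrix behind it."""

    probability: np.ndarray  # parcels x parcels, values in [0, 1]
    partition: Partition
    converged: bool = True
    network_names: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probability, dtype=float)
        if not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("co-assignment probability matrix must be symmetric")
        if not np.allclose(np.diag(p), 1.0):
            raise ValueError("co-assignment probability diagonal must be 1")
        if p.min() < -1e-12 or p.max() > 1 + 1e-12:
            raise ValueError("co-assignment probabilities must lie in [0, 1]")
        self.probability = p
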