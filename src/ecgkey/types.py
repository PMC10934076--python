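"""Shared in-memory containers for the key-generation pipeline.

Conventions
-----------
* All sample indices are 0-based integers at the record's sampling rate.
* Amplitudes are millivolts, durations milliseconds unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LANDMARKS = ("Pon", "Ppk", "QRSon", "Q", "Rpeak", "S", "QRSoff", "Tpk", "Toff")

# Ordering constraints: (a, b, strict) meaning index(a) < index(b) (strict)
# or index(a) <= index(b).
_ORDER = (
    ("Pon", "Ppk", False),
    ("Ppk", "QRSon", True),
    ("QRSon", "Q", False),
    ("Q", "Rpeak", True),
    ("Rpeak", "S", True),
    ("S", "QRSoff", False),
    ("QRSoff", "Tpk", True),
    ("Tpk", "Toff", False),
)


@dataclass
class FiducialMap:
    """Per-beat landmark positions (sample indices) and amplitudes (mV)."""

    Pon: int
    Ppk: int
    QRSon: int
    Q: int
    Rpeak: int
    S: int
    QRSoff: int
    Tpk: int
    Toff: int
    amplitudes: dict[str, float] | None = None

    def index(self, name: str) -> int:
        return int(getattr(self, name))

    def as_dict(self) -> dict[str, int]:
        return {k: self.index(k) for k in LANDMARKS}

    def is_ordered(self) -> bool:
        """True when the canonical landmark ordering holds."""
        for a, b, strict in _ORDER:
            ia, ib = self.index(a), self.index(b)
            if (ia >= ib) if strict else (ia > ib):
                return False
        return True

    def shifted(self, offset: int) -> "FiducialMap":
        """Return a copy with every index shifted by ``offset``."""
        return FiducialMap(
            **{k: self.index(k) + offset for k in LANDMARKS},
            amplitudes=dict(self.amplitudes) if self.amplitudes else None,
        )


@dataclass
class ECGRecord:
    """A sampled lead-I waveform with identity and optional ground truth."""

    samples: np.ndarray
    fs: float = 500.0
    subject_id: str = ""
    session_index: int = 0
    truth: list[FiducialMap] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size < self.fs:
            raise ValueError("record must contain at least 1 s of data")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class BeatSet:
    """Fixed-length beat windows with per-beat fiducials.

    ``condition`` carries a named warning/failure state ("no_beats",
    "too_few_for_outlier_removal", ...) instead of raising, so callers can
    decide how hard to fail.
    """

    beats: np.ndarray  # (N, L) mV
    fiducials: list[FiducialMap]
    fs: float
    condition: str | None = None
    r_abs: np.ndarray | None = None  # absolute R-peak sample indices

    def __len__(self) -> int:
        return int(self.beats.shape[0]) if self.beats.size else 0


@dataclass
class EnsembleBeat:
    """Pointwise mean of three aligned beats (the ensemble beat)."""

    samples: np.ndarray
    fiducials: FiducialMap
    fs: float
    source_count: int = 3


FEATURE_NAMES = (
    # amplitudes (mV), features 1-9
    "ST amplitude", "RS amplitude", "RQ amplitude",
    "PQ amplitude", "PR amplitude", "RT amplitude",
    "PS amplitude", "PT amplitude", "QT amplitude",
    # durations (ms), features 10-18
    "QS interval", "QR interval", "RS interval",
    "PR interval", "RT interval", "ST interval",
    "PQ interval", "PT interval", "QT interval",
    # slopes (mV/s), features 19-23
    "PR slop", "PQ slop", "QS slop", "ST slop", "RT slop",
    # distances (composite ms/mV), features 24-28
    "PR distance", "PQ distance", "QS distance", "ST distance", "RT distance",
    # area (mV*ms), feature 29
    "QRS area",
)

N_FEATURES = len(FEATURE_NAMES)  # 29


@dataclass
class FeatureSet:
    """The 29 fiducial features of one ensemble beat, in table order."""

    values: np.ndarray  # (29,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must all be finite")

    def __getitem__(self, feature_id: int) -> float:
        """1-based access by table feature number."""
        if not 1 <= feature_id <= N_FEATURES:
            raise IndexError(f"feature id {feature_id} out of [1, {N_FEATURES}]")
        return float(self.values[feature_id - 1])

    def by_name(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


@dataclass
class FeatureIndexSet:
    """Top-10 personalized feature indices (1-based, table numbering)."""

    indices: tuple[int, ...]
    weights: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.indices = tuple(int(i) for i in self.indices)
        self.weights = tuple(float(w) for w in self.weights)
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("feature indices must be distinct")
        if any(not 1 <= i <= N_FEATURES for i in self.indices):
            raise ValueError(f"feature indices must lie in [1, {N_FEATURES}]")

    @property
    def positions(self) -> np.ndarray:
        """0-based column positions into a 29-column feature matrix."""
        return np.asarray(self.indices, dtype=int) - 1

    def __len__(self) -> int:
        return len(self.indices)
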