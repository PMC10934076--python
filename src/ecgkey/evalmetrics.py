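"""Evaluation statistics for seeds and bio-keys.

Covers binarization error rates (error seed rate / error bit rate), Shannon
and min-entropy of bit strings, four statistical randomness tests of the
NIST SP 800-22 family (frequency monobit, block frequency, runs, longest
run of ones in a block), confusion-matrix authentication metrics, and the
fixed-length interval-coding baseline binarizer used as a comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special as sp

from .exceptions import ParameterError
from .quantize import Seed

# --------------------------------------------------------------------------
# binarization error rates
# --------------------------------------------------------------------------


@dataclass
class SeedTrialSet:
    """An enrolled seed and the seeds reproduced in later trials."""

    enrolled: str
    reproduced: list[str]

    def __post_init__(self) -> None:
        if isinstance(self.enrolled, Seed):
            self.enrolled = self.enrolled.bits
        self.reproduced = [s.bits if isinstance(s, Seed) else str(s)
                           for s in self.reproduced]
        L = len(self.enrolled)
        if any(len(s) != L for s in self.reproduced):
            raise ParameterError("all seeds in a trial set must share length")
        if not self.reproduced:
            raise ParameterError("trial set needs at least one reproduction")

    def hamming(self) -> np.ndarray:
        e = np.frombuffer(self.enrolled.encode(), dtype=np.uint8)
        return np.array([(np.frombuffer(s.encode(), dtype=np.uint8) != e).sum()
                         for s in self.reproduced])


def error_rates(trials: SeedTrialSet) -> tuple[float, float]:
    """(error seed rate %, error bit rate %).

    ESR = 100 * (#reproduced seeds differing from the enrolled) / #trials.
    EBR = 100 * (mean Hamming distance among the error seeds) / seed length;
    flagged 0.0 when there are no error seeds.
    """
    hd = trials.hamming()
    n_total = hd.size
    errors = hd[hd > 0]
    esr = 100.0 * errors.size / n_total
    if errors.size == 0:
        warnings.warn("no error seeds: error bit rate undefined, reported 0",
                      stacklevel=2)
        return esr, 0.0
    ebr = 100.0 * float(errors.mean()) / len(trials.enrolled)
    return esr, ebr


def error_rates_from_counts(n_error_seeds: int, n_total_seeds: int,
                            mean_error_bits: float, seed_len: float
                            ) -> tuple[float, float]:
    """The same two rates computed directly from summary counts."""
    if n_total_seeds < 1 or seed_len <= 0:
        raise ParameterError("counts must be positive")
    esr = 100.0 * n_error_seeds / n_total_seeds
    ebr = 100.0 * mean_error_bits / seed_len
    return esr, ebr


# --------------------------------------------------------------------------
# entropies
# --------------------------------------------------------------------------

def _bit_probs(bits: str) -> np.ndarray:
    if not bits:
        raise ParameterError("empty bit string")
    arr = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    p1 = arr.mean()
    return np.array([1.0 - p1, p1])


def shannon_entropy(bits: str) -> float:
    """Empirical per-bit Shannon entropy, in [0, 1] bits."""
    p = _bit_probs(bits)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def min_entropy(bits: str) -> float:
    """-log2 of the most likely bit value's empirical probability."""
    p = _bit_probs(bits)
    return float(-np.log2(p.max()))


# --------------------------------------------------------------------------
# NIST SP 800-22 tests (closed forms)
# --------------------------------------------------------------------------

def _as_bits(bits: str | np.ndarray) -> np.ndarray:
    if isinstance(bits, str):
        return np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    return np.asarray(bits, dtype=np.uint8)


def nist_monobit(bits: str | np.ndarray) -> float:
    """Frequency (monobit) test: p = erfc(|S_n| / sqrt(2 n))."""
    x = _as_bits(bits)
    n = x.size
    if n == 0:
        raise ParameterError("empty sequence")
    s = np.abs(2.0 * x.sum() - n)
    return float(sp.erfc(s / np.sqrt(2.0 * n)))


def nist_block_frequency(bits: str | np.ndarray, M: int | None = None) -> float:
    """Frequency test within a block; M defaults to 8 for short keys and
    128 once the sequence is long enough for the standard recommendation."""
    x = _as_bits(bits)
    n = x.size
    if M is None:
        M = 128 if n >= 128 * 20 else 8
    N = n // M
    if N < 1:
        raise ParameterError("sequence shorter than one block")
    if n < 100:
        warnings.warn("block-frequency test below its recommended length",
                      stacklevel=2)
    pi = x[:N * M].reshape(N, M).mean(axis=1)
    chi2 = 4.0 * M * np.sum((pi - 0.5) ** 2)
    return float(sp.gammaincc(N / 2.0, chi2 / 2.0))


def nist_runs(bits: str | np.ndarray) -> float:
    """Runs test: total number of runs against its expectation."""
    x = _as_bits(bits)
    n = x.size
    if n < 2:
        raise ParameterError("sequence too short for the runs test")
    if n < 100:
        warnings.warn("runs test below its recommended length", stacklevel=2)
    pi = x.mean()
    if abs(pi - 0.5) >= 2.0 / np.sqrt(n):
        return 0.0
    v = 1 + int(np.sum(x[1:] != x[:-1]))
    num = abs(v - 2.0 * n * pi * (1 - pi))
    den = 2.0 * np.sqrt(2.0 * n) * pi * (1 - pi)
    return float(sp.erfc(num / den))


# longest-run category tables: M -> (K+1 category upper bounds, probabilities)
_LONGEST_RUN_TABLES = {
    8: ((1, 2, 3), (0.2148, 0.3672, 0.2305, 0.1875)),
    128: ((4, 5, 6, 7, 8),
          (0.1174, 0.2430, 0.2493, 0.1752, 0.1027, 0.1124)),
    10000: ((10, 11, 12, 13, 14, 15),
            (0.0882, 0.2092, 0.2483, 0.1933, 0.1208, 0.0675, 0.0727)),
}


def _longest_run_in(block: np.ndarray) -> int:
    best = cur = 0
    for b in block:
        cur = cur + 1 if b else 0
        best = max(best, cur)
    return best


def nist_longest_run(bits: str | np.ndarray) -> float:
    """Longest run of ones in a block, chi-square against tabulated classes."""
    x = _as_bits(bits)
    n = x.size
    if n >= 750000:
        M = 10000
    elif n >= 6272:
        M = 128
    elif n >= 8:
        M = 8
        if n < 128:
            warnings.warn("longest-run test below its recommended length",
                          stacklevel=2)
    else:
        raise ParameterError("sequence too short for the longest-run test")
    bounds, probs = _LONGEST_RUN_TABLES[M]
    N = n // M
    blocks = x[:N * M].reshape(N, M)
    # vectorized longest run of ones per block
    padded = np.zeros((N, M + 2), dtype=np.int8)
    padded[:, 1:-1] = blocks
    counts = np.zeros(len(probs))
    for row in padded:
        d = np.diff(row)
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        longest = int((ends - starts).max()) if starts.size else 0
        cat = np.searchsorted(bounds, longest)
        counts[min(cat, len(probs) - 1)] += 1
    exp = N * np.asarray(probs)
    chi2 = float(np.sum((counts - exp) ** 2 / exp))
    K = len(probs) - 1
    return float(sp.gammaincc(K / 2.0, chi2 / 2.0))


NIST_TESTS = {
    "monobit": nist_monobit,
    "block_frequency": nist_block_frequency,
    "runs": nist_runs,
    "longest_run": nist_longest_run,
}


# --------------------------------------------------------------------------
# authentication metrics
# --------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ParameterError("counts must be non-negative")
        if self.TP + self.FP + self.FN + self.TN == 0:
            raise ParameterError("confusion counts sum to zero")


def auth_metrics(c: ConfusionCounts, conventional_far: bool = False
                 ) -> dict[str, float]:
    """Accuracy, FAR and FRR from confusion counts.

    FAR follows the printed definition FP / (FP + FN); setting
    ``conventional_far`` additionally reports the conventional
    FP / (FP + TN) under the key ``far_conventional``.
    """
    total = c.TP + c.TN + c.FP + c.FN
    out = {"accuracy": (c.TP + c.TN) / total}
    out["far"] = c.FP / (c.FP + c.FN) if (c.FP + c.FN) > 0 else float("nan")
    out["frr"] = c.FN / (c.TP + c.FN) if (c.TP + c.FN) > 0 else float("nan")
    if conventional_far:
        out["far_conventional"] = (c.FP / (c.FP + c.TN)
                                   if (c.FP + c.TN) > 0 else float("nan"))
    return out


# --------------------------------------------------------------------------
# fixed-length baseline binarizer (comparison only)
# --------------------------------------------------------------------------

BASELINE_BITS = 152


@dataclass
class BaselineStats:
    """Per-feature population min/max for equal-width interval coding."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def from_population(cls, matrix: np.ndarray) -> "BaselineStats":
        X = np.atleast_2d(np.asarray(matrix, dtype=float))
        return cls(lo=X.min(axis=0), hi=X.max(axis=0))


def baseline_binarizer(features: np.ndarray, stats: BaselineStats,
                       total_bits: int = BASELINE_BITS) -> str:
    """Fixed-length per-feature equal-width interval coding.

    Each of the 29 features is coded independently into equal-width bins of
    its population range (values clipped to the range); bin indices are
    emitted as fixed-width binary words and the concatenation is truncated
    to ``total_bits``. This is the representative fixed-quantization
    comparator: one global code per feature, no personalization, no
    collinearity screening.
    """
    x = np.asarray(features, dtype=float).ravel()
    p = x.size
    if stats.lo.size != p:
        raise ParameterError("population stats do not match the feature count")
    bits_per = int(np.ceil(total_bits / p))
    n_bins = 2 ** bits_per
    span = np.where(stats.hi > stats.lo, stats.hi - stats.lo, 1.0)
    frac = np.clip((x - stats.lo) / span, 0.0, 1.0)
    idx = np.minimum((frac * n_bins).astype(int), n_bins - 1)
    coded = "".join(format(i, f"0{bits_per}b") for i in idx)
    return coded[:total_bits]
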