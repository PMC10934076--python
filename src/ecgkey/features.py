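"""The 29 fiducial features of an ensemble beat.

Endpoints named P, Q, R, S, T refer to the wave peaks (Ppk, Q, Rpeak, S,
Tpk). Conventions:

* ``AB amplitude`` = amp(A) - amp(B) in mV (so "RS amplitude" is the
  R-peak-to-S-trough drop, positive for an upright beat);
* ``AB interval``  = t(B) - t(A) in ms;
* ``AB slop``      = (amp(B) - amp(A)) / (t(B) - t(A)) in mV/s;
* ``AB distance``  = Euclidean norm of the (delta-t ms, delta-amp mV)
  vector — the two axes are combined without rescaling;
* ``QRS area``     = trapezoidal integral of |signal - baseline| over
  [QRSon, QRSoff] in mV*ms, baseline = mean of the 20 ms before QRSon.
"""

from __future__ import annotations

import numpy as np

from .exceptions import MissingLandmarkError
from .types import FEATURE_NAMES, EnsembleBeat, FeatureSet, FiducialMap

# wave-peak landmark used for each single-letter endpoint
_PEAK = {"P": "Ppk", "Q": "Q", "R": "Rpeak", "S": "S", "T": "Tpk"}

_AMPLITUDE_PAIRS = ("ST", "RS", "RQ", "PQ", "PR", "RT", "PS", "PT", "QT")
_DURATION_PAIRS = ("QS", "QR", "RS", "PR", "RT", "ST", "PQ", "PT", "QT")
_SLOPE_PAIRS = ("PR", "PQ", "QS", "ST", "RT")
_DISTANCE_PAIRS = ("PR", "PQ", "QS", "ST", "RT")


def _endpoint(beat: EnsembleBeat, letter: str) -> tuple[float, float]:
    """(time ms, amplitude mV) of a wave-peak endpoint."""
    fid = beat.fiducials
    name = _PEAK[letter]
    idx = fid.index(name)
    if not 0 <= idx < beat.samples.size:
        raise MissingLandmarkError(f"landmark {name} outside the beat window")
    t_ms = idx / beat.fs * 1000.0
    return t_ms, float(beat.samples[idx])


def amplitude(beat: EnsembleBeat, pair: str) -> float:
    (_, aa), (_, ab) = _endpoint(beat, pair[0]), _endpoint(beat, pair[1])
    return aa - ab


def interval(beat: EnsembleBeat, pair: str) -> float:
    (ta, _), (tb, _) = _endpoint(beat, pair[0]), _endpoint(beat, pair[1])
    return tb - ta


def slope(beat: EnsembleBeat, pair: str) -> float:
    (ta, aa), (tb, ab) = _endpoint(beat, pair[0]), _endpoint(beat, pair[1])
    if tb == ta:
        raise MissingLandmarkError(f"{pair} slope: coincident landmarks")
    return (ab - aa) / ((tb - ta) / 1000.0)


def distance(beat: EnsembleBeat, pair: str) -> float:
    (ta, aa), (tb, ab) = _endpoint(beat, pair[0]), _endpoint(beat, pair[1])
    return float(np.hypot(tb - ta, ab - aa))


def qrs_area(beat: EnsembleBeat, baseline_ms: float = 20.0) -> float:
    fid = beat.fiducials
    on, off = fid.QRSon, fid.QRSoff
    if not 0 <= on < off < beat.samples.size:
        raise MissingLandmarkError("QRS area: QRSon/QRSoff out of bounds")
    nb = max(1, int(round(baseline_ms / 1000.0 * beat.fs)))
    baseline = float(beat.samples[max(0, on - nb):on].mean()) if on > 0 else 0.0
    seg = np.abs(beat.samples[on:off + 1] - baseline)
    dt_ms = 1000.0 / beat.fs
    return float(np.trapezoid(seg, dx=dt_ms))


def extract_features(beat: EnsembleBeat) -> FeatureSet:
    """Extract the 29-entry feature set from one ensemble beat."""
    if beat.fiducials is None:
        raise MissingLandmarkError("ensemble beat carries no fiducials")
    values = []
    for pair in _AMPLITUDE_PAIRS:
        values.append(amplitude(beat, pair))
    for pair in _DURATION_PAIRS:
        values.append(interval(beat, pair))
    for pair in _SLOPE_PAIRS:
        values.append(slope(beat, pair))
    for pair in _DISTANCE_PAIRS:
        values.append(distance(beat, pair))
    values.append(qrs_area(beat))
    return FeatureSet(values=np.asarray(values))


def feature_matrix(beats: list[EnsembleBeat]) -> np.ndarray:
    """(n, 29) matrix of features for a list of ensemble beats."""
    return np.vstack([extract_features(b).values for b in beats])


def to_frame(matrix: np.ndarray):
    """Feature matrix as a pandas DataFrame with the documented header."""
    import pandas as pd

    return pd.DataFrame(np.atleast_2d(matrix), columns=list(FEATURE_NAMES))


def beat_features(beat_samples: np.ndarray, fiducials: FiducialMap,
                  fs: float) -> FeatureSet:
    """Features of a single (non-ensemble) beat, e.g. for enrollment rows."""
    return extract_features(
        EnsembleBeat(samples=np.asarray(beat_samples, dtype=float),
                     fiducials=fiducials, fs=fs, source_count=1))
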