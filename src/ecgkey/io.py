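"""Plain-text record I/O.

Records are exchanged as two-column CSV (seconds, millivolts) with an
optional JSON sidecar (``<record>.fiducials.json``) holding the sampling
rate, identity and ground-truth fiducials as 0-based sample indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import LANDMARKS, ECGRecord, FiducialMap


def write_csv(record: ECGRecord, path: str | Path,
              sidecar: bool = True) -> Path:
    """Write (seconds, millivolts) CSV plus an optional truth sidecar."""
    path = Path(path)
    df = pd.DataFrame({"seconds": record.times(), "millivolts": record.samples})
    df.to_csv(path, index=False, float_format="%.6f")
    if sidecar:
        meta = {
            "fs": record.fs,
            "subject_id": record.subject_id,
            "session_index": record.session_index,
            "fiducials": [f.as_dict() for f in (record.truth or [])],
        }
        sidecar_path = path.with_suffix(".fiducials.json")
        sidecar_path.write_text(json.dumps(meta, indent=2))
    return path


def read_csv(path: str | Path, fs: float | None = None,
             subject_id: str = "", session_index: int = 0) -> ECGRecord:
    """Read a (seconds, millivolts) CSV; the sidecar is used when present."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("CSV must have (seconds, millivolts) columns")
    seconds = df.iloc[:, 0].to_numpy(dtype=float)
    mv = df.iloc[:, 1].to_numpy(dtype=float)
    truth = None
    sidecar = path.with_suffix(".fiducials.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = fs or float(meta.get("fs", 0)) or None
        subject_id = subject_id or meta.get("subject_id", "")
        session_index = meta.get("session_index", session_index)
        fid = meta.get("fiducials") or []
        if fid:
            truth = [FiducialMap(**{k: int(d[k]) for k in LANDMARKS})
                     for d in fid]
    if fs is None:
        dt = np.diff(seconds)
        if dt.size == 0 or np.any(dt <= 0):
            raise ValueError("cannot infer sampling rate from the time column")
        fs = 1.0 / float(np.median(dt))
    return ECGRecord(samples=mv, fs=fs, subject_id=subject_id,
                     session_index=session_index, truth=truth)
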