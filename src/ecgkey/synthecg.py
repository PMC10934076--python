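"""Seedable synthetic multi-session ECG cohorts.

Each subject is a template of five Gaussian waves (P, Q, R, S, T) whose
amplitude/center/width parameters are drawn from documented population priors.
A session perturbs the template with a multiplicative amplitude factor
(electrode repositioning) and a per-wave timing offset; a record is a train
of beats at a requested heart rate with small RR jitter, plus configurable
baseline wander, powerline interference and broadband noise.

Because beats are analytic Gaussian sums, every record carries exact
ground-truth fiducials: wave peaks at the Gaussian centers, wave onsets and
offsets at +/-3 sigma.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from .types import ECGRecord, FiducialMap

WAVES = ("P", "Q", "R", "S", "T")

# Population priors: (mean, sd, low clip, high clip) per parameter.
# Amplitudes mV, centers ms relative to the R peak, widths = Gaussian sigma ms.
# Spreads follow standard adult lead-I normal limits (R 0.4-2.2 mV, P up to
# 0.3 mV, PR-interval spread of a few tens of ms, etc.) so that the surrogate
# population shows the wide inter-subject morphology of an open multi-age DB.
_PRIORS: dict[str, tuple[float, float, float, float]] = {
    "p_amp": (0.15, 0.05, 0.04, 0.30),
    "p_center": (-165.0, 20.0, -200.0, -120.0),
    "p_width": (22.0, 4.0, 12.0, 30.0),
    "q_amp": (-0.12, 0.06, -0.35, -0.02),
    "q_center": (-30.0, 5.0, -45.0, -15.0),
    "q_width": (7.0, 1.5, 4.0, 11.0),
    "r_amp": (1.00, 0.35, 0.40, 2.20),
    "r_center": (0.0, 0.0, 0.0, 0.0),
    "r_width": (10.0, 2.0, 6.0, 16.0),
    "s_amp": (-0.25, 0.12, -0.70, -0.03),
    "s_center": (30.0, 5.0, 15.0, 45.0),
    "s_width": (8.0, 1.5, 4.0, 12.0),
    "t_amp": (0.30, 0.12, 0.08, 0.70),
    "t_center": (180.0, 30.0, 120.0, 250.0),
    "t_width": (48.0, 10.0, 25.0, 65.0),
    "baseline_hr": (72.0, 10.0, 55.0, 95.0),
    "amp_jitter": (0.15, 0.0, 0.0, 0.5),
    "timing_jitter_ms": (4.0, 0.0, 0.0, 20.0),
}

NOISE_PRESETS: dict[str, dict[str, float]] = {
    "none": {"baseline_amp": 0.0, "baseline_freq": 0.3,
             "powerline_amp": 0.0, "white_sd": 0.0},
    # default session noise: visible but benign for a resting dry-electrode setup
    "default": {"baseline_amp": 0.08, "baseline_freq": 0.3,
                "powerline_amp": 0.04, "white_sd": 0.015},
    "high": {"baseline_amp": 0.2, "baseline_freq": 0.45,
             "powerline_amp": 0.1, "white_sd": 0.04},
}


@dataclass
class SubjectTemplate:
    """Per-subject beat morphology and variability parameters."""

    subject_id: str
    wave_params: dict[str, tuple[float, float, float]]  # wave -> (amp, center, width)
    baseline_hr: float
    amp_jitter: float = 0.15
    timing_jitter_ms: float = 4.0

    def __post_init__(self) -> None:
        p = self.wave_params
        if p["R"][0] <= 0:
            raise ParameterError("r_amp: R amplitude must be positive")
        if any(p[w][2] <= 0 for w in WAVES):
            raise ParameterError("width: all wave widths must be positive")
        centers = [p[w][1] for w in WAVES]
        if not (centers[0] < centers[1] < 0 <= centers[2] < centers[3] < centers[4]):
            raise ParameterError("center: wave centers must satisfy P < Q < 0 <= S < T")

    def param(self, key: str) -> float:
        wave, what = key.split("_", 1)
        idx = {"amp": 0, "center": 1, "width": 2}[what]
        return self.wave_params[wave.upper()][idx]


def _subject_rng(rng_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(rng_seed))


def make_subject(rng_seed: int, overrides: dict | None = None,
                 subject_id: str | None = None) -> SubjectTemplate:
    """Sample a subject template from the population priors.

    ``overrides`` pins named parameters (e.g. ``{"r_amp": 1.0}``); keys must
    come from the documented parameter set and values must lie within the
    prior's clip range.
    """
    overrides = dict(overrides or {})
    for key, val in overrides.items():
        if key not in _PRIORS:
            raise ParameterError(f"unknown override parameter: {key!r}")
        _, _, lo, hi = _PRIORS[key]
        if not lo <= float(val) <= hi:
            raise ParameterError(f"override {key!r}={val} outside [{lo}, {hi}]")

    rng = _subject_rng(rng_seed)
    drawn: dict[str, float] = {}
    for key in _PRIORS:  # fixed iteration order -> deterministic stream
        mean, sd, lo, hi = _PRIORS[key]
        drawn[key] = float(np.clip(rng.normal(mean, sd), lo, hi)) if sd else mean
    drawn.update({k: float(v) for k, v in overrides.items()})

    wave_params = {
        w: (drawn[f"{w.lower()}_amp"], drawn[f"{w.lower()}_center"],
            drawn[f"{w.lower()}_width"])
        for w in WAVES
    }
    return SubjectTemplate(
        subject_id=subject_id or f"synth-{rng_seed:04d}",
        wave_params=wave_params,
        baseline_hr=drawn["baseline_hr"],
        amp_jitter=drawn["amp_jitter"],
        timing_jitter_ms=drawn["timing_jitter_ms"],
    )


def _resolve_noise(noise_cfg: dict | str | None) -> dict[str, float]:
    if noise_cfg is None:
        return dict(NOISE_PRESETS["default"])
    if isinstance(noise_cfg, str):
        if noise_cfg not in NOISE_PRESETS:
            raise ParameterError(f"unknown noise preset: {noise_cfg!r}")
        return dict(NOISE_PRESETS[noise_cfg])
    cfg = dict(NOISE_PRESETS["none"])
    for key, val in noise_cfg.items():
        if key not in cfg:
            raise ParameterError(f"unknown noise parameter: {key!r}")
        cfg[key] = float(val)
    if not 0 < cfg["baseline_freq"] <= 0.5:
        raise ParameterError("baseline_freq must lie in (0, 0.5] Hz")
    return cfg


def _record_rng(template: SubjectTemplate, session_index: int,
                rng_seed: int) -> np.random.Generator:
    sid = zlib.crc32(template.subject_id.encode()) % (2**31)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(rng_seed) % (2**31),
                               spawn_key=(sid, int(session_index))))


def synth_record(template: SubjectTemplate, session_index: int = 0,
                 duration_s: float = 20.0, hr_bpm: float | None = None,
                 noise_cfg: dict | str | None = None, rng_seed: int = 0,
                 fs: float = 500.0) -> ECGRecord:
    """Synthesize one session record with ground-truth fiducials."""
    if duration_s < 2:
        raise ParameterError("duration_s must be at least 2 s")
    hr = float(hr_bpm if hr_bpm is not None else template.baseline_hr)
    if not 30 <= hr <= 180:
        raise ParameterError("hr_bpm must lie in [30, 180]")
    noise = _resolve_noise(noise_cfg)
    rng = _record_rng(template, session_index, rng_seed)

    # Session effects: one amplitude factor, one timing offset per wave.
    j = template.amp_jitter
    amp_factor = float(rng.uniform(1 - j, 1 + j))
    t_off = {w: float(rng.normal(0.0, template.timing_jitter_ms)) for w in WAVES}
    waves = {
        w: (a * amp_factor, c + t_off[w], width)
        for w, (a, c, width) in template.wave_params.items()
    }

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # Beat train: constant HR with small per-beat RR jitter; first and last
    # beats kept clear of the record edges so full windows exist.
    rr = 60.0 / hr
    r_times: list[float] = []
    tr = 0.5
    while tr < duration_s - 0.5:
        r_times.append(tr)
        tr += rr * (1.0 + float(rng.normal(0.0, 0.02)))

    def clean_at(times_s: np.ndarray) -> np.ndarray:
        out = np.zeros_like(times_s)
        for tri in r_times:
            for amp, c_ms, w_ms in waves.values():
                mu = tri + c_ms / 1000.0
                sig = w_ms / 1000.0
                out += amp * np.exp(-0.5 * ((times_s - mu) / sig) ** 2)
        return out

    x = clean_at(t)
    truth: list[FiducialMap] = []
    for tri in r_times:
        idx = {}
        for w, (_, c_ms, w_ms) in waves.items():
            idx[w] = int(round((tri + c_ms / 1000.0) * fs))
        pon = int(round((tri + (waves["P"][1] - 3 * waves["P"][2]) / 1000.0) * fs))
        toff = int(round((tri + (waves["T"][1] + 3 * waves["T"][2]) / 1000.0) * fs))
        qrson = int(round((tri + (waves["Q"][1] - 3 * waves["Q"][2]) / 1000.0) * fs))
        qrsoff = int(round((tri + (waves["S"][1] + 3 * waves["S"][2]) / 1000.0) * fs))
        marks = dict(Pon=pon, Ppk=idx["P"], QRSon=qrson, Q=idx["Q"],
                     Rpeak=idx["R"], S=idx["S"], QRSoff=qrsoff,
                     Tpk=idx["T"], Toff=toff)
        amps = {k: float(clean_at(np.array([v / fs]))[0]) for k, v in marks.items()}
        truth.append(FiducialMap(**marks, amplitudes=amps))

    if noise["baseline_amp"]:
        phase = float(rng.uniform(0, 2 * np.pi))
        x = x + noise["baseline_amp"] * np.sin(
            2 * np.pi * noise["baseline_freq"] * t + phase)
    if noise["powerline_amp"]:
        phase = float(rng.uniform(0, 2 * np.pi))
        x = x + noise["powerline_amp"] * np.sin(2 * np.pi * 60.0 * t + phase)
    if noise["white_sd"]:
        x = x + rng.normal(0.0, noise["white_sd"], size=n)

    return ECGRecord(samples=x, fs=fs, subject_id=template.subject_id,
                     session_index=session_index, truth=truth)


def synth_population(n_subjects: int, rng_seed: int,
                     duration_s: float = 20.0, fs: float = 500.0,
                     noise_cfg: dict | str | None = "default") -> list[ECGRecord]:
    """Surrogate population database: one mild-noise session per subject."""
    if n_subjects < 2:
        raise ParameterError("n_subjects must be at least 2")
    ss = np.random.SeedSequence(int(rng_seed) % (2**31))
    children = ss.spawn(n_subjects)
    records = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        tpl = make_subject(sub_seed, subject_id=f"pop-{i:03d}")
        records.append(synth_record(tpl, session_index=0, duration_s=duration_s,
                                    hr_bpm=tpl.baseline_hr, noise_cfg=noise_cfg,
                                    rng_seed=sub_seed, fs=fs))
    return records
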