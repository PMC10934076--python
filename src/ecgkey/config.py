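"""Structured run configuration.

A single nested mapping covers every documented knob; unknown keys are
rejected with a message enumerating all of them, and the fully resolved
configuration can be logged/serialized for reproducibility.
"""

from __future__ import annotations

import copy
from dataclasses import fields

from .exceptions import ConfigError
from .preprocess import PreprocessConfig
from .quantize import QuantizeConfig
from .keygen import PipelineConfig

DEFAULTS: dict = {
    "simulate": {
        "subjects": 10,
        "sessions": 4,
        "duration_s": 20.0,
        "hr_range": [55.0, 95.0],
        "noise": "default",
        "population": 90,
    },
    "preprocess": {f.name: f.default for f in fields(PreprocessConfig)
                   if f.name not in ("p_search_ms", "t_search_ms")},
    "select": {
        "k_neighbors": 10,
    },
    "quantize": {f.name: f.default for f in fields(QuantizeConfig)
                 if f.name != "k_values"},
    "keygen": {
        "tau": 0.05,
        "key_len": 128,
    },
    "evaluate": {
        "subjects": 10,
        "sessions": 6,
        "impostor_pairs": 60,
        "taus": [0.01, 0.03, 0.05, 0.07, 0.09],
        "ensembles_per_session": 1,
    },
}


def _check_keys(user: dict, defaults: dict, prefix: str, bad: list[str]) -> None:
    for key, val in user.items():
        if key not in defaults:
            bad.append(f"{prefix}{key}")
        elif isinstance(defaults[key], dict):
            if isinstance(val, dict):
                _check_keys(val, defaults[key], f"{prefix}{key}.", bad)
            else:
                bad.append(f"{prefix}{key} (expected a mapping)")


def resolve_config(user: dict | None = None) -> dict:
    """Merge a user mapping over the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULTS)
    if not user:
        return cfg
    bad: list[str] = []
    _check_keys(user, DEFAULTS, "", bad)
    if bad:
        raise ConfigError("unknown configuration key(s): " + ", ".join(sorted(bad)))

    def merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    merge(cfg, user)
    return cfg


def load_config(path: str | None) -> dict:
    """Read a YAML config file (or return pure defaults for None)."""
    if path is None:
        return resolve_config(None)
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config file must contain a mapping")
    return resolve_config(user)


def build_pipeline_config(cfg: dict) -> PipelineConfig:
    """Materialize the dataclass configs from a resolved mapping."""
    pre_kwargs = {k: v for k, v in cfg["preprocess"].items()}
    q_kwargs = {k: v for k, v in cfg["quantize"].items()}
    return PipelineConfig(
        preprocess=PreprocessConfig(**pre_kwargs),
        quantize=QuantizeConfig(**q_kwargs),
        k_neighbors=int(cfg["select"]["k_neighbors"]),
        tau=float(cfg["keygen"]["tau"]),
        key_len=int(cfg["keygen"]["key_len"]),
    )
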