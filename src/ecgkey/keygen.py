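"""Fuzzy-extractor key generation plus enrollment and authentication.

Code-offset construction: Gen draws a random codeword c of a shortened
binary BCH code with correction capacity t = ceil(tau * seed_len), stores
sketch = seed XOR c (with a random salt) as helper data, and derives the
bio-key as the first l bits of SHA-256(salt || seed). Rep XORs a fresh seed
with the sketch and BCH-decodes to recover c, hence the enrolled seed
(sketch XOR c); whenever the fresh seed is within Hamming distance t of the
enrolled one the same seed — and the same key — is recovered.

``enroll`` and ``authenticate`` wire the full pipeline together: denoise ->
delineate -> normalize -> outlier removal -> features -> ReliefF selection
-> dynamic quantization -> voting -> seed -> Gen / Rep.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import features as feat
from . import preprocess as pre
from . import select as sel
from .bch import get_code
from .exceptions import (
    InsufficientBeatsError,
    ParameterError,
    ReproductionError,
)
from .quantize import (
    QuantizeConfig,
    QuantizerModel,
    PairModel,
    Seed,
    build_quantizer,
    model_labels,
    bits_from_labels,
    quantize_bits,
    vote_labels,
)
from .types import ECGRecord, FeatureIndexSet


@dataclass
class HelperData:
    """Non-secret fuzzy-extractor helper (the Hfz structure)."""

    sketch: str                     # binary string, seed_len bits
    salt: str                       # hex
    code_n_bits: int
    code_k: int                     # message bits (k_short)
    t: int
    tau: float
    key_len: int


@dataclass
class BioKey:
    bits: str

    def __len__(self) -> int:
        return len(self.bits)

    def digest(self) -> str:
        return hashlib.sha256(self.bits.encode()).hexdigest()


@dataclass
class IDRecord:
    """Enrolled identity: feature indices, quantizer, helper, key digest."""

    subject_id: str
    fidx: FeatureIndexSet
    quantizer: QuantizerModel
    helper: HelperData
    key_digest: str
    config: dict = field(default_factory=dict)


def _bits_to_bytes(bits: str) -> bytes:
    return int(bits, 2).to_bytes((len(bits) + 7) // 8, "big") if bits else b""


def _derive_key(salt_hex: str, seed_bits: str, l: int) -> BioKey:
    digest = hashlib.sha256(bytes.fromhex(salt_hex) + _bits_to_bytes(seed_bits)
                            + len(seed_bits).to_bytes(2, "big")).digest()
    bitstring = "".join(f"{byte:08b}" for byte in digest)
    while len(bitstring) < l:
        digest = hashlib.sha256(digest).digest()
        bitstring += "".join(f"{byte:08b}" for byte in digest)
    return BioKey(bits=bitstring[:l])


def correction_capacity(tau: float, seed_len: int) -> int:
    """t = ceil(tau * seed_len)."""
    return math.ceil(tau * seed_len)


def gen(seed: Seed | str, l: int = 128, tau: float = 0.05,
        rng_seed: int = 0) -> tuple[BioKey, HelperData]:
    """Generate a bio-key and helper data from a seed (the Gen function)."""
    bits = seed.bits if isinstance(seed, Seed) else str(seed)
    seed_len = len(bits)
    if not 0 < tau < 0.5:
        raise ParameterError("tau must lie in (0, 0.5)")
    if l < 1:
        raise ParameterError("key length l must be positive")
    t = correction_capacity(tau, seed_len)
    code = get_code(seed_len, t)
    rng = np.random.default_rng(int(rng_seed) % (2**31))
    message = rng.integers(0, 2, code.k_short).astype(np.uint8)
    codeword = code.encode(message)
    seed_arr = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    sketch = (seed_arr.astype(np.uint8) ^ codeword)
    salt = rng.bytes(16).hex()
    key = _derive_key(salt, bits, l)
    helper = HelperData(sketch="".join(str(int(b)) for b in sketch),
                        salt=salt, code_n_bits=code.n_bits,
                        code_k=code.k_short, t=t, tau=tau, key_len=l)
    return key, helper


def rep(seed_prime: Seed | str, helper: HelperData) -> BioKey:
    """Reproduce the bio-key from a fresh seed (the Rep function).

    Raises ReproductionError when the fresh seed is too far from the
    enrolled one for the code to decode.
    """
    bits = seed_prime.bits if isinstance(seed_prime, Seed) else str(seed_prime)
    if len(bits) != len(helper.sketch):
        raise ParameterError(
            f"seed length {len(bits)} != sketch length {len(helper.sketch)}")
    code = get_code(helper.code_n_bits, helper.t)
    seed_arr = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    sketch_arr = np.frombuffer(helper.sketch.encode(), dtype=np.uint8) - ord("0")
    noisy_codeword = (seed_arr ^ sketch_arr).astype(np.uint8)
    message, _ = code.decode(noisy_codeword)
    codeword = code.encode(message)
    recovered = (sketch_arr ^ codeword).astype(np.uint8)
    seed_bits = "".join(str(int(b)) for b in recovered)
    return _derive_key(helper.salt, seed_bits, helper.key_len)


# --------------------------------------------------------------------------
# pipeline flows
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    preprocess: pre.PreprocessConfig = field(default_factory=pre.PreprocessConfig)
    quantize: QuantizeConfig = field(default_factory=QuantizeConfig)
    k_neighbors: int = 10
    tau: float = 0.05
    key_len: int = 128


@dataclass
class PopulationFeatures:
    """Per-beat feature rows pooled over the population database."""

    matrix: np.ndarray  # (rows, 29)

    @classmethod
    def from_records(cls, records: list[ECGRecord],
                     config: pre.PreprocessConfig | None = None
                     ) -> "PopulationFeatures":
        cfg = config or pre.PreprocessConfig()
        rows = []
        for rec in records:
            try:
                rows.append(record_feature_rows(rec, cfg))
            except (InsufficientBeatsError, ParameterError):
                continue
        if not rows:
            raise InsufficientBeatsError("no population record yielded beats")
        return cls(matrix=np.vstack(rows))


def record_feature_rows(record: ECGRecord,
                        config: pre.PreprocessConfig | None = None
                        ) -> np.ndarray:
    """Denoise/delineate/normalize/clean one record; per-beat feature rows."""
    cfg = config or pre.PreprocessConfig()
    den = pre.denoise(record, cfg)
    beats = pre.delineate(den, cfg)
    if len(beats) == 0:
        raise InsufficientBeatsError("no beats delineated")
    hr = pre.observed_heart_rate(beats) if len(beats) >= 2 else 70.0
    norm = pre.normalize_beats(beats, hr, cfg)
    clean = pre.remove_outliers(norm, cfg)
    if len(clean) == 0:
        raise InsufficientBeatsError("no beats survived outlier removal")
    rows = [feat.beat_features(b, f, clean.fs).values
            for b, f in zip(clean.beats, clean.fiducials)]
    return np.vstack(rows)


def record_clean_beats(record: ECGRecord,
                       config: pre.PreprocessConfig | None = None):
    """Preprocess one record and return the outlier-cleaned beat set."""
    cfg = config or pre.PreprocessConfig()
    den = pre.denoise(record, cfg)
    beats = pre.delineate(den, cfg)
    if len(beats) == 0:
        raise InsufficientBeatsError("no beats delineated")
    hr = pre.observed_heart_rate(beats) if len(beats) >= 2 else 70.0
    norm = pre.normalize_beats(beats, hr, cfg)
    return pre.remove_outliers(norm, cfg)


def enroll(record_t0: ECGRecord,
           population: PopulationFeatures | list[ECGRecord],
           config: PipelineConfig | None = None,
           rng_seed: int = 0) -> IDRecord:
    """Enrollment: first-session record + population DB -> IDRecord."""
    cfg = config or PipelineConfig()
    if isinstance(population, list):
        population = PopulationFeatures.from_records(population, cfg.preprocess)

    clean = record_clean_beats(record_t0, cfg.preprocess)
    if len(clean) < 3:
        raise InsufficientBeatsError(
            f"enrollment needs >= 3 beats, got {len(clean)}")
    subject_rows = np.vstack([
        feat.beat_features(b, f, clean.fs).values
        for b, f in zip(clean.beats, clean.fiducials)])

    fidx = sel.select_features(subject_rows, population.matrix,
                               k_neighbors=cfg.k_neighbors, rng_seed=rng_seed)
    quantizer = build_quantizer(population.matrix, fidx,
                                criterion=cfg.quantize.criterion,
                                config=cfg.quantize, rng_seed=rng_seed)

    label_matrix = np.array([model_labels(row, quantizer)
                             for row in subject_rows])
    voted = vote_labels(label_matrix)
    seed = bits_from_labels(voted, quantizer)
    key, helper = gen(seed, l=cfg.key_len, tau=cfg.tau, rng_seed=rng_seed)
    return IDRecord(subject_id=record_t0.subject_id, fidx=fidx,
                    quantizer=quantizer, helper=helper,
                    key_digest=key.digest(),
                    config={"tau": cfg.tau, "key_len": cfg.key_len,
                            "criterion": cfg.quantize.criterion})


@dataclass
class AuthResult:
    accepted: bool
    key: BioKey | None
    reason: str
    seed: Seed | None = None


def reproduce_seed(record_tk: ECGRecord, id_record: IDRecord,
                   config: PipelineConfig | None = None,
                   selector_start: int = 0) -> Seed:
    """Fresh-session seed via one ensemble beat quantized with the stored model."""
    cfg = config or PipelineConfig()
    clean = record_clean_beats(record_tk, cfg.preprocess)
    if len(clean) < 3:
        raise InsufficientBeatsError(
            f"authentication needs >= 3 beats, got {len(clean)}")
    ens = pre.ensemble(clean, selector_start=selector_start, config=cfg.preprocess)
    fs = feat.extract_features(ens)
    seed, _ = quantize_bits(fs, id_record.quantizer)
    return seed


def authenticate(record_tk: ECGRecord, id_record: IDRecord,
                 config: PipelineConfig | None = None,
                 selector_start: int = 0) -> AuthResult:
    """Reproduce a key from a fresh record and compare digests."""
    try:
        seed = reproduce_seed(record_tk, id_record, config, selector_start)
    except (InsufficientBeatsError, ParameterError) as exc:
        return AuthResult(accepted=False, key=None, reason=str(exc))
    try:
        key = rep(seed, id_record.helper)
    except ReproductionError as exc:
        return AuthResult(accepted=False, key=None,
                          reason=f"rep failed: {exc}", seed=seed)
    ok = key.digest() == id_record.key_digest
    return AuthResult(accepted=ok, key=key,
                      reason="match" if ok else "digest mismatch", seed=seed)


# --------------------------------------------------------------------------
# IDRecord (de)serialization
# --------------------------------------------------------------------------

def id_record_to_json(idr: IDRecord) -> str:
    payload = {
        "subject_id": idr.subject_id,
        "fidx": {"indices": list(idr.fidx.indices),
                 "weights": list(idr.fidx.weights)},
        "quantizer": {
            "criterion": idr.quantizer.criterion,
            "pad_bits": idr.quantizer.pad_bits,
            "seed_len": idr.quantizer.seed_len,
            "models": [{
                "feature_pair": list(m.feature_pair),
                "k": m.k,
                "centroids": m.centroids.tolist(),
                "scaler_mean": m.scaler_mean.tolist(),
                "scaler_sd": m.scaler_sd.tolist(),
                "silhouette": m.silhouette,
                "bit_width": m.bit_width,
            } for m in idr.quantizer.models],
        },
        "helper": asdict(idr.helper),
        "key_digest": idr.key_digest,
        "config": idr.config,
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def id_record_from_json(text: str) -> IDRecord:
    d = json.loads(text)
    fidx = FeatureIndexSet(indices=tuple(d["fidx"]["indices"]),
                           weights=tuple(d["fidx"]["weights"]))
    models = [PairModel(feature_pair=tuple(m["feature_pair"]), k=m["k"],
                        centroids=np.asarray(m["centroids"]),
                        scaler_mean=np.asarray(m["scaler_mean"]),
                        scaler_sd=np.asarray(m["scaler_sd"]),
                        silhouette=m["silhouette"], bit_width=m["bit_width"])
              for m in d["quantizer"]["models"]]
    quant = QuantizerModel(models=models, pad_bits=d["quantizer"]["pad_bits"],
                           seed_len=d["quantizer"]["seed_len"],
                           criterion=d["quantizer"]["criterion"], fidx=fidx)
    helper = HelperData(**d["helper"])
    return IDRecord(subject_id=d["subject_id"], fidx=fidx, quantizer=quant,
                    helper=helper, key_digest=d["key_digest"],
                    config=d.get("config", {}))
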