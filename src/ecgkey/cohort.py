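"""Synthetic-cohort evaluation of the full key-generation system.

Builds a surrogate population and a multi-session subject cohort, enrolls
every subject on their first session, reproduces seeds from later sessions
(genuine trials) and from other subjects' sessions (impostor trials), and
computes the evaluation suite: error seed/bit rates for the proposed
quantizer and the fixed-length baseline, seed/key entropies, the four
randomness tests, and accuracy/FAR/FRR over a tau sweep for either cluster
selection criterion.

Preprocessing and feature extraction are done once per record; criteria and
tau values reuse the cached features, so sweeping them is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as feat
from . import preprocess as pre
from . import synthecg
from .evalmetrics import (
    BaselineStats,
    ConfusionCounts,
    SeedTrialSet,
    auth_metrics,
    baseline_binarizer,
    error_rates,
    min_entropy,
    nist_block_frequency,
    nist_longest_run,
    nist_monobit,
    nist_runs,
    shannon_entropy,
)
from .exceptions import (
    EcgKeyError,
    InsufficientBeatsError,
    QuantizerBuildError,
    ReproductionError,
)
from .keygen import PipelineConfig, gen, rep, record_clean_beats
from .quantize import (
    bits_from_labels,
    build_quantizer,
    model_labels,
    vote_labels,
)
from .select import select_features


@dataclass
class SubjectData:
    """Cached per-subject material, independent of criterion and tau."""

    subject_id: str
    t0_rows: np.ndarray                  # per-beat features, session 0
    session_features: list[np.ndarray]   # ensemble features per later session
    fidx: object = None


@dataclass
class CohortData:
    population: np.ndarray               # (rows, 29) population features
    subjects: list[SubjectData]
    config: PipelineConfig


def build_cohort(n_subjects: int = 20, n_sessions: int = 10,
                 n_population: int = 90, rng_seed: int = 1,
                 config: PipelineConfig | None = None,
                 ensembles_per_session: int = 1,
                 noise: str | dict = "default") -> CohortData:
    """Simulate and preprocess a cohort; cache everything tau-independent."""
    cfg = config or PipelineConfig()
    seed = int(rng_seed) % (2**31)
    pop_records = synthecg.synth_population(n_population, rng_seed=seed)
    pop_rows = []
    for rec in pop_records:
        try:
            pop_rows.append(_record_rows(rec, cfg))
        except EcgKeyError:
            continue
    population = np.vstack(pop_rows)

    subjects = []
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    children = ss.spawn(n_subjects)
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        tpl = synthecg.make_subject(sub_seed, subject_id=f"subj-{i:03d}")
        try:
            rec0 = synthecg.synth_record(tpl, 0, 20.0, None, noise,
                                         rng_seed=sub_seed)
            t0_rows = _record_rows(rec0, cfg)
            if t0_rows.shape[0] < 3:
                continue
            sessions = []
            for s in range(1, n_sessions + 1):
                rec = synthecg.synth_record(tpl, s, 20.0, None, noise,
                                            rng_seed=sub_seed)
                sessions.extend(_session_ensembles(
                    rec, cfg, ensembles_per_session))
            subjects.append(SubjectData(subject_id=tpl.subject_id,
                                        t0_rows=t0_rows,
                                        session_features=sessions))
        except EcgKeyError:
            continue
    return CohortData(population=population, subjects=subjects, config=cfg)


def _record_rows(record, cfg: PipelineConfig) -> np.ndarray:
    clean = record_clean_beats(record, cfg.preprocess)
    if len(clean) == 0:
        raise InsufficientBeatsError("no clean beats")
    return np.vstack([feat.beat_features(b, f, clean.fs).values
                      for b, f in zip(clean.beats, clean.fiducials)])


def _session_ensembles(record, cfg: PipelineConfig, count: int
                       ) -> list[np.ndarray]:
    clean = record_clean_beats(record, cfg.preprocess)
    out = []
    for start in range(count):
        if len(clean) < 3 + start:
            break
        ens = pre.ensemble(clean, selector_start=start, config=cfg.preprocess)
        out.append(feat.extract_features(ens).values)
    if not out:
        raise InsufficientBeatsError("no ensemble from session record")
    return out


# --------------------------------------------------------------------------


@dataclass
class SubjectSeeds:
    subject_id: str
    enrolled: str                  # enrolled (voted) seed bits
    genuine: list[str]             # reproduced seeds, later sessions
    impostor: list[str]            # seeds quantized from other subjects
    pad_bits: int = 0              # trailing zero padding in every seed


@dataclass
class CohortEvaluation:
    criterion: str
    seeds: list[SubjectSeeds]
    seed_lengths: list[int]
    esr: float
    ebr: float
    esr_baseline: float
    ebr_baseline: float
    per_tau: dict[float, dict[str, float]] = field(default_factory=dict)
    entropy: dict[str, float] = field(default_factory=dict)
    nist: dict[str, float] = field(default_factory=dict)


def quantize_cohort(data: CohortData, criterion: str = "pu",
                    rng_seed: int = 1, impostors_per_subject: int = 5
                    ) -> list[SubjectSeeds]:
    """Per-subject quantizer models and all enrolled/genuine/impostor seeds."""
    cfg = data.config
    seed = int(rng_seed) % (2**31)
    out: list[SubjectSeeds] = []
    quantizers = {}
    n = len(data.subjects)
    for i, sub in enumerate(data.subjects):
        fidx = sub.fidx
        if fidx is None:
            fidx = select_features(sub.t0_rows, data.population,
                                   k_neighbors=cfg.k_neighbors,
                                   rng_seed=seed + i)
            sub.fidx = fidx
        try:
            q = build_quantizer(data.population, fidx, criterion=criterion,
                                config=cfg.quantize, rng_seed=seed + i)
        except QuantizerBuildError:
            continue
        quantizers[i] = q
        labels = np.array([model_labels(r, q) for r in sub.t0_rows])
        enrolled = bits_from_labels(vote_labels(labels), q).bits
        genuine = [bits_from_labels(model_labels(f, q), q).bits
                   for f in sub.session_features]
        out.append(SubjectSeeds(subject_id=sub.subject_id, enrolled=enrolled,
                                genuine=genuine, impostor=[],
                                pad_bits=q.pad_bits))
    # impostor seeds: other subjects' first later-session ensemble, quantized
    # with this subject's model
    enrolled_ids = [i for i in quantizers]
    for pos, i in enumerate(enrolled_ids):
        q = quantizers[i]
        others = [j for j in enrolled_ids if j != i]
        rng = np.random.default_rng(seed + 7919 * (i + 1))
        picks = rng.permutation(others)[:impostors_per_subject]
        for j in picks:
            feats = data.subjects[j].session_features
            k = int(rng.integers(0, len(feats)))
            out[pos].impostor.append(
                bits_from_labels(model_labels(feats[k], q), q).bits)
    return out


def evaluate_cohort(data: CohortData, criterion: str = "pu",
                    taus: tuple[float, ...] = (0.01, 0.03, 0.05, 0.07, 0.09),
                    rng_seed: int = 1, impostors_per_subject: int = 5,
                    key_len: int = 128) -> CohortEvaluation:
    seeds = quantize_cohort(data, criterion, rng_seed, impostors_per_subject)
    if not seeds:
        raise QuantizerBuildError("no subject could be enrolled")

    # ---- seed-level error rates (proposed) ----
    esr_list, ebr_list = [], []
    for s in seeds:
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            esr, ebr = error_rates(SeedTrialSet(s.enrolled, s.genuine))
        esr_list.append(esr)
        ebr_list.append(ebr)
    esr = float(np.mean(esr_list))
    ebr = float(np.mean([e for e in ebr_list]))

    # ---- fixed-length baseline on the same cohort ----
    stats = BaselineStats.from_population(data.population)
    esr_b, ebr_b = [], []
    for sub in data.subjects:
        enrolled_b = baseline_binarizer(sub.t0_rows.mean(axis=0), stats)
        rep_b = [baseline_binarizer(f, stats) for f in sub.session_features]
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            e, b = error_rates(SeedTrialSet(enrolled_b, rep_b))
        esr_b.append(e)
        ebr_b.append(b)
    esr_baseline = float(np.mean(esr_b))
    ebr_baseline = float(np.mean(ebr_b))

    ev = CohortEvaluation(criterion=criterion, seeds=seeds,
                          seed_lengths=[len(s.enrolled) for s in seeds],
                          esr=esr, ebr=ebr, esr_baseline=esr_baseline,
                          ebr_baseline=ebr_baseline)

    # ---- tau sweep: fuzzy-extractor authentication ----
    seed0 = int(rng_seed) % (2**31)
    for tau in taus:
        TP = FN = FP = TN = 0
        keys = []
        for i, s in enumerate(seeds):
            key, helper = gen(s.enrolled, l=key_len, tau=tau,
                              rng_seed=seed0 + 31 * i)
            digest = key.digest()
            keys.append(key.bits)
            for g in s.genuine:
                try:
                    ok = rep(g, helper).digest() == digest
                except ReproductionError:
                    ok = False
                TP += ok
                FN += not ok
            for imp in s.impostor:
                try:
                    ok = rep(imp, helper).digest() == digest
                except ReproductionError:
                    ok = False
                FP += ok
                TN += not ok
        m = auth_metrics(ConfusionCounts(TP=TP, FP=FP, FN=FN, TN=TN),
                         conventional_far=True)
        m.update(TP=TP, FP=FP, FN=FN, TN=TN,
                 genuine_accept=TP / max(TP + FN, 1),
                 impostor_accept=FP / max(FP + TN, 1))
        ev.per_tau[tau] = m
        if abs(tau - 0.05) < 1e-12:
            _randomness(ev, seeds, keys)
    if not ev.entropy:  # tau sweep did not include 0.05
        keys = []
        for i, s in enumerate(seeds):
            key, _ = gen(s.enrolled, l=key_len, tau=taus[0],
                         rng_seed=seed0 + 31 * i)
            keys.append(key.bits)
        _randomness(ev, seeds, keys)
    return ev


def _randomness(ev: CohortEvaluation, seeds: list[SubjectSeeds],
                keys: list[str]) -> None:
    """Entropy (per-string averaged and pooled) and the four NIST tests.

    Seed entropies are computed on the unpadded bit strings (the trailing
    zero padding is bookkeeping, not biometric information).
    """
    seed_bits = [s.enrolled[:len(s.enrolled) - s.pad_bits] for s in seeds]
    seed_bits = [b for b in seed_bits if b]
    pooled_seed = "".join(seed_bits)
    pooled_key = "".join(keys)
    ev.entropy = {
        "seed_shannon_mean": float(np.mean([shannon_entropy(b)
                                            for b in seed_bits])),
        "seed_min_mean": float(np.mean([min_entropy(b) for b in seed_bits])),
        "seed_shannon_pooled": shannon_entropy(pooled_seed),
        "seed_min_pooled": min_entropy(pooled_seed),
        "key_shannon_mean": float(np.mean([shannon_entropy(b) for b in keys])),
        "key_min_mean": float(np.mean([min_entropy(b) for b in keys])),
        "key_shannon_pooled": shannon_entropy(pooled_key),
        "key_min_pooled": min_entropy(pooled_key),
    }
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        ev.nist = {
            "monobit": nist_monobit(pooled_key),
            "block_frequency": nist_block_frequency(pooled_key),
            "runs": nist_runs(pooled_key),
            "longest_run": nist_longest_run(pooled_key),
        }
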