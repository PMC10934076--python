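import numpy as np
import pytest

from ecgkey import keygen, synthecg
from ecgkey.bch import BCH
from ecgkey.exceptions import (
    CodeParameterError,
    InsufficientBeatsError,
    ParameterError,
    ReproductionError,
)
from ecgkey.quantize import Seed


def _random_seed_bits(rng, n=64):
    return "".join(rng.choice(["0", "1"], n))


class TestBCH:
    def test_codewords_have_zero_syndromes(self):
        code = BCH(64, 4)
        rng = np.random.default_rng(0)
        for _ in range(20):
            cw = code.encode(rng.integers(0, 2, code.k_short).astype(np.uint8))
            assert not np.any(code._syndromes(cw))

    @pytest.mark.parametrize("n_bits,t", [(16, 1), (32, 2), (64, 4), (127, 6)])
    def test_roundtrip_with_random_errors(self, n_bits, t):
        code = BCH(n_bits, t)
        rng = np.random.default_rng(t)
        for _ in range(25):
            msg = rng.integers(0, 2, code.k_short).astype(np.uint8)
            cw = code.encode(msg)
            e = np.zeros(n_bits, dtype=np.uint8)
            w = int(rng.integers(0, t + 1))
            e[rng.choice(n_bits, w, replace=False)] = 1
            dec, n_err = code.decode(cw ^ e)
            assert np.array_equal(dec, msg)
            assert n_err == w

    def test_infeasible_parameters_list_options(self):
        with pytest.raises(CodeParameterError) as exc:
            BCH(16, 5)  # 15 parity-heavy; no message bits left
        assert "feasible" in str(exc.value)


class TestGenRep:
    def test_zero_error_roundtrip(self):
        rng = np.random.default_rng(1)
        seed = Seed(_random_seed_bits(rng))
        key, helper = keygen.gen(seed, l=128, tau=0.05, rng_seed=2)
        assert len(key) == 128
        assert keygen.rep(seed, helper).bits == key.bits

    def test_capacity_ceiling(self):
        rng = np.random.default_rng(2)
        _, helper = keygen.gen(Seed(_random_seed_bits(rng)), tau=0.05,
                               rng_seed=0)
        assert helper.t == 4  # ceil(0.05 * 64) = ceil(3.2)
        assert keygen.correction_capacity(0.05, 64) == 4

    def test_salt_sensitivity(self):
        rng = np.random.default_rng(3)
        seed = Seed(_random_seed_bits(rng))
        k1, _ = keygen.gen(seed, l=64, tau=0.05, rng_seed=10)
        k2, _ = keygen.gen(seed, l=64, tau=0.05, rng_seed=11)
        assert len(k1) == len(k2) == 64
        assert k1.bits != k2.bits

    def test_flips_up_to_t_reproduce(self):
        rng = np.random.default_rng(4)
        seed = Seed(_random_seed_bits(rng))
        key, helper = keygen.gen(seed, tau=0.05, rng_seed=5)
        arr = seed.as_array()
        for w in (1, 2, 3, 4):
            for _ in range(20):
                flipped = arr.copy()
                flipped[rng.choice(64, w, replace=False)] ^= 1
                s2 = Seed("".join(map(str, flipped)))
                assert keygen.rep(s2, helper).bits == key.bits

    def test_complement_rejected_or_mismatched(self):
        rng = np.random.default_rng(5)
        seed = Seed(_random_seed_bits(rng))
        key, helper = keygen.gen(seed, tau=0.05, rng_seed=6)
        comp = Seed("".join(str(1 - b) for b in seed.as_array()))
        try:
            assert keygen.rep(comp, helper).bits != key.bits
        except ReproductionError:
            pass

    def test_tau_guard(self):
        with pytest.raises(ParameterError):
            keygen.gen(Seed("0" * 64), tau=0.7, rng_seed=0)

    def test_length_mismatch_guard(self):
        rng = np.random.default_rng(6)
        _, helper = keygen.gen(Seed(_random_seed_bits(rng)), rng_seed=0)
        with pytest.raises(ParameterError):
            keygen.rep(Seed("01" * 16), helper)

    def test_key_bits_balanced_over_random_seeds(self):
        rng = np.random.default_rng(7)
        ones = np.zeros(128)
        n = 300
        for i in range(n):
            seed = Seed(_random_seed_bits(rng))
            key, _ = keygen.gen(seed, l=128, tau=0.05, rng_seed=1000 + i)
            ones += key.as_array() if hasattr(key, "as_array") else \
                np.frombuffer(key.bits.encode(), dtype=np.uint8) - ord("0")
        frac = ones / n
        # no structurally stuck/biased key bit (bound ~ 5 sigma at n=300)
        assert np.all(np.abs(frac - 0.5) < 0.15)
        assert abs(frac.mean() - 0.5) < 0.02


class TestEnrollAuthenticate:
    def test_enroll_deterministic(self, template, population_features,
                                  pipeline_config):
        rec = synthecg.synth_record(template, 0, 20.0, None, "default",
                                    rng_seed=42)
        a = keygen.enroll(rec, population_features, pipeline_config, rng_seed=5)
        b = keygen.enroll(rec, population_features, pipeline_config, rng_seed=5)
        assert a.key_digest == b.key_digest
        assert a.fidx.indices == b.fidx.indices
        assert keygen.id_record_to_json(a) == keygen.id_record_to_json(b)

    def test_enrollment_replay_accepts(self, template, population_features,
                                       pipeline_config):
        rec = synthecg.synth_record(template, 0, 20.0, None, "default",
                                    rng_seed=42)
        idr = keygen.enroll(rec, population_features, pipeline_config,
                            rng_seed=5)
        result = keygen.authenticate(rec, idr, pipeline_config)
        assert result.accepted

    def test_short_record_insufficient_beats(self, template,
                                             population_features,
                                             pipeline_config):
        rec = synthecg.synth_record(template, 0, 2.5, 60.0, "none", rng_seed=1)
        with pytest.raises(InsufficientBeatsError):
            keygen.enroll(rec, population_features, pipeline_config, rng_seed=0)

    def test_different_subjects_get_different_identities(
            self, population_features):
        # pm keeps every screened pair, so enrollment always succeeds and
        # the identity separation property is isolated from pu rejections
        cfg = keygen.PipelineConfig()
        cfg.quantize.criterion = "pm"
        digests = []
        for s in (401, 402, 403, 404):
            tpl = synthecg.make_subject(s)
            rec = synthecg.synth_record(tpl, 0, 20.0, None, "default",
                                        rng_seed=7)
            idr = keygen.enroll(rec, population_features, cfg, rng_seed=5)
            digests.append(idr.key_digest)
        assert len(set(digests)) == len(digests)

    def test_id_record_json_roundtrip(self, template, population_features,
                                      pipeline_config):
        rec = synthecg.synth_record(template, 0, 20.0, None, "default",
                                    rng_seed=42)
        idr = keygen.enroll(rec, population_features, pipeline_config,
                            rng_seed=5)
        text = keygen.id_record_to_json(idr)
        back = keygen.id_record_from_json(text)
        assert back.key_digest == idr.key_digest
        assert back.fidx.indices == idr.fidx.indices
        assert keygen.id_record_to_json(back) == text
        # the round-tripped ID still authenticates the enrollment record
        assert keygen.authenticate(rec, back, pipeline_config).accepted
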