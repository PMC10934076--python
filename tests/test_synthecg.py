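import numpy as np
import pytest

from ecgkey import preprocess, synthecg
from ecgkey.exceptions import ParameterError


class TestMakeSubject:
    def test_same_seed_identical_templates(self):
        a = synthecg.make_subject(1)
        b = synthecg.make_subject(1)
        assert a.wave_params == b.wave_params
        assert a.baseline_hr == b.baseline_hr

    def test_different_seed_differs(self):
        a = synthecg.make_subject(1)
        b = synthecg.make_subject(2)
        assert any(a.wave_params[w] != b.wave_params[w] for w in synthecg.WAVES)

    def test_override_passthrough(self):
        tpl = synthecg.make_subject(3, overrides={"r_amp": 1.0})
        assert tpl.wave_params["R"][0] == 1.0

    @pytest.mark.parametrize("overrides", [
        {"bogus_param": 1.0},
        {"r_amp": 99.0},          # outside the prior clip range
        {"baseline_hr": 10.0},
    ])
    def test_invalid_override_rejected(self, overrides):
        with pytest.raises(ParameterError):
            synthecg.make_subject(3, overrides=overrides)

    def test_wave_center_ordering_invariant(self):
        for seed in range(30):
            p = synthecg.make_subject(seed).wave_params
            assert p["P"][1] < p["Q"][1] < 0 <= p["S"][1] < p["T"][1]


class TestSynthRecord:
    def test_beat_count_and_rr(self, template):
        rec = synthecg.synth_record(template, 0, 20.0, 70.0, "none", rng_seed=5)
        assert abs(len(rec.truth) - 23) <= 1
        rr_ms = np.diff([f.Rpeak for f in rec.truth]) / rec.fs * 1000
        # 857 ms nominal with 2% RR jitter
        assert np.all(np.abs(rr_ms - 857) < 6 * 0.02 * 857)

    def test_noiseless_record_matches_analytic_sum(self, template, clean_record):
        rec = clean_record
        # rebuild the analytic Gaussian sum from the session-perturbed truth
        rng = synthecg._record_rng(template, 0, 5)
        j = template.amp_jitter
        amp_factor = float(rng.uniform(1 - j, 1 + j))
        t_off = {w: float(rng.normal(0, template.timing_jitter_ms))
                 for w in synthecg.WAVES}
        # replay the beat-time stream (truth indices are rounded to samples)
        rr = 60.0 / 70.0
        r_times = []
        tr = 0.5
        while tr < 20.0 - 0.5:
            r_times.append(tr)
            tr += rr * (1.0 + float(rng.normal(0.0, 0.02)))
        t = rec.times()
        expected = np.zeros_like(t)
        for w, (amp, c, width) in template.wave_params.items():
            for tr in r_times:
                mu = tr + (c + t_off[w]) / 1000.0
                expected += (amp * amp_factor
                             * np.exp(-0.5 * ((t - mu) / (width / 1000.0)) ** 2))
        assert np.max(np.abs(rec.samples - expected)) < 1e-9

    def test_determinism(self, template):
        a = synthecg.synth_record(template, 1, 10.0, 70.0, "default", rng_seed=9)
        b = synthecg.synth_record(template, 1, 10.0, 70.0, "default", rng_seed=9)
        assert np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("kwargs", [
        {"duration_s": 1.0},
        {"hr_bpm": 20.0},
        {"hr_bpm": 200.0},
    ])
    def test_parameter_guards(self, template, kwargs):
        with pytest.raises(ParameterError):
            synthecg.synth_record(template, 0, rng_seed=1,
                                  **{"duration_s": 20.0, **kwargs})

    def test_truth_fiducials_ordered_nonoverlapping(self, clean_record):
        prev_end = -1
        for f in clean_record.truth:
            assert f.is_ordered()
            assert f.Pon > prev_end
            prev_end = f.Toff


class TestSynthPopulation:
    def test_sizing_and_determinism(self):
        pop = synthecg.synth_population(5, rng_seed=7, duration_s=20.0)
        assert len(pop) == 5
        assert all(r.samples.size == 10000 for r in pop)
        again = synthecg.synth_population(5, rng_seed=7, duration_s=20.0)
        assert all(np.array_equal(a.samples, b.samples)
                   for a, b in zip(pop, again))

    def test_subjects_distinct(self):
        pop = synthecg.synth_population(6, rng_seed=7)
        ids = {r.subject_id for r in pop}
        assert len(ids) == 6
        assert not np.array_equal(pop[0].samples, pop[1].samples)

    def test_too_few_subjects(self):
        with pytest.raises(ParameterError):
            synthecg.synth_population(1, rng_seed=0)


class TestGroundTruthFidelity:
    def test_zero_noise_r_recovery_within_10ms(self):
        hits = total = 0
        for seed in range(4):
            tpl = synthecg.make_subject(100 + seed)
            rec = synthecg.synth_record(tpl, 0, 20.0, None, "none", rng_seed=seed)
            bs = preprocess.delineate(preprocess.denoise(rec))
            det = np.asarray(bs.r_abs)
            tol = int(0.010 * rec.fs)
            for f in rec.truth:
                total += 1
                hits += det.size and np.min(np.abs(det - f.Rpeak)) <= tol
        assert hits / total >= 0.99

    def test_default_noise_r_recovery_within_20ms(self):
        hits = total = 0
        for seed in range(4):
            tpl = synthecg.make_subject(200 + seed)
            rec = synthecg.synth_record(tpl, 0, 20.0, None, "default",
                                        rng_seed=seed)
            bs = preprocess.delineate(preprocess.denoise(rec))
            det = np.asarray(bs.r_abs)
            tol = int(0.020 * rec.fs)
            for f in rec.truth:
                total += 1
                hits += det.size and np.min(np.abs(det - f.Rpeak)) <= tol
        assert hits / total >= 0.95
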