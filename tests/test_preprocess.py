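import numpy as np
import pytest

from ecgkey import preprocess, synthecg
from ecgkey.exceptions import InsufficientBeatsError, ParameterError
from ecgkey.preprocess import PreprocessConfig
from ecgkey.types import BeatSet, ECGRecord, FiducialMap


def _record(x, fs=500.0):
    return ECGRecord(samples=x, fs=fs, subject_id="t")


class TestDenoise:
    def test_60hz_attenuated_30db(self):
        t = np.arange(10000) / 500.0
        rec = _record(np.sin(2 * np.pi * 60 * t))
        out = preprocess.denoise(rec).samples[500:-500]
        rms_in = np.sqrt(np.mean(rec.samples[500:-500] ** 2))
        rms_out = np.sqrt(np.mean(out ** 2))
        assert 20 * np.log10(rms_in / rms_out) >= 30

    def test_dc_removed(self):
        rec = _record(np.full(5000, 0.5))
        out = preprocess.denoise(rec).samples
        assert np.mean(np.abs(out[1000:-1000])) < 1e-3

    def test_10hz_passband_preserved(self):
        t = np.arange(10000) / 500.0
        rec = _record(np.sin(2 * np.pi * 10 * t))
        out = preprocess.denoise(rec).samples[1000:-1000]
        amp = (out.max() - out.min()) / 2
        assert abs(amp - 1.0) < 0.05

    def test_zero_phase_no_lag(self, clean_record):
        out = preprocess.denoise(clean_record).samples
        x = clean_record.samples - clean_record.samples.mean()
        y = out - out.mean()
        corr = np.correlate(y, x, mode="full")
        lag = int(np.argmax(corr)) - (x.size - 1)
        assert lag == 0

    def test_low_fs_rejected(self):
        rec = ECGRecord(samples=np.zeros(200), fs=100.0)
        with pytest.raises(ParameterError):
            preprocess.denoise(rec)


class TestDelineate:
    def test_zero_noise_r_peaks_matched(self, clean_record, clean_beats):
        det = np.asarray(clean_beats.r_abs)
        truth = np.array([f.Rpeak for f in clean_record.truth])
        tol = int(0.010 * clean_record.fs)
        matched = sum(np.min(np.abs(det - t)) <= tol for t in truth)
        assert matched == truth.size
        # no false positives: every detection near some truth R
        assert all(np.min(np.abs(truth - d)) <= tol for d in det)

    def test_flat_signal_no_beats(self):
        bs = preprocess.delineate(_record(np.zeros(5000)))
        assert len(bs) == 0
        assert bs.condition == "no_beats"

    def test_median_rr_recovered(self, clean_beats):
        rr_ms = np.median(np.diff(clean_beats.r_abs)) / clean_beats.fs * 1000
        assert abs(rr_ms - 857) <= 10

    def test_fiducial_ordering_invariant_random_records(self):
        for seed in range(6):
            tpl = synthecg.make_subject(300 + seed)
            rec = synthecg.synth_record(tpl, seed % 3, 20.0, None, "default",
                                        rng_seed=seed)
            bs = preprocess.delineate(preprocess.denoise(rec))
            assert all(f.is_ordered() for f in bs.fiducials)


class TestNormalize:
    def test_sections_reach_standard_durations(self, template):
        rec = synthecg.synth_record(template, 0, 20.0, 100.0, "none", rng_seed=2)
        bs = preprocess.delineate(preprocess.denoise(rec))
        hr = preprocess.observed_heart_rate(bs)
        nb = preprocess.normalize_beats(bs, hr)
        cfg = PreprocessConfig()
        fs = bs.fs
        for f in nb.fiducials:
            assert f.QRSon - f.Pon == round(cfg.standard_pr_ms / 1000 * fs)
            assert f.QRSoff - f.QRSon == round(cfg.standard_qrs_ms / 1000 * fs)
            assert f.Toff - f.QRSoff == round(cfg.standard_st_ms / 1000 * fs)

    def test_idempotence(self, normalized_beats):
        b, f = normalized_beats.beats[0], normalized_beats.fiducials[0]
        b2, f2 = preprocess.normalize_beat(b, f, 70.0, normalized_beats.fs)
        assert np.allclose(b, b2)
        assert f.as_dict() == f2.as_dict()

    def test_landmark_amplitudes_conserved(self, clean_beats):
        hr = preprocess.observed_heart_rate(clean_beats)
        for b, f in list(zip(clean_beats.beats, clean_beats.fiducials))[:5]:
            nb, nf = preprocess.normalize_beat(b, f, hr, clean_beats.fs)
            for k in f.as_dict():
                assert abs(b[f.index(k)] - nb[nf.index(k)]) < 1e-6

    def test_hr_guard(self, clean_beats):
        with pytest.raises(ParameterError):
            preprocess.normalize_beat(clean_beats.beats[0],
                                      clean_beats.fiducials[0], 20.0,
                                      clean_beats.fs)


def _beatset(beats):
    beats = np.asarray(beats, dtype=float)
    fid = FiducialMap(Pon=0, Ppk=1, QRSon=2, Q=3, Rpeak=4, S=5, QRSoff=6,
                      Tpk=7, Toff=8)
    return BeatSet(beats=beats, fiducials=[fid] * beats.shape[0], fs=500.0)


def _outlier_oracle(beats):
    """Brute-force restatement of the correlation outlier rule."""
    template = np.mean(beats, axis=0)
    rhos = np.array([np.corrcoef(b, template)[0, 1] for b in beats])
    thr = rhos.mean() - 0.5 * rhos.std()
    return [i for i in range(len(beats)) if rhos[i] < thr]


class TestRemoveOutliers:
    def test_identical_beats_none_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 50)
        bs = _beatset([base] * 10)
        out = preprocess.remove_outliers(bs)
        assert len(out) == 10

    def test_inverted_beat_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 50)
        beats = [base + 0.01 * rng.normal(size=50) for _ in range(10)]
        beats.append(-base)
        out = preprocess.remove_outliers(_beatset(beats))
        assert len(out) == 10
        assert not any(np.allclose(b, -base) for b in out.beats)

    def test_single_beat_passthrough_with_warning(self):
        bs = _beatset([np.sin(np.linspace(0, 3, 50))])
        with pytest.warns(UserWarning):
            out = preprocess.remove_outliers(bs)
        assert len(out) == 1
        assert out.condition == "too_few_for_outlier_removal"

    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 1), (12, 2)])
    def test_matches_bruteforce_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        base = np.sin(np.linspace(0, 6, 80))
        beats = np.array([base * rng.uniform(0.5, 1.5)
                          + rng.normal(0, 0.3, 80) for _ in range(n)])
        out = preprocess.remove_outliers(_beatset(beats))
        removed_oracle = set(_outlier_oracle(beats))
        kept = {i for i in range(n)
                if any(np.array_equal(beats[i], b) for b in out.beats)}
        assert kept == set(range(n)) - removed_oracle


class TestEnsemble:
    def test_mean_of_identical_beats(self):
        base = np.sin(np.linspace(0, 6, 50))
        out = preprocess.ensemble(_beatset([base] * 3))
        assert np.allclose(out.samples, base)
        assert out.source_count == 3

    def test_linearity_of_mean(self):
        base = np.sin(np.linspace(0, 6, 50))
        eps = 0.3
        out = preprocess.ensemble(_beatset([base, base, base + eps]))
        assert np.allclose(out.samples, base + eps / 3)

    def test_too_few_beats_raises(self):
        with pytest.raises(InsufficientBeatsError):
            preprocess.ensemble(_beatset([np.ones(50), np.ones(50)]))

    def test_selector_start_shifts_choice(self, normalized_beats):
        clean = preprocess.remove_outliers(normalized_beats)
        e0 = preprocess.ensemble(clean, selector_start=0)
        e1 = preprocess.ensemble(clean, selector_start=1)
        assert not np.allclose(e0.samples, e1.samples)
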