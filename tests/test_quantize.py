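import numpy as np
import pytest

from ecgkey import quantize
from ecgkey.exceptions import ParameterError
from ecgkey.quantize import QuantizeConfig, Seed, next_pow2
from ecgkey.types import FeatureIndexSet

FIDX10 = FeatureIndexSet(indices=tuple(range(1, 11)))


def _training(seed=0, n=500):
    rng = np.random.default_rng(seed)
    return rng.normal(0, 1, (n, 29)), rng


def silhouette_oracle(X, labels):
    """Silhouette by definition (mean over points of (b-a)/max(a,b))."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        same = labels == labels[i]
        a = d[i][same & (np.arange(n) != i)].mean()
        b = min(d[i][labels == lab].mean()
                for lab in np.unique(labels) if lab != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def _blobs(centers, sigma, n, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    assign = rng.integers(0, len(centers), n)
    return centers[assign] + rng.normal(0, sigma, (n, 2))


class TestScreenPairs:
    def test_collinear_pair_excluded(self):
        X, rng = _training()
        X[:, 1] = 2 * X[:, 0] + 1  # features 1 and 2 perfectly collinear
        pairs = quantize.screen_pairs(X[:, :10], FIDX10, r_max=0.8)
        assert (1, 2) not in pairs

    def test_independent_columns_retained(self):
        X, _ = _training(seed=1)
        r = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        assert abs(r) < 0.2
        pairs = quantize.screen_pairs(X[:, :10], FIDX10, r_max=0.8)
        assert (1, 2) in pairs

    def test_all_45_pairs_when_independent(self):
        X, _ = _training(seed=2)
        pairs = quantize.screen_pairs(X[:, :10], FIDX10, r_max=0.8)
        assert len(pairs) == 45
        assert pairs == sorted(pairs)

    def test_constant_column_warns_and_drops(self):
        X, _ = _training(seed=3)
        X[:, 4] = 7.0
        with pytest.warns(UserWarning):
            pairs = quantize.screen_pairs(X[:, :10], FIDX10)
        assert all(5 not in p for p in pairs)
        assert len(pairs) == 36  # 45 - 9 pairs touching feature 5


class TestFitPairModel:
    def test_four_blobs_pm_selects_k4(self):
        X = _blobs([[0, 0], [0, 1], [1, 0], [1, 1]], 0.05, 400, seed=4)
        m = quantize.fit_pair_model(X, (1, 2), "pm", rng_seed=0)
        assert m.k == 4
        # silhouette agrees with the by-definition oracle
        z = (X - X.mean(0)) / X.std(0)
        labels = np.array([m.label(x) for x in X]) - 1
        assert m.silhouette == pytest.approx(silhouette_oracle(z, labels),
                                             abs=1e-6)

    def test_two_blobs_pm_selects_k2(self):
        X = _blobs([[0, 0], [1, 1]], 0.05, 400, seed=5)
        m = quantize.fit_pair_model(X, (1, 2), "pm", rng_seed=0)
        assert m.k == 2

    def test_single_cloud_rejected_by_pu(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (400, 2))
        m = quantize.fit_pair_model(X, (1, 2), "pu",
                                    config=QuantizeConfig(theta_s=0.4),
                                    rng_seed=0)
        assert m is None

    def test_relabeling_stable_across_rng(self):
        X = _blobs([[0, 0], [0, 1], [1, 0], [1, 1]], 0.05, 400, seed=7)
        m1 = quantize.fit_pair_model(X, (1, 2), "pm", rng_seed=1)
        m2 = quantize.fit_pair_model(X, (1, 2), "pm", rng_seed=999)
        assert np.allclose(m1.centroids, m2.centroids, atol=1e-8)
        for x in X[:50]:
            assert m1.label(x) == m2.label(x)


class TestBuildQuantizer:
    def test_pm_keeps_all_screened_pairs_and_sizes_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (600, 29))
        qm = quantize.build_quantizer(X, FIDX10, criterion="pm", rng_seed=0)
        # pm never rejects a non-degenerate pair
        assert len(qm.models) == 45
        width = sum(m.bit_width for m in qm.models)
        assert qm.seed_len == next_pow2(width)
        assert qm.pad_bits == qm.seed_len - width
        assert all(m.k in (2, 4) for m in qm.models)

    @pytest.mark.parametrize("width,expected_len,expected_pad", [
        (45, 64, 19), (57, 64, 7), (64, 64, 0), (1, 1, 0), (33, 64, 31),
    ])
    def test_padding_arithmetic(self, width, expected_len, expected_pad):
        assert next_pow2(width) == expected_len
        assert next_pow2(width) - width == expected_pad


class TestQuantizeBits:
    @pytest.mark.parametrize("label,k,bits", [
        (1, 2, "0"), (2, 2, "1"),
        (1, 4, "00"), (2, 4, "01"), (3, 4, "10"), (4, 4, "11"),
    ])
    def test_label_to_bits(self, label, k, bits):
        m = quantize.PairModel(feature_pair=(1, 2), k=k,
                               centroids=np.zeros((k, 2)),
                               scaler_mean=np.zeros(2), scaler_sd=np.ones(2),
                               silhouette=0.5, bit_width=k // 2)
        assert m.bits(label) == bits

    def test_concatenation_and_padding(self):
        widths_labels = [(2, 3), (1, 2), (2, 1)]  # "10" + "1" + "00"
        models = []
        for w, _ in widths_labels:
            k = 2 * w
            models.append(quantize.PairModel(
                feature_pair=(1, 2), k=k, centroids=np.zeros((k, 2)),
                scaler_mean=np.zeros(2), scaler_sd=np.ones(2),
                silhouette=0.5, bit_width=w))
        qm = quantize.QuantizerModel(models=models, pad_bits=3, seed_len=8,
                                     criterion="pm")
        seed = quantize.bits_from_labels([l for _, l in widths_labels], qm)
        assert seed.bits == "10100000"

    def test_seed_invariants(self):
        X = _blobs([[0, 0], [0, 1], [1, 0], [1, 1]], 0.05, 400, seed=9)
        rng = np.random.default_rng(9)
        training = rng.normal(0, 1, (400, 29))
        training[:, [0, 2]] = X  # features 1 and 3 structured
        qm = quantize.build_quantizer(training, FIDX10, criterion="pm",
                                      rng_seed=3)
        seed, labels = quantize.quantize_bits(training[0], qm)
        assert len(seed) == qm.seed_len
        assert next_pow2(len(seed)) == len(seed)
        if qm.pad_bits:
            assert set(seed.bits[-qm.pad_bits:]) == {"0"}
        assert qm.total_width + qm.pad_bits == qm.seed_len

    def test_determinism_and_jitter_robustness(self):
        X = _blobs([[0, 0], [0, 3], [3, 0], [3, 3]], 0.1, 500, seed=10)
        rng = np.random.default_rng(10)
        training = rng.normal(0, 1, (500, 29))
        training[:, [0, 1]] = X
        qm1 = quantize.build_quantizer(training, FIDX10, "pm", rng_seed=5)
        qm2 = quantize.build_quantizer(training, FIDX10, "pm", rng_seed=5)
        v = training[3]
        s1, _ = quantize.quantize_bits(v, qm1)
        s2, _ = quantize.quantize_bits(v, qm2)
        assert s1.bits == s2.bits
        # perturbations well below the inter-centroid half-distance
        for trial in range(100):
            s3, _ = quantize.quantize_bits(v + rng.normal(0, 1e-6, 29), qm1)
            assert s3.bits == s1.bits

    def test_non_finite_feature_rejected(self):
        m = quantize.PairModel(feature_pair=(1, 2), k=2,
                               centroids=np.array([[0., 0.], [1., 1.]]),
                               scaler_mean=np.zeros(2), scaler_sd=np.ones(2),
                               silhouette=0.5, bit_width=1)
        qm = quantize.QuantizerModel(models=[m], pad_bits=1, seed_len=2,
                                     criterion="pm")
        bad = np.zeros(29)
        bad[0] = np.nan
        with pytest.raises(ParameterError):
            quantize.quantize_bits(bad, qm)


class TestVoteLabels:
    @pytest.mark.parametrize("labels,expected", [
        ([[2], [2], [3], [2]], [2]),
        ([[1], [1], [2], [2]], [1]),
        ([[3]], [3]),
    ])
    def test_vote_rules(self, labels, expected):
        assert quantize.vote_labels(labels) == expected

    def test_multi_model_vote(self):
        lm = [[2, 1], [2, 2], [3, 2], [2, 1]]
        assert quantize.vote_labels(lm) == [2, 1]
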