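"""Clustering-based Dynamic Quantization.

The subject's 10 selected features are combined into all 45 unordered
pairs; pairs showing multicollinearity (|Pearson r| >= r_max on the
population training data) are screened out. Each surviving pair gets a
2-D k-means model with k in {2, 4}; k is chosen either by maximum
silhouette (criterion "pm") or by requiring the silhouette to reach a
threshold and then maximizing cluster-occupancy uniformity (criterion
"pu" — pairs for which no k qualifies are dropped, which is what makes
seed lengths subject-specific). Cluster labels map to bits (label C with
k clusters -> binary of C-1 in k/2 bits); the concatenated bits are
zero-padded to the next power of two to form the seed.

Cluster labels are relabeled deterministically by ascending centroid
coordinates so the label-to-bit mapping is reproducible across refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .exceptions import ParameterError, QuantizerBuildError
from .types import FeatureIndexSet, FeatureSet


@dataclass
class QuantizeConfig:
    r_max: float = 0.8          # multicollinearity cutoff on |Pearson r|
    theta_s: float = 0.4        # pu silhouette threshold
    criterion: str = "pu"       # "pm" or "pu"
    k_values: tuple[int, ...] = (2, 4)
    n_init: int = 10
    max_iter: int = 300
    tol: float = 1e-4
    min_training_rows: int = 30
    forced_seed_len: int | None = None  # override the power-of-two rule


@dataclass
class PairModel:
    """Fitted k-means quantizer for one feature pair."""

    feature_pair: tuple[int, int]      # 1-based feature ids
    k: int
    centroids: np.ndarray              # (k, 2) standardized space
    scaler_mean: np.ndarray            # (2,)
    scaler_sd: np.ndarray              # (2,)
    silhouette: float
    bit_width: int

    def standardize(self, xy: np.ndarray) -> np.ndarray:
        return (np.asarray(xy, dtype=float) - self.scaler_mean) / self.scaler_sd

    def label(self, xy: np.ndarray) -> int:
        """Nearest-centroid cluster label in 1..k (ties -> lower label)."""
        z = self.standardize(xy)
        d = np.linalg.norm(self.centroids - z, axis=1)
        return int(np.argmin(d)) + 1  # argmin takes the first minimum

    def bits(self, label: int) -> str:
        if not 1 <= label <= self.k:
            raise ParameterError(f"label {label} outside 1..{self.k}")
        return format(label - 1, f"0{self.bit_width}b")


@dataclass
class QuantizerModel:
    """Ordered per-pair models plus padding bookkeeping (the Hclust data)."""

    models: list[PairModel]
    pad_bits: int
    seed_len: int
    criterion: str
    fidx: FeatureIndexSet | None = None
    config: QuantizeConfig = field(default_factory=QuantizeConfig)

    @property
    def total_width(self) -> int:
        return sum(m.bit_width for m in self.models)


@dataclass
class Seed:
    """Zero-padded binary seed string."""

    bits: str

    def __post_init__(self) -> None:
        if set(self.bits) - {"0", "1"}:
            raise ParameterError("seed bits must be binary")

    def __len__(self) -> int:
        return len(self.bits)

    def as_array(self) -> np.ndarray:
        return np.frombuffer(self.bits.encode(), dtype=np.uint8) - ord("0")

    def hex(self) -> str:
        return f"{int(self.bits, 2):0{(len(self.bits) + 3) // 4}x}" if self.bits else ""


def next_pow2(n: int) -> int:
    """Smallest power of two >= n (and >= 1)."""
    p = 1
    while p < n:
        p *= 2
    return p


def screen_pairs(training: np.ndarray, fidx: FeatureIndexSet,
                 r_max: float = 0.8) -> list[tuple[int, int]]:
    """Candidate feature pairs free of multicollinearity.

    ``training`` holds the population rows restricted to the fidx columns
    (same order as ``fidx.indices``). Returns pairs of 1-based feature ids,
    sorted lexicographically.
    """
    X = np.atleast_2d(np.asarray(training, dtype=float))
    if not 0 < r_max < 1:
        raise ParameterError("r_max must lie in (0, 1)")
    if X.shape[0] < 30:
        raise ParameterError("screening needs at least 30 training rows")
    if X.shape[1] != len(fidx):
        raise ParameterError("training columns must match the feature index set")

    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn("constant feature column(s) excluded from pairing",
                      stacklevel=2)
    ids = list(fidx.indices)
    col = {fid: j for j, fid in enumerate(ids)}
    pairs = sorted((min(a, b), max(a, b))
                   for i, a in enumerate(ids) for b in ids[i + 1:])
    kept = []
    for i, j in pairs:
        ci, cj = col[i], col[j]
        if constant[ci] or constant[cj]:
            continue
        r = np.corrcoef(X[:, ci], X[:, cj])[0, 1]
        if abs(r) >= r_max:
            continue
        kept.append((i, j))
    return kept


def _relabel(centroids: np.ndarray, labels: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic relabeling by ascending centroid coordinates."""
    order = np.lexsort((centroids[:, 1], centroids[:, 0]))
    new_centroids = centroids[order]
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(len(order))
    return new_centroids, remap[labels] + 1  # labels 1..k


def fit_pair_model(pair_columns: np.ndarray, feature_pair: tuple[int, int],
                   criterion: str = "pu",
                   config: QuantizeConfig | None = None,
                   rng_seed: int = 0) -> PairModel | None:
    """Fit k-means for k in {2, 4} and select k by the pm or pu criterion.

    Returns None when the pair is rejected (pu criterion unmet, or a
    degenerate clustering).
    """
    cfg = config or QuantizeConfig()
    if criterion not in ("pm", "pu"):
        raise ParameterError("criterion must be 'pm' or 'pu'")
    X = np.atleast_2d(np.asarray(pair_columns, dtype=float))
    if X.shape[0] < cfg.min_training_rows:
        raise ParameterError(
            f"need >= {cfg.min_training_rows} training rows, got {X.shape[0]}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        return None
    Z = (X - mean) / sd

    fits: dict[int, tuple[float, float, np.ndarray, np.ndarray]] = {}
    for k in cfg.k_values:
        km = KMeans(n_clusters=k, n_init=cfg.n_init, max_iter=cfg.max_iter,
                    tol=cfg.tol, random_state=int(rng_seed) % (2**31),
                    algorithm="lloyd")
        labels = km.fit_predict(Z)
        if len(np.unique(labels)) < k:
            continue  # degenerate: empty cluster
        sil = float(silhouette_score(Z, labels))
        occupancy = np.bincount(labels, minlength=k) / labels.size
        fits[k] = (sil, float(occupancy.min()), km.cluster_centers_, labels)

    if not fits:
        return None

    if criterion == "pm":
        # maximum silhouette; ties to the smaller k
        k_best = max(sorted(fits), key=lambda k: fits[k][0])
    else:
        qualified = [k for k in sorted(fits) if fits[k][0] >= cfg.theta_s]
        if not qualified:
            return None
        # most uniform occupancy; ties to higher silhouette, then smaller k
        k_best = max(qualified, key=lambda k: (fits[k][1], fits[k][0], -k))

    sil, _, centroids, labels = fits[k_best]
    centroids, _ = _relabel(centroids, labels)
    return PairModel(feature_pair=tuple(feature_pair), k=k_best,
                     centroids=centroids, scaler_mean=mean, scaler_sd=sd,
                     silhouette=sil, bit_width=k_best // 2)


def build_quantizer(training: np.ndarray, fidx: FeatureIndexSet,
                    criterion: str = "pu",
                    config: QuantizeConfig | None = None,
                    rng_seed: int = 0) -> QuantizerModel:
    """Screen pairs, fit per-pair models, and size the padded seed.

    ``training`` is the full 29-column population feature matrix; the fidx
    columns are taken from it.
    """
    cfg = config or QuantizeConfig()
    X = np.atleast_2d(np.asarray(training, dtype=float))
    sub = X[:, fidx.positions]
    pairs = screen_pairs(sub, fidx, r_max=cfg.r_max)
    col = {fid: j for j, fid in enumerate(fidx.indices)}

    models: list[PairModel] = []
    for idx, (i, j) in enumerate(pairs):
        pm = fit_pair_model(sub[:, [col[i], col[j]]], (i, j),
                            criterion=criterion, config=cfg,
                            rng_seed=(int(rng_seed) + idx) % (2**31))
        if pm is not None:
            models.append(pm)
    if not models:
        raise QuantizerBuildError(
            "no feature pair survived screening and cluster fitting")
    width = sum(m.bit_width for m in models)
    seed_len = cfg.forced_seed_len or next_pow2(width)
    if seed_len < width:
        raise ParameterError("forced seed length shorter than the bit string")
    return QuantizerModel(models=models, pad_bits=seed_len - width,
                          seed_len=seed_len, criterion=criterion, fidx=fidx,
                          config=cfg)


def _pair_values(features: FeatureSet | np.ndarray,
                 pair: tuple[int, int]) -> np.ndarray:
    if isinstance(features, FeatureSet):
        return np.array([features[pair[0]], features[pair[1]]])
    arr = np.asarray(features, dtype=float)
    return np.array([arr[pair[0] - 1], arr[pair[1] - 1]])


def model_labels(features: FeatureSet | np.ndarray,
                 model: QuantizerModel) -> list[int]:
    """Per-pair cluster labels for one feature vector."""
    labels = []
    for pm in model.models:
        xy = _pair_values(features, pm.feature_pair)
        if not np.all(np.isfinite(xy)):
            raise ParameterError(
                f"non-finite value for feature pair {pm.feature_pair}")
        labels.append(pm.label(xy))
    return labels


def bits_from_labels(labels: list[int], model: QuantizerModel) -> Seed:
    """Eq-style binarization of per-pair labels plus zero padding."""
    bits = "".join(pm.bits(lab) for pm, lab in zip(model.models, labels))
    bits += "0" * model.pad_bits
    return Seed(bits=bits)


def quantize_bits(features: FeatureSet | np.ndarray, model: QuantizerModel
                  ) -> tuple[Seed, list[int]]:
    """Feature vector -> (padded seed, per-pair labels)."""
    labels = model_labels(features, model)
    return bits_from_labels(labels, model), labels


def vote_labels(label_matrix: np.ndarray) -> list[int]:
    """Per-model modal label across beats; ties to the lowest label."""
    L = np.atleast_2d(np.asarray(label_matrix, dtype=int))
    if L.shape[0] < 1:
        raise ParameterError("need at least one beat row")
    out = []
    for col in L.T:
        counts = np.bincount(col)
        out.append(int(np.argmax(counts)))  # first maximum = lowest label
    return out
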