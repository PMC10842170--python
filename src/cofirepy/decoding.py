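"""Linear-SVM decoding of environment and location from ensemble activity.

Environment decoding uses 1-s activity vectors (one feature per cell) or
60-s windowed coactivity vectors (one feature per valid cell pair computed
from position-tuning-independent rates).  Training/testing uses 100
repetitions of random stratified 2/3 - 1/3 splits; accuracies and signed
feature weights are averaged across repetitions.  Weights are read directly
(linear kernel, hinge loss, C = 1, no feature standardization) so that each
cell's or pair's contribution is interpretable; the cells with the top 20%
absolute weights form the "environment-discriminating subset".

Location decoding scores the mean pairwise-bin accuracy over all
n(n-1)/2 pairs of spatial bins, from either 1-s activity vectors or 1-s
coincidence vectors (per cell pair: 0 if neither cell active, 1 if one, 2
if both).  Comparisons across input types of different dimensionality
downsample features to the smaller dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .coactivity import CoactivityMatrix, PTISeries, kendall_tau_matrix

__all__ = [
    "FeatureSet",
    "DecoderResult",
    "train_environment_decoder",
    "coactivity_window_features",
    "coincidence_vectors",
    "cross_day_transfer",
    "subset_decoding",
    "environment_discriminating_subset",
    "proportion_ratio",
    "location_decoder",
]

DEFAULT_REPS = 100
TRAIN_FRACTION = 2.0 / 3.0
SVM_C = 1.0


@dataclass
class FeatureSet:
    """Samples x features with binary labels and feature identities."""

    X: np.ndarray             # (n_samples, n_features)
    y: np.ndarray             # (n_samples,) binary labels
    feature_ids: np.ndarray   # cell indices, or (i, j) pair rows
    sample_times: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y must align")
        if len(np.unique(self.y)) != 2:
            raise ValueError("labels must be binary")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class DecoderResult:
    accuracies: np.ndarray    # per repetition
    weights: np.ndarray       # mean signed weight per feature
    feature_ids: np.ndarray
    n_samples: int

    @property
    def accuracy(self) -> float:
        return float(self.accuracies.mean())


def _fit_svm(X, y):
    clf = SVC(kernel="linear", C=SVM_C)
    clf.fit(X, y)
    return clf


def _stratified_split(y, rng, train_fraction=TRAIN_FRACTION):
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        k = max(1, int(round(train_fraction * len(idx))))
        k = min(k, len(idx) - 1)
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def train_environment_decoder(
    features: FeatureSet,
    reps: int = DEFAULT_REPS,
    seed: int | np.random.Generator = 0,
) -> DecoderResult:
    """Cross-validated linear-SVM decoding with weight averaging.

    Each repetition draws a stratified 2/3 train / 1/3 test split; accuracy is
    the fraction of correct test decisions, and the signed weight vector is
    averaged over repetitions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accs = np.empty(reps)
    weights = np.zeros(features.n_features)
    for r in range(reps):
        tr, te = _stratified_split(features.y, rng)
        clf = _fit_svm(features.X[tr], features.y[tr])
        accs[r] = float((clf.predict(features.X[te]) == features.y[te]).mean())
        weights += clf.coef_.ravel()
    return DecoderResult(accuracies=accs, weights=weights / reps,
                         feature_ids=features.feature_ids, n_samples=len(features.y))


def coactivity_window_features(
    pti_list: list[tuple[PTISeries, object]],
    window_s: float = 60.0,
    min_active_fraction: float = 0.02,
) -> FeatureSet:
    """Non-overlapping 60-s windows of cell-pair coactivity as samples.

    ``pti_list`` pairs a PTI (or observed) binned series with its label.  One
    sample per window is the vector of pairwise Kendall tau values over the
    window's 1-s bins.  Cells silent in any window are dropped everywhere so
    the feature set is consistent across samples.
    """
    bins_per_win = int(round(window_s))
    windows, labels = [], []
    for series, label in pti_list:
        data = series.data if hasattr(series, "data") else np.asarray(series, float)
        n_win = data.shape[1] // bins_per_win
        if n_win < 1:
            raise ValueError("recording shorter than one window")
        for w in range(n_win):
            windows.append(data[:, w * bins_per_win:(w + 1) * bins_per_win])
            labels.append(label)
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    n_cells = windows[0].shape[0]
    active = np.ones(n_cells, bool)
    for wdat in windows:
        active &= (np.abs(wdat) > 0).mean(axis=1) >= min_active_fraction
    keep = np.flatnonzero(active)
    iu, ju = np.triu_indices(len(keep), 1)
    X = np.empty((len(windows), len(iu)))
    for k, wdat in enumerate(windows):
        tau = kendall_tau_matrix(wdat[keep])
        X[k] = np.nan_to_num(tau[iu, ju], nan=0.0)
    classes = sorted(set(labels))
    y = np.array([classes.index(l) for l in labels])
    pair_ids = np.stack([keep[iu], keep[ju]], axis=1)
    return FeatureSet(X=X, y=y, feature_ids=pair_ids)


def cross_day_transfer(
    train: FeatureSet, test: FeatureSet, min_shared: int = 20,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Train on one day's full dataset, evaluate on another day (no
    cross-validation), restricted to shared features; also returns the
    Pearson correlation between the two days' independently trained weights."""
    shared, ia, ib = np.intersect1d(
        _flat_ids(train.feature_ids), _flat_ids(test.feature_ids), return_indices=True)
    if len(shared) < min_shared:
        raise ValueError(f"fewer than {min_shared} shared features")
    Xa, Xb = train.X[:, ia], test.X[:, ib]
    clf = _fit_svm(Xa, train.y)
    acc = float((clf.predict(Xb) == test.y).mean())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wa = clf.coef_.ravel()
    wb = _fit_svm(Xb, test.y).coef_.ravel()
    return {"accuracy": acc, "weight_correlation": float(np.corrcoef(wa, wb)[0, 1]),
            "n_shared": len(shared)}


def _flat_ids(ids: np.ndarray) -> np.ndarray:
    ids = np.asarray(ids)
    if ids.ndim == 1:
        return ids
    # encode (i, j) pairs as single integers for set operations
    return ids[:, 0] * 1_000_000 + ids[:, 1]


def subset_decoding(
    features: FeatureSet,
    result: DecoderResult,
    selection: str | tuple[float, float],
    reps: int = DEFAULT_REPS,
    seed: int | np.random.Generator = 0,
    downsample_to: int | None = None,
    min_features: int = 5,
) -> DecoderResult:
    """Retrain the decoder on a weight-ranked feature subset.

    ``selection`` is either a quantile interval over the |weight| ranking --
    (0.8, 1.0) is the top quintile, (0.0, 0.4) the bottom 40% -- or the string
    "random:<fraction>".  ``downsample_to`` randomly subsamples the kept
    features so comparisons across input types use equal dimension.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = features.n_features
    order = np.argsort(np.abs(result.weights))  # ascending |weight|
    if isinstance(selection, str):
        if not selection.startswith("random:"):
            raise ValueError(f"unknown selection {selection!r}")
        frac = float(selection.split(":")[1])
        keep = rng.choice(n, size=max(1, int(round(frac * n))), replace=False)
    else:
        lo, hi = selection
        keep = order[int(np.floor(lo * n)): int(np.ceil(hi * n))]
    if downsample_to is not None and len(keep) > downsample_to:
        keep = rng.choice(keep, size=downsample_to, replace=False)
    if len(keep) < min_features:
        raise ValueError(f"subset smaller than {min_features} features")
    sub = FeatureSet(X=features.X[:, keep], y=features.y, feature_ids=features.feature_ids[keep])
    return train_environment_decoder(sub, reps=reps, seed=rng)


def environment_discriminating_subset(result: DecoderResult, fraction: float = 0.2) -> np.ndarray:
    """Feature ids of the top ``fraction`` by absolute mean weight."""
    n = len(result.weights)
    k = max(1, int(round(fraction * n)))
    top = np.argsort(np.abs(result.weights))[::-1][:k]
    return result.feature_ids[top]


def proportion_ratio(
    subset_ids: np.ndarray, all_ids: np.ndarray, property_flags: np.ndarray
) -> float:
    """Enrichment of a cell property in a subset: prevalence within the subset
    divided by prevalence in the full population (1 = chance)."""
    all_ids = np.asarray(all_ids)
    flags = np.asarray(property_flags, bool)
    pop = flags[all_ids].mean()
    if pop == 0:
        raise ValueError("property absent from the population")
    return float(flags[np.asarray(subset_ids)].mean() / pop)


def coincidence_vectors(binned: np.ndarray) -> np.ndarray:
    """1-s coincidence code: per cell pair 0 (neither active), 1 (one), 2 (both).

    ``binned`` is cells x bins; activity is binarized at > 0.
    """
    act = (np.asarray(binned) > 0).astype(np.int8)
    iu, ju = np.triu_indices(act.shape[0], 1)
    return (act[iu] + act[ju]).T  # (bins, n_pairs)


def location_decoder(
    X: np.ndarray,
    location_bins: np.ndarray,
    reps: int = 20,
    seed: int | np.random.Generator = 0,
    min_samples: int = 10,
    downsample_to: int | None = None,
) -> dict:
    """Pairwise location decoding: mean cross-validated accuracy over all
    pairs of location bins with at least ``min_samples`` samples each.

    ``X`` is samples x features (activity or coincidence vectors);
    ``location_bins`` labels each sample with its spatial bin.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, float)
    if downsample_to is not None and X.shape[1] > downsample_to:
        keep = rng.choice(X.shape[1], size=downsample_to, replace=False)
        X = X[:, keep]
    bins, counts = np.unique(location_bins, return_counts=True)
    usable = bins[counts >= min_samples]
    dropped = [int(b) for b in bins[counts < min_samples]]
    if len(usable) < 2:
        raise ValueError("need at least two location bins with enough samples")
    accs = []
    for a in range(len(usable)):
        for b in range(a + 1, len(usable)):
            sel = np.isin(location_bins, (usable[a], usable[b]))
            fs = FeatureSet(X=X[sel], y=(location_bins[sel] == usable[b]).astype(int),
                            feature_ids=np.arange(X.shape[1]))
            accs.append(train_environment_decoder(fs, reps=reps, seed=rng).accuracy)
    return {"score": float(np.mean(accs)), "pair_accuracies": np.array(accs),
            "dropped_bins": dropped, "n_bins": len(usable)}
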