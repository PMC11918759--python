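"""Handcrafted-feature machine-learning baselines.

Per subject, six statistics (mean, variance, kurtosis, skewness, peak
value, time to peak) are computed from each indicator-channel time course,
giving 6 indicators x 68 channels x 6 statistics = 2,448 candidate features
for the default montage.  Within each leave-one-subject-out fold the
features are z-scored with training-set statistics, ranked by Fisher score
on the training rows only, and a classifier (shrinkage LDA or
ridge-regularized linear SVM) is trained on the top-N features for
N = 1..50; the best per-N accuracy across the sweep is the reported
accuracy.

Conventions (the source toolboxes leave these open; all are documented and
swappable): kurtosis is Pearson (non-excess); skewness is the adjusted
Fisher-Pearson estimator; peak value is the signed maximum; time to peak is
the latency of that maximum in seconds with first-index tie-break; z-score
uses the population standard deviation; the Fisher score is
``sum_c n_c (mu_c - mu)^2 / sum_c n_c var_c`` with ties broken by feature
index.  sLDA uses the Ledoit-Wolf analytic shrinkage estimate; rSVM is a
linear SVM with L2 penalty, C = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import LinearSVC

from .indicators import INDICATOR_NAMES

STATISTIC_NAMES = ("mean", "variance", "kurtosis", "skewness", "peak", "time_to_peak")

__all__ = [
    "STATISTIC_NAMES",
    "FeatureTable",
    "extract_features",
    "build_feature_table",
    "zscore_fit_apply",
    "fisher_score",
    "train_slda",
    "train_rsvm",
    "n_feature_accuracy_sweep",
    "SweepResult",
]


@dataclass(frozen=True)
class FeatureTable:
    """Subject-by-feature matrix with decodable (indicator, channel, statistic) names."""

    matrix: np.ndarray  # (n_subjects, n_features)
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("feature name count does not match matrix width")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names are not unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.feature_names))

    @staticmethod
    def decode_name(name: str) -> tuple[str, int, str]:
        """``'dCBV.ch07.skewness' -> ('dCBV', 7, 'skewness')``."""
        indicator, ch, stat = name.split(".")
        return indicator, int(ch.removeprefix("ch")), stat


def _feature_names(n_channels: int) -> tuple[str, ...]:
    return tuple(
        f"{ind}.ch{ch + 1:02d}.{stat}"
        for ind in INDICATOR_NAMES
        for ch in range(n_channels)
        for stat in STATISTIC_NAMES
    )


def extract_features(sample: np.ndarray, sampling_rate: float = 8.138) -> np.ndarray:
    """Statistics of every indicator-channel time course of one subject.

    ``sample`` is the ``(6, n_times, n_channels)`` indicator tensor; the
    result is the flat feature row in indicator-major, channel-then-
    statistic order (length ``6 * n_channels * 6``).
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 3 or sample.shape[0] != len(INDICATOR_NAMES):
        raise ValueError(f"expected (6, time, channel) tensor, got {sample.shape}")
    if not np.isfinite(sample).all():
        raise ValueError("non-finite values in sample")
    n_ind, n_t, n_ch = sample.shape
    # (indicator, channel, time)
    x = np.swapaxes(sample, 1, 2)
    mean = x.mean(axis=-1)
    var = x.var(axis=-1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant traces
        kurt = stats.kurtosis(x, axis=-1, fisher=False, bias=True)
        skew = stats.skew(x, axis=-1, bias=False)
    skew = np.nan_to_num(skew)
    kurt = np.nan_to_num(kurt)
    peak_idx = x.argmax(axis=-1)
    peak = np.take_along_axis(x, peak_idx[..., None], axis=-1)[..., 0]
    ttp = peak_idx / sampling_rate
    feats = np.stack([mean, var, kurt, skew, peak, ttp], axis=-1)
    return feats.reshape(-1)


def build_feature_table(
    samples: np.ndarray, sampling_rate: float = 8.138
) -> FeatureTable:
    """Feature rows for a stack of subjects, ``(n, 6, time, channel)``."""
    rows = np.stack([extract_features(s, sampling_rate) for s in samples])
    return FeatureTable(matrix=rows, feature_names=_feature_names(samples.shape[-1]))


def zscore_fit_apply(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both splits with mean/sd estimated on the training rows only.

    Features with zero training variance map to 0 in both splits (with a
    warning) rather than producing infinities.
    """
    train = np.asarray(train, dtype=float)
    test = np.atleast_2d(np.asarray(test, dtype=float))
    if train.shape[0] < 2:
        raise ValueError("need at least two training rows to estimate variance")
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance features mapped to 0")
        sd = np.where(dead, 1.0, sd)
    tr = (train - mu) / sd
    te = (test - mu) / sd
    tr[:, dead] = 0.0
    te[:, dead] = 0.0
    return tr, te


def fisher_score(train: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fisher score per feature and the descending ranking.

    ``F_j = (n1 (mu1 - mu)^2 + n2 (mu2 - mu)^2) / (n1 var1 + n2 var2)``,
    with class-wise population variances.  Returns ``(scores, order)``
    where ``order`` ranks features best-first, ties broken by index.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("fisher_score needs exactly two classes")
    mu = train.mean(axis=0)
    num = np.zeros(train.shape[1])
    den = np.zeros(train.shape[1])
    for c in classes:
        rows = train[labels == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c} has fewer than two members")
        num += rows.shape[0] * (rows.mean(axis=0) - mu) ** 2
        den += rows.shape[0] * rows.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    order = np.argsort(-scores, kind="stable")
    return scores, order


def train_slda(train: np.ndarray, labels: np.ndarray) -> LinearDiscriminantAnalysis:
    """Shrinkage LDA: lsqr solver with Ledoit-Wolf analytic shrinkage."""
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    clf.fit(train, labels)
    return clf


def train_rsvm(train: np.ndarray, labels: np.ndarray, C: float = 1.0) -> LinearSVC:
    """Ridge (L2)-regularized linear SVM."""
    clf = LinearSVC(C=C)
    clf.fit(train, labels)
    return clf


_CLASSIFIERS = {"slda": train_slda, "rsvm": train_rsvm}


@dataclass(frozen=True)
class SweepResult:
    """Per-N LOSO accuracies of the N-feature sweep."""

    accuracy_per_n: np.ndarray  # index 0 <-> N = 1
    best_n: int
    best_accuracy: float  # percent

    def as_dict(self) -> dict:
        return {
            "accuracy_per_n": self.accuracy_per_n.tolist(),
            "best_n": self.best_n,
            "best_accuracy": self.best_accuracy,
        }


def n_feature_accuracy_sweep(
    features: FeatureTable | np.ndarray,
    labels: np.ndarray,
    classifier: str = "slda",
    n_max: int = 50,
) -> SweepResult:
    """Leave-one-subject-out N-feature accuracy sweep.

    For each fold, normalization statistics and the Fisher ranking are
    computed from the training rows only (no leakage); for each
    N in 1..n_max a fresh classifier is trained on the top-N features and
    the held-out subject is predicted.  Accuracies are averaged over folds
    per N; the maximum over N is the designated accuracy.
    """
    x = features.matrix if isinstance(features, FeatureTable) else np.asarray(features)
    labels = np.asarray(labels)
    if classifier not in _CLASSIFIERS:
        raise ValueError(f"classifier must be one of {sorted(_CLASSIFIERS)}")
    if n_max > x.shape[1]:
        raise ValueError(f"n_max={n_max} exceeds feature count {x.shape[1]}")
    if min(np.bincount(labels)) < 3:
        raise ValueError("need at least three subjects per class")
    fit = _CLASSIFIERS[classifier]
    n_subj = x.shape[0]
    correct = np.zeros(n_max)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_subj):
            mask = np.ones(n_subj, dtype=bool)
            mask[i] = False
            tr, te = zscore_fit_apply(x[mask], x[i])
            _, order = fisher_score(tr, labels[mask])
            for n in range(1, n_max + 1):
                cols = order[:n]
                clf = fit(tr[:, cols], labels[mask])
                correct[n - 1] += int(clf.predict(te[:, cols])[0] == labels[i])
    acc = 100.0 * correct / n_subj
    best = int(np.argmax(acc))
    return SweepResult(accuracy_per_n=acc, best_n=best + 1, best_accuracy=float(acc[best]))
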