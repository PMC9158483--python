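"""RBF-SVM classification of oxygen groups from per-taxon CLR features.

For each taxon (default: taxonomic class), the CLR values of its OTUs
are the feature matrix and the per-sample oxygen group (binary, ternary
or quaternary) is the response. The protocol:

* a guard refuses problems where one group holds more than 60% of the
  samples (accuracy would be dominated by the majority class);
* each analysis runs ``n_iterations`` (default 128) train/test cycles,
  each on a fresh random 25% test split; hyperparameters (C, gamma) are
  tuned per iteration by 10-fold cross-validation on the training set;
* a matched null run repeats the same protocol with the label vector
  permuted once per iteration before splitting, so train and test share
  the same broken labelling;
* per-sample accuracy is the fraction of times a sample was classified
  correctly when it appeared in a test set;
* an incremental-OTU scan (10 OTUs, then +20 at a time, OTUs ordered by
  decreasing total read count) exposes overfitting plateaus.

Multi-group problems use the standard one-vs-one reduction of the
RBF-kernel SVM. The gamma grid is anchored at the median heuristic
(inverse median squared Euclidean distance between training samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr
from sklearn.model_selection import KFold
from sklearn.svm import SVC

from .coda import ClrMatrix

__all__ = [
    "ClassifierConfig",
    "AccuracyResult",
    "OverfitScanResult",
    "DominanceError",
    "dominance_guard",
    "build_features",
    "run_classification",
    "overfit_scan",
    "accuracy_correlations",
]

C_GRID = (0.25, 1.0, 4.0, 16.0, 64.0)
GAMMA_FACTORS = (0.1, 1.0, 10.0)


class DominanceError(ValueError):
    """One group holds more than the allowed share of samples."""


@dataclass
class ClassifierConfig:
    """Protocol parameters for the iterated SVM analysis."""

    n_iterations: int = 128
    test_fraction: float = 0.25
    cv_folds: int = 10
    dominance_max: float = 0.60
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class AccuracyResult:
    """Per-iteration and per-sample accuracies for one taxon/grouping."""

    taxon: str
    grouping: str
    shuffled: bool
    accuracies: np.ndarray  # one test accuracy per iteration
    per_sample_correct: pd.Series
    per_sample_tested: pd.Series
    confusion: pd.DataFrame  # true group x predicted group tallies

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.accuracies))

    @property
    def iqr(self) -> float:
        q1, q3 = np.percentile(self.accuracies, [25, 75])
        return float(q3 - q1)

    def per_sample_accuracy(self) -> pd.Series:
        """Fraction of test appearances in which each sample was correct."""
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = self.per_sample_correct / self.per_sample_tested
        return acc


@dataclass
class OverfitScanResult:
    """Median accuracy as the number of (abundance-ranked) OTUs grows."""

    taxon: str
    ks: list[int]
    median_accuracies: list[float]
    optimum_k: int
    optimum_fraction: float  # optimum_k / total OTUs in taxon


def dominance_guard(labels, dominance_max: float = 0.60) -> None:
    """Raise if any single group exceeds ``dominance_max`` of samples."""
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    share = counts / counts.sum()
    if share.iloc[0] > dominance_max:
        raise DominanceError(
            f"group {share.index[0]!r} holds {share.iloc[0]:.1%} of samples "
            f"(> {dominance_max:.0%})"
        )


def build_features(
    clr_matrix: ClrMatrix,
    taxon_otus,
    otu_totals: pd.Series,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Samples x OTUs CLR feature matrix for one taxon.

    OTUs are ordered by decreasing dataset-wide read count (ties broken
    by id for determinism); ``top_k`` truncates to the most abundant k,
    clamped at the taxon size.
    """
    taxon_otus = [o for o in taxon_otus if o in clr_matrix.otu_ids]
    if not taxon_otus:
        raise ValueError("taxon has no OTUs in the CLR matrix")
    ordered = sorted(taxon_otus, key=lambda o: (-otu_totals.loc[o], o))
    if top_k is not None:
        ordered = ordered[: min(top_k, len(ordered))]
    return clr_matrix.values.loc[ordered].T


def _median_heuristic_gamma(features: np.ndarray) -> float:
    sq = pdist(features, metric="sqeuclidean")
    med = np.median(sq) if len(sq) else 0.0
    return 1.0 / med if med > 0 else 1.0


def _tune_and_fit(
    x_train: np.ndarray, y_train: np.ndarray, cv_folds: int, rng: np.random.Generator
) -> SVC:
    """Grid-search (C, gamma) by k-fold CV accuracy; first best wins,
    so ties resolve to the smallest C then smallest gamma."""
    gamma0 = _median_heuristic_gamma(x_train)
    grid = [(c, gamma0 * f) for c in C_GRID for f in GAMMA_FACTORS]
    n_splits = min(cv_folds, len(x_train))
    folds = list(
        KFold(n_splits=n_splits, shuffle=True,
              random_state=int(rng.integers(2**31 - 1))).split(x_train)
    )
    best_score, best_params = -1.0, grid[0]
    for c, gamma in grid:
        scores = []
        for tr, va in folds:
            if len(np.unique(y_train[tr])) < 2:
                continue
            model = SVC(kernel="rbf", C=c, gamma=gamma)
            model.fit(x_train[tr], y_train[tr])
            scores.append(np.mean(model.predict(x_train[va]) == y_train[va]))
        score = float(np.mean(scores)) if scores else -1.0
        if score > best_score:
            best_score, best_params = score, (c, gamma)
    model = SVC(kernel="rbf", C=best_params[0], gamma=best_params[1])
    model.fit(x_train, y_train)
    return model


def run_classification(
    features: pd.DataFrame,
    labels: pd.Series,
    config: ClassifierConfig | None = None,
    shuffle: bool = False,
    taxon: str = "",
    grouping: str = "",
    rng: np.random.Generator | None = None,
) -> AccuracyResult:
    """Iterated random-split SVM accuracy estimation.

    ``features`` is samples x OTUs; ``labels`` maps the same samples to
    group names. With ``shuffle=True`` the full label vector is permuted
    once per iteration before splitting (the matched null protocol).
    """
    config = config or ClassifierConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    labels = labels.reindex(features.index)
    if labels.isna().any():
        raise ValueError("every sample in the feature matrix needs a label")
    dominance_guard(labels, config.dominance_max)

    x = features.to_numpy(dtype=float)
    y_orig = labels.to_numpy()
    n = len(x)
    n_test = max(1, int(round(config.test_fraction * n)))
    groups = sorted(pd.unique(y_orig))

    accuracies = np.empty(config.n_iterations)
    correct = np.zeros(n)
    tested = np.zeros(n)
    confusion = pd.DataFrame(0, index=groups, columns=groups)

    # one child seed per iteration so results are order-independent
    seeds = rng.integers(2**31 - 1, size=config.n_iterations)
    for it in range(config.n_iterations):
        it_rng = np.random.default_rng(seeds[it])
        y = it_rng.permutation(y_orig) if shuffle else y_orig
        for _attempt in range(100):
            perm = it_rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if len(np.unique(y[train_idx])) >= 2:
                break
        else:  # pragma: no cover - requires pathological label vectors
            raise RuntimeError("could not draw a training split with 2 groups")
        model = _tune_and_fit(x[train_idx], y[train_idx], config.cv_folds, it_rng)
        pred = model.predict(x[test_idx])
        hits = pred == y[test_idx]
        accuracies[it] = float(np.mean(hits))
        correct[test_idx] += hits
        tested[test_idx] += 1
        for truth, guess in zip(y[test_idx], pred):
            confusion.loc[truth, guess] += 1

    return AccuracyResult(
        taxon=taxon,
        grouping=grouping,
        shuffled=shuffle,
        accuracies=accuracies,
        per_sample_correct=pd.Series(correct, index=features.index),
        per_sample_tested=pd.Series(tested, index=features.index),
        confusion=confusion,
    )


def overfit_scan(
    clr_matrix: ClrMatrix,
    taxon_otus,
    otu_totals: pd.Series,
    labels: pd.Series,
    config: ClassifierConfig | None = None,
    taxon: str = "",
    rng: np.random.Generator | None = None,
) -> OverfitScanResult:
    """Accuracy as a function of the number of most-abundant OTUs used.

    Models are built on the first 10 OTUs, then in increments of 20
    (10, 30, 50, ...) until all of the taxon's OTUs are included. The
    optimum is the smallest k achieving the maximum median accuracy.
    """
    config = config or ClassifierConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    total = len([o for o in taxon_otus if o in clr_matrix.otu_ids])
    if total == 0:
        raise ValueError("taxon has no OTUs in the CLR matrix")
    ks = [k for k in range(10, total, 20)] if total > 10 else []
    ks.append(total)
    medians = []
    for k in ks:
        feats = build_features(clr_matrix, taxon_otus, otu_totals, top_k=k)
        result = run_classification(
            feats, labels, config, shuffle=False, taxon=taxon, rng=rng
        )
        medians.append(result.median_accuracy)
    best = max(medians)
    optimum_k = ks[int(np.argmax([m == best for m in medians]))]
    return OverfitScanResult(
        taxon=taxon,
        ks=ks,
        median_accuracies=medians,
        optimum_k=optimum_k,
        optimum_fraction=optimum_k / total,
    )


def accuracy_correlations(
    per_sample_accuracy: pd.Series,
    categories: pd.Series,
    depths: pd.Series,
) -> dict[str, tuple[float, float]]:
    """Spearman rank correlation of per-sample accuracy with oxygen
    category and with depth (ties mid-ranked, asymptotic p).

    A constant input yields an undefined correlation, reported as
    (nan, nan).
    """
    acc = per_sample_accuracy.dropna()
    if len(acc) < 4:
        raise ValueError("need at least 4 samples with accuracy values")
    out = {}
    for name, covariate in (("category", categories), ("depth", depths)):
        cov = covariate.reindex(acc.index)
        if acc.nunique() < 2 or cov.nunique() < 2:
            out[name] = (float("nan"), float("nan"))
            continue
        rho, p = spearmanr(acc.to_numpy(), cov.to_numpy(dtype=float))
        out[name] = (float(rho), float(p))
    return out
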