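"""Repeated-split evaluation harness: Gini ranking, forward selection,
randomized-tree classification and ROC summary statistics.

The evaluation protocol mirrors a small-cohort radiomics study design:

1. draw a stratified train/test split (default: 15 benign + 16 malignant
   lesions for training out of a 31 + 32 cohort, the rest for testing);
2. rank all descriptor variables by mean Gini-impurity importance from a
   random forest fitted on the training fold;
3. forward-step selection: evaluate nested prefixes of the ranking
   (sizes 1..K) and keep the prefix with the highest selection AUC;
4. fit the final forest (default 2000 trees, sqrt(n_features) candidate
   variables per split) on the selected subset and score the test fold;
5. summarize AUC / accuracy / sensitivity / specificity over the repeated
   splits (default 100 unique iterations).

Two selection-scoring modes are provided because small-cohort protocols
differ in where step 3's AUC comes from: ``"leakage-safe"`` (default)
scores prefixes by out-of-bag AUC on the training fold only, while
``"test-scored"`` scores prefixes directly on the test fold.  The second
mode leaks the test labels into model selection and optimistically biases
the reported AUC; it is included for protocol comparison, clearly flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "EnsembleParams",
    "SplitPlan",
    "EvalResult",
    "auc_ranksum",
    "gini_rank",
    "forward_select",
    "fit_predict",
    "evaluate_scheme",
]


@dataclass(frozen=True)
class EnsembleParams:
    """Random-forest hyperparameters used for ranking, selection and the
    final fit.  ``max_features="sqrt"`` realizes the sqrt(n_features)
    candidate-variable rule."""

    n_trees: int = 2000
    max_features: str | int | float = "sqrt"
    max_subset_size: int = 30
    mode: str = "leakage-safe"  # or "test-scored"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mode not in ("leakage-safe", "test-scored"):
            raise ValueError(f"unknown selection-scoring mode {self.mode!r}")


def _forest(params: EnsembleParams, seed: int, oob: bool = False) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=params.max_features,
        criterion="gini",
        oob_score=oob,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def auc_ranksum(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by the rank-sum (Mann-Whitney) statistic.

    Equivalent to trapezoidal integration of the ROC curve; ties in the
    scores receive average ranks.
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class SplitPlan:
    """Repeated stratified train/test splits with distinct index sets.

    ``splits[k]`` is a (train_idx, test_idx) pair; every train fold holds
    ``n_train_benign`` class-0 and ``n_train_malignant`` class-1 lesions.
    """

    n_iterations: int
    n_train_benign: int
    n_train_malignant: int
    seed: int
    splits: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]

    @classmethod
    def generate(
        cls,
        labels: Sequence[int],
        n_iterations: int = 100,
        n_train_benign: int = 15,
        n_train_malignant: int = 16,
        seed: int = 0,
    ) -> "SplitPlan":
        labels = np.asarray(labels).astype(int)
        benign = np.flatnonzero(labels == 0)
        malignant = np.flatnonzero(labels == 1)
        if len(benign) <= n_train_benign or len(malignant) <= n_train_malignant:
            raise ValueError("cohort too small for the requested split plan")
        from math import comb

        n_possible = comb(len(benign), n_train_benign) * comb(
            len(malignant), n_train_malignant
        )
        if n_possible < n_iterations:
            raise ValueError("fewer distinct stratified splits than iterations")
        rng = np.random.default_rng(seed)
        seen: set[frozenset[int]] = set()
        splits = []
        while len(splits) < n_iterations:
            tb = rng.choice(benign, size=n_train_benign, replace=False)
            tm = rng.choice(malignant, size=n_train_malignant, replace=False)
            train = frozenset(map(int, np.concatenate([tb, tm])))
            if train in seen:
                continue
            seen.add(train)
            train_idx = tuple(sorted(train))
            test_idx = tuple(i for i in range(len(labels)) if i not in train)
            splits.append((train_idx, test_idx))
        return cls(
            n_iterations=n_iterations,
            n_train_benign=n_train_benign,
            n_train_malignant=n_train_malignant,
            seed=seed,
            splits=tuple(splits),
        )


@dataclass(frozen=True)
class EvalResult:
    """Per-iteration and aggregate metrics over the repeated splits."""

    auc: np.ndarray
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    selected_features: tuple[tuple[int, ...], ...]

    @property
    def mean_auc(self) -> float:
        return float(self.auc.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.auc.std(ddof=1)) if len(self.auc) > 1 else 0.0

    def summary(self) -> dict[str, float]:
        return {
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_accuracy": float(self.accuracy.mean()),
            "mean_sensitivity": float(self.sensitivity.mean()),
            "mean_specificity": float(self.specificity.mean()),
            "n_iterations": len(self.auc),
        }


def gini_rank(
    features: np.ndarray,
    labels: np.ndarray,
    params: EnsembleParams = EnsembleParams(),
    seed: int = 0,
) -> np.ndarray:
    """Feature indices ordered by decreasing mean Gini-impurity importance
    from a fitted random forest; ties broken by original index."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ranking requires both classes")
    forest = _forest(params, seed)
    forest.fit(features, labels)
    imp = forest.feature_importances_
    # stable sort on negated importance => ties keep original index order
    return np.argsort(-imp, kind="stable")


def fit_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    params: EnsembleParams = EnsembleParams(),
    seed: int = 0,
) -> np.ndarray:
    """Class-1 vote fraction for each test lesion from a random forest."""
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.asarray(test_x, dtype=float)
    if train_x.shape[1] != test_x.shape[1]:
        raise ValueError("train and test feature counts differ")
    if len(np.unique(train_y)) < 2:
        raise ValueError("training fold must contain both classes")
    forest = _forest(params, seed)
    forest.fit(train_x, np.asarray(train_y).astype(int))
    return forest.predict_proba(test_x)[:, 1]


def _oob_auc(
    x: np.ndarray, y: np.ndarray, params: EnsembleParams, seed: int
) -> float:
    forest = _forest(params, seed, oob=True)
    forest.fit(x, y)
    oob = forest.oob_decision_function_[:, 1]
    # lesions never out-of-bag get a neutral score
    oob = np.where(np.isnan(oob), 0.5, oob)
    return auc_ranksum(y, oob)


def forward_select(
    train_x: np.ndarray,
    train_y: np.ndarray,
    ranking: np.ndarray,
    params: EnsembleParams = EnsembleParams(),
    seed: int = 0,
    test_x: np.ndarray | None = None,
    test_y: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Evaluate nested prefixes of the ranking and return the best subset.

    Prefix sizes 1..min(K, n_features) are scored either by out-of-bag AUC
    on the training fold (``leakage-safe``) or, when ``mode ==
    "test-scored"`` and a test fold is supplied, by test AUC.  The first
    prefix attaining the maximum wins ties.
    """
    ranking = np.asarray(ranking, dtype=int)
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    train_y = np.asarray(train_y).astype(int)
    kmax = min(params.max_subset_size, len(ranking))
    best_score, best_k = -np.inf, 1
    for k in range(1, kmax + 1):
        cols = ranking[:k]
        if params.mode == "test-scored":
            if test_x is None or test_y is None:
                raise ValueError("test-scored mode needs the test fold")
            scores = fit_predict(
                train_x[:, cols], train_y, np.asarray(test_x)[:, cols], params, seed
            )
            s = auc_ranksum(test_y, scores)
        else:
            s = _oob_auc(train_x[:, cols], train_y, params, seed)
        if s > best_score:
            best_score, best_k = s, k
    return ranking[:best_k], float(best_score)


def evaluate_scheme(
    features: np.ndarray,
    labels: np.ndarray,
    plan: SplitPlan,
    params: EnsembleParams = EnsembleParams(),
) -> EvalResult:
    """Run the full harness over every split of the plan.

    Per iteration: rank on the training fold, forward-select, fit the
    final ensemble on the selected subset, score the test fold, and record
    rank-sum AUC plus accuracy / sensitivity / specificity at the 0.5
    vote-fraction threshold.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    if features.shape[0] != len(labels):
        raise ValueError("feature table and labels disagree on cohort size")
    if not np.isfinite(features).all():
        raise ValueError("feature table contains non-finite values")
    seed_rng = np.random.default_rng(plan.seed)
    iter_seeds = seed_rng.integers(0, 2**31 - 1, size=plan.n_iterations)

    aucs, accs, sens, specs, chosen = [], [], [], [], []
    for (train_idx, test_idx), it_seed in zip(plan.splits, iter_seeds):
        tr = np.asarray(train_idx)
        te = np.asarray(test_idx)
        it_seed = int(it_seed)
        ranking = gini_rank(features[tr], labels[tr], params, seed=it_seed)
        subset, _ = forward_select(
            features[tr],
            labels[tr],
            ranking,
            params,
            seed=it_seed,
            test_x=features[te] if params.mode == "test-scored" else None,
            test_y=labels[te] if params.mode == "test-scored" else None,
        )
        scores = fit_predict(
            features[tr][:, subset], labels[tr], features[te][:, subset],
            params, seed=it_seed,
        )
        y = labels[te]
        pred = (scores >= 0.5).astype(int)
        aucs.append(auc_ranksum(y, scores))
        accs.append(float((pred == y).mean()))
        pos, neg = y == 1, y == 0
        sens.append(float((pred[pos] == 1).mean()) if pos.any() else np.nan)
        specs.append(float((pred[neg] == 0).mean()) if neg.any() else np.nan)
        chosen.append(tuple(int(c) for c in subset))
    return EvalResult(
        auc=np.array(aucs),
        accuracy=np.array(accs),
        sensitivity=np.array(sens),
        specificity=np.array(specs),
        selected_features=tuple(chosen),
    )
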