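"""Skewness-controlled, SVR-validated wrapper feature selection.

Candidate features are screened by Pearson's second skewness
coefficient,

    Skew = 3 * (mean - median) / s,

computed on the vector of per-column means of the fused matrix (sample
standard deviation, n-1 denominator).  A column is a candidate iff its
mean clears the Skew value.  The candidate set is then validated by a
fitness function: an epsilon-insensitive support-vector regressor with a
radial-basis kernel is fit on a seeded stratified 70:30 split of the
candidate columns, its real-valued predictions are rounded to the
nearest class code, and held-out accuracy is the fitness.  While the
fitness falls short of the target (default 90%) and iterations remain
(default 5), the threshold is relaxed multiplicatively so the candidate
set can only grow, and fitness is re-evaluated.  The best candidate set
seen is returned with the full fitness trace.

Interpretation notes (the source procedure leaves these open): accuracy
from a regressor requires discretization — nearest-integer rounding with
clipping to the label range is used; "updating" the selection on a
failed iteration is realized as threshold relaxation (default factor
0.8, applied toward minus infinity so the candidate set is monotonically
non-shrinking); SVR hyperparameters default to C=1, epsilon=0.1 and a
kernel width set by the median pairwise distance heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import train_test_split
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted, check_X_y

from .matrix import FeatureMatrix

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "pearson_skewness",
    "skew_threshold",
    "svr_fitness",
    "select_features",
    "SkewnessSVRSelector",
]


@dataclass
class SelectionConfig:
    """Knobs of the selection loop; defaults follow the reference recipe."""

    target_accuracy: float = 0.90
    max_iterations: int = 5
    C: float = 1.0
    epsilon: float = 0.1
    gamma: float | None = None  # None -> median pairwise distance heuristic
    relaxation: float = 0.8
    split_ratio: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_accuracy <= 1:
            raise ValueError("target_accuracy must lie in [0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.C <= 0 or self.epsilon < 0:
            raise ValueError("require C > 0 and epsilon >= 0")
        if not 0 < self.relaxation < 1:
            raise ValueError("relaxation must lie in (0, 1)")


@dataclass
class SelectionResult:
    """Outcome of the selection loop."""

    selected_idx: np.ndarray
    skew: float
    iterations_run: int
    fitness_trace: list[float] = field(default_factory=list)
    converged: bool = False


def pearson_skewness(values: np.ndarray) -> float:
    """Pearson's second skewness coefficient, 3(mean - median)/SD."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least two values")
    s = float(np.std(values, ddof=1))
    if s == 0:
        raise ValueError("degenerate distribution: zero standard deviation")
    return float(3.0 * (values.mean() - np.median(values)) / s)


def skew_threshold(fm: FeatureMatrix) -> tuple[np.ndarray, float]:
    """Candidate columns: those whose per-column mean clears the Skew value."""
    if fm.n_features == 0 or fm.n_samples == 0:
        raise ValueError("skew threshold needs a non-empty matrix")
    means = fm.values.mean(axis=0)
    try:
        skew = pearson_skewness(means)
    except ValueError:
        warnings.warn(
            "all column means equal; selecting every column", stacklevel=2
        )
        return np.arange(fm.n_features), 0.0
    return np.nonzero(means >= skew)[0], skew


def _median_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    """RBF width from the median pairwise Euclidean distance, gamma=1/(2 rho^2)."""
    n = X.shape[0]
    sub = X if n <= 200 else X[rng.choice(n, 200, replace=False)]
    d = pairwise_distances(sub)
    rho = float(np.median(d[np.triu_indices_from(d, k=1)]))
    if rho <= 0:
        return 1.0 / max(X.shape[1], 1)
    return 1.0 / (2.0 * rho**2)


def svr_fitness(
    X: np.ndarray, labels: np.ndarray, cfg: SelectionConfig | None = None
) -> float:
    """Held-out accuracy of an RBF-kernel SVR with rounded predictions.

    Labels are encoded as consecutive integer codes; the regressor is fit
    on a seeded stratified split and its predictions on the held-out part
    are rounded to the nearest code (clipped to the code range).
    """
    cfg = cfg or SelectionConfig()
    X, labels = check_X_y(X, labels, ensure_min_features=1)
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("fitness needs at least two classes")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        train_size=cfg.split_ratio,
        stratify=y,
        random_state=cfg.seed % (2**32),
    )
    rng = np.random.default_rng(cfg.seed)
    gamma = cfg.gamma if cfg.gamma is not None else _median_gamma(X_tr, rng)
    model = SVR(kernel="rbf", C=cfg.C, epsilon=cfg.epsilon, gamma=gamma)
    model.fit(X_tr, y_tr.astype(float))
    pred = np.clip(np.rint(model.predict(X_te)), 0, classes.size - 1)
    return float(np.mean(pred == y_te))


class SkewnessSVRSelector(BaseEstimator, TransformerMixin):
    """scikit-learn transformer wrapping the full selection loop.

    Fitted attributes: ``selected_idx_``, ``skew_``, ``iterations_run_``,
    ``fitness_trace_``, ``converged_``.
    """

    def __init__(
        self,
        target_accuracy: float = 0.90,
        max_iterations: int = 5,
        C: float = 1.0,
        epsilon: float = 0.1,
        gamma: float | None = None,
        relaxation: float = 0.8,
        seed: int = 0,
        n_features_cap: int | None = None,
    ):
        self.target_accuracy = target_accuracy
        self.max_iterations = max_iterations
        self.C = C
        self.epsilon = epsilon
        self.gamma = gamma
        self.relaxation = relaxation
        self.seed = seed
        self.n_features_cap = n_features_cap

    def _config(self) -> SelectionConfig:
        return SelectionConfig(
            target_accuracy=self.target_accuracy,
            max_iterations=self.max_iterations,
            C=self.C,
            epsilon=self.epsilon,
            gamma=self.gamma,
            relaxation=self.relaxation,
            seed=self.seed,
        )

    def fit(self, X, y):
        cfg = self._config()
        X, y = check_X_y(X, y, ensure_min_features=1)
        means = X.mean(axis=0)
        fm = FeatureMatrix(X, y, column_ids=[f"c{j}" for j in range(X.shape[1])])
        candidates, skew = skew_threshold(fm)
        self.skew_ = skew
        threshold = skew
        trace: list[float] = []
        best_idx, best_fit = candidates, -np.inf
        converged = False
        iterations = 0
        for _ in range(cfg.max_iterations):
            iterations += 1
            if candidates.size == 0:
                fit = 0.0
            else:
                fit = svr_fitness(X[:, candidates], y, cfg)
            trace.append(fit)
            if fit > best_fit:
                best_fit, best_idx = fit, candidates
            if fit >= cfg.target_accuracy:
                converged = True
                break
            # relax toward -inf so the candidate set can only grow
            threshold = (
                threshold * cfg.relaxation
                if threshold >= 0
                else threshold / cfg.relaxation
            )
            candidates = np.nonzero(means >= threshold)[0]
        if self.n_features_cap is not None and best_idx.size > self.n_features_cap:
            order = np.argsort(means[best_idx])[::-1][: self.n_features_cap]
            best_idx = np.sort(best_idx[order])
        self.selected_idx_ = best_idx
        self.fitness_trace_ = trace
        self.iterations_run_ = iterations
        self.converged_ = converged
        self.final_fitness_ = best_fit if np.isfinite(best_fit) else 0.0
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_idx_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("transform width differs from fit width")
        return X[:, self.selected_idx_]


def select_features(
    fm: FeatureMatrix, labels=None, cfg: SelectionConfig | None = None
) -> SelectionResult:
    """Run the selection loop on a feature matrix; labels default to fm's."""
    cfg = cfg or SelectionConfig()
    y = fm.labels if labels is None else np.asarray(labels)
    sel = SkewnessSVRSelector(
        target_accuracy=cfg.target_accuracy,
        max_iterations=cfg.max_iterations,
        C=cfg.C,
        epsilon=cfg.epsilon,
        gamma=cfg.gamma,
        relaxation=cfg.relaxation,
        seed=cfg.seed,
    ).fit(fm.values, y)
    return SelectionResult(
        selected_idx=sel.selected_idx_,
        skew=sel.skew_,
        iterations_run=sel.iterations_run_,
        fitness_trace=sel.fitness_trace_,
        converged=sel.converged_,
    )
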