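"""Dependence tests between demographic attributes and image labels.

Two complementary tests:

* Pearson chi-square on the (group x label-state) contingency table.
* A permutation test on the in-sample AUC of a logistic regression that
  predicts the label from one-hot demographic features.  The label vector is
  shuffled (100,000 times by default), the model is refitted on every
  permutation, and the p-value uses the add-one (Phipson-Smyth) correction
  ``p = (1 + #{AUC_perm >= AUC_obs}) / (1 + n_permutations)`` so it can never
  be exactly zero.

Because the features are categorical, every sample collapses onto one of a
handful of one-hot patterns.  Fitting therefore runs on grouped sufficient
statistics (pattern counts and per-pattern positives) via Newton/IRLS, which
makes refit-per-permutation cheap enough for 1e5 shuffles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PermutationConfig",
    "ContingencyTable",
    "contingency_table",
    "chi_square_test",
    "LinearLogOdds",
    "fit_linear_logodds",
    "permutation_auc_test",
]


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 100_000
    alpha: float = 0.001
    seed: int = 2021

    def validate(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ContingencyTable:
    counts: np.ndarray                  # (groups, label states) non-negative ints
    row_names: tuple = ()
    col_names: tuple = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("contingency counts must be a 2D matrix")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = np.round(self.counts).astype(np.int64)

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def contingency_table(groups, labels) -> ContingencyTable:
    """Cross-tabulate a categorical group vector against a binary label vector."""
    groups = np.asarray(groups)
    labels = np.asarray(labels).astype(int)
    gs = np.unique(groups)
    counts = np.array([
        [int(np.sum((groups == g) & (labels == s))) for s in (0, 1)] for g in gs
    ])
    return ContingencyTable(counts, row_names=tuple(gs), col_names=(0, 1))


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence -> (statistic, dof, p-value)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    counts = ContingencyTable(counts).counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty contingency table")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ValueError(
            "zero expected count in the contingency table; merge sparse categories "
            "before testing"
        )
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


# ---------------------------------------------------------------------------
# grouped logistic regression
# ---------------------------------------------------------------------------

def _group_patterns(features: np.ndarray):
    """Collapse rows of a one-hot design onto unique patterns.

    Returns (U, pattern_index) where U is (P, K) unique rows and
    pattern_index maps each sample to its row of U.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a 2D (n_samples, n_features) array")
    U, inv = np.unique(features, axis=0, return_inverse=True)
    return U, inv.ravel()


def _irls(U1: np.ndarray, k: np.ndarray, n: np.ndarray,
          tol: float = 1e-10, max_iter: int = 100, ridge: float = 1e-9):
    """Newton maximisation of the grouped binomial log-likelihood.

    U1: (P, K+1) design with intercept column; k: positives per pattern;
    n: samples per pattern.  Returns (beta, loglik, converged).
    """
    P, K1 = U1.shape
    beta = np.zeros(K1)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(U1 @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(k * eta - n * np.log1p(np.exp(eta))))
        grad = U1.T @ (k - n * mu)
        w = n * mu * (1.0 - mu)
        H = (U1 * w[:, None]).T @ U1 + ridge * np.eye(K1)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    eta = np.clip(U1 @ beta, -30, 30)
    ll = float(np.sum(k * eta - n * np.log1p(np.exp(eta))))
    return beta, ll, converged


class LinearLogOdds:
    """A fitted linear log-odds scorer over one-hot demographic features."""

    def __init__(self, coef: np.ndarray, intercept: float, loglik: float, converged: bool):
        self.coef_ = np.asarray(coef, dtype=float)
        self.intercept_ = float(intercept)
        self.loglik_ = float(loglik)
        self.converged_ = bool(converged)

    def decision_function(self, features) -> np.ndarray:
        F = np.asarray(features, dtype=float)
        return F @ self.coef_ + self.intercept_

    def predict_proba(self, features) -> np.ndarray:
        eta = np.clip(self.decision_function(features), -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_linear_logodds(features, label) -> LinearLogOdds:
    """Maximum-likelihood logistic regression on one-hot categorical features.

    Perfect separation does not raise: the fit stops at the iteration cap and
    returns usable (saturating) scores with a warning.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(label).astype(int).ravel()
    if features.shape[0] != len(y):
        raise ValueError("features and label lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("label must contain both classes")
    U, idx = _group_patterns(features)
    n = np.bincount(idx, minlength=len(U)).astype(float)
    k = np.bincount(idx, weights=y, minlength=len(U))
    U1 = np.column_stack([U, np.ones(len(U))])
    beta, ll, converged = _irls(U1, k, n)
    if not converged or np.max(np.abs(beta)) > 15:
        warnings.warn("logistic fit did not fully converge (possible perfect separation); "
                      "scores are still returned")
    return LinearLogOdds(beta[:-1], beta[-1], ll, converged)


def _grouped_auc(score_per_pattern: np.ndarray, pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC from per-pattern scores with pattern-level positive/negative counts."""
    n1, n0 = pos.sum(), neg.sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    s = score_per_pattern
    gt = (s[:, None] > s[None, :] + 1e-12).astype(float)
    eq = (np.abs(s[:, None] - s[None, :]) <= 1e-12).astype(float)
    wins = pos @ gt @ neg + 0.5 * (pos @ eq @ neg)
    return float(wins / (n1 * n0))


def permutation_auc_test(
    features,
    label,
    config: PermutationConfig = PermutationConfig(),
) -> tuple[float, float]:
    """Permutation test of the logistic model's in-sample AUC.

    The scorer is refitted on every label shuffle; returns
    ``(observed_auc, p_value)`` with the add-one correction.
    """
    config.validate()
    features = np.asarray(features, dtype=float)
    y = np.asarray(label).astype(int).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("label must contain both classes")
    U, idx = _group_patterns(features)
    P = len(U)
    n = np.bincount(idx, minlength=P).astype(float)
    U1 = np.column_stack([U, np.ones(P)])

    def fit_and_auc(yvec) -> float:
        k = np.bincount(idx, weights=yvec, minlength=P)
        beta, _, _ = _irls(U1, k, n)
        eta = U1 @ beta
        return _grouped_auc(eta, k, n - k)

    observed = fit_and_auc(y)
    rng = np.random.default_rng(config.seed)
    count = 0
    for _ in range(config.n_permutations):
        yperm = rng.permutation(y)
        if fit_and_auc(yperm) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (1 + config.n_permutations)
    return float(observed), float(p)
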