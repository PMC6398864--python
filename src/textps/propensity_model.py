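"""L1-penalized logistic propensity model and cross-validated AUC evaluation.

The fit maximizes the penalized binomial log-likelihood

    l(beta, b) - penalty * sum_i |beta_i|

with an unpenalized intercept ``b`` and no feature standardization (features
are binary 0/1). The Laplace-prior hyper-parameter is exposed as ``penalty``
(default 0.01), applied per coefficient against the total (unnormalized)
log-likelihood.

Optimization: scikit-learn's liblinear solver with ``C = 1 / penalty`` and a
large ``intercept_scaling`` (liblinear penalizes the intercept; the scaling
makes that contribution O(penalty / 1e4)), followed by a sign-restricted
L-BFGS-B polish on the liblinear support, which removes the residual
intercept-penalty distortion and leaves the objective at its optimum to
near machine precision. The polish can only decrease the penalized objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .text_featurizer import FeatureMatrix

__all__ = [
    "PropensityModel",
    "CvReport",
    "fit_ps",
    "score",
    "auc",
    "cross_validate",
    "top_covariates",
    "penalized_objective",
]


@dataclass
class PropensityModel:
    covariate_labels: list[str]
    coefficients: np.ndarray
    intercept: float
    penalty: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.covariate_labels),):
            raise ValueError("one coefficient per covariate label required")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "covariate_labels": list(self.covariate_labels),
                    "coefficients": [float(b) for b in self.coefficients],
                    "intercept": float(self.intercept),
                    "penalty": float(self.penalty),
                    "converged": bool(self.converged),
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PropensityModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            list(d["covariate_labels"]),
            np.asarray(d["coefficients"], dtype=float),
            float(d["intercept"]),
            float(d["penalty"]),
            bool(d.get("converged", True)),
        )


@dataclass
class CvReport:
    fold_aucs: list[float]
    seed: int
    mean_auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_auc = float(np.mean(self.fold_aucs))


def penalized_objective(
    X, y: np.ndarray, beta: np.ndarray, intercept: float, penalty: float
) -> float:
    """Negative penalized log-likelihood (the quantity the fit minimizes)."""
    z = np.asarray(X @ beta).ravel() + intercept
    y = np.asarray(y, dtype=float)
    # -sum[ y*log(p) + (1-y)*log(1-p) ] written stably
    nll = float(np.sum(np.logaddexp(0.0, z) - y * z))
    return nll + penalty * float(np.abs(beta).sum())


def fit_ps(
    matrix: FeatureMatrix, treatment: Sequence[bool], penalty: float = 0.01, tol: float = 1e-8
) -> PropensityModel:
    """Fit the L1-penalized propensity model.

    Covariates never seen in the data (all-zero columns) keep a coefficient of
    exactly zero. Non-convergence (e.g. separation with a tiny penalty) is
    flagged on the returned model, not raised.
    """
    if penalty <= 0:
        raise ValueError("penalty must be > 0")
    y = np.asarray(treatment, dtype=int)
    if y.min() == y.max():
        raise ValueError("both treatment classes required")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 episodes of each treatment class")

    X = matrix.values
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / penalty,
        solver="liblinear",
        tol=tol,
        max_iter=10_000,
        fit_intercept=True,
        intercept_scaling=1e4,
        random_state=0,  # liblinear permutes coordinates; pin for determinism
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(X, y)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)

    beta = clf.coef_.ravel().astype(float)
    # all-zero columns are unidentified; pin them to exactly 0
    seen = np.asarray((X != 0).sum(axis=0)).ravel() > 0
    beta[~seen] = 0.0
    beta, intercept = _polish(X, y, beta, float(clf.intercept_[0]), penalty)
    return PropensityModel(
        list(matrix.covariate_labels),
        beta,
        intercept,
        penalty,
        converged,
    )


def _polish(
    X, y: np.ndarray, beta: np.ndarray, intercept: float, penalty: float
) -> tuple[np.ndarray, float]:
    """Minimize the penalized objective with signs fixed to liblinear's support.

    On the orthant ``sign(beta_i)`` (zeros pinned at 0) the L1 term is linear,
    so the problem is smooth and L-BFGS-B solves it to high precision; the
    result never has a worse penalized objective than the starting point.
    """
    signs = np.sign(beta)
    free = signs != 0
    yv = np.asarray(y, dtype=float)
    Xf = X[:, np.flatnonzero(free)]
    sf = signs[free]

    def fun(params: np.ndarray) -> tuple[float, np.ndarray]:
        b = params[:-1]
        c = params[-1]
        z = np.asarray(Xf @ b).ravel() + c
        nll = float(np.sum(np.logaddexp(0.0, z) - yv * z))
        f = nll + penalty * float(np.dot(sf, b))
        p = 1.0 / (1.0 + np.exp(-z))
        resid = p - yv
        grad_b = np.asarray(Xf.T @ resid).ravel() + penalty * sf
        grad_c = float(resid.sum())
        return f, np.append(grad_b, grad_c)

    bounds = [(0.0, None) if s > 0 else (None, 0.0) for s in sf] + [(None, None)]
    x0 = np.append(beta[free], intercept)
    from scipy.optimize import minimize

    res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 10_000, "ftol": 1e-14, "gtol": 1e-10})
    start_obj = penalized_objective(X, yv, beta, intercept, penalty)
    out_beta = beta.copy()
    out_beta[free] = res.x[:-1]
    end_obj = penalized_objective(X, yv, out_beta, float(res.x[-1]), penalty)
    if end_obj <= start_obj:
        return out_beta, float(res.x[-1])
    return beta, intercept


def score(model: PropensityModel, matrix: FeatureMatrix) -> np.ndarray:
    """Propensity score per episode, in (0, 1).

    Model covariates absent from the matrix contribute zero (the zero-fill
    rule); matrix columns unknown to the model are ignored.
    """
    col_of = {}
    for j, lab in enumerate(matrix.covariate_labels):
        if lab in col_of:
            raise ValueError(f"duplicate covariate label {lab!r}")
        col_of[lab] = j
    z = np.full(matrix.shape[0], model.intercept, dtype=float)
    cols = []
    coefs = []
    for b, lab in zip(model.coefficients, model.covariate_labels):
        j = col_of.get(lab)
        if j is not None and b != 0.0:
            cols.append(j)
            coefs.append(b)
    if cols:
        z += np.asarray(matrix.values[:, cols] @ np.asarray(coefs)).ravel()
    return 1.0 / (1.0 + np.exp(-z))


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Mann-Whitney concordance: P(score_pos > score_neg) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = rankdata(s, method="average")
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def cross_validate(
    matrix: FeatureMatrix,
    treatment: Sequence[bool],
    k: int = 3,
    seed: int = 0,
    penalty: float = 0.01,
    tol: float = 1e-8,
    max_retries: int = 100,
) -> CvReport:
    """Seeded random k-fold split; per-fold held-out AUC and their mean.

    Folds are a simple random partition into near-equal parts (unstratified).
    A partition leaving any fold without both classes is redrawn, up to
    ``max_retries`` times.
    """
    y = np.asarray(treatment, dtype=bool)
    n = y.shape[0]
    if n < k:
        raise ValueError("need at least k episodes")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        if all(0 < y[f].sum() < len(f) for f in folds):
            break
    else:
        raise ValueError("could not draw a partition with both classes in every fold")

    fold_aucs = []
    for f in folds:
        train = np.setdiff1d(np.arange(n), f)
        train_matrix = FeatureMatrix(
            [matrix.episode_ids[i] for i in train],
            matrix.covariate_labels,
            matrix.values[train].tocsr(),
            matrix.lookback_days,
            matrix.binary,
        )
        model = fit_ps(train_matrix, y[train], penalty=penalty, tol=tol)
        test_matrix = FeatureMatrix(
            [matrix.episode_ids[i] for i in f],
            matrix.covariate_labels,
            matrix.values[f].tocsr(),
            matrix.lookback_days,
            matrix.binary,
        )
        fold_aucs.append(auc(score(model, test_matrix), y[f]))
    return CvReport(fold_aucs, seed)


def top_covariates(model: PropensityModel, n: int = 25) -> list[tuple[str, float]]:
    """Covariates ranked by |beta| descending (ties by label); zeros excluded."""
    pairs = [
        (lab, float(b))
        for lab, b in zip(model.covariate_labels, model.coefficients)
        if b != 0.0
    ]
    pairs.sort(key=lambda p: (-abs(p[1]), p[0]))
    return pairs[:n]
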