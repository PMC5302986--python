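"""Cross-cohort evaluation of miRNA panels as recurrence classifiers.

A logistic regression model is fit on one patient cohort for a given miRNA
combination (marker panel), then scored on every cohort; prediction
performance is summarized by the area under the ROC curve.  Entries where the
fit and test cohort coincide are flagged as training performance, all others
as independent test performance.  Feature standardization parameters are
learned on the fit cohort only and applied unchanged to test cohorts, since
cohorts profiled in different batches are not assumed to share a scale.

A tiny ridge penalty keeps the maximum-likelihood fit finite on separable
data; it is a numerical guard, not a tuned hyperparameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CohortDataset",
    "LogisticModel",
    "ROCResult",
    "fit_logistic",
    "roc_auc",
    "cross_cohort_matrix",
    "marker_combinations",
]

RIDGE = 1e-6
MAX_ITER = 500
GRAD_TOL = 1e-8


@dataclass
class CohortDataset:
    """One patient cohort: sample x miRNA log2 expression + binary labels."""

    cohort_id: str
    expression: pd.DataFrame  # samples x miRNAs
    labels: pd.Series  # 0 = no recurrence, 1 = recurrence

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.expression.index)
        vals = set(self.labels.unique().tolist())
        if not vals <= {0, 1}:
            raise ValueError(f"cohort {self.cohort_id!r}: labels must be 0/1, got {vals}")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_recurrent(self) -> int:
        return int(self.labels.sum())


@dataclass
class LogisticModel:
    """Fitted logistic classifier with fit-cohort standardization."""

    combo: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    mean: np.ndarray
    scale: np.ndarray
    fit_cohort: str
    converged: bool
    n_iter: int

    def decision_scores(self, expression: pd.DataFrame) -> np.ndarray:
        """Linear predictor (monotone in recurrence probability)."""
        x = expression[list(self.combo)].to_numpy(dtype=float)
        z = (x - self.mean) / self.scale
        return self.intercept + z @ self.coef

    def predict_proba(self, expression: pd.DataFrame) -> np.ndarray:
        return expit(self.decision_scores(expression))


def fit_logistic(
    cohort: CohortDataset,
    combo: list[str] | tuple[str, ...],
    ridge: float = RIDGE,
    max_iter: int = MAX_ITER,
    tol: float = GRAD_TOL,
) -> LogisticModel:
    """Ridge-stabilized maximum-likelihood logistic regression (Newton/IRLS).

    Features are standardized with the fit cohort's mean and standard
    deviation.  Convergence: penalized gradient norm below ``tol`` or
    ``max_iter`` Newton steps (with step halving).
    """
    combo = tuple(combo)
    missing = [m for m in combo if m not in cohort.expression.columns]
    if missing:
        raise KeyError(f"cohort {cohort.cohort_id!r} lacks miRNAs {missing}")
    y = cohort.labels.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"cohort {cohort.cohort_id!r} has a single outcome class")
    x = cohort.expression[list(combo)].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    z = (x - mean) / scale
    design = np.column_stack([np.ones(len(y)), z])
    p_dim = design.shape[1]
    pen = np.full(p_dim, ridge)
    pen[0] = 0.0  # intercept unpenalized
    beta = np.zeros(p_dim)

    def neg_loglik(b: np.ndarray) -> float:
        eta = design @ b
        # log(1 + exp(eta)) - y*eta, numerically stable
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.sum(pen * b * b))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        p = expit(eta)
        grad = design.T @ (p - y) + pen * beta
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-10, None)
        hess = (design * w[:, None]).T @ design + np.diag(pen + 1e-12)
        step = np.linalg.solve(hess, grad)
        f0 = neg_loglik(beta)
        alpha = 1.0
        for _ in range(30):
            candidate = beta - alpha * step
            if neg_loglik(candidate) <= f0:
                break
            alpha *= 0.5
        beta = beta - alpha * step
    return LogisticModel(
        combo=combo,
        coef=beta[1:],
        intercept=float(beta[0]),
        mean=mean,
        scale=scale,
        fit_cohort=cohort.cohort_id,
        converged=converged,
        n_iter=it,
    )


@dataclass
class ROCResult:
    """ROC curve and AUC for one (fit cohort, test cohort, combo) cell."""

    fit_cohort: str
    test_cohort: str
    combo: tuple[str, ...]
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    role: str = "test"  # "training" when fit == test


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """ROC curve by threshold sweep and trapezoid AUC.

    Tied scores are grouped at a single threshold, so the trapezoid AUC
    equals the tie-corrected Mann-Whitney U statistic divided by n1*n0.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both outcome classes present")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # group ties: cumulative counts at the last index of each distinct score
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr


def marker_combinations(markers: list[str], max_size: int = 3) -> list[tuple[str, ...]]:
    """All marker combinations of size 1..max_size, in listed order."""
    combos: list[tuple[str, ...]] = []
    for k in range(1, max_size + 1):
        combos.extend(combinations(markers, k))
    return combos


def cross_cohort_matrix(
    cohorts: list[CohortDataset],
    combos: list[tuple[str, ...]] | list[list[str]],
) -> list[ROCResult]:
    """Fit each combo on each cohort, evaluate on every cohort.

    Returns fits x cohorts x combos ROC results; diagonal entries (fit ==
    test) are flagged as training performance.
    """
    if len(cohorts) < 2:
        raise ValueError("need >= 2 cohorts for cross-cohort evaluation")
    results: list[ROCResult] = []
    for fit_cohort in cohorts:
        for combo in combos:
            model = fit_logistic(fit_cohort, combo)
            for test_cohort in cohorts:
                scores = model.decision_scores(test_cohort.expression)
                auc, fpr, tpr = roc_auc(scores, test_cohort.labels.to_numpy())
                results.append(
                    ROCResult(
                        fit_cohort=fit_cohort.cohort_id,
                        test_cohort=test_cohort.cohort_id,
                        combo=tuple(combo),
                        auc=auc,
                        fpr=fpr,
                        tpr=tpr,
                        role="training" if fit_cohort.cohort_id == test_cohort.cohort_id else "test",
                    )
                )
    return results


def roc_results_table(results: list[ROCResult]) -> pd.DataFrame:
    """Flatten ROC results into a (fit_cohort, test_cohort, combo, auc, role) table."""
    return pd.DataFrame(
        {
            "fit_cohort": [r.fit_cohort for r in results],
            "test_cohort": [r.test_cohort for r in results],
            "combo": ["+".join(r.combo) for r in results],
            "auc": [r.auc for r in results],
            "role": [r.role for r in results],
        }
    )
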