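"""Multiple imputation by chained equations (simplified) with Rubin pooling.

Each incomplete column gets a conditional model on all other columns plus any
auxiliary predictors: Bayesian linear regression with posterior-predictive
noise for continuous columns, logistic regression with parameter draws for
binary columns, and rounded-clipped linear draws for ordinal columns (a
documented simplification of a full ordinal model).  Cycling these
conditionals for a few iterations per completed dataset removes
missing-at-random bias that complete-case analysis retains.

Pooling across the m completed datasets follows Rubin's rules: the pooled
estimate is the mean, and the total variance is W + (1 + 1/m)·B with W the
mean within-imputation variance and B the between-imputation variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["ImputationSet", "mice", "pool_rubin"]


@dataclass
class ImputationSet:
    m: int
    completed: list[pd.DataFrame]
    iterations: int
    seed: int

    def __iter__(self):
        return iter(self.completed)


def _column_kind(col: pd.Series) -> str:
    vals = pd.unique(col.dropna())
    if set(vals) <= {0, 1, 0.0, 1.0}:
        return "binary"
    if np.all(vals == np.floor(vals)) and len(vals) <= 10:
        return "ordinal"
    return "continuous"


def _bayes_linear_draw(X: np.ndarray, y: np.ndarray, Xmis: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = resid @ resid / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(XtX)
    beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return Xmis @ beta + rng.normal(0, np.sqrt(sigma2), len(Xmis))


def _logistic_draw(X: np.ndarray, y: np.ndarray, Xmis: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    import statsmodels.api as sm
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
        beta = rng.multivariate_normal(np.asarray(res.params),
                                       np.asarray(res.cov_params()),
                                       method="cholesky")
    except Exception:  # separation etc.: fall back to the observed rate
        p = np.full(len(Xmis), y.mean())
        return (rng.random(len(Xmis)) < p).astype(float)
    p = expit(Xmis @ beta)
    return (rng.random(len(Xmis)) < p).astype(float)


def mice(cohort: pd.DataFrame, m: int = 10, iterations: int = 5,
         seed: int = 0, auxiliary_columns: tuple[str, ...] = ()
         ) -> ImputationSet:
    """Generate m completed datasets by chained conditional draws.

    Columns without missing cells act only as predictors; auxiliary columns
    are always included as predictors for every imputation model.  Observed
    cells are never altered.
    """
    numeric = cohort.select_dtypes(include=[np.number])
    incomplete = [c for c in numeric.columns if cohort[c].isna().any()]
    for col in incomplete:
        if cohort[col].isna().all():
            raise ValueError(f"column {col!r} is entirely missing; "
                             "its imputation model is inestimable")
    predictors_base = [c for c in numeric.columns
                       if not cohort[c].isna().any() and c != "id"]
    for aux in auxiliary_columns:
        if aux not in cohort.columns:
            raise KeyError(f"auxiliary column {aux!r} not in cohort")
    kinds = {c: _column_kind(cohort[c]) for c in incomplete}
    bounds = {c: (cohort[c].min(), cohort[c].max()) for c in incomplete}

    master = np.random.default_rng(seed)
    completed = []
    for _ in range(m):
        rng = np.random.default_rng(int(master.integers(2**31)))
        work = cohort.copy()
        # initial fill: random draws from the observed values
        for col in incomplete:
            mask = work[col].isna()
            obs = work.loc[~mask, col].to_numpy()
            work.loc[mask, col] = rng.choice(obs, size=int(mask.sum()))
        if not incomplete:
            completed.append(work)
            continue
        for _ in range(iterations):
            for col in incomplete:
                mask = cohort[col].isna().to_numpy()
                preds = [c for c in dict.fromkeys(
                    predictors_base + list(auxiliary_columns) + incomplete)
                    if c != col]
                Xall = np.column_stack(
                    [np.ones(len(work))] +
                    [work[c].to_numpy(dtype=float) for c in preds])
                yobs = work.loc[~mask, col].to_numpy(dtype=float)
                X, Xmis = Xall[~mask], Xall[mask]
                kind = kinds[col]
                if kind == "binary":
                    draw = _logistic_draw(X, yobs, Xmis, rng)
                else:
                    draw = _bayes_linear_draw(X, yobs, Xmis, rng)
                    if kind == "ordinal":
                        lo, hi = bounds[col]
                        draw = np.clip(np.round(draw), lo, hi)
                work.loc[mask, col] = draw
        completed.append(work)
    return ImputationSet(m=m, completed=completed, iterations=iterations,
                         seed=seed)


def pool_rubin(per_dataset_estimates, per_dataset_variances
               ) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Rubin's rules: pooled estimate and total variance W + (1 + 1/m)·B."""
    est = np.asarray(per_dataset_estimates, dtype=float)
    var = np.asarray(per_dataset_variances, dtype=float)
    if est.shape != var.shape:
        raise ValueError("estimate and variance arrays must align")
    m = est.shape[0]
    if m < 1:
        raise ValueError("need at least one imputed dataset")
    pooled = est.mean(axis=0)
    within = var.mean(axis=0)
    between = est.var(axis=0, ddof=1) if m > 1 else np.zeros_like(pooled)
    total = within + (1 + 1 / m) * between
    if np.ndim(pooled) == 0:
        return float(pooled), float(total)
    return pooled, total
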