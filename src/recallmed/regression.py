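"""Regression backends: modified Poisson with robust variance, and OLS.

Relative risks for binary (or count) outcomes come from a log-link Poisson
model whose standard errors are the heteroskedasticity-robust (HC0) sandwich
— the "modified Poisson" approach that yields consistent RRs and valid
inference for binomial data.  Continuous [0, 10] outcomes use ordinary least
squares.  Confidence intervals default to 99%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["ModelSpec", "FitResult", "fit_poisson_rr", "fit_ols",
           "screen_interactions"]


@dataclass(frozen=True)
class ModelSpec:
    """One regression: outcome, exposure term(s), covariates, family."""

    outcome: str
    exposure_terms: tuple[str, ...]
    covariate_terms: tuple[str, ...] = ()
    family: str = "ols"
    ci_level: float = 0.99

    def __post_init__(self) -> None:
        object.__setattr__(self, "exposure_terms", tuple(self.exposure_terms))
        object.__setattr__(self, "covariate_terms", tuple(self.covariate_terms))
        if self.family not in ("ols", "poisson_robust"):
            raise ValueError(f"unknown family {self.family!r}")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        terms = self.exposure_terms + self.covariate_terms
        if self.outcome in terms:
            raise ValueError("outcome must not appear among model terms")
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate model terms")

    @property
    def terms(self) -> tuple[str, ...]:
        return self.exposure_terms + self.covariate_terms

    def to_dict(self) -> dict:
        return {"outcome": self.outcome,
                "exposure_terms": list(self.exposure_terms),
                "covariate_terms": list(self.covariate_terms),
                "family": self.family, "ci_level": self.ci_level}


@dataclass
class FitResult:
    """Coefficients (log-RR scale for poisson_robust, outcome units for OLS)
    with robust standard errors and Wald confidence intervals."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    robust_se: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    p_values: np.ndarray
    n_used: int
    scale_tag: str  # "log_rr" or "linear"
    ci_level: float = 0.99

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.robust_se[self.terms.index(term)])

    def rr(self, term: str) -> float:
        if self.scale_tag != "log_rr":
            raise ValueError("relative risks only defined for log-link fits")
        return float(np.exp(self.coef(term)))

    def ci(self, term: str) -> tuple[float, float]:
        i = self.terms.index(term)
        return float(self.ci_lo[i]), float(self.ci_hi[i])

    def rr_ci(self, term: str) -> tuple[float, float]:
        lo, hi = self.ci(term)
        return float(np.exp(lo)), float(np.exp(hi))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "term": self.terms,
            "estimate": self.coefficients,
            "se": self.robust_se,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "p": self.p_values,
        })
        if self.scale_tag == "log_rr":
            df.insert(2, "rr", np.exp(self.coefficients))
        return df


def _design(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, int]:
    cols = [spec.outcome, *spec.terms]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks columns: {missing}")
    data = cohort[cols].dropna()
    y = data[spec.outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data))] +
                        [data[t].to_numpy(dtype=float) for t in spec.terms])
    return y, X, len(data)


def _wrap(spec: ModelSpec, params: np.ndarray, se: np.ndarray, n: int,
          scale_tag: str) -> FitResult:
    z = stats.norm.ppf(0.5 + spec.ci_level / 2)
    pvals = 2 * stats.norm.sf(np.abs(params / se))
    return FitResult(
        terms=("const", *spec.terms),
        coefficients=params, robust_se=se,
        ci_lo=params - z * se, ci_hi=params + z * se,
        p_values=pvals, n_used=n, scale_tag=scale_tag, ci_level=spec.ci_level)


def fit_poisson_rr(cohort: pd.DataFrame, spec: ModelSpec,
                   max_iter: int = 100, tol: float = 1e-8) -> FitResult:
    """Log-link Poisson fit with HC0 sandwich standard errors.

    Exponentiated coefficients are relative risks when the outcome is binary
    (or rate ratios for the 0/1/2 abuse-frequency count).
    """
    y, X, n = _design(cohort, spec)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("poisson_robust requires a non-negative integer outcome")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=max_iter, tol=tol, cov_type="HC0")
    if not res.converged:
        raise RuntimeError(
            f"Poisson fit did not converge in {max_iter} iterations "
            f"(last deviance {res.deviance:.6g})")
    mu = res.fittedvalues
    if np.any(mu > 1 - 1e-6) and set(np.unique(y)) <= {0.0, 1.0}:
        import warnings
        warnings.warn("fitted risks approach 1; RR interpretation unstable",
                      stacklevel=2)
    return _wrap(spec, np.asarray(res.params), np.asarray(res.bse), n, "log_rr")


def fit_ols(cohort: pd.DataFrame, spec: ModelSpec,
            robust: bool = False) -> FitResult:
    """Ordinary least squares; conventional SEs by default, HC0 on request
    (reported intervals normally come from the bootstrap instead)."""
    y, X, n = _design(cohort, spec)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear columns for the error message
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [("const", *spec.terms)[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    res = sm.OLS(y, X).fit(cov_type="HC0" if robust else "nonrobust")
    return _wrap(spec, np.asarray(res.params), np.asarray(res.bse), n, "linear")


def _is_binary(col: pd.Series) -> bool:
    vals = set(pd.unique(col.dropna()))
    return vals <= {0, 1, 0.0, 1.0}


def screen_interactions(cohort: pd.DataFrame, outcome: str,
                        variable_pairs: list[tuple[str, str]],
                        alpha: float = 0.05,
                        covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """Wald tests of pairwise multiplicative interaction.

    For each (a, b) pair, fits main effects plus the product term in the
    family matching the outcome type (modified Poisson for binary, OLS
    otherwise) and reports the product-term estimate and p-value, flagging
    pairs with p < alpha.  Difference-method mediation assumes no
    exposure–mediator and no mediator–mediator multiplicative interaction;
    this screen is how that assumption is checked.
    """
    rows = []
    family = "poisson_robust" if _is_binary(cohort[outcome]) else "ols"
    for a, b in variable_pairs:
        prod_col = f"__{a}_x_{b}"
        work = cohort.copy()
        work[prod_col] = work[a] * work[b]
        spec = ModelSpec(outcome=outcome, exposure_terms=(a, b, prod_col),
                         covariate_terms=tuple(covariates), family=family)
        fit = (fit_poisson_rr if family == "poisson_robust" else fit_ols)(work, spec)
        est, p = fit.coef(prod_col), float(fit.p_values[fit.terms.index(prod_col)])
        rows.append({"var_a": a, "var_b": b, "interaction_estimate": est,
                     "p": p, "flagged": p < alpha})
    return pd.DataFrame(rows, columns=["var_a", "var_b",
                                       "interaction_estimate", "p", "flagged"])
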