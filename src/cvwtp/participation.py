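"""First-stage participation model: binary logit on the yes/no answer.

Fits P(yes) = logistic(β0 + Xβ) by maximum likelihood, and reports the
quantities conventionally printed for contingent-valuation participation
models: odds ratios with Wald intervals, marginal effects at covariate
means (discrete change for binary covariates), Nagelkerke pseudo-R²,
−2·log-likelihood, small-sample AICc and the percent of correct
classifications at the 0.5 cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

_GRADIENT_TOL = 1e-8


class SeparationError(RuntimeError):
    """Complete separation: the likelihood has no finite maximizer."""


class DegenerateOutcomeError(ValueError):
    """Only one outcome class present — the logit is not estimable."""


@dataclass(frozen=True)
class LogitFit:
    """Maximum-likelihood logit fit. ``coefficients`` carries the
    intercept under ``const`` followed by one entry per covariate;
    ``vcov`` is the observed-information inverse."""

    coefficients: pd.Series
    vcov: pd.DataFrame
    loglik: float
    n: int
    converged: bool
    iterations: int

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.coefficients.index)

    @property
    def p_values(self) -> pd.Series:
        from scipy.stats import norm

        z = self.coefficients / self.se
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.coefficients.index)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        design = _design(X)
        return expit(design.to_numpy() @ self.coefficients.reindex(design.columns).to_numpy())


@dataclass(frozen=True)
class LogitReport:
    odds_ratios: pd.DataFrame
    marginal_effects: pd.Series
    p_values: pd.Series
    nagelkerke_r2: float
    neg2loglik: float
    aicc: float
    percent_correct: float


def _design(X: pd.DataFrame) -> pd.DataFrame:
    design = pd.DataFrame(X).astype(float)
    if "const" not in design.columns:
        design = sm.add_constant(design, has_constant="add")
    return design


def fit_logit(y, X: pd.DataFrame, maxiter: int = 100) -> LogitFit:
    """Fit the Bernoulli-logit MLE by Newton iterations.

    Requires both outcome classes; detects complete separation (either
    via the optimizer or via perfect in-sample prediction with runaway
    coefficients) and raises :class:`SeparationError` naming the most
    suspect covariate.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("both outcome classes must be present")
    design = _design(X)
    if not np.all(np.isfinite(design.to_numpy())):
        raise ValueError("covariates must be finite")

    model = sm.Logit(y, design)
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is re-detected below and raised as an error
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            result = model.fit(method="newton", maxiter=maxiter, tol=1e-12, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"complete separation detected: {exc}") from exc

    params = result.params
    fitted = expit(design.to_numpy() @ params.to_numpy())
    perfect = np.all((fitted > 0.5) == (y > 0.5)) and np.all(
        np.abs(fitted - y) < 1e-6
    )
    slopes = params.drop("const", errors="ignore")
    if perfect or slopes.abs().max() > 50:
        suspect = slopes.abs().idxmax()
        raise SeparationError(
            f"complete separation detected (diverging coefficient on {suspect!r})"
        )

    score = model.score(params.to_numpy())
    converged = bool(result.mle_retvals.get("converged", False)) and (
        np.max(np.abs(score)) < _GRADIENT_TOL
    )
    return LogitFit(
        coefficients=params,
        vcov=pd.DataFrame(result.cov_params(), index=params.index, columns=params.index),
        loglik=float(result.llf),
        n=len(y),
        converged=converged,
        iterations=int(result.mle_retvals.get("iterations", -1)),
    )


def odds_ratios(fit: LogitFit, level: float = 0.95) -> pd.DataFrame:
    """exp(β) per covariate with Wald CI exp(β ± z·SE); intercept excluded."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    coef = fit.coefficients.drop("const", errors="ignore")
    se = fit.se.reindex(coef.index)
    return pd.DataFrame(
        {
            "odds_ratio": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
        }
    )


def _binary_columns(X: pd.DataFrame) -> set[str]:
    out = set()
    for col in X.columns:
        values = set(pd.unique(X[col].dropna()))
        if values <= {0, 1, 0.0, 1.0}:
            out.add(col)
    return out


def marginal_effects(fit: LogitFit, X: pd.DataFrame, kind: str = "at_means") -> pd.Series:
    """Marginal effects on P(yes).

    ``at_means`` (default): continuous covariates get the density rule
    p̄(1−p̄)·β at covariate means; binary covariates get the discrete
    change P(y|x_j=1) − P(y|x_j=0) holding the others at their means.
    ``average`` computes the same quantities per respondent and averages
    (average marginal effects, non-default).
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if kind not in ("at_means", "average"):
        raise ValueError(f"unknown marginal-effects kind {kind!r}")
    frame = pd.DataFrame(X).astype(float)
    coef = fit.coefficients
    binary = _binary_columns(frame)
    design = _design(frame)
    beta = coef.reindex(design.columns).to_numpy()

    def effects_at(point: np.ndarray) -> dict[str, float]:
        out = {}
        p = float(expit(point @ beta))
        for j, col in enumerate(design.columns):
            if col == "const":
                continue
            if col in binary:
                hi, lo = point.copy(), point.copy()
                hi[j], lo[j] = 1.0, 0.0
                out[col] = float(expit(hi @ beta) - expit(lo @ beta))
            else:
                out[col] = p * (1 - p) * float(coef[col])
        return out

    if kind == "at_means":
        point = design.mean().to_numpy()
        return pd.Series(effects_at(point), name="marginal_effect")
    rows = design.to_numpy()
    acc = pd.DataFrame([effects_at(r) for r in rows])
    return acc.mean().rename("marginal_effect")


def null_loglik(y) -> float:
    """Log-likelihood of the intercept-only (null) logit, in closed form."""
    y = np.asarray(y, dtype=float)
    p = y.mean()
    if p in (0.0, 1.0):
        raise DegenerateOutcomeError("both outcome classes must be present")
    n = len(y)
    return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))


def fit_statistics(fit: LogitFit, y, X: pd.DataFrame) -> LogitReport:
    """Fit summary: Nagelkerke R², −2LogLik, AICc (k counts the
    intercept), percent correct at cutoff 0.5 (p = 0.5 predicts 1),
    plus odds ratios, marginal effects at means and Wald p-values."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = len(fit.coefficients)
    ll0 = null_loglik(y)
    ll1 = fit.loglik
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    nagelkerke = cox_snell / (1.0 - np.exp((2.0 / n) * ll0))
    if n <= k + 1:
        raise ValueError("AICc undefined: n must exceed k + 1")
    aicc = -2 * ll1 + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    predicted = (fit.predict(X) >= 0.5).astype(float)
    percent_correct = 100.0 * float(np.mean(predicted == y))
    return LogitReport(
        odds_ratios=odds_ratios(fit),
        marginal_effects=marginal_effects(fit, X),
        p_values=fit.p_values,
        nagelkerke_r2=float(nagelkerke),
        neg2loglik=float(-2 * ll1),
        aicc=float(aicc),
        percent_correct=percent_correct,
    )
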