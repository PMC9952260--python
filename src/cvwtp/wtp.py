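"""Second-stage willingness-to-pay model for multiple-bounded payment
cards.

The certainty grid is collapsed to yes/no at a chosen certainty
threshold (Welsh–Poe recoding; default scheme treats "definitely yes"
and "probably yes" as yes). The highest accepted and lowest refused
amounts bracket the latent WTP, A^L ≤ WTP < A^U, and the bracketed data
are fitted by interval-censored maximum likelihood under a log-logistic
distribution whose CDF is logistic in log-amount:

    F(A) = 1 / (1 + exp(δX − α·ln A)),   α > 0,

so ln L = Σ_i ln[F(A_i^U) − F(A_i^L)] with F(0) ≡ 0 and F(∞) ≡ 1.
δ is the covariate parameter vector (intercept included) and α, the bid
coefficient, acts as the marginal utility of money. Median WTP at
covariate point x̄ is exp(δx̄/α); the mean is computed either from the
log-logistic closed form exp(δx̄/α)·(π/α)/sin(π/α) (α > 1), by
truncating the survival integral at the top bid, or from a
log-normal-style variant exp(δx̄/α + 1/(2α²)) kept for comparability.
Confidence intervals come from a nonparametric respondent-level
bootstrap, and totals from mean × share of willing payers × households.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_expit
from statsmodels.tools.numdiff import approx_fprime

from .survey_io import BidSchedule, Certainty, DEFAULT_BIDS

_GRADIENT_TOL = 1e-6
_LOGLIK_FLOOR = -700.0  # per-interval floor, ~log of the smallest double


class NonIdentifiableError(ValueError):
    """Every interval is (0, ∞): the likelihood carries no information."""


class ConvergenceError(RuntimeError):
    """The optimizer failed to reach the gradient tolerance."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class MeanUndefinedError(ValueError):
    """Closed-form log-logistic mean diverges for α ≤ 1."""


# --- recoding -------------------------------------------------------------


@dataclass(frozen=True)
class RecodingScheme:
    """Certainty levels mapped to "yes"; must be a downward-closed prefix
    of the certainty order (DY alone, DY+PY, or DY+PY+NS)."""

    name: str
    yes_set: frozenset[Certainty]

    def __post_init__(self) -> None:
        allowed = [
            frozenset({Certainty.DEFINITELY_YES}),
            frozenset({Certainty.DEFINITELY_YES, Certainty.PROBABLY_YES}),
            frozenset(
                {Certainty.DEFINITELY_YES, Certainty.PROBABLY_YES, Certainty.NOT_SURE}
            ),
        ]
        if frozenset(self.yes_set) not in allowed:
            raise ValueError("yes_set must be a prefix of the certainty order")
        object.__setattr__(self, "yes_set", frozenset(self.yes_set))


DEFINITELY_YES_SCHEME = RecodingScheme(
    "definitely_yes", frozenset({Certainty.DEFINITELY_YES})
)
PROBABLY_YES_SCHEME = RecodingScheme(
    "probably_yes", frozenset({Certainty.DEFINITELY_YES, Certainty.PROBABLY_YES})
)
NOT_SURE_SCHEME = RecodingScheme(
    "not_sure",
    frozenset({Certainty.DEFINITELY_YES, Certainty.PROBABLY_YES, Certainty.NOT_SURE}),
)
SCHEMES = {
    s.name: s for s in (DEFINITELY_YES_SCHEME, PROBABLY_YES_SCHEME, NOT_SURE_SCHEME)
}


def recode_certainty(
    grid: Sequence[Certainty | int], scheme: RecodingScheme = PROBABLY_YES_SCHEME
) -> np.ndarray:
    """Collapse a certainty grid to booleans: level ∈ yes_set → yes."""
    out = np.empty(len(grid), dtype=bool)
    for i, level in enumerate(grid):
        try:
            level = Certainty(level)
        except ValueError:
            raise ValueError(f"unknown certainty level {level!r}") from None
        out[i] = level in scheme.yes_set
    return out


# --- interval construction ------------------------------------------------


@dataclass(frozen=True)
class WtpInterval:
    """Bracket A^L ≤ WTP < A^U around a respondent's latent WTP.

    ``lower`` is 0 exactly when no bid was accepted (left-censored);
    ``upper`` is ∞ exactly when no bid above A^L was refused
    (right-censored). ``monotone`` is False when some "yes" occurs at a
    bid above some "no" (internally inconsistent raw responses)."""

    lower: float
    upper: float
    left_censored: bool = False
    right_censored: bool = False
    monotone: bool = True

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"need lower < upper, got [{self.lower}, {self.upper})")
        if self.lower < 0:
            raise ValueError("lower bound must be >= 0")
        if (self.lower == 0) != self.left_censored:
            raise ValueError("lower = 0 iff left_censored")
        if np.isinf(self.upper) != self.right_censored:
            raise ValueError("upper = inf iff right_censored")


def build_interval(binary: Sequence[bool], bids: BidSchedule = DEFAULT_BIDS) -> WtpInterval:
    """Envelope rule: A^L = highest accepted bid (0 if none), A^U =
    lowest refused bid above A^L (∞ if none). Non-monotone raw patterns
    (a refusal below an acceptance) are kept but flagged."""
    answers = np.asarray(binary, dtype=bool)
    if answers.size == 0:
        raise ValueError("empty response grid")
    if answers.size != len(bids):
        raise ValueError("grid length must equal the number of bids")
    amounts = np.asarray(bids.amounts)
    yes_amounts = amounts[answers]
    lower = float(yes_amounts.max()) if yes_amounts.size else 0.0
    refused_above = amounts[(~answers) & (amounts > lower)]
    upper = float(refused_above.min()) if refused_above.size else np.inf
    # non-monotone iff some yes sits above some no
    monotone = True
    if answers.any() and (~answers).any():
        monotone = amounts[answers].max() < amounts[~answers].min()
    return WtpInterval(
        lower=lower,
        upper=upper,
        left_censored=lower == 0.0,
        right_censored=np.isinf(upper),
        monotone=monotone,
    )


def build_intervals(
    grids: Iterable[Sequence[Certainty | int]],
    bids: BidSchedule = DEFAULT_BIDS,
    scheme: RecodingScheme = PROBABLY_YES_SCHEME,
    nonmonotone: str = "keep",
) -> tuple[list[WtpInterval], np.ndarray]:
    """Recode + bracket every grid. ``nonmonotone`` is ``"keep"``
    (default: flag and retain) or ``"drop"``. Returns the intervals and
    a boolean mask of the rows kept (for aligning covariates)."""
    if nonmonotone not in ("keep", "drop"):
        raise ValueError(f"unknown non-monotone policy {nonmonotone!r}")
    intervals, kept = [], []
    for grid in grids:
        interval = build_interval(recode_certainty(grid, scheme), bids)
        if nonmonotone == "drop" and not interval.monotone:
            kept.append(False)
            continue
        kept.append(True)
        intervals.append(interval)
    return intervals, np.asarray(kept, dtype=bool)


# --- likelihood -----------------------------------------------------------


def loglogistic_cdf(amount, delta_x, alpha: float):
    """F(A) = 1/(1 + exp(δX − α ln A)) for A > 0 (limits handled by
    callers: F(0)=0, F(∞)=1)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    amount = np.asarray(amount, dtype=float)
    if np.any(amount <= 0):
        raise ValueError("amount must be strictly positive")
    return expit(alpha * np.log(amount) - np.asarray(delta_x, dtype=float))


def _bounds_arrays(intervals: Sequence[WtpInterval]) -> tuple[np.ndarray, np.ndarray]:
    lower = np.array([iv.lower for iv in intervals], dtype=float)
    upper = np.array([iv.upper for iv in intervals], dtype=float)
    return lower, upper


def _log_prob_mass(eta, alpha, log_lower, log_upper):
    """Per-interval ln[F(A^U) − F(A^L)], computed stably.

    With a = α·lnL − η and b = α·lnU − η (a = −∞ for left-censored,
    b = +∞ for right-censored):
        ln(F(U) − F(L)) = log1p(−e^{a−b}) + log_expit(b) + log_expit(−a).
    """
    a = np.where(np.isneginf(log_lower), -np.inf, alpha * log_lower - eta)
    b = np.where(np.isposinf(log_upper), np.inf, alpha * log_upper - eta)
    out = np.zeros_like(eta)
    finite_b = np.isfinite(b)
    out[finite_b] += log_expit(b[finite_b])
    finite_a = np.isfinite(a)
    out[finite_a] += log_expit(-a[finite_a])
    both = finite_a & finite_b
    with np.errstate(divide="ignore"):
        out[both] += np.log1p(-np.exp(a[both] - b[both]))
    return out, a, b


def interval_loglik(
    delta, alpha: float, intervals: Sequence[WtpInterval], X
) -> float:
    """ln L = Σ_i ln[F(A_i^U) − F(A_i^L)] under the log-logistic model.

    ``X`` is row-aligned with ``intervals`` and must already contain the
    intercept column if δ has one. Vanishing interval masses are floored
    (with a warning) instead of propagating −∞.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    Xmat = np.asarray(pd.DataFrame(X), dtype=float)
    delta = np.asarray(delta, dtype=float)
    if Xmat.shape[0] != len(intervals):
        raise ValueError("X must be row-aligned with intervals")
    lower, upper = _bounds_arrays(intervals)
    with np.errstate(divide="ignore"):
        log_lower = np.log(lower)
    log_upper = np.log(upper)
    eta = Xmat @ delta
    parts, _, _ = _log_prob_mass(eta, alpha, log_lower, log_upper)
    floored = parts < _LOGLIK_FLOOR
    if floored.any():
        warnings.warn(
            f"{int(floored.sum())} interval(s) with vanishing probability mass "
            "floored in the log-likelihood",
            RuntimeWarning,
            stacklevel=2,
        )
        parts = np.maximum(parts, _LOGLIK_FLOOR)
    return float(parts.sum())


def _neg_loglik_and_grad(theta, Xmat, log_lower, log_upper, weights):
    """Negative weighted ln L and its gradient wrt θ = (δ, ln α)."""
    delta, alpha = theta[:-1], np.exp(theta[-1])
    eta = Xmat @ delta
    parts, a, b = _log_prob_mass(eta, alpha, log_lower, log_upper)
    parts = np.maximum(parts, _LOGLIK_FLOOR)
    loglik = float(weights @ parts)

    finite_a, finite_b = np.isfinite(a), np.isfinite(b)
    # d lnD/dη = expit(a) − expit(−b)   (censored bounds contribute 0)
    g_eta = np.zeros_like(eta)
    g_eta[finite_a] += expit(a[finite_a])
    g_eta[finite_b] -= expit(-b[finite_b])
    # d lnD/dα: boundary terms plus the log1p(−e^{a−b}) cross term
    g_alpha = np.zeros_like(eta)
    g_alpha[finite_b] += expit(-b[finite_b]) * log_upper[finite_b]
    g_alpha[finite_a] -= expit(a[finite_a]) * log_lower[finite_a]
    both = finite_a & finite_b
    if both.any():
        r = np.exp(a[both] - b[both])
        g_alpha[both] += r / (1.0 - r) * (log_upper[both] - log_lower[both])
    grad_delta = Xmat.T @ (weights * g_eta)
    grad_logalpha = alpha * float(weights @ g_alpha)
    return -loglik, -np.append(grad_delta, grad_logalpha)


def _grouped(Xmat, lower, upper):
    """Collapse identical (bounds, covariates) rows into weighted rows."""
    stacked = np.column_stack([lower, upper, Xmat])
    uniq, counts = np.unique(stacked, axis=0, return_counts=True)
    return uniq[:, 2:], uniq[:, 0], uniq[:, 1], counts.astype(float)


@dataclass(frozen=True)
class IntervalFit:
    """Interval-censored log-logistic ML fit. ``delta`` includes the
    intercept (``const``); ``vcov`` covers (δ, α) on the natural scale;
    ``covariate_means`` stores X̄ over the fitted subsample for the
    default mean-WTP evaluation point."""

    delta: pd.Series
    alpha: float
    vcov: pd.DataFrame
    loglik: float
    n: int
    converged: bool
    iterations: int
    covariate_means: pd.Series
    n_floored: int = 0

    @property
    def params(self) -> pd.Series:
        return pd.concat([self.delta, pd.Series({"alpha": self.alpha})])

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.vcov.index)

    @property
    def p_values(self) -> pd.Series:
        from scipy.stats import norm

        z = self.params / self.se
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.params.index)


def _initial_values(Xmat, lower, upper, alpha0: float = 1.0) -> np.ndarray:
    """Scale-aware start: δ0 from least squares of α0·ln(midpoint) on X,
    midpoint = geometric mean of the bounds (U/2 if left-censored,
    2L if right-censored)."""
    mid = np.where(
        np.isinf(upper), 2.0 * lower, np.where(lower == 0.0, upper / 2.0, np.sqrt(lower * upper))
    )
    target = alpha0 * np.log(np.maximum(mid, 1e-12))
    delta0, *_ = np.linalg.lstsq(Xmat, target, rcond=None)
    return np.append(delta0, np.log(alpha0))


def _newton_polish(theta, args, max_steps: int = 25):
    """Damped Newton refinement of θ = (δ, ln α) until the gradient
    sup-norm is far below tolerance; the Hessian is differenced from the
    analytic gradient."""
    grad_of = lambda t: _neg_loglik_and_grad(t, *args)[1]
    f, g = _neg_loglik_and_grad(theta, *args)
    steps = 0
    for _ in range(max_steps):
        if np.max(np.abs(g)) <= 0.01 * _GRADIENT_TOL:
            break
        hess = approx_fprime(theta, grad_of, centered=True)
        hess = (hess + hess.T) / 2.0
        try:
            direction = np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            direction = np.linalg.lstsq(hess, g, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            cand = theta - scale * direction
            f_new, g_new = _neg_loglik_and_grad(cand, *args)
            if f_new <= f or np.max(np.abs(g_new)) < np.max(np.abs(g)):
                theta, f, g = cand, f_new, g_new
                break
            scale /= 2.0
        else:
            break  # no productive step available
        steps += 1
    return theta, np.max(np.abs(g)), steps


def _fit_grouped(gX, log_lower, log_upper, weights, columns, init, maxiter=500,
                 want_vcov=True):
    """ML fit on grouped rows (unique patterns with multiplicities)."""
    args = (gX, log_lower, log_upper, weights)
    theta0 = np.asarray(init, dtype=float)
    result = optimize.minimize(
        _neg_loglik_and_grad,
        theta0,
        args=args,
        jac=True,
        method="BFGS",
        options={"gtol": 1e-9, "maxiter": maxiter},
    )
    theta, nit = result.x, int(result.nit)
    grad_norm = np.max(np.abs(result.jac))
    if grad_norm > 0.1 * _GRADIENT_TOL:
        # BFGS line searches stall on precision loss near the optimum;
        # polish with damped Newton steps on the analytic gradient
        theta, grad_norm, extra = _newton_polish(theta, args)
        nit += extra
    if grad_norm > _GRADIENT_TOL:
        raise ConvergenceError(
            f"interval ML did not converge (gradient sup-norm {grad_norm:.2e})",
            trace=result,
        )
    delta, alpha = theta[:-1], float(np.exp(theta[-1]))

    vcov = None
    if want_vcov:
        # observed information on the (δ, α) scale
        def grad_natural(params):
            t = np.append(params[:-1], np.log(params[-1]))
            _, g = _neg_loglik_and_grad(t, *args)
            g = -g  # back to loglik gradient
            g[-1] = g[-1] / params[-1]  # d/dα = d/d(lnα) / α
            return g

        natural = np.append(delta, alpha)
        hess = approx_fprime(natural, grad_natural, centered=True)
        hess = (hess + hess.T) / 2.0
        names = list(columns) + ["alpha"]
        vcov = pd.DataFrame(np.linalg.pinv(-hess), index=names, columns=names)

    parts, _, _ = _log_prob_mass(gX @ delta, alpha, log_lower, log_upper)
    n_floored = int(weights[parts < _LOGLIK_FLOOR].sum())
    loglik, _ = _neg_loglik_and_grad(theta, *args)
    return (
        pd.Series(delta, index=columns, name="delta"),
        alpha,
        vcov,
        -float(loglik),
        True,
        nit,
        n_floored,
    )


def _fit_arrays(Xmat, lower, upper, columns, init=None, maxiter: int = 500,
                want_vcov: bool = True):
    if not ((lower > 0).any() or np.isfinite(upper).any()):
        raise NonIdentifiableError("all intervals are (0, inf); no finite bound present")
    gX, glo, gup, weights = _grouped(Xmat, lower, upper)
    with np.errstate(divide="ignore"):
        log_lower = np.log(glo)
    log_upper = np.log(gup)
    theta0 = _initial_values(Xmat, lower, upper) if init is None else init
    return _fit_grouped(gX, log_lower, log_upper, weights, columns, theta0,
                        maxiter=maxiter, want_vcov=want_vcov)


def fit_interval_model(
    intervals: Sequence[WtpInterval],
    X=None,
    init=None,
    maxiter: int = 500,
) -> IntervalFit:
    """Maximize Σ ln[F(A^U) − F(A^L)] over (δ, ln α) by quasi-Newton with
    the analytic gradient; the positivity constraint on α is enforced by
    optimizing ln α. ``X`` (optional) holds covariates; an intercept
    column ``const`` is added when absent. The covariance matrix is the
    inverse observed information on the (δ, α) scale.
    """
    if len(intervals) == 0:
        raise ValueError("need at least one interval")
    n = len(intervals)
    if X is None:
        design = pd.DataFrame({"const": np.ones(n)})
    else:
        design = pd.DataFrame(X).astype(float).reset_index(drop=True)
        if "const" not in design.columns:
            design.insert(0, "const", 1.0)
    if design.shape[0] != n:
        raise ValueError("X must be row-aligned with intervals")
    Xmat = design.to_numpy()
    lower, upper = _bounds_arrays(intervals)
    delta, alpha, vcov, loglik, success, nit, n_floored = _fit_arrays(
        Xmat, lower, upper, list(design.columns), init=init, maxiter=maxiter
    )
    return IntervalFit(
        delta=delta,
        alpha=alpha,
        vcov=vcov,
        loglik=loglik,
        n=n,
        converged=success,
        iterations=nit,
        covariate_means=design.mean(),
        n_floored=n_floored,
    )


# --- mean WTP, bootstrap, aggregation -------------------------------------

MEAN_METHODS = ("closed_form", "printed_eq4", "truncated_at_max_bid")


@dataclass(frozen=True)
class WtpEstimate:
    mean: float
    median: float
    method: str
    covariate_point: pd.Series
    ci_low: float | None = None
    ci_high: float | None = None

    def with_ci(self, low: float, high: float) -> "WtpEstimate":
        return WtpEstimate(
            mean=self.mean,
            median=self.median,
            method=self.method,
            covariate_point=self.covariate_point,
            ci_low=low,
            ci_high=high,
        )

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "median": self.median,
            "method": self.method,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _mean_from_params(delta_x: float, alpha: float, method: str, top_bid: float) -> float:
    if method == "closed_form":
        if alpha <= 1.0:
            raise MeanUndefinedError(
                f"closed-form log-logistic mean diverges for alpha = {alpha:.4f} <= 1; "
                "use method='truncated_at_max_bid'"
            )
        return float(np.exp(delta_x / alpha) * (np.pi / alpha) / np.sin(np.pi / alpha))
    if method == "printed_eq4":
        return float(np.exp(delta_x / alpha + 1.0 / (2.0 * alpha**2)))
    if method == "truncated_at_max_bid":
        from scipy.integrate import quad

        survival = lambda A: expit(delta_x - alpha * np.log(A))
        value, _ = quad(survival, 0.0, top_bid, limit=200)
        return float(value)
    raise ValueError(f"unknown mean method {method!r}; choose from {MEAN_METHODS}")


def mean_wtp(
    fit: IntervalFit,
    covariate_point: pd.Series | None = None,
    method: str = "closed_form",
    top_bid: float = DEFAULT_BIDS.amounts[-1],
) -> WtpEstimate:
    """Mean and median WTP at a covariate point (default: subsample means).

    median = exp(δx̄/α) always; the mean follows ``method``. The closed
    form requires α > 1 (otherwise :class:`MeanUndefinedError` advises
    the truncated estimator, which integrates the fitted survival curve
    from 0 to the top bid).
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    point = fit.covariate_means if covariate_point is None else pd.Series(covariate_point)
    point = point.reindex(fit.delta.index)
    if point.isna().any():
        raise ValueError("covariate_point must supply every model covariate")
    delta_x = float(fit.delta @ point)
    return WtpEstimate(
        mean=_mean_from_params(delta_x, fit.alpha, method, top_bid),
        median=float(np.exp(delta_x / fit.alpha)),
        method=method,
        covariate_point=point,
    )


@dataclass(frozen=True)
class BootstrapCI:
    ci_low: float
    ci_high: float
    replicates: np.ndarray
    n_failed: int
    reliable: bool


def bootstrap_ci(
    intervals: Sequence[WtpInterval],
    X=None,
    B: int = 1000,
    seed: int | None = None,
    method: str = "closed_form",
    top_bid: float = DEFAULT_BIDS.amounts[-1],
    covariate_point: pd.Series | None = None,
) -> BootstrapCI:
    """Percentile bootstrap CI for mean WTP.

    Respondents (interval + covariate row) are resampled with
    replacement B times — realized as multinomial reweighting of the
    unique response patterns, which is distribution-identical and avoids
    regrouping; each replicate refits the interval model (warm-started
    at the full-sample estimate) and recomputes the mean at the
    replicate's covariate means (or a fixed ``covariate_point``).
    Deterministic given ``seed``. Replicates that fail to converge or
    have α ≤ 1 under the closed form are dropped and counted; more than
    10% failures marks the result unreliable (with a warning).
    """
    if B < 100:
        raise ValueError("need B >= 100 bootstrap replicates")
    n = len(intervals)
    if n == 0:
        raise ValueError("empty second-stage subsample")
    full = fit_interval_model(intervals, X)
    design = pd.DataFrame(
        {"const": np.ones(n)} if X is None else pd.DataFrame(X).astype(float)
    ).reset_index(drop=True)
    if "const" not in design.columns:
        design.insert(0, "const", 1.0)
    Xmat = design.to_numpy()
    lower, upper = _bounds_arrays(intervals)
    columns = list(design.columns)
    init = np.append(full.delta.to_numpy(), np.log(full.alpha))
    fixed_point = (
        None
        if covariate_point is None
        else pd.Series(covariate_point).reindex(full.delta.index).to_numpy()
    )

    gX, glo, gup, weights = _grouped(Xmat, lower, upper)
    with np.errstate(divide="ignore"):
        log_lower = np.log(glo)
    log_upper = np.log(gup)
    pattern_probs = weights / n

    rng = np.random.default_rng(seed)
    means, n_failed = [], 0
    for _ in range(B):
        w = rng.multinomial(n, pattern_probs).astype(float)
        live = w > 0
        try:
            if not ((glo[live] > 0).any() or np.isfinite(gup[live]).any()):
                raise NonIdentifiableError("resample carries no finite bound")
            delta, alpha, _, _, _, _, _ = _fit_grouped(
                gX, log_lower, log_upper, w, columns, init, want_vcov=False
            )
            point = (w @ gX) / n if fixed_point is None else fixed_point
            delta_x = float(delta.to_numpy() @ point)
            means.append(_mean_from_params(delta_x, alpha, method, top_bid))
        except (ConvergenceError, MeanUndefinedError, NonIdentifiableError,
                np.linalg.LinAlgError):
            n_failed += 1
    if not means:
        raise ConvergenceError("every bootstrap replicate failed to converge")
    reliable = n_failed <= 0.1 * B
    if not reliable:
        warnings.warn(
            f"{n_failed}/{B} bootstrap replicates failed; CI may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    replicates = np.asarray(means)
    low, high = np.percentile(replicates, [2.5, 97.5])
    return BootstrapCI(
        ci_low=float(low),
        ci_high=float(high),
        replicates=replicates,
        n_failed=n_failed,
        reliable=reliable,
    )


@dataclass(frozen=True)
class AggregationResult:
    """Population revenue: mean WTP × share of willing payers × units."""

    total: float
    total_low: float | None
    total_high: float | None
    mean_wtp_used: float
    proportion_yes: float
    n_units: int

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "total_low": self.total_low,
            "total_high": self.total_high,
            "mean_wtp_used": self.mean_wtp_used,
            "proportion_yes": self.proportion_yes,
            "n_units": self.n_units,
        }


def aggregate_wtp(
    mean_estimate: WtpEstimate | float,
    proportion_yes: float,
    n_units: int,
    ci: tuple[float, float] | None = None,
) -> AggregationResult:
    """total = mean × proportion_yes × n_units, with CI bounds scaled by
    the same product when available."""
    if not 0.0 <= proportion_yes <= 1.0:
        raise ValueError("proportion_yes must lie in [0, 1]")
    if n_units <= 0:
        raise ValueError("n_units must be positive")
    if isinstance(mean_estimate, WtpEstimate):
        mean = mean_estimate.mean
        bounds = (
            (mean_estimate.ci_low, mean_estimate.ci_high)
            if mean_estimate.ci_low is not None
            else None
        )
    else:
        mean = float(mean_estimate)
        bounds = ci
    scale = proportion_yes * n_units
    return AggregationResult(
        total=mean * scale,
        total_low=None if bounds is None else bounds[0] * scale,
        total_high=None if bounds is None else bounds[1] * scale,
        mean_wtp_used=mean,
        proportion_yes=proportion_yes,
        n_units=int(n_units),
    )
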