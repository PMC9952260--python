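"""Synthetic payment-card survey generator with known ground truth.

Emulates the statistical structure the two-stage analysis assumes:
covariates with realistic regional-survey moments, a logit participation
process, latent WTP drawn from a log-logistic random-utility model, and
a five-level certainty grid produced by banding the log acceptance
margin m = ln W − ln A at each bid. Every generator is a pure function
of (config, seed), so parameter recovery, bootstrap coverage and
pipeline determinism are all testable without any external data.

Composite covariates are drawn from moment-matched truncated normals on
their declared supports; for mean/SD targets a truncated normal cannot
reach (heavily skewed batteries near a scale endpoint) a moment-matched
scaled Beta is used instead. Raw Likert items are then generated around
each latent composite (rounded, clipped, reverse-stored for
reverse-coded items) so the written CSV carries the full questionnaire.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from . import scales as scales_mod
from .survey_io import (
    BidSchedule,
    Certainty,
    DEFAULT_BIDS,
    RespondentRecord,
    write_survey,
)

#: Composite covariates: (mean, sd) targets on the 1–5 metric.
DEFAULT_COMPOSITE_MOMENTS: dict[str, tuple[float, float]] = {
    "attitude": (3.30, 0.73),
    "knowledge": (3.25, 1.00),
    "conservation_actions": (3.16, 1.10),
    "moralistic": (4.79, 0.49),
    "dominionistic": (2.05, 1.29),
}

#: Item-level noise around the latent composite, per scale.
DEFAULT_ITEM_NOISE_SD: dict[str, float] = {
    "attitude": 0.95,
    "knowledge": 0.60,
    "conservation_actions": 0.65,
    "moralistic": 0.35,
    "dominionistic": 0.40,
}

#: Ordinal recreation-frequency covariates: P(level 1..5), chosen to
#: approximate survey moments (consumptive ~1.12/0.61, nonconsumptive
#: ~2.65/1.12) on the integer 1–5 support.
DEFAULT_ORDINAL_PROBS: dict[str, tuple[float, ...]] = {
    "consumptive": (0.955, 0.01, 0.01, 0.01, 0.015),
    "nonconsumptive": (0.169, 0.281, 0.311, 0.177, 0.062),
}

#: Participation probability 0.616 with no covariate effects.
DEFAULT_PARTICIPATION_BETA: dict[str, float] = {"const": math.log(0.616 / 0.384)}

DEFAULT_WTP_ALPHA = 1.8
#: Median WTP EUR 40: δ0 = α·ln 40.
DEFAULT_WTP_DELTA: dict[str, float] = {"const": DEFAULT_WTP_ALPHA * math.log(40.0)}

#: Log-margin thresholds (DY, yes/no cut, NS, PN): m ≥ 0.5 → definitely
#: yes, 0 ≤ m < 0.5 → probably yes, then not sure / probably no /
#: definitely no at −0.5 and −1.0.
DEFAULT_CERTAINTY_BANDS = (0.5, 0.0, -0.5, -1.0)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic survey draw."""

    n: int = 500
    seed: int = 0
    bids: BidSchedule = DEFAULT_BIDS
    composite_moments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITE_MOMENTS)
    )
    item_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_NOISE_SD)
    )
    seen_p: float = 0.33
    gender_p: float = 0.51
    education_p: float = 0.19
    age_moments: tuple[float, float, float, float] = (43.84, 17.86, 18.0, 90.0)
    income_moments: tuple[float, float, float, float] = (16.97, 15.45, 0.0, 130.0)
    ordinal_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ORDINAL_PROBS)
    )
    participation_beta: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARTICIPATION_BETA)
    )
    wtp_delta: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WTP_DELTA)
    )
    wtp_alpha: float = DEFAULT_WTP_ALPHA
    certainty_bands: tuple[float, float, float, float] = DEFAULT_CERTAINTY_BANDS
    jitter_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigError("n must be positive")
        if self.wtp_alpha <= 0:
            raise ConfigError("wtp_alpha must be positive")
        b = self.certainty_bands
        if not (b[0] >= b[1] >= b[2] >= b[3]):
            raise ConfigError("certainty bands must be ordered high to low")
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be nonnegative")
        for name, probs in self.ordinal_probs.items():
            p = np.asarray(probs, dtype=float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-8:
                raise ConfigError(f"ordinal probabilities for {name!r} must sum to 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth echoed alongside a generated survey."""

    latent_wtp: np.ndarray
    participation_prob: np.ndarray
    participation_beta: dict[str, float]
    wtp_delta: dict[str, float]
    wtp_alpha: float

    def to_dict(self) -> dict:
        return {
            "participation_beta": self.participation_beta,
            "wtp_delta": self.wtp_delta,
            "wtp_alpha": self.wtp_alpha,
            "latent_wtp": self.latent_wtp.tolist(),
            "participation_prob": self.participation_prob.tolist(),
        }


# --- distribution helpers --------------------------------------------------


@lru_cache(maxsize=64)
def _matched_sampler_params(mean: float, sd: float, lo: float, hi: float):
    """Parameters of a bounded sampler whose moments equal (mean, sd).

    Tries a truncated normal first (solving for the parent loc/scale);
    if the target is outside that family's reachable set, falls back to
    a Beta rescaled to [lo, hi] (feasible whenever sd² < (mean−lo)(hi−mean)).
    """
    if not lo < mean < hi:
        raise ConfigError(f"mean {mean} outside the support ({lo}, {hi})")
    if sd <= 0:
        raise ConfigError("sd must be positive")

    def residual(p):
        loc, log_scale = p
        scale = math.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        d = stats.truncnorm(a, b, loc=loc, scale=scale)
        return [d.mean() - mean, d.std() - sd]

    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # fsolve probes infeasible parent parameters while searching
        warnings.simplefilter("ignore", RuntimeWarning)
        sol, _, ier, _ = optimize.fsolve(
            residual, [mean, math.log(sd)], full_output=True
        )
    if ier == 1 and max(abs(r) for r in residual(sol)) < 1e-8:
        loc, scale = sol[0], math.exp(sol[1])
        return ("truncnorm", ((lo - loc) / scale, (hi - loc) / scale, loc, scale))

    span = hi - lo
    mu = (mean - lo) / span
    var = (sd / span) ** 2
    if var >= mu * (1 - mu):
        raise ConfigError(
            f"moments (mean={mean}, sd={sd}) unreachable on [{lo}, {hi}]"
        )
    nu = mu * (1 - mu) / var - 1.0
    return ("beta", (mu * nu, (1 - mu) * nu, lo, span))


def sample_bounded(
    mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw from the moment-matched bounded distribution."""
    family, params = _matched_sampler_params(mean, sd, lo, hi)
    if family == "truncnorm":
        a, b, loc, scale = params
        return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)
    a, b, lo, span = params
    return lo + span * rng.beta(a, b, size=size)


def _items_from_composite(
    composite: np.ndarray,
    scale: scales_mod.ScaleDefinition,
    noise_sd: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Integer 1–5 item answers scattered around the latent composite;
    reverse-coded items are stored mirrored so scoring recovers them."""
    lo, hi = scale.response_range
    out = {}
    for item in scale.items:
        raw = np.clip(np.rint(composite + rng.normal(0.0, noise_sd, len(composite))), lo, hi)
        if item in scale.reverse_coded:
            raw = (lo + hi) - raw
        out[item] = raw.astype(int)
    return out


# --- generators -------------------------------------------------------------


def simulate_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Covariate table: latent composites, their raw Likert items, and
    sociodemographics. Deterministic given (config, seed)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n
    frame = pd.DataFrame(index=pd.RangeIndex(n))

    for name, (mean, sd) in config.composite_moments.items():
        if name not in scales_mod.DEFAULT_SCALES:
            raise ConfigError(f"unknown composite scale {name!r}")
        scale = scales_mod.DEFAULT_SCALES[name]
        lo, hi = scale.response_range
        composite = sample_bounded(mean, sd, lo, hi, n, rng)
        frame[name] = composite
        for item, values in _items_from_composite(
            composite, scale, config.item_noise_sd.get(name, 0.6), rng
        ).items():
            frame[item] = values

    frame["seen"] = (rng.random(n) < config.seen_p).astype(int)
    a_mean, a_sd, a_lo, a_hi = config.age_moments
    frame["age"] = np.round(sample_bounded(a_mean, a_sd, a_lo, a_hi, n, rng), 1)
    frame["gender"] = (rng.random(n) < config.gender_p).astype(int)
    frame["education"] = (rng.random(n) < config.education_p).astype(int)
    i_mean, i_sd, i_lo, i_hi = config.income_moments
    frame["income"] = np.round(sample_bounded(i_mean, i_sd, i_lo, i_hi, n, rng), 3)
    for name, probs in config.ordinal_probs.items():
        frame[name] = rng.choice(np.arange(1, len(probs) + 1), size=n, p=probs)
    return frame


def _linear_predictor(covariates: pd.DataFrame, beta: Mapping[str, float]) -> np.ndarray:
    eta = np.full(len(covariates), float(beta.get("const", 0.0)))
    for name, value in beta.items():
        if name == "const":
            continue
        if name not in covariates.columns:
            raise ConfigError(f"coefficient on unknown covariate {name!r}")
        eta += value * covariates[name].to_numpy(dtype=float)
    return eta


def simulate_participation(
    covariates: pd.DataFrame,
    beta_true: Mapping[str, float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """First-stage outcomes: y ~ Bernoulli(logistic(β0 + Xβ)).
    Returns (y, true probabilities)."""
    rng = np.random.default_rng(seed) if rng is None else rng
    prob = expit(_linear_predictor(covariates, beta_true))
    y = (rng.random(len(prob)) < prob).astype(int)
    return y, prob


def simulate_payment_card(
    covariates: pd.DataFrame,
    delta_true: Mapping[str, float],
    alpha_true: float,
    bids: BidSchedule = DEFAULT_BIDS,
    certainty_bands: tuple[float, float, float, float] = DEFAULT_CERTAINTY_BANDS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    jitter_sd: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent WTP draws and their certainty grids.

    W is sampled by inverse-CDF from the log-logistic with linear
    predictor η = δX and shape α (median exp(η/α)). At each bid A the
    log acceptance margin m = ln W − ln A is banded into the five
    levels. The yes/no side of the scale is decided by the noiseless
    margin against the second band (the Welsh–Poe cut), while a
    per-respondent Gaussian jitter shifts the refinement *within* each
    side — so all five levels occur near the threshold, grids stay
    monotone down the ladder, and the probably-yes recoding reproduces
    W ≥ A exactly.

    Returns (grids: n × n_bids integer certainty codes, W)."""
    if alpha_true <= 0:
        raise ConfigError("alpha must be positive")
    b1, b2, b3, b4 = certainty_bands
    if not (b1 >= b2 >= b3 >= b4):
        raise ConfigError("certainty bands must be ordered high to low")
    rng = np.random.default_rng(seed) if rng is None else rng
    eta = _linear_predictor(covariates, delta_true)
    n = len(eta)
    u = rng.random(n)
    latent = np.exp((eta + logit(u)) / alpha_true)
    eps = rng.normal(0.0, jitter_sd, n) if jitter_sd > 0 else np.zeros(n)

    amounts = np.asarray(bids.amounts)
    m = np.log(latent)[:, None] - np.log(amounts)[None, :]  # n × J
    mj = m + eps[:, None]
    yes_side = m >= b2
    grids = np.where(
        yes_side,
        np.where(mj >= b1, int(Certainty.DEFINITELY_YES), int(Certainty.PROBABLY_YES)),
        np.where(
            mj >= b3,
            int(Certainty.NOT_SURE),
            np.where(mj >= b4, int(Certainty.PROBABLY_NO), int(Certainty.DEFINITELY_NO)),
        ),
    )
    return grids.astype(int), latent


def simulate_survey(
    config: SimulationConfig,
) -> tuple[list[RespondentRecord], pd.DataFrame, SyntheticTruth]:
    """Full survey draw: records (grids only for participants), the
    covariate table (latent composites included), and the ground truth."""
    rng = np.random.default_rng(config.seed)
    covariates = simulate_covariates(config, rng=rng)
    y, prob = simulate_participation(covariates, config.participation_beta, rng=rng)
    grids, latent = simulate_payment_card(
        covariates,
        config.wtp_delta,
        config.wtp_alpha,
        bids=config.bids,
        certainty_bands=config.certainty_bands,
        rng=rng,
        jitter_sd=config.jitter_sd,
    )

    records = []
    item_cols = [c for s in scales_mod.DEFAULT_SCALES.values() for c in s.items]
    for i in range(config.n):
        grid = tuple(Certainty(int(c)) for c in grids[i]) if y[i] == 1 else None
        records.append(
            RespondentRecord(
                id=f"r{i + 1:04d}",
                participates=int(y[i]),
                certainty_grid=grid,
                items={c: int(covariates.at[i, c]) for c in item_cols},
                seen=int(covariates.at[i, "seen"]),
                age=float(covariates.at[i, "age"]),
                gender=int(covariates.at[i, "gender"]),
                education=int(covariates.at[i, "education"]),
                income=float(covariates.at[i, "income"]),
                consumptive=int(covariates.at[i, "consumptive"]),
                nonconsumptive=int(covariates.at[i, "nonconsumptive"]),
            )
        )
    truth = SyntheticTruth(
        latent_wtp=latent,
        participation_prob=prob,
        participation_beta=dict(config.participation_beta),
        wtp_delta=dict(config.wtp_delta),
        wtp_alpha=config.wtp_alpha,
    )
    return records, covariates, truth


def make_fixture(
    config: SimulationConfig,
    csv_path: str | Path,
    truth_path: str | Path | None = None,
    certainty_as: str = "label",
) -> tuple[Path, Path | None]:
    """Write a read_survey-compatible CSV plus a ground-truth JSON sidecar."""
    records, _, truth = simulate_survey(config)
    csv_path = write_survey(records, csv_path, bids=config.bids, certainty_as=certainty_as)
    if truth_path is not None:
        truth_path = Path(truth_path)
        truth_path.write_text(json.dumps(truth.to_dict(), indent=1))
    return csv_path, truth_path
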