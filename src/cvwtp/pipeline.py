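"""Config-driven orchestration of the two-stage WTP analysis.

Stages: read (or simulate) the survey → score psychometric composites →
screen collinearity → first-stage participation logit → second-stage
interval model on the first-stage "yes" respondents → mean WTP with
bootstrap CI → aggregation to population revenue → rendered reports
(text, CSV and JSON twins of the two regression tables).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import CollinearityReport, vif_screen
from .participation import LogitFit, LogitReport, fit_logit, fit_statistics
from .scales import DEFAULT_SCALES, ScaleDefinition, score_all
from .simulate import SimulationConfig, simulate_survey
from .survey_io import (
    BidSchedule,
    DEFAULT_BIDS,
    SampleSummary,
    SurveySchema,
    read_survey,
    records_to_frame,
    summarize_sample,
)
from .wtp import (
    AggregationResult,
    BootstrapCI,
    IntervalFit,
    SCHEMES,
    WtpEstimate,
    aggregate_wtp,
    bootstrap_ci,
    build_intervals,
    fit_interval_model,
    mean_wtp,
)

logger = logging.getLogger("cvwtp")

#: Covariates entering both models, in report order.
MODEL_COVARIATES = (
    "attitude",
    "knowledge",
    "conservation_actions",
    "moralistic",
    "dominionistic",
    "seen",
    "age",
    "gender",
    "education",
    "income",
    "consumptive",
    "nonconsumptive",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs. Exactly one of ``input_path`` /
    ``simulation`` must be set."""

    input_path: str | None = None
    simulation: SimulationConfig | None = None
    schema: SurveySchema = field(default_factory=SurveySchema)
    bids: BidSchedule = DEFAULT_BIDS
    scales: Mapping[str, ScaleDefinition] = field(default_factory=lambda: dict(DEFAULT_SCALES))
    recoding_scheme: str = "probably_yes"
    mean_method: str = "closed_form"
    nonmonotone_policy: str = "keep"
    bootstrap_b: int = 1000
    seed: int = 0
    n_households: int = 235_349
    proportion_yes_override: float | None = None
    n_approached: int | None = None
    vif_threshold: float = 5.0
    rho_threshold: float = 0.7

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path / simulation must be given")
        if self.recoding_scheme not in SCHEMES:
            raise ValueError(f"unknown recoding scheme {self.recoding_scheme!r}")
        if self.n_households <= 0:
            raise ValueError("n_households must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        if "input_path" in raw:
            kwargs["input_path"] = raw["input_path"]
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            if "bids" in sim:
                sim["bids"] = BidSchedule(tuple(sim["bids"]))
            kwargs["simulation"] = SimulationConfig(**sim)
        if "schema" in raw:
            kwargs["schema"] = SurveySchema(**raw["schema"])
        if "bids" in raw:
            kwargs["bids"] = BidSchedule(tuple(raw["bids"]))
        if "scales" in raw:
            defs = dict(DEFAULT_SCALES)
            for name, spec in raw["scales"].items():
                defs[name] = ScaleDefinition(
                    name=name,
                    items=tuple(spec["items"]),
                    reverse_coded=frozenset(spec.get("reverse_coded", ())),
                    response_range=tuple(spec.get("response_range", (1, 5))),
                )
            kwargs["scales"] = defs
        for key in (
            "recoding_scheme",
            "mean_method",
            "nonmonotone_policy",
            "bootstrap_b",
            "seed",
            "n_households",
            "proportion_yes_override",
            "n_approached",
            "vif_threshold",
            "rho_threshold",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def fingerprint(self) -> str:
        """Hash of the full configuration, for the run manifest."""

        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {str(k): encode(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple, set, frozenset)):
                return [encode(v) for v in sorted(obj, key=str) if not isinstance(obj, (list, tuple))] \
                    if isinstance(obj, (set, frozenset)) else [encode(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        blob = json.dumps(encode(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Every artifact of one pipeline run, JSON-serializable."""

    config_fingerprint: str
    version: str
    n_total: int
    n_stage2: int
    n_refused: int
    n_excluded_stage1: int
    n_excluded_stage2: int
    sample_summary: SampleSummary | None
    collinearity: CollinearityReport
    logit_fit: LogitFit
    logit_report: LogitReport
    interval_fit: IntervalFit
    wtp_estimate: WtpEstimate
    bootstrap: BootstrapCI
    aggregation: AggregationResult
    warnings: list[str]

    def logit_table(self) -> pd.DataFrame:
        """First-stage report: odds ratio / marginal effect / p per covariate."""
        rep = self.logit_report
        rows = rep.odds_ratios.index
        return pd.DataFrame(
            {
                "odds_ratio": rep.odds_ratios["odds_ratio"],
                "marginal_effect": rep.marginal_effects.reindex(rows),
                "p": rep.p_values.reindex(rows),
            }
        )

    def interval_table(self) -> pd.DataFrame:
        """Second-stage report: coefficient / SE / p per covariate."""
        fit = self.interval_fit
        return pd.DataFrame(
            {"coefficient": fit.params, "se": fit.se, "p": fit.p_values}
        )

    def to_dict(self) -> dict:
        rep = self.logit_report
        return {
            "config_fingerprint": self.config_fingerprint,
            "version": self.version,
            "counts": {
                "n_total": self.n_total,
                "n_stage2": self.n_stage2,
                "n_refused": self.n_refused,
                "n_excluded_stage1": self.n_excluded_stage1,
                "n_excluded_stage2": self.n_excluded_stage2,
            },
            "sample_summary": None if self.sample_summary is None else self.sample_summary.to_dict(),
            "collinearity": self.collinearity.to_dict(),
            "logit": {
                "table": json.loads(self.logit_table().to_json(orient="index")),
                "coefficients": self.logit_fit.coefficients.to_dict(),
                "nagelkerke_r2": rep.nagelkerke_r2,
                "neg2loglik": rep.neg2loglik,
                "aicc": rep.aicc,
                "percent_correct": rep.percent_correct,
            },
            "interval": {
                "table": json.loads(self.interval_table().to_json(orient="index")),
                "alpha": self.interval_fit.alpha,
                "loglik": self.interval_fit.loglik,
                "n": self.interval_fit.n,
            },
            "wtp": self.wtp_estimate.to_dict(),
            "bootstrap": {
                "n_failed": self.bootstrap.n_failed,
                "reliable": self.bootstrap.reliable,
            },
            "aggregation": self.aggregation.to_dict(),
            "warnings": self.warnings,
        }


def _listwise(design: pd.DataFrame, stage: str, warnings_out: list[str]) -> pd.DataFrame:
    complete = design.dropna()
    dropped = len(design) - len(complete)
    if dropped:
        message = f"{stage}: {dropped} record(s) excluded by listwise deletion"
        logger.info(message)
        warnings_out.append(message)
    return complete


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full two-stage analysis; see module docstring."""
    warnings_out: list[str] = []

    # --- input
    try:
        if config.simulation is not None:
            records, _, _ = simulate_survey(config.simulation)
            bids = config.simulation.bids
        else:
            records = read_survey(config.input_path, schema=config.schema, bids=config.bids)
            bids = config.bids
    except Exception as exc:
        raise PipelineError(f"input stage failed: {exc}") from exc

    frame = records_to_frame(records)
    n_total = len(records)

    # --- scales
    try:
        composites = score_all(frame, dict(config.scales))
    except Exception as exc:
        raise PipelineError(f"scales stage failed: {exc}") from exc

    design_full = pd.concat(
        [composites, frame[[c for c in MODEL_COVARIATES if c in frame.columns]]], axis=1
    )
    design_full = design_full.loc[:, ~design_full.columns.duplicated()]
    design_full = design_full[[c for c in MODEL_COVARIATES if c in design_full.columns]]
    design_full = design_full.astype(float)

    # --- sample summary (optional: needs n_approached)
    summary = None
    if config.n_approached is not None:
        try:
            summary = summarize_sample(records, config.n_approached)
        except Exception as exc:
            raise PipelineError(f"sample-summary stage failed: {exc}") from exc

    # --- diagnostics
    stage1 = _listwise(
        pd.concat([frame["participates"].astype(float), design_full], axis=1),
        "stage 1",
        warnings_out,
    )
    try:
        collinearity = vif_screen(
            stage1[list(design_full.columns)],
            threshold=config.vif_threshold,
            rho_threshold=config.rho_threshold,
        )
    except Exception as exc:
        raise PipelineError(f"diagnostics stage failed: {exc}") from exc
    if collinearity.dropped:
        warnings_out.append(f"collinearity screen flagged: {collinearity.dropped}")

    # --- first stage
    y = stage1["participates"].to_numpy()
    X1 = stage1[list(design_full.columns)]
    try:
        logit_fit = fit_logit(y, X1)
        logit_report = fit_statistics(logit_fit, y, X1)
    except Exception as exc:
        raise PipelineError(f"participation stage failed: {exc}") from exc

    # --- second stage: first-stage "yes" respondents with grids
    scheme = SCHEMES[config.recoding_scheme]
    stage2_records = [
        r for r in records if r.participates == 1 and r.certainty_grid is not None
    ]
    n_grid_missing = sum(
        1 for r in records if r.participates == 1 and r.certainty_grid is None
    )
    if n_grid_missing:
        warnings_out.append(
            f"stage 2: {n_grid_missing} participant(s) without certainty grid excluded"
        )
    if not stage2_records:
        raise PipelineError("second stage failed: empty second-stage subsample")
    ids2 = [r.id for r in stage2_records]
    design2 = design_full.loc[ids2]
    complete2 = design2.dropna().index
    n_excl2 = len(design2) - len(complete2)
    if n_excl2:
        warnings_out.append(f"stage 2: {n_excl2} record(s) excluded by listwise deletion")
    stage2_records = [r for r in stage2_records if r.id in set(complete2)]
    design2 = design_full.loc[[r.id for r in stage2_records]]

    try:
        intervals, kept = build_intervals(
            [r.certainty_grid for r in stage2_records],
            bids=bids,
            scheme=scheme,
            nonmonotone=config.nonmonotone_policy,
        )
        design2 = design2.iloc[np.flatnonzero(kept)]
        n_nonmono = int((~kept).sum())
        if n_nonmono:
            warnings_out.append(f"stage 2: {n_nonmono} non-monotone respondent(s) dropped")
        interval_fit = fit_interval_model(intervals, design2)
    except Exception as exc:
        raise PipelineError(f"interval stage failed: {exc}") from exc

    # --- WTP and bootstrap
    try:
        estimate = mean_wtp(
            interval_fit, method=config.mean_method, top_bid=bids.amounts[-1]
        )
    except Exception as exc:
        if config.mean_method == "closed_form":
            warnings_out.append(
                f"closed-form mean unavailable ({exc}); fell back to the "
                "truncated estimator"
            )
            estimate = mean_wtp(
                interval_fit, method="truncated_at_max_bid", top_bid=bids.amounts[-1]
            )
        else:
            raise PipelineError(f"mean-WTP stage failed: {exc}") from exc
    try:
        boot = bootstrap_ci(
            intervals,
            design2,
            B=config.bootstrap_b,
            seed=config.seed,
            method=estimate.method,
            top_bid=bids.amounts[-1],
        )
    except Exception as exc:
        raise PipelineError(f"bootstrap stage failed: {exc}") from exc
    estimate = estimate.with_ci(boot.ci_low, boot.ci_high)
    if not boot.reliable:
        warnings_out.append(
            f"bootstrap: {boot.n_failed}/{config.bootstrap_b} replicates failed"
        )

    # --- aggregation
    proportion_yes = (
        config.proportion_yes_override
        if config.proportion_yes_override is not None
        else float(np.mean(y))
    )
    aggregation = aggregate_wtp(estimate, proportion_yes, config.n_households)

    n_stage2 = len(intervals)
    return RunReport(
        config_fingerprint=config.fingerprint(),
        version=__version__,
        n_total=n_total,
        n_stage2=n_stage2,
        n_refused=n_total - int(np.sum([r.participates for r in records])),
        n_excluded_stage1=n_total - len(stage1),
        n_excluded_stage2=n_excl2 + n_nonmono + n_grid_missing,
        sample_summary=summary,
        collinearity=collinearity,
        logit_fit=logit_fit,
        logit_report=logit_report,
        interval_fit=interval_fit,
        wtp_estimate=estimate,
        bootstrap=boot,
        aggregation=aggregation,
        warnings=warnings_out,
    )


def render_tables(
    report: RunReport, out_dir: str | Path, formats: tuple[str, ...] = ("txt", "csv", "json")
) -> list[Path]:
    """Write the report. Numbers are rounded only at render time
    (3 decimals in the text tables); the JSON twin keeps full precision."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    unknown = set(formats) - {"txt", "csv", "json"}
    if unknown:
        raise ValueError(f"unknown render format(s): {sorted(unknown)}")

    if "json" in formats:
        path = out_dir / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=1))
        written.append(path)
    if "csv" in formats:
        for name, table in (
            ("participation_model.csv", report.logit_table()),
            ("wtp_model.csv", report.interval_table()),
        ):
            path = out_dir / name
            table.to_csv(path)
            written.append(path)
    if "txt" in formats:
        path = out_dir / "report.txt"
        rep = report.logit_report
        est = report.wtp_estimate
        agg = report.aggregation
        lines = [
            "Participation model (binary logit)",
            report.logit_table().round(3).to_string(),
            f"Nagelkerke R2      {rep.nagelkerke_r2:.3f}",
            f"-2LogLik           {rep.neg2loglik:.3f}",
            f"AICc               {rep.aicc:.3f}",
            f"Percent correct    {rep.percent_correct:.1f}",
            "",
            "WTP model (log-logistic interval regression)",
            report.interval_table().round(3).to_string(),
            f"-2LogLik           {-2 * report.interval_fit.loglik:.3f}",
            f"Mean WTP (EUR)     {est.mean:.3f}",
            f"95% CI of mean WTP (EUR)  {est.ci_low:.3f}-{est.ci_high:.3f}",
            f"Median WTP (EUR)   {est.median:.3f}",
            "",
            f"Aggregation: {agg.mean_wtp_used:.3f} x {agg.proportion_yes:.3f} x "
            f"{agg.n_units} households = EUR {agg.total:,.0f}",
            f"  bounds: EUR {agg.total_low:,.0f} - EUR {agg.total_high:,.0f}",
            "",
            "warnings: " + ("; ".join(report.warnings) if report.warnings else "none"),
        ]
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written
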