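"""Data model, CSV I/O and sample-representativeness summaries for
multiple-bounded payment-card contingent-valuation surveys.

A survey record holds the two-stage elicitation: a yes/no answer on
paying an annual conservation tax at all, and — for participants — a
five-level certainty response (definitely yes … definitely no) at each
amount of a fixed bid ladder, plus Likert scale items and
sociodemographic covariates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class SurveyValidationError(ValueError):
    """A field value violates the survey's range/consistency invariants."""


class SchemaError(ValueError):
    """The input file does not carry a mandatory column."""


class DegenerateExpectationError(ValueError):
    """A goodness-of-fit stratum has zero expected count."""


class Certainty(enum.IntEnum):
    """Five-level payment-certainty response, coded 5 (definitely yes)
    down to 1 (definitely no)."""

    DEFINITELY_NO = 1
    PROBABLY_NO = 2
    NOT_SURE = 3
    PROBABLY_YES = 4
    DEFINITELY_YES = 5


CERTAINTY_LABELS: dict[Certainty, str] = {c: c.name.lower() for c in Certainty}
LABEL_TO_CERTAINTY: dict[str, Certainty] = {v: k for k, v in CERTAINTY_LABELS.items()}

#: Default bid ladder (EUR): nine payment-card amounts.
DEFAULT_BID_AMOUNTS = (1.0, 5.0, 10.0, 20.0, 40.0, 80.0, 150.0, 300.0, 500.0)


@dataclass(frozen=True)
class BidSchedule:
    """Ordered ladder of strictly positive payment-card amounts (EUR)."""

    amounts: tuple[float, ...] = DEFAULT_BID_AMOUNTS

    def __post_init__(self) -> None:
        amounts = tuple(float(a) for a in self.amounts)
        object.__setattr__(self, "amounts", amounts)
        if len(amounts) < 2:
            raise SurveyValidationError("bid schedule needs at least 2 amounts")
        if any(a <= 0 for a in amounts):
            raise SurveyValidationError("bid amounts must be strictly positive")
        if any(b <= a for a, b in zip(amounts, amounts[1:])):
            raise SurveyValidationError("bid amounts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.amounts)

    @property
    def columns(self) -> tuple[str, ...]:
        """Canonical CSV column name per bid, e.g. ``bid_40``."""
        return tuple(f"bid_{a:g}" for a in self.amounts)


DEFAULT_BIDS = BidSchedule()

#: Canonical raw scale-item columns: attitude a1–a6, knowledge k1–k6,
#: conservation actions c1–c5, worldview w1–w6 (w1–w3 moralistic,
#: w4–w6 dominionistic).
ITEM_COLUMNS: tuple[str, ...] = (
    tuple(f"a{i}" for i in range(1, 7))
    + tuple(f"k{i}" for i in range(1, 7))
    + tuple(f"c{i}" for i in range(1, 6))
    + tuple(f"w{i}" for i in range(1, 7))
)

COVARIATE_COLUMNS: tuple[str, ...] = (
    "seen",
    "age",
    "gender",
    "education",
    "income",
    "consumptive",
    "nonconsumptive",
)

_ORDINAL_RANGES = {
    "consumptive": (1, 5),
    "nonconsumptive": (1, 5),
}
_BINARY_FIELDS = ("seen", "gender", "education")


@dataclass(frozen=True)
class SurveySchema:
    """CSV dialect description: delimiter plus a remapping from canonical
    column names to the names actually used in the file."""

    delimiter: str = ","
    column_map: Mapping[str, str] = field(default_factory=dict)

    def file_column(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)


@dataclass(frozen=True)
class RespondentRecord:
    """One completed answer sheet.

    ``certainty_grid`` is present iff the respondent said yes at the
    participation step; ``items`` maps raw item columns (a1…w6) to 1–5
    answers. ``missing`` lists canonical fields that were blank in the
    source file — records are flagged, never silently dropped.
    """

    id: str
    participates: int
    certainty_grid: tuple[Certainty, ...] | None
    items: Mapping[str, int | None]
    seen: int | None
    age: float | None
    gender: int | None
    education: int | None
    income: float | None
    consumptive: int | None
    nonconsumptive: int | None
    missing: frozenset[str] = frozenset()

    def validate(self, bids: BidSchedule = DEFAULT_BIDS) -> None:
        rid = self.id
        if self.participates not in (0, 1):
            raise SurveyValidationError(f"respondent {rid}: participates must be 0/1")
        if self.participates == 1 and self.certainty_grid is not None:
            if len(self.certainty_grid) != len(bids):
                raise SurveyValidationError(
                    f"respondent {rid}: certainty grid length "
                    f"{len(self.certainty_grid)} != {len(bids)} bids"
                )
        if self.participates == 0 and self.certainty_grid is not None:
            raise SurveyValidationError(
                f"respondent {rid}: non-participant carries a certainty grid"
            )
        for name, value in self.items.items():
            if value is not None and not 1 <= value <= 5:
                raise SurveyValidationError(
                    f"respondent {rid}: item {name}={value} outside 1..5"
                )
        for name in _BINARY_FIELDS:
            value = getattr(self, name)
            if value is not None and value not in (0, 1):
                raise SurveyValidationError(
                    f"respondent {rid}: {name}={value} not binary"
                )
        for name, (lo, hi) in _ORDINAL_RANGES.items():
            value = getattr(self, name)
            if value is not None and not lo <= value <= hi:
                raise SurveyValidationError(
                    f"respondent {rid}: {name}={value} outside {lo}..{hi}"
                )
        if self.age is not None and self.age < 18:
            raise SurveyValidationError(f"respondent {rid}: age {self.age} < 18")
        if self.income is not None and self.income < 0:
            raise SurveyValidationError(f"respondent {rid}: negative income")


def _parse_certainty(raw: str, row_id: str, column: str) -> Certainty:
    text = raw.strip().lower()
    if text in LABEL_TO_CERTAINTY:
        return LABEL_TO_CERTAINTY[text]
    try:
        code = int(text)
    except ValueError:
        raise SurveyValidationError(
            f"respondent {row_id}: unknown certainty {raw!r} in {column}"
        ) from None
    if code not in (1, 2, 3, 4, 5):
        raise SurveyValidationError(
            f"respondent {row_id}: certainty code {code} in {column} outside 1..5"
        )
    return Certainty(code)


def _parse_number(raw: str, kind, row_id: str, column: str):
    text = raw.strip()
    if text == "":
        return None
    try:
        value = kind(float(text)) if kind is int else kind(text)
    except ValueError:
        raise SurveyValidationError(
            f"respondent {row_id}: cannot parse {column}={raw!r}"
        ) from None
    if kind is int and float(text) != value:
        raise SurveyValidationError(
            f"respondent {row_id}: {column}={raw!r} is not an integer"
        )
    return value


def read_survey(
    path: str | Path,
    schema: SurveySchema | None = None,
    bids: BidSchedule = DEFAULT_BIDS,
) -> list[RespondentRecord]:
    """Read a survey CSV into validated :class:`RespondentRecord` objects.

    Certainty cells accept both labels (``probably_yes``) and integer
    codes (4). Blank cells are flagged in ``record.missing`` rather than
    dropped. Raises :class:`SchemaError` for absent mandatory columns and
    :class:`SurveyValidationError` (citing the row id) for out-of-range
    values.
    """
    schema = schema or SurveySchema()
    frame = pd.read_csv(path, sep=schema.delimiter, dtype=str, keep_default_na=False)
    mandatory = ("id", "participates") + bids.columns + ITEM_COLUMNS + COVARIATE_COLUMNS
    rename = {}
    for canonical in mandatory:
        actual = schema.file_column(canonical)
        if actual not in frame.columns:
            raise SchemaError(f"mandatory column {actual!r} missing from {path}")
        rename[actual] = canonical
    frame = frame.rename(columns=rename)

    records: list[RespondentRecord] = []
    for _, row in frame.iterrows():
        rid = row["id"].strip()
        missing: set[str] = set()
        participates = _parse_number(row["participates"], int, rid, "participates")
        if participates is None:
            raise SurveyValidationError(f"respondent {rid}: blank participation answer")

        grid: tuple[Certainty, ...] | None = None
        if participates == 1:
            cells = [row[c].strip() for c in bids.columns]
            if any(cell == "" for cell in cells):
                missing.add("certainty_grid")
            else:
                grid = tuple(
                    _parse_certainty(cell, rid, col)
                    for cell, col in zip(cells, bids.columns)
                )

        items: dict[str, int | None] = {}
        for col in ITEM_COLUMNS:
            value = _parse_number(row[col], int, rid, col)
            items[col] = value
            if value is None:
                missing.add(col)

        numbers = {}
        for col in COVARIATE_COLUMNS:
            kind = float if col in ("age", "income") else int
            value = _parse_number(row[col], kind, rid, col)
            numbers[col] = value
            if value is None:
                missing.add(col)

        record = RespondentRecord(
            id=rid,
            participates=participates,
            certainty_grid=grid,
            items=items,
            missing=frozenset(missing),
            **numbers,
        )
        record.validate(bids)
        records.append(record)
    return records


def write_survey(
    records: Iterable[RespondentRecord],
    path: str | Path,
    schema: SurveySchema | None = None,
    bids: BidSchedule = DEFAULT_BIDS,
    certainty_as: str = "label",
) -> Path:
    """Write records to CSV so that :func:`read_survey` round-trips them.

    ``certainty_as`` selects the on-disk certainty dialect: ``"label"``
    or ``"code"`` (5 = definitely yes … 1 = definitely no).
    """
    if certainty_as not in ("label", "code"):
        raise ValueError(f"unknown certainty dialect {certainty_as!r}")
    schema = schema or SurveySchema()
    rows = []
    for rec in records:
        row: dict[str, object] = {"id": rec.id, "participates": rec.participates}
        for col, amount in zip(bids.columns, bids.amounts):
            if rec.certainty_grid is None:
                row[col] = ""
            else:
                level = rec.certainty_grid[bids.amounts.index(amount)]
                row[col] = CERTAINTY_LABELS[level] if certainty_as == "label" else int(level)
        for col in ITEM_COLUMNS:
            value = rec.items.get(col)
            row[col] = "" if value is None else value
        for col in COVARIATE_COLUMNS:
            value = getattr(rec, col)
            row[col] = "" if value is None else value
        rows.append(row)
    columns = ["id", "participates", *bids.columns, *ITEM_COLUMNS, *COVARIATE_COLUMNS]
    frame = pd.DataFrame(rows, columns=columns)
    frame = frame.rename(columns={c: schema.file_column(c) for c in columns})
    path = Path(path)
    frame.to_csv(path, sep=schema.delimiter, index=False)
    return path


def records_to_frame(records: Sequence[RespondentRecord]) -> pd.DataFrame:
    """Tabulate records: id index, participation, raw items, covariates."""
    data = {
        "participates": [r.participates for r in records],
        **{c: [r.items.get(c) for r in records] for c in ITEM_COLUMNS},
        **{c: [getattr(r, c) for r in records] for c in COVARIATE_COLUMNS},
    }
    return pd.DataFrame(data, index=pd.Index([r.id for r in records], name="id"))


# --- sample representativeness -------------------------------------------

#: Census reference structure of the study region used for
#: representativeness checks (gender / age class / education shares).
DEFAULT_POPULATION_PROPORTIONS: dict[str, dict[str, float]] = {
    "gender": {"female": 0.507, "male": 0.493},
    "age_class": {"18_34": 0.299, "35_54": 0.347, "55_plus": 0.354},
    "education": {"higher": 0.192, "lower": 0.808},
}


def age_class(age: float) -> str:
    """Representativeness age classes: 18–34, 35–54, 55+."""
    if age < 18:
        raise SurveyValidationError(f"age {age} < 18")
    if age < 35:
        return "18_34"
    if age < 55:
        return "35_54"
    return "55_plus"


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class SampleSummary:
    n_completed: int
    n_approached: int
    response_rate: float
    group_proportions: dict[str, dict[str, float]]
    gof_tests: dict[str, GofResult]

    @property
    def response_rate_percent(self) -> int:
        return round(100 * self.response_rate)

    def to_dict(self) -> dict:
        return {
            "n_completed": self.n_completed,
            "n_approached": self.n_approached,
            "response_rate": self.response_rate,
            "response_rate_percent": self.response_rate_percent,
            "group_proportions": self.group_proportions,
            "gof_tests": {
                k: {"statistic": g.statistic, "df": g.df, "p_value": g.p_value}
                for k, g in self.gof_tests.items()
            },
        }


def gof_chi_square(
    observed_counts: Sequence[float], expected_proportions: Sequence[float]
) -> GofResult:
    """Pearson goodness-of-fit test of observed counts against reference
    proportions: X² = Σ (O−E)²/E with E = n·p, df = k−1, upper-tail p.
    """
    observed = np.asarray(observed_counts, dtype=float)
    proportions = np.asarray(expected_proportions, dtype=float)
    if observed.shape != proportions.shape or observed.ndim != 1:
        raise ValueError("observed counts and expected proportions must be 1-d and equal length")
    if np.any(observed < 0):
        raise ValueError("observed counts must be nonnegative")
    if np.any(proportions <= 0):
        raise DegenerateExpectationError("expected proportions must be strictly positive")
    if abs(proportions.sum() - 1.0) > 1e-8:
        raise ValueError("expected proportions must sum to 1")
    n = observed.sum()
    if n == 0:
        raise DegenerateExpectationError("zero total count gives zero expectations")
    statistic, p_value = stats.chisquare(observed, f_exp=n * proportions)
    return GofResult(float(statistic), len(observed) - 1, float(p_value))


def _stratum_of(record: RespondentRecord, stratification: str) -> str | None:
    if stratification == "gender":
        if record.gender is None:
            return None
        return "female" if record.gender == 1 else "male"
    if stratification == "age_class":
        return None if record.age is None else age_class(record.age)
    if stratification == "education":
        if record.education is None:
            return None
        return "higher" if record.education == 1 else "lower"
    raise ValueError(f"unknown stratification {stratification!r}")


def summarize_sample(
    records: Sequence[RespondentRecord],
    n_approached: int,
    population_proportions: Mapping[str, Mapping[str, float]] | None = None,
) -> SampleSummary:
    """Response rate plus per-stratification chi-square comparisons of the
    sample structure against reference population proportions."""
    population = population_proportions or DEFAULT_POPULATION_PROPORTIONS
    n_completed = len(records)
    if n_approached < n_completed:
        raise ValueError("n_approached must be >= number of completed records")
    if n_completed == 0:
        raise ValueError("no completed records")

    proportions: dict[str, dict[str, float]] = {}
    gof: dict[str, GofResult] = {}
    for stratification, reference in population.items():
        labels = list(reference)
        counts = {label: 0 for label in labels}
        for rec in records:
            stratum = _stratum_of(rec, stratification)
            if stratum is not None:
                counts[stratum] += 1
        total = sum(counts.values())
        if total == 0:
            raise DegenerateExpectationError(
                f"no usable records for stratification {stratification!r}"
            )
        proportions[stratification] = {k: counts[k] / total for k in labels}
        gof[stratification] = gof_chi_square(
            [counts[k] for k in labels], [reference[k] for k in labels]
        )
    return SampleSummary(
        n_completed=n_completed,
        n_approached=n_approached,
        response_rate=n_completed / n_approached,
        group_proportions=proportions,
        gof_tests=gof,
    )
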