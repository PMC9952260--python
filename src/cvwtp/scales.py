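"""Psychometric composite scoring and reliability.

Each multi-item Likert battery (attitude toward the species, knowledge,
intention to participate in conservation actions, moralistic and
dominionistic worldviews) is scored as the mean of its items after
reverse coding, keeping composites on the raw 1–5 metric. Internal
consistency is reported as Cronbach's alpha with corrected item-total
correlations and alpha-if-item-deleted.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd


class DegenerateScaleError(ValueError):
    """The item battery has zero total variance — alpha is undefined."""


@dataclass(frozen=True)
class ScaleDefinition:
    """An item battery: ordered item columns, the subset that is
    reverse-coded (keyed-false statements), and the response range."""

    name: str
    items: tuple[str, ...]
    reverse_coded: frozenset[str] = frozenset()
    response_range: tuple[int, int] = (1, 5)

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "reverse_coded", frozenset(self.reverse_coded))
        if not self.reverse_coded <= set(self.items):
            raise ValueError(f"scale {self.name}: reverse_coded not a subset of items")
        lo, hi = self.response_range
        if hi <= lo:
            raise ValueError(f"scale {self.name}: empty response range")


#: Default scale definitions. Knowledge items k4–k6 are the keyed-false
#: statements and are reverse-coded; worldview items split into
#: moralistic (w1–w3) and dominionistic (w4–w6) subscales.
DEFAULT_SCALES: dict[str, ScaleDefinition] = {
    "attitude": ScaleDefinition("attitude", tuple(f"a{i}" for i in range(1, 7))),
    "knowledge": ScaleDefinition(
        "knowledge",
        tuple(f"k{i}" for i in range(1, 7)),
        reverse_coded=frozenset({"k4", "k5", "k6"}),
    ),
    "conservation_actions": ScaleDefinition(
        "conservation_actions", tuple(f"c{i}" for i in range(1, 6))
    ),
    "moralistic": ScaleDefinition("moralistic", ("w1", "w2", "w3")),
    "dominionistic": ScaleDefinition("dominionistic", ("w4", "w5", "w6")),
}


def reverse_code(values, response_range: tuple[int, int] = (1, 5)):
    """Mirror responses within the scale range: x → (min + max) − x."""
    lo, hi = response_range
    return (lo + hi) - np.asarray(values, dtype=float)


def score_composite(items: pd.DataFrame, scale: ScaleDefinition) -> pd.Series:
    """Per-respondent composite: mean of the scale's items after reverse
    coding. Missing items propagate to a missing composite; out-of-range
    values raise, citing the respondent.
    """
    missing_cols = [c for c in scale.items if c not in items.columns]
    if missing_cols:
        raise KeyError(f"scale {scale.name}: item columns {missing_cols} absent")
    lo, hi = scale.response_range
    block = items[list(scale.items)].astype(float)
    bad = (block < lo) | (block > hi)
    if bad.to_numpy(na_value=False).any():
        rows = block.index[bad.any(axis=1)].tolist()
        raise ValueError(
            f"scale {scale.name}: item values outside {lo}..{hi} "
            f"for respondents {rows[:5]}"
        )
    for col in scale.reverse_coded:
        block[col] = reverse_code(block[col], scale.response_range)
    return block.mean(axis=1, skipna=False).rename(scale.name)


@dataclass(frozen=True)
class ReliabilityReport:
    alpha: float
    item_total: pd.Series
    alpha_if_deleted: pd.Series


def _alpha(matrix: np.ndarray) -> float:
    k = matrix.shape[1]
    item_var = matrix.var(axis=0, ddof=1)
    total_var = matrix.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DegenerateScaleError("zero variance of the item sum")
    return k / (k - 1) * (1.0 - item_var.sum() / total_var)


def cronbach_alpha(item_matrix: pd.DataFrame) -> ReliabilityReport:
    """Cronbach's alpha with per-item diagnostics.

    alpha = k/(k−1) · (1 − Σ s²_i / s²_total), sample (n−1) variances.
    Corrected item-total correlation correlates each item with the sum
    of the remaining items; alpha-if-deleted recomputes alpha without
    the focal item (requires ≥ 3 items, else NaN).
    """
    frame = pd.DataFrame(item_matrix).astype(float)
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 items")
    if frame.shape[0] < 3:
        raise ValueError("need at least 3 respondents")
    if frame.isna().any().any():
        frame = frame.dropna()
        if frame.shape[0] < 3:
            raise ValueError("fewer than 3 complete respondents")
    matrix = frame.to_numpy()
    alpha = _alpha(matrix)

    item_total = {}
    alpha_del = {}
    for j, col in enumerate(frame.columns):
        rest = np.delete(matrix, j, axis=1).sum(axis=1)
        focal = matrix[:, j]
        if focal.std(ddof=1) == 0 or rest.std(ddof=1) == 0:
            item_total[col] = np.nan
        else:
            item_total[col] = float(np.corrcoef(focal, rest)[0, 1])
        if matrix.shape[1] >= 3:
            alpha_del[col] = _alpha(np.delete(matrix, j, axis=1))
        else:
            alpha_del[col] = np.nan
    return ReliabilityReport(
        alpha=float(alpha),
        item_total=pd.Series(item_total, name="item_total"),
        alpha_if_deleted=pd.Series(alpha_del, name="alpha_if_deleted"),
    )


def score_all(items: pd.DataFrame, scales: dict[str, ScaleDefinition] | None = None) -> pd.DataFrame:
    """Score every scale in ``scales`` (default battery) into one frame."""
    scales = scales or DEFAULT_SCALES
    return pd.concat([score_composite(items, s) for s in scales.values()], axis=1)
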