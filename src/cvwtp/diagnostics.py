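"""Pre-model multicollinearity screening.

Variance inflation factors (stepwise removal of the worst offender, as
in the usual stepwise-VIF workflow) and a Spearman rank-correlation
matrix, with configurable thresholds (defaults: VIF < 5, |rho| < 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_VIF_THRESHOLD = 5.0
DEFAULT_RHO_THRESHOLD = 0.7

# Auxiliary R-squared this close to 1 is treated as exact linear dependence.
_R2_SINGULAR = 1.0 - 1e-10


@dataclass(frozen=True)
class CollinearityReport:
    vif: pd.Series
    spearman: pd.DataFrame
    retained: list[str]
    dropped: list[str]
    rho_exceedances: list[tuple[str, str, float]]

    def to_dict(self) -> dict:
        return {
            "vif": {k: (None if np.isinf(v) else float(v)) for k, v in self.vif.items()},
            "retained": self.retained,
            "dropped": self.dropped,
            "rho_exceedances": [
                {"a": a, "b": b, "rho": float(r)} for a, b, r in self.rho_exceedances
            ],
        }


def _single_vif(design: np.ndarray, j: int) -> float:
    """VIF_j = 1/(1−R²_j) from regressing column j on the others + intercept."""
    y = design[:, j]
    others = np.delete(design, j, axis=1)
    X = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return np.nan  # constant column: undefined rather than inflated
    r2 = 1.0 - (resid**2).sum() / sst
    if r2 >= _R2_SINGULAR:
        return np.inf
    return 1.0 / (1.0 - r2)


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """VIF per covariate (binary/ordinal columns enter as numeric)."""
    frame = pd.DataFrame(design).astype(float)
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 covariates")
    if frame.shape[0] <= frame.shape[1]:
        raise ValueError("need more respondents than covariates")
    matrix = frame.to_numpy()
    return pd.Series(
        {col: _single_vif(matrix, j) for j, col in enumerate(frame.columns)},
        name="vif",
    )


def spearman_matrix(design: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho with average-rank ties. Constant columns give
    NaN against every other column (undefined correlation), unit diagonal."""
    frame = pd.DataFrame(design).astype(float)
    if frame.shape[0] < 3:
        raise ValueError("need at least 3 respondents")
    cols = list(frame.columns)
    import warnings

    with warnings.catch_warnings():
        # constant columns are reported as NaN below, not warned about
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(frame.to_numpy(), axis=0).statistic
    if np.isscalar(rho):  # two-column case returns a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.asarray(rho, dtype=float)
    constant = frame.nunique().to_numpy() <= 1
    for i in np.flatnonzero(constant):
        rho[i, :] = np.nan
        rho[:, i] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=cols, columns=cols)


def vif_screen(
    design: pd.DataFrame,
    threshold: float = DEFAULT_VIF_THRESHOLD,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
) -> CollinearityReport:
    """Stepwise VIF screen: repeatedly drop the covariate with the largest
    VIF ≥ threshold and recompute, until all remaining VIFs pass. Exact
    linear dependence surfaces as an infinite VIF, not a crash. The
    report also lists |rho| ≥ rho_threshold Spearman pairs.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    frame = pd.DataFrame(design).astype(float)
    full_vif = compute_vif(frame)
    spearman = spearman_matrix(frame)

    dropped: list[str] = []
    current = frame
    while current.shape[1] >= 2:
        vif = compute_vif(current)
        worst = vif.idxmax()
        if not (vif[worst] >= threshold):  # NaN-safe: NaN never drops
            break
        dropped.append(worst)
        current = current.drop(columns=[worst])

    exceed = []
    cols = list(spearman.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = spearman.loc[a, b]
            if np.isfinite(r) and abs(r) >= rho_threshold:
                exceed.append((a, b, float(r)))

    return CollinearityReport(
        vif=full_vif,
        spearman=spearman,
        retained=[c for c in frame.columns if c not in dropped],
        dropped=dropped,
        rho_exceedances=exceed,
    )
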