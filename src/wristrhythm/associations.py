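"""Residualized association statistics for rhythm-cognition analyses.

The scheme: each cognitive outcome is first adjusted by taking residuals
from an OLS regression on the confounders (age, sex, education, recording
length); each rhythm predictor is then related to the adjusted outcome in a
simple regression with both variables z-scored, so the slope is a
standardized beta (equal to the Pearson correlation) with dof = n - 2.
Within the family of intradaily-variability timescales, p values are
converted to Benjamini-Hochberg false-discovery-rate q values.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "residualize_outcome",
    "standardized_association",
    "welch_unequal_var",
    "bh_adjust",
    "association_scan",
]

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    predictor: str
    outcome: str
    beta_std: float
    ci_low: float
    ci_high: float
    t_stat: float
    dof: int
    p_value: float
    q_value: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def residualize_outcome(outcome: np.ndarray, confounders: np.ndarray) -> np.ndarray:
    """OLS residuals of ``outcome`` on ``confounders`` plus an intercept.

    Residuals are mean-zero and orthogonal to every confounder column.
    Raises on rank deficiency, naming the offending column indices.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(confounders, dtype=float)])
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than confounders + intercept")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = []
        for j in range(1, X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(j - 1)
        raise ValueError(f"rank-deficient confounder design; collinear columns {collinear}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return (v - v.mean()) / sd


def standardized_association(
    predictor: np.ndarray,
    residualized_outcome: np.ndarray,
    predictor_name: str = "predictor",
    outcome_name: str = "outcome",
    ci_level: float = 0.95,
) -> AssociationResult:
    """Simple regression of the z-scored adjusted outcome on the z-scored
    predictor: slope = standardized beta = Pearson r, dof = n - 2, t-based CI.
    """
    x = _zscore(predictor)
    y = _zscore(residualized_outcome)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("need n >= 4 and equal-length vectors")
    dof = n - 2
    beta = float(np.dot(x, y) / np.dot(x, x))
    resid = y - beta * x
    se = float(np.sqrt(np.sum(resid**2) / dof / np.dot(x, x)))
    if se == 0:
        t_stat, p = np.inf * np.sign(beta), 0.0
    else:
        t_stat = beta / se
        p = float(2 * stats.t.sf(abs(t_stat), dof))
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2, dof))
    return AssociationResult(
        predictor=predictor_name,
        outcome=outcome_name,
        beta_std=beta,
        ci_low=beta - tcrit * se,
        ci_high=beta + tcrit * se,
        t_stat=float(t_stat),
        dof=dof,
        p_value=p,
    )


def welch_unequal_var(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t statistic, Satterthwaite dof, and two-sided p.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2);
    dof = (s1^2/n1 + s2^2/n2)^2 / [ (s1^2/n1)^2/(n1-1) + (s2^2/n2)^2/(n2-1) ].
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t_stat = (mean1 - mean2) / np.sqrt(v1 + v2)
    dof = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2 * stats.t.sf(abs(t_stat), dof))
    return float(t_stat), float(dof), p


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q values for one test family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def association_scan(
    table: pd.DataFrame,
    confounders: list[str],
    outcomes: list[str],
    predictors: list[str],
    bh_families: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Run the residualize-then-regress scan over every predictor x outcome.

    Rows with missing values in any modeled column are listwise-deleted (the
    dropped count is logged). ``bh_families`` maps a family name to the
    predictor columns whose p values are BH-adjusted together within each
    outcome (e.g. the 12 IV timescales); predictors outside any family keep
    q = NaN.
    """
    modeled = list(dict.fromkeys(confounders + outcomes + predictors))
    missing_cols = [c for c in modeled if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table missing columns {missing_cols}")
    complete = table[modeled].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("listwise-deleted %d rows with missing modeled values", n_dropped)
    data = table.loc[complete]
    if len(data) < len(confounders) + 3:
        raise ValueError("too few complete rows for the confounder model")

    X = data[confounders].to_numpy(dtype=float)
    rows = []
    for outcome in outcomes:
        resid = residualize_outcome(data[outcome].to_numpy(dtype=float), X)
        for pred in predictors:
            res = standardized_association(
                data[pred].to_numpy(dtype=float), resid, pred, outcome
            )
            rows.append(res.to_dict())
    out = pd.DataFrame(rows)
    out["family"] = None
    out["q_value"] = np.nan
    if bh_families:
        for fam, members in bh_families.items():
            out.loc[out["predictor"].isin(members), "family"] = fam
            for outcome in outcomes:
                sel = (out["outcome"] == outcome) & (out["family"] == fam)
                if sel.any():
                    out.loc[sel, "q_value"] = bh_adjust(out.loc[sel, "p_value"].to_numpy())
    return out
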