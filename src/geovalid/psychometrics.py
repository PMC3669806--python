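"""Standardized questionnaire indicators and unit-weighted factor scores.

The Active Lifestyle (AL) factor is the unit-weighted average of the
standardized Positive Affect, Mini-K life-history, Conscientiousness,
Extraversion and Agreeableness totals; the Sedentary Lifestyle (SL)
factor averages standardized BDI, CES-D, Negative Affect, reversed
Satisfaction-with-Life and Neuroticism totals.  Unit weighting (±1 on
z-scores) is the small-sample alternative to estimated factor loadings:
robust, transparent, and adequate when indicators correlate ≥ ~0.6 with
their composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INDICATOR_RANGES",
    "FactorSpec",
    "AL_SPEC",
    "SL_SPEC",
    "standardize_columns",
    "unit_weighted_score",
    "cronbach_alpha",
    "factor_indicator_corr",
]

# possible score ranges for the standard instruments (total scores)
INDICATOR_RANGES: dict[str, tuple[float, float]] = {
    "BDI": (0, 63),
    "CESD": (0, 60),
    "NA": (10, 50),
    "PA": (10, 50),
    "SWL": (5, 35),
    "N": (-24, 24),
    "E": (-24, 24),
    "A": (-24, 24),
    "C": (-24, 24),
    "O": (-24, 24),
    "MK": (-3, 3),
}


@dataclass
class FactorSpec:
    """Definition of a unit-weighted composite.

    ``reverse`` lists indicators negated after standardization (the
    composite's sign convention); a score is emitted only when at least
    ``min_present`` indicators are non-missing.
    """

    name: str
    indicators: list[str]
    reverse: list[str] = field(default_factory=list)
    min_present: int = 3

    def __post_init__(self) -> None:
        unknown = set(self.reverse) - set(self.indicators)
        if unknown:
            raise ValueError(f"reverse-scored indicators {sorted(unknown)} not in indicator list")


AL_SPEC = FactorSpec("AL", ["PA", "MK", "C", "E", "A"])
SL_SPEC = FactorSpec("SL", ["BDI", "CESD", "NA", "SWL", "N"], reverse=["SWL"])


def standardize_columns(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """z-score each column over its non-missing entries (ddof=1).

    Raises on a zero-variance column, naming it.
    """
    out = table.copy()
    for col in columns or table.columns:
        x = out[col]
        if x.notna().sum() < 2:
            raise ValueError(f"column {col!r} has fewer than 2 non-missing values")
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (x - x.mean()) / sd
    return out


def unit_weighted_score(ztable: pd.DataFrame, spec: FactorSpec) -> pd.Series:
    """Mean of available indicator z-scores, reverse set negated.

    Missing (NaN) where fewer than ``spec.min_present`` indicators are
    available.  Invariant to indicator order; each available indicator
    carries weight 1/#available.
    """
    missing_cols = set(spec.indicators) - set(ztable.columns)
    if missing_cols:
        raise KeyError(f"indicator table lacks columns {sorted(missing_cols)} required by factor {spec.name}")
    z = ztable[spec.indicators].copy()
    for col in spec.reverse:
        z[col] = -z[col]
    score = z.mean(axis=1, skipna=True)
    score[z.notna().sum(axis=1) < spec.min_present] = np.nan
    score.name = spec.name
    return score


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha: (k/(k−1))·(1 − Σ item variances / total variance).

    Requires ≥2 items, ≥3 complete rows; variance denominator n−1.
    """
    x = np.asarray(items, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    if n < 3:
        raise ValueError("alpha needs at least 3 complete rows")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    item_vars = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def factor_indicator_corr(scores: pd.DataFrame, ztable: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson r, p and n for each factor × indicator.

    ``scores`` holds factor columns (e.g. AL, SL); every cell uses the
    subjects with both the factor and the indicator observed (minimum 3).
    """
    rows = []
    for fac in scores.columns:
        for ind in ztable.columns:
            pair = pd.concat([scores[fac], ztable[ind]], axis=1).dropna()
            n = len(pair)
            if n < 3:
                rows.append({"factor": fac, "indicator": ind, "r": np.nan, "p": np.nan, "n": n})
                continue
            r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append({"factor": fac, "indicator": ind, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)
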