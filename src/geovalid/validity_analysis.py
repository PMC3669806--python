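"""Convergent-validity correlations and split-plot GLMs for NPV.

The design is a split plot: between-subjects predictors (the AL and SL
lifestyle factors and their interaction, plus the subject block factor
SID) are crossed with within-subjects factors (Time = weekday vs weekend,
and two planned orthogonal method contrasts C1 = Diary vs Google and
C2 = mean(self-report) vs GPS).  Variance is partitioned hierarchically
with Type-I (sequential) sums of squares — each term's SS is the drop in
residual SS when the term enters, in the declared order — and every
tested term is referred to its own error stratum (e.g. the lifestyle
factors against the subject term, Time against Time×SID), in the
expected-mean-squares tradition rather than via a mixed-model fit.

Effect sizes: semi-partial R² is a term's SS over the corrected total SS;
partial R² is the semi-partial divided by its broad stratum's
(between-subjects or within-subjects) semi-partial total, so each
stratum's partials sum to 1 and the two stratum totals sum to the model
R².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson_ci",
    "correlation_panel",
    "method_contrasts",
    "build_long_table",
    "TermSpec",
    "MODEL1_TERMS",
    "MODEL2_TERMS",
    "AnovaResult",
    "SplitPlotAnova",
    "sequential_anova",
    "effect_sizes",
    "fit_both_orders",
    "final_parameter_fit",
    "missingness_screen",
    "PUBLISHED_SPLITPLOT_EFFECT_SIZES",
]

METHODS = ("Diary", "Google", "GPS")

# planned orthogonal method contrasts: C1 compares the two self-report
# methods; C2 compares their average against the GPS
_C1 = {"Diary": 1.0, "Google": -1.0, "GPS": 0.0}
_C2 = {"Diary": 0.5, "Google": 0.5, "GPS": -1.0}

TIME_CODES = {"weekday": -0.5, "weekend": 0.5}


# ---------------------------------------------------------------------------
# correlations


def pearson_ci(x, y) -> dict:
    """Pairwise-complete Pearson r with p, n and a Fisher-z 95% CI.

    p is two-sided from t = r·sqrt((n−2)/(1−r²)); the CI is
    tanh(atanh(r) ± 1.96/sqrt(n−3)).  Returns NaNs (with a reason) below
    n=4 or at zero variance.
    """
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    ok = x.notna() & y.notna()
    n = int(ok.sum())
    if n < 4:
        return {"r": np.nan, "p": np.nan, "n": n, "ci_low": np.nan, "ci_high": np.nan, "reason": "n < 4"}
    xs, ys = x[ok].to_numpy(), y[ok].to_numpy()
    if xs.std() == 0 or ys.std() == 0:
        return {"r": np.nan, "p": np.nan, "n": n, "ci_low": np.nan, "ci_high": np.nan, "reason": "zero variance"}
    r = float(np.corrcoef(xs, ys)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
        lo = hi = float(np.sign(r))
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    return {"r": r, "p": p, "n": n, "ci_low": lo, "ci_high": hi, "reason": ""}


def correlation_panel(npv_wide: pd.DataFrame, methods=METHODS) -> pd.DataFrame:
    """All method-pair correlations for one period, pairwise-complete.

    ``npv_wide``: one row per subject, one column per method; NaN marks a
    missing measurement.  One row per unordered pair.
    """
    rows = []
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            cell = pearson_ci(npv_wide[a], npv_wide[b])
            rows.append({"method_a": a, "method_b": b, **cell})
    return pd.DataFrame(rows)


def method_contrasts() -> pd.DataFrame:
    """The planned contrast code table (rows: methods; columns C1, C2)."""
    return pd.DataFrame({"C1": _C1, "C2": _C2}).loc[list(METHODS)]


# ---------------------------------------------------------------------------
# long table


def build_long_table(npv: pd.DataFrame, factors: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the subject × period × method long table for the GLMs.

    ``npv``: columns ``subject_id``, ``method``, ``period``, ``npv`` with
    period in {weekday, weekend} (4-day totals are excluded here).
    ``factors``: per-subject AL/SL scores (index or ``subject_id``
    column); subjects without scores keep their rows with AL/SL NaN — the
    model fit drops them listwise and reports the count.

    Output columns: SID, method, period, NPV, Time (−½ weekday, +½
    weekend), C1, C2, AL, SL.
    """
    df = npv.copy()
    df = df[df["period"].isin(TIME_CODES)]
    df = df.dropna(subset=["npv"])
    out = pd.DataFrame(
        {
            "SID": df["subject_id"].astype(str),
            "method": df["method"],
            "period": df["period"],
            "NPV": df["npv"].astype(float),
            "Time": df["period"].map(TIME_CODES),
            "C1": df["method"].map(_C1),
            "C2": df["method"].map(_C2),
        }
    )
    if out["C1"].isna().any():
        bad = sorted(set(df.loc[out["C1"].isna(), "method"]))
        raise ValueError(f"unknown method labels {bad}; expected {METHODS}")
    if factors is not None:
        fac = factors.copy()
        if "subject_id" in fac.columns:
            fac = fac.set_index("subject_id")
        fac.index = fac.index.astype(str)
        out["AL"] = out["SID"].map(fac["AL"]).astype(float)
        out["SL"] = out["SID"].map(fac["SL"]).astype(float)
    else:
        out["AL"] = np.nan
        out["SL"] = np.nan
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sequential split-plot engine


@dataclass
class TermSpec:
    """Ordered model terms plus the error-stratum map.

    ``terms``: entry order; components of a term are separated by ``:``
    (e.g. ``"Time:SID"``).  ``error_strata`` maps each tested term to its
    denominator term, or ``"residual"``.  ``bs_terms`` lists the
    between-subjects terms (for the effect-size strata); everything else
    is within-subjects.
    """

    terms: list[str]
    error_strata: dict[str, str]
    bs_terms: tuple[str, ...] = ("AL", "SL", "AL:SL", "SID")

    def __post_init__(self) -> None:
        for t in self.terms:
            d = self.error_strata.get(t)
            if d is None:
                raise ValueError(f"term {t!r} has no declared error stratum")
            if d != "residual" and d not in self.terms:
                raise ValueError(f"denominator {d!r} of term {t!r} is not a model term")


def _standard_strata(first: str, second: str) -> dict[str, str]:
    inter = f"{first}:{second}"
    return {
        first: "SID",
        second: "SID",
        inter: "SID",
        "SID": "residual",
        "Time": "Time:SID",
        f"Time:{first}": "Time:SID",
        f"Time:{second}": "Time:SID",
        f"Time:{inter}": "Time:SID",
        "C2": "C2:SID",
        f"{first}:C2": "C2:SID",
        f"{second}:C2": "C2:SID",
        f"{inter}:C2": "C2:SID",
        "C1": "C1:SID",
        f"{first}:C1": "C1:SID",
        f"{second}:C1": "C1:SID",
        f"{inter}:C1": "C1:SID",
        "Time:C2": "residual",
        "Time:C1": "residual",
        "Time:SID": "residual",
        "C2:SID": "residual",
        "C1:SID": "residual",
    }


def _standard_terms(first: str, second: str) -> list[str]:
    inter = f"{first}:{second}"
    return [
        first,
        second,
        inter,
        "SID",
        "Time",
        "C2",
        "C1",
        "Time:C2",
        "Time:C1",
        f"Time:{first}",
        f"Time:{second}",
        f"Time:{inter}",
        f"{first}:C2",
        f"{second}:C2",
        f"{inter}:C2",
        f"{first}:C1",
        f"{second}:C1",
        f"{inter}:C1",
        "Time:SID",
        "C2:SID",
        "C1:SID",
    ]


#: causal priority to AL (lifestyle factors enter AL-first)
MODEL1_TERMS = TermSpec(_standard_terms("AL", "SL"), _standard_strata("AL", "SL"))
#: causal priority to SL (entry order of AL and SL reversed throughout)
MODEL2_TERMS = TermSpec(_standard_terms("SL", "AL"), _standard_strata("SL", "AL"))


def _term_matrix(term: str, df: pd.DataFrame, sid_dummies: np.ndarray) -> np.ndarray:
    parts = term.split(":")
    numeric = np.ones(len(df))
    has_sid = False
    for p in parts:
        if p == "SID":
            has_sid = True
        else:
            numeric = numeric * df[p].to_numpy(float)
    if has_sid:
        return sid_dummies * numeric[:, None]
    return numeric[:, None]


@dataclass
class AnovaResult:
    """Per-term table plus fit-level summaries."""

    table: pd.DataFrame
    ss_total: float
    ss_residual: float
    df_residual: int
    n_obs: int
    n_dropped: int = 0

    @property
    def model_r2(self) -> float:
        return 1.0 - self.ss_residual / self.ss_total

    @property
    def error_r2(self) -> float:
        return self.ss_residual / self.ss_total

    @property
    def bs_total_r2(self) -> float:
        return float(self.table.loc[self.table["type"] == "BS", "semi_partial_R2"].sum())

    @property
    def ws_total_r2(self) -> float:
        return float(self.table.loc[self.table["type"] == "WS", "semi_partial_R2"].sum())


class SplitPlotAnova:
    """Sequential (Type-I) split-plot GLM with stratum-specific F tests.

    Parameters
    ----------
    spec : TermSpec
        Term order and error-stratum map; defaults to the AL-first model.
    rank_tol : float
        Relative singular-value tolerance for the rank of each term's
        column-space increment on the realized (possibly unbalanced)
        design.

    After :meth:`fit`, ``result_`` holds the :class:`AnovaResult` and
    ``anova_table_`` its per-term table.
    """

    def __init__(self, spec: TermSpec | None = None, rank_tol: float = 1e-8):
        self.spec = spec or MODEL1_TERMS
        self.rank_tol = rank_tol

    def fit(self, long: pd.DataFrame) -> "SplitPlotAnova":
        spec = self.spec
        needed = sorted({p for t in spec.terms for p in t.split(":") if p != "SID"})
        cols = ["NPV", "SID", *needed]
        data = long.dropna(subset=[c for c in cols if c in long.columns])
        n_dropped = len(long) - len(data)
        n = len(data)
        if data["SID"].nunique() < 2:
            raise ValueError("split-plot fit needs at least 2 subjects")
        y = data["NPV"].to_numpy(float)
        sid_dummies = pd.get_dummies(data["SID"]).to_numpy(float)

        # sequential orthogonal projection; Q starts with the intercept
        Q = np.ones((n, 1)) / np.sqrt(n)
        ss: dict[str, float] = {}
        ndf: dict[str, int] = {}
        yty = float(y @ y)
        grand = float((np.ones(n) @ y) ** 2 / n)
        ss_total = yty - grand
        if ss_total <= 0:
            raise ValueError("outcome has zero variance")

        for term in spec.terms:
            X = _term_matrix(term, data, sid_dummies)
            R = X - Q @ (Q.T @ X)
            # second pass stabilizes the projection
            R = R - Q @ (Q.T @ R)
            U, s, _ = np.linalg.svd(R, full_matrices=False)
            if s.size and s[0] > 0:
                rank = int(np.sum(s > self.rank_tol * max(s[0], np.sqrt(n))))
            else:
                rank = 0
            ndf[term] = rank
            if rank == 0:
                ss[term] = 0.0
                continue
            U = U[:, :rank]
            proj = U.T @ y
            ss[term] = float(proj @ proj)
            Q = np.hstack([Q, U])

        ss_residual = yty - float((Q.T @ y) @ (Q.T @ y))
        ss_residual = max(ss_residual, 0.0)
        df_residual = n - Q.shape[1]

        rows = []
        for term in spec.terms:
            denom = spec.error_strata[term]
            if denom == "residual":
                ss_d, df_d = ss_residual, df_residual
            else:
                ss_d, df_d = ss[denom], ndf[denom]
            if df_d <= 0:
                raise ValueError(f"error stratum {denom!r} for term {term!r} has no degrees of freedom")
            if ndf[term] == 0:
                F = np.nan
                p = np.nan
            else:
                ms_t = ss[term] / ndf[term]
                ms_d = ss_d / df_d
                F = ms_t / ms_d if ms_d > 0 else np.inf
                p = float(stats.f.sf(F, ndf[term], df_d)) if np.isfinite(F) else 0.0
            rows.append(
                {
                    "type": "BS" if term in spec.bs_terms else "WS",
                    "term": term,
                    "NDF": ndf[term],
                    "DDF": df_d,
                    "F": F,
                    "p": p,
                    "SS": ss[term],
                }
            )
        table = pd.DataFrame(rows)
        table = effect_sizes(table, ss_total)
        self.result_ = AnovaResult(
            table=table,
            ss_total=ss_total,
            ss_residual=ss_residual,
            df_residual=df_residual,
            n_obs=n,
            n_dropped=n_dropped,
        )
        self.anova_table_ = table
        return self


def effect_sizes(table: pd.DataFrame, ss_total: float) -> pd.DataFrame:
    """Attach semi-partial and partial R² columns to a per-term SS table.

    semi-partial = SS/SS_total; partial = semi-partial / its broad
    (BS or WS) stratum's semi-partial total.
    """
    out = table.copy()
    out["semi_partial_R2"] = out["SS"] / ss_total
    totals = out.groupby("type")["semi_partial_R2"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["partial_R2"] = np.where(totals > 0, out["semi_partial_R2"] / totals, np.nan)
    return out


def sequential_anova(long: pd.DataFrame, spec: TermSpec | None = None) -> AnovaResult:
    """Functional wrapper over :class:`SplitPlotAnova`."""
    return SplitPlotAnova(spec).fit(long).result_


def fit_both_orders(long: pd.DataFrame) -> tuple[AnovaResult, AnovaResult]:
    """Fit the AL-first and SL-first orderings of the same model.

    The joint SS of the lifestyle block {AL, SL, AL×SL} and the model R²
    are identical across orders; only the sequential split between AL and
    SL changes.
    """
    return sequential_anova(long, MODEL1_TERMS), sequential_anova(long, MODEL2_TERMS)


@dataclass
class ParameterFit:
    params: pd.Series
    bse: pd.Series
    n_obs: int


def final_parameter_fit(long: pd.DataFrame) -> ParameterFit:
    """OLS of NPV on AL and Time only (the surviving predictors).

    With Time coded ±½ the intercept estimates the grand per-period mean
    and the Time coefficient the weekend-minus-weekday difference.
    """
    import statsmodels.api as sm

    data = long.dropna(subset=["NPV", "AL", "Time"])
    X = sm.add_constant(data[["AL", "Time"]])
    if len(data) <= X.shape[1]:
        raise ValueError("fewer rows than parameters")
    res = sm.OLS(data["NPV"], X).fit()
    params = res.params.rename({"const": "Intercept"})
    bse = res.bse.rename({"const": "Intercept"})
    return ParameterFit(params=params, bse=bse, n_obs=len(data))


# ---------------------------------------------------------------------------
# missingness screen


def missingness_screen(completion: pd.DataFrame, covariates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Screen task completion (0/1 per subject × task) against covariates.

    For each task column: the completion rate, then one test per
    covariate — Welch two-sample t for numeric covariates (completers vs
    non-completers), chi-square for categoricals.  Degenerate (all-0 or
    all-1) tasks are reported without tests.  Report only; no imputation.
    """
    rows = []
    for task in completion.columns:
        c = completion[task].astype(int)
        rate = float(c.mean())
        if c.nunique() < 2:
            rows.append(
                {"task": task, "completion_rate": rate, "covariate": None, "test": "degenerate", "stat": np.nan, "p": np.nan, "flag": False}
            )
            continue
        for cov in covariates.columns:
            x = covariates[cov]
            if pd.api.types.is_numeric_dtype(x):
                a = x[c == 1].dropna()
                b = x[c == 0].dropna()
                if len(a) < 2 or len(b) < 2:
                    stat, p, test = np.nan, np.nan, "t (insufficient n)"
                else:
                    stat, p = stats.ttest_ind(a, b, equal_var=False)
                    test = "welch-t"
            else:
                tab = pd.crosstab(c, x)
                if tab.shape[0] < 2 or tab.shape[1] < 2:
                    stat, p, test = np.nan, np.nan, "chi2 (insufficient levels)"
                else:
                    stat, p, _, _ = stats.chi2_contingency(tab)
                    test = "chi2"
            rows.append(
                {
                    "task": task,
                    "completion_rate": rate,
                    "covariate": cov,
                    "test": test,
                    "stat": float(stat) if np.isfinite(np.asarray(stat, dtype=float)) else np.nan,
                    "p": float(p) if p == p else np.nan,
                    "flag": bool(p == p and p < alpha),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published reference effect sizes (original GPS-NPV validation study)

#: Semi-partial R² cells of the AL-first split-plot table as published in
#: the original validation study; used to exercise the effect-size
#: accounting identities (partial = semi-partial / stratum total; model R²
#: = BS total + WS total) on real printed values.
PUBLISHED_SPLITPLOT_EFFECT_SIZES = pd.DataFrame(
    [
        ("BS", "AL", 0.068),
        ("BS", "SL", 0.001),
        ("BS", "AL:SL", 0.001),
        ("BS", "SID", 0.381),
        ("WS", "Time", 0.072),
        ("WS", "C2", 0.008),
        ("WS", "C1", 0.011),
        ("WS", "Time:C2", 0.001),
        ("WS", "Time:C1", 0.002),
        ("WS", "Time:AL", 0.001),
        ("WS", "Time:SL", 0.000),
        ("WS", "Time:AL:SL", 0.001),
        ("WS", "AL:C2", 0.002),
        ("WS", "SL:C2", 0.001),
        ("WS", "AL:SL:C2", 0.002),
        ("WS", "AL:C1", 0.001),
        ("WS", "SL:C1", 0.000),
        ("WS", "AL:SL:C1", 0.000),
        ("WS", "Time:SID", 0.105),
        ("WS", "C2:SID", 0.108),
        ("WS", "C1:SID", 0.098),
    ],
    columns=["type", "term", "semi_partial_R2"],
)
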