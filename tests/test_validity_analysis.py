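import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geovalid.synthetic_data import SimConfig, simulate_study
from geovalid.validity_analysis import (
    MODEL1_TERMS,
    MODEL2_TERMS,
    TermSpec,
    build_long_table,
    correlation_panel,
    effect_sizes,
    final_parameter_fit,
    fit_both_orders,
    method_contrasts,
    missingness_screen,
    pearson_ci,
    sequential_anova,
)


def brute_force_sequential_ss(long, terms):
    """Independent oracle: nested OLS refits, SS = drop in residual SS."""
    y = long["NPV"].to_numpy(float)
    n = len(y)
    sid_d = pd.get_dummies(long["SID"]).to_numpy(float)

    def rss(X):
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        return float(r @ r)

    X = np.ones((n, 1))
    prev = rss(X)
    out = {}
    for t in terms:
        numeric = np.ones(n)
        has_sid = False
        for p in t.split(":"):
            if p == "SID":
                has_sid = True
            else:
                numeric = numeric * long[p].to_numpy(float)
        M = sid_d * numeric[:, None] if has_sid else numeric[:, None]
        X = np.hstack([X, M])
        cur = rss(X)
        out[t] = prev - cur
        prev = cur
    return out, prev


def random_small_instance(rng, n_subj=None, p_missing=0.15):
    n_subj = n_subj or int(rng.integers(3, 7))
    rows = []
    for s in range(n_subj):
        for period in ("weekday", "weekend"):
            for m in ("Diary", "Google", "GPS"):
                if rng.random() < p_missing:
                    continue
                rows.append({"subject_id": f"S{s}", "method": m, "period": period, "npv": rng.normal(10, 3)})
    npv = pd.DataFrame(rows)
    fac = pd.DataFrame(
        {"subject_id": [f"S{s}" for s in range(n_subj)], "AL": rng.normal(size=n_subj), "SL": rng.normal(size=n_subj)}
    )
    return build_long_table(npv, fac)


class TestPearsonCi:
    def test_perfect_positive(self):
        out = pearson_ci([1, 2, 3, 4], [2, 4, 6, 8])
        assert out["r"] == pytest.approx(1.0)

    def test_perfect_negative_small_n(self):
        out = pearson_ci([1, 2, 3, 4], [4, 3, 2, 1])
        assert out["r"] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        out = pearson_ci([1, 2, 3, 4], [1, 3, 2, 4])
        assert out["r"] == pytest.approx(0.8)

    def test_p_and_ci_match_reference_formulas(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        out = pearson_ci(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert out["r"] == pytest.approx(r_ref)
        assert out["p"] == pytest.approx(p_ref, rel=1e-9)
        lo, hi = np.tanh(np.arctanh(r_ref) + np.array([-1, 1]) * 1.959963984540054 / np.sqrt(37))
        assert out["ci_low"] == pytest.approx(lo) and out["ci_high"] == pytest.approx(hi)

    def test_too_few_pairs_reported_with_reason(self):
        out = pearson_ci([1, 2, 3], [3, 2, 1])
        assert np.isnan(out["r"]) and out["reason"] == "n < 4"


class TestCorrelationPanel:
    def test_identical_columns_give_unit_correlations(self):
        wide = pd.DataFrame({"Diary": [1, 2, 3, 4, 5], "Google": [1, 2, 3, 4, 5], "GPS": [1, 2, 3, 4, 5]})
        panel = correlation_panel(wide)
        assert np.allclose(panel["r"], 1.0)

    def test_pairwise_n_bookkeeping(self):
        wide = pd.DataFrame(
            {"Diary": [1, 2, 3, 4, np.nan, 6], "Google": [2, 1, 4, 3, 5, np.nan], "GPS": [1, 1, 2, 2, 3, 3]}
        )
        panel = correlation_panel(wide).set_index(["method_a", "method_b"])
        assert panel.loc[("Diary", "Google"), "n"] == 4
        assert panel.loc[("Diary", "GPS"), "n"] == 5


class TestMethodContrasts:
    def test_orthogonal_centered_codes(self):
        codes = method_contrasts()
        assert codes["C1"].sum() == 0 and codes["C2"].sum() == 0
        assert codes["C1"] @ codes["C2"] == 0

    def test_c2_contrasts_self_report_mean_against_gps(self):
        codes = method_contrasts()
        means = pd.Series({"Diary": 10.0, "Google": 14.0, "GPS": 9.0})
        assert (codes["C2"] * means).sum() == pytest.approx(0.5 * 10 + 0.5 * 14 - 9)


class TestBuildLongTable:
    def _npv(self, n_subj, drop=None):
        rows = []
        for s in range(n_subj):
            for period in ("weekday", "weekend", "total4day"):
                for m in ("Diary", "Google", "GPS"):
                    if drop and (f"S{s}", m, period) in drop:
                        continue
                    rows.append({"subject_id": f"S{s}", "method": m, "period": period, "npv": 10})
        return pd.DataFrame(rows)

    def test_fully_observed_row_count(self):
        long = build_long_table(self._npv(96))
        assert len(long) == 576  # 96 subjects x 2 periods x 3 methods

    def test_missing_cell_drops_single_row(self):
        long = build_long_table(self._npv(1, drop={("S0", "GPS", "weekend")}))
        assert len(long) == 5

    def test_time_and_contrast_codes(self):
        long = build_long_table(self._npv(2))
        assert set(long["Time"]) == {-0.5, 0.5}
        gps = long[long["method"] == "GPS"].iloc[0]
        assert gps["C1"] == 0.0 and gps["C2"] == -1.0

    def test_subject_without_factors_kept_with_nan(self):
        fac = pd.DataFrame({"subject_id": ["S0"], "AL": [0.5], "SL": [-0.2]})
        long = build_long_table(self._npv(2), fac)
        assert len(long) == 12
        assert long.loc[long["SID"] == "S1", "AL"].isna().all()


class TestSequentialAnova:
    def test_matches_brute_force_oracle_on_small_instances(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 25:
            long = random_small_instance(rng)
            if long.groupby("SID").size().min() < 2:
                continue
            try:
                res = sequential_anova(long, MODEL1_TERMS)
            except ValueError:
                continue  # degenerate stratum in this draw
            oracle_ss, oracle_rss = brute_force_sequential_ss(long, MODEL1_TERMS.terms)
            got = res.table.set_index("term")["SS"]
            for t in MODEL1_TERMS.terms:
                assert got[t] == pytest.approx(oracle_ss[t], abs=1e-8 * max(1.0, res.ss_total))
            assert res.ss_residual == pytest.approx(oracle_rss, abs=1e-8 * max(1.0, res.ss_total))
            checked += 1

    def test_ss_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            long = random_small_instance(rng, n_subj=6, p_missing=0.1)
            try:
                res = sequential_anova(long, MODEL1_TERMS)
            except ValueError:
                continue
            assert res.table["SS"].sum() + res.ss_residual == pytest.approx(res.ss_total, rel=1e-8)

    def test_balanced_f_time_equals_squared_paired_t(self):
        rng = np.random.default_rng(11)
        rows = []
        for s in range(8):
            base = rng.normal(10, 3)
            for period, tc in (("weekday", -0.5), ("weekend", 0.5)):
                rows.append({"subject_id": f"S{s}", "method": "GPS", "period": period, "npv": base + 2 * tc + rng.normal()})
        npv = pd.DataFrame(rows)
        long = build_long_table(npv)
        spec = TermSpec(["SID", "Time"], {"SID": "residual", "Time": "residual"}, bs_terms=("SID",))
        res = sequential_anova(long, spec)
        F = float(res.table.set_index("term").loc["Time", "F"])
        wide = npv.pivot(index="subject_id", columns="period", values="npv")
        t_stat = stats.ttest_rel(wide["weekend"], wide["weekday"]).statistic
        assert F == pytest.approx(t_stat**2, abs=1e-10 * max(1.0, F))

    def test_ddf_read_off_declared_strata(self):
        study = simulate_study(SimConfig(n_subjects=24, mcar_rate_npv=0.0, mcar_rate_indicator=0.0, seed=8))
        long = build_long_table(study.npv_records, study.truth.latents)
        res = sequential_anova(long, MODEL1_TERMS)
        tab = res.table.set_index("term")
        assert tab.loc["AL", "DDF"] == tab.loc["SID", "NDF"]
        assert tab.loc["Time", "DDF"] == tab.loc["Time:SID", "NDF"]
        assert tab.loc["C2", "DDF"] == tab.loc["C2:SID", "NDF"]
        assert tab.loc["C1", "DDF"] == tab.loc["C1:SID", "NDF"]
        assert tab.loc["SID", "DDF"] == res.df_residual

    def test_degenerate_stratum_raises_named_error(self):
        rows = []
        for s in range(2):
            for period in ("weekday", "weekend"):
                rows.append({"subject_id": f"S{s}", "method": "GPS", "period": period, "npv": float(s + 1)})
        long = build_long_table(pd.DataFrame(rows), pd.DataFrame({"subject_id": ["S0", "S1"], "AL": [0.0, 1.0], "SL": [1.0, 0.0]}))
        with pytest.raises(ValueError, match="stratum"):
            sequential_anova(long, MODEL1_TERMS)


class TestEffectSizes:
    def test_semi_partial_and_stratum_partials(self):
        table = pd.DataFrame(
            {"type": ["BS", "BS", "WS", "WS"], "term": ["A", "SID", "T", "TxS"], "SS": [10.0, 30.0, 20.0, 40.0]}
        )
        out = effect_sizes(table, ss_total=200.0)
        assert list(out["semi_partial_R2"]) == pytest.approx([0.05, 0.15, 0.1, 0.2])
        assert out.set_index("term").loc["A", "partial_R2"] == pytest.approx(0.05 / 0.20)
        assert out.set_index("term").loc["T", "partial_R2"] == pytest.approx(0.1 / 0.3)

    def test_single_term_stratum_partial_is_one(self):
        table = pd.DataFrame({"type": ["BS"], "term": ["A"], "SS": [5.0]})
        assert effect_sizes(table, 50.0)["partial_R2"].iloc[0] == pytest.approx(1.0)


class TestBothOrders:
    def test_joint_lifestyle_ss_and_model_r2_order_invariant(self):
        study = simulate_study(SimConfig(n_subjects=30, seed=17))
        long = build_long_table(study.npv_records, study.truth.latents)
        r1, r2 = fit_both_orders(long)
        joint1 = r1.table.set_index("term").loc[["AL", "SL", "AL:SL"], "SS"].sum()
        joint2 = r2.table.set_index("term").loc[["SL", "AL", "SL:AL"], "SS"].sum()
        assert joint1 == pytest.approx(joint2, abs=1e-10 * max(1.0, joint1))
        assert r1.model_r2 == pytest.approx(r2.model_r2, abs=1e-10)

    def test_al_split_equal_when_factors_uncorrelated(self):
        study = simulate_study(SimConfig(n_subjects=60, latent_corr=0.0, mcar_rate_npv=0.0, mcar_rate_indicator=0.0, seed=19))
        long = build_long_table(study.npv_records, study.truth.latents)
        r1, r2 = fit_both_orders(long)
        al1 = float(r1.table.set_index("term").loc["AL", "SS"])
        al2 = float(r2.table.set_index("term").loc["AL", "SS"])
        # finite-sample latent correlation is not exactly zero; allow slack
        assert al2 == pytest.approx(al1, rel=0.15)


class TestFinalParameterFit:
    def test_noiseless_recovery_is_exact(self):
        cfg = SimConfig(
            subject_sd=0.0,
            residual_sd=0.0,
            method_sd_diary=0.0,
            method_sd_google=0.0,
            method_sd_gps=0.0,
            discretize=False,
            mcar_rate_npv=0.0,
            mcar_rate_indicator=0.0,
            n_subjects=30,
            seed=23,
        )
        study = simulate_study(cfg)
        long = build_long_table(study.npv_records, study.truth.latents)
        fit = final_parameter_fit(long)
        assert fit.params["Intercept"] == pytest.approx(11.87, abs=1e-8)
        assert fit.params["AL"] == pytest.approx(1.79, abs=1e-8)
        assert fit.params["Time"] == pytest.approx(-3.68, abs=1e-8)

    def test_zero_al_column_gives_mean_intercept(self):
        long = pd.DataFrame(
            {"NPV": [8.0, 12.0, 9.0, 11.0], "AL": [0.0] * 4, "Time": [-0.5, 0.5, -0.5, 0.5], "SID": list("abab")}
        )
        fit = final_parameter_fit(long)
        assert fit.params["AL"] == pytest.approx(0.0)
        assert fit.params["Intercept"] == pytest.approx(10.0)

    def test_underdetermined_is_error(self):
        long = pd.DataFrame({"NPV": [1.0], "AL": [0.0], "Time": [0.5], "SID": ["a"]})
        with pytest.raises(ValueError):
            final_parameter_fit(long)


class TestMissingnessScreen:
    def test_all_complete_reports_rates_without_tests(self):
        comp = pd.DataFrame({"Diary": [1, 1, 1], "GPS": [1, 1, 1]})
        cov = pd.DataFrame({"AL": [0.1, 0.2, 0.3]})
        out = missingness_screen(comp, cov)
        assert (out["completion_rate"] == 1.0).all()
        assert (out["test"] == "degenerate").all()

    def test_mcar_no_flags_expected(self, rng):
        n = 300
        comp = pd.DataFrame({"Diary": (rng.random(n) > 0.2).astype(int)})
        cov = pd.DataFrame({"AL": rng.normal(size=n)})
        out = missingness_screen(comp, cov)
        assert out["p"].iloc[0] > 0.01  # seeded draw: no spurious association

    def test_dependent_completion_flagged(self, rng):
        n = 300
        al = rng.normal(size=n)
        comp = pd.DataFrame({"Diary": (al + rng.normal(scale=0.5, size=n) > 0).astype(int)})
        out = missingness_screen(comp, pd.DataFrame({"AL": al}))
        assert bool(out["flag"].iloc[0])
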