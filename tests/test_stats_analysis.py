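"""Normality screen, correlation/regression battery, stratified grids."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from gaitcomp.errors import DegenerateDataError, ValidationError
from gaitcomp.body_comp import INDICATOR_COLUMNS
from gaitcomp.stats_analysis import (
    correlation_matrix,
    format_correlation_grid,
    pearson_r,
    regression_table,
    shapiro_wilk_screen,
    significance_marker,
    simple_ols,
    spearman_r,
    stratified_analysis,
)
from gaitcomp.synth_cohort import SynthCohortConfig, generate_feature_table


class TestMarkers:
    @pytest.mark.parametrize("p,mark", [
        (0.0005, "***"), (0.001, "**"), (0.005, "**"), (0.01, "*"),
        (0.049, "*"), (0.05, ""), (0.9, ""),
    ])
    def test_star_rule(self, p, mark):
        assert significance_marker(p) == mark

    def test_marker_always_consistent_with_p(self, rng):
        for _ in range(200):
            n = rng.integers(5, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            cell = pearson_r(x, y)
            assert cell.marker == significance_marker(cell.p)


class TestPearson:
    def test_perfect_positive_and_negative(self, rng):
        x = rng.normal(size=20)
        assert pearson_r(x, x).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_published_r_n17_reconciles_t_and_p(self):
        # r = 0.561 at 17 complete cases: t = 2.625 on 15 df, p = 0.019
        r = 0.561
        n = 17
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        p = 2 * scipy.stats.t.sf(abs(t), n - 2)
        assert t == pytest.approx(2.625, abs=0.01)
        assert p == pytest.approx(0.019, abs=0.001)
        assert significance_marker(p) == "*"

    def test_matches_scipy_cross_check(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            x = rng.normal(size=n)
            y = 0.4 * x + rng.normal(size=n)
            cell = pearson_r(x, y)
            ref = scipy.stats.pearsonr(x, y)
            assert cell.r == pytest.approx(ref.statistic, abs=1e-12)
            assert cell.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_symmetry_and_affine_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        assert pearson_r(x, y).r == pytest.approx(pearson_r(y, x).r)
        assert pearson_r(2.5 * x + 7, y).r == pytest.approx(
            pearson_r(x, y).r)

    def test_pairwise_complete_n_recorded(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        x[3] = np.nan
        y[7] = np.nan
        assert pearson_r(x, y).n == 18

    def test_zero_variance_errors(self):
        with pytest.raises(DegenerateDataError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateDataError):
            pearson_r([1.0, 2.0], [3.0, 4.0])


class TestSpearman:
    def test_monotone_transform_gives_unity(self, rng):
        x = rng.normal(size=30)
        assert spearman_r(x, np.exp(x)).r == pytest.approx(1.0)
        assert spearman_r(x, -x ** 3).r == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        for _ in range(30):
            x = rng.integers(0, 5, size=25).astype(float)
            y = rng.integers(0, 5, size=25).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            cell = spearman_r(x, y)
            rx = scipy.stats.rankdata(x)
            ry = scipy.stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert cell.r == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy_spearman(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        ref = scipy.stats.spearmanr(x, y)
        assert spearman_r(x, y).r == pytest.approx(ref.statistic, abs=1e-12)


class TestShapiroScreen:
    def test_null_acceptance_rate(self):
        # n=50 standard normal draws conform in >= 95% of 100 seeds at alpha=.05
        hits = 0
        for seed in range(100):
            vals = np.random.default_rng(seed).standard_normal(50)
            row = shapiro_wilk_screen(pd.DataFrame({"v": vals}))
            hits += bool(row["conforms"].iloc[0])
        assert hits >= 90  # binomial slack around the 95% expectation

    def test_lognormal_rejected(self):
        vals = np.random.default_rng(3).lognormal(0, 1, 200)
        row = shapiro_wilk_screen(pd.DataFrame({"v": vals}))
        assert not row["conforms"].iloc[0]
        # agrees with the reference implementation
        ref = scipy.stats.shapiro(vals)
        assert row["W"].iloc[0] == pytest.approx(ref.statistic)

    def test_constant_vector_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            row = shapiro_wilk_screen(pd.DataFrame({"v": [2.0] * 10}))
        assert not row["conforms"].iloc[0]
        assert row["degenerate"].iloc[0]

    def test_small_n_skipped(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = shapiro_wilk_screen(pd.DataFrame({"v": [1.0, 2.0]}))
        assert len(out) == 0


class TestSimpleOls:
    def test_exact_line_flagged_perfect(self):
        x = np.arange(10, dtype=float)
        rr = simple_ols(2 * x + 1, x)
        assert rr.intercept == pytest.approx(1.0)
        assert rr.slope == pytest.approx(2.0)
        assert rr.perfect_fit and np.isinf(rr.t_slope)

    def test_uncorrelated_noise_not_significant(self):
        rng = np.random.default_rng(12)
        hits = sum(
            simple_ols(rng.normal(size=30), rng.normal(size=30)).marker != ""
            for _ in range(100))
        assert hits <= 12  # ~5% expected at alpha=.05

    def test_t_equals_pearson_implied_t(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 50))
            x = rng.normal(size=n)
            y = 0.3 * x + rng.normal(size=n)
            rr = simple_ols(y, x)
            r = pearson_r(x, y).r
            t_implied = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            assert rr.t_slope == pytest.approx(t_implied, abs=1e-10)

    def test_zero_variance_regressor(self):
        with pytest.raises(DegenerateDataError):
            simple_ols([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


def _tables(n=40, seed=5):
    tab = generate_feature_table(
        SynthCohortConfig(n_participants=n, seed=seed))
    features = tab[["participant_id", "mean_directional_shift"]].copy()
    features["mean_displacement"] = tab["TBW"] * 0.1  # any dynamic column
    indicators = tab.drop(columns=["mean_directional_shift", "time_1",
                                   "time_2"])
    return features, indicators


class TestCorrelationMatrix:
    def test_indicator_duplicated_as_feature_gives_unity(self):
        features, indicators = _tables()
        features = features.copy()
        features["mean_directional_shift"] = indicators["SMI"]
        cells = correlation_matrix(features, indicators,
                                   dynamic_variables=(
                                       "mean_directional_shift",))
        row = cells[cells["indicator"] == "SMI"].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_planted_correlation_recovered_at_large_n(self):
        tab = generate_feature_table(
            SynthCohortConfig(n_participants=2000, seed=9))
        cell = pearson_r(tab["mean_directional_shift"], tab["SMI"])
        assert cell.r == pytest.approx(0.561, abs=0.05)

    def test_unmatched_ids_reported(self):
        features, indicators = _tables(n=4)
        features = features.copy()
        features["participant_id"] = ["X1", "X2", "X3", "X4"]
        with pytest.raises(ValidationError, match="X1"):
            correlation_matrix(features, indicators)

    def test_formatted_cell_style(self):
        features, indicators = _tables()
        cells = correlation_matrix(features, indicators)
        for _, row in cells.iterrows():
            expect = f"{row['r']:.3f}"
            if row["marker"]:
                expect += f" {row['marker']}"
            expect += f"({row['p']:.3f})"
            assert row["formatted"] == expect

    def test_grid_pivot_layout(self):
        features, indicators = _tables()
        cells = correlation_matrix(features, indicators)
        grid = format_correlation_grid(cells)
        assert list(grid.index) == list(INDICATOR_COLUMNS)
        assert "mean_directional_shift" in grid.columns

    def test_bh_correction_appends_adjusted_p(self):
        features, indicators = _tables()
        cells = correlation_matrix(features, indicators, correct=True)
        assert (cells["p_adj"] >= cells["p"] - 1e-12).all()

    def test_normality_flag_annotates_cells(self):
        features, indicators = _tables()
        screen = pd.DataFrame({"variable": ["SMI"], "conforms": [False]})
        cells = correlation_matrix(features, indicators, normality=screen)
        assert cells.loc[cells["indicator"] == "SMI",
                         "normality_flag"].all()
        assert not cells.loc[cells["indicator"] == "TBW",
                             "normality_flag"].any()


class TestRegressionTable:
    def test_rows_reconcile_with_pearson(self):
        features, indicators = _tables()
        table = regression_table(features, indicators).set_index("variable")
        merged = features.merge(indicators, on="participant_id")
        for var in ("SMI", "PBF", "TBW"):
            r = pearson_r(merged["mean_directional_shift"],
                          merged[var]).r
            n = len(merged)
            t_implied = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            assert table.loc[var, "t_statistic"] == pytest.approx(
                t_implied, abs=1e-10)

    def test_ns_label_for_insignificant(self):
        features, indicators = _tables()
        table = regression_table(features, indicators)
        assert set(table["significance"]) <= {"ns", "*", "**", "***"}


class TestStratified:
    def test_identical_strata_identical_grids(self):
        features, indicators = _tables(n=30)
        indicators = indicators.copy()
        indicators["sex"] = ["male"] * 15 + ["female"] * 15
        # make the strata identical row-for-row
        half_f = features.iloc[:15].reset_index(drop=True)
        half_i = indicators.iloc[:15].reset_index(drop=True)
        mirror_i = half_i.copy()
        mirror_i["participant_id"] = [f"F{i}" for i in range(15)]
        mirror_i["sex"] = "female"
        mirror_f = half_f.copy()
        mirror_f["participant_id"] = mirror_i["participant_id"]
        features2 = pd.concat([half_f, mirror_f], ignore_index=True)
        indicators2 = pd.concat([half_i.assign(sex="male"), mirror_i],
                                ignore_index=True)
        out = stratified_analysis(features2, indicators2)
        male = out["male"]["cells"].drop(columns="n")
        female = out["female"]["cells"].drop(columns="n")
        pd.testing.assert_frame_equal(male, female)

    def test_planted_per_stratum_correlations_recovered(self):
        male = generate_feature_table(SynthCohortConfig(
            n_participants=1000, seed=21, female_fraction=0.0,
            planted_rho={"SMI": 0.5}))
        female = generate_feature_table(SynthCohortConfig(
            n_participants=1000, seed=22, female_fraction=1.0,
            planted_rho={"SMI": 0.8}))
        tab = pd.concat([male, female], ignore_index=True)
        tab["participant_id"] = [f"P{i}" for i in range(len(tab))]
        features = tab[["participant_id", "mean_directional_shift"]]
        indicators = tab.drop(columns=["mean_directional_shift", "time_1",
                                       "time_2"])
        out = stratified_analysis(features, indicators)
        for label, rho in (("male", 0.5), ("female", 0.8)):
            cells = out[label]["cells"]
            row = cells[(cells["indicator"] == "SMI")
                        & (cells["dynamic"] == "mean_directional_shift")]
            assert row["r"].iloc[0] == pytest.approx(rho, abs=0.05)

    def test_small_stratum_warned_and_flagged(self):
        features, indicators = _tables(n=10)
        indicators = indicators.copy()
        indicators["sex"] = ["male"] * 7 + ["female"] * 3
        with pytest.warns(UserWarning, match="small"):
            out = stratified_analysis(features, indicators)
        assert out["female"]["low_n"] and out["female"]["n"] == 3
        assert set(out["female"]["summary"]) == {"min", "q1", "median",
                                                 "q3", "max"}

    def test_unknown_stratum_label_rejected(self):
        features, indicators = _tables(n=6)
        indicators = indicators.copy()
        indicators["sex"] = ["male"] * 5 + ["nonbinary-unmapped"]
        with pytest.raises(ValidationError, match="labels"):
            stratified_analysis(features, indicators)
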