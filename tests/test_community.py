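"""Community statistics against independent oracles and constructions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microzoo import community, synthetic
from microzoo.schema import (
    GROUP_COLUMNS,
    ConstantColumnError,
    InputError,
    RankDeficientError,
    UndefinedCompositionError,
)

GROUPS = list(GROUP_COLUMNS)


def anosim_oracle(D, labels):
    """Exhaustive-permutation ANOSIM, written independently of the library.

    Computes Clarke's R from scratch (rank loop, no shared helpers) and the
    exact p as the fraction of all label orderings with R >= observed.
    """
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    d = np.array([D[i, j] for i, j in pairs])
    order = stats.rankdata(d, method="average")

    def r_stat(lab):
        within = [order[k] for k, (i, j) in enumerate(pairs)
                  if lab[i] == lab[j]]
        between = [order[k] for k, (i, j) in enumerate(pairs)
                   if lab[i] != lab[j]]
        return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4.0)

    r_obs = r_stat(labels)
    all_r = [r_stat(p) for p in itertools.permutations(labels)]
    p = np.mean([r >= r_obs - 1e-12 for r in all_r])
    return r_obs, p


def anova_projection_oracle(y, season, region):
    """Type-III F tests via explicit full-vs-reduced column projections."""
    y = np.asarray(y, dtype=float)
    s_levels = sorted(set(season))
    r_levels = sorted(set(region))

    def sum_code(values, levels):
        # sum-to-zero contrast columns
        cols = []
        for lev in levels[:-1]:
            col = np.where(
                np.asarray(values) == lev, 1.0,
                np.where(np.asarray(values) == levels[-1], -1.0, 0.0),
            )
            cols.append(col)
        return np.column_stack(cols)

    S = sum_code(season, s_levels)
    R = sum_code(region, r_levels)
    inter = np.column_stack(
        [S[:, i] * R[:, j] for i in range(S.shape[1])
         for j in range(R.shape[1])]
    )
    one = np.ones((len(y), 1))
    full = np.column_stack([one, S, R, inter])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid)

    rss_full = rss(full)
    df_resid = len(y) - full.shape[1]
    out = {}
    for name, drop in (
        ("season", S), ("region", R), ("season:region", inter)
    ):
        keep = [c for c in (S, R, inter) if c is not drop]
        reduced = np.column_stack([one] + keep)
        num = (rss(reduced) - rss_full) / drop.shape[1]
        f = num / (rss_full / df_resid)
        p = stats.f.sf(f, drop.shape[1], df_resid)
        out[name] = (f, p)
    return out


class TestRelativeBiomass:
    def test_simple_proportions(self):
        table = pd.DataFrame([{g: v for g, v in zip(GROUPS, (6, 2, 1, 1))}])
        rel = community.relative_biomass(table)
        assert list(rel.iloc[0][GROUPS]) == pytest.approx([0.6, 0.2, 0.1, 0.1])

    def test_single_nonzero_group(self):
        table = pd.DataFrame([{g: v for g, v in zip(GROUPS, (5, 0, 0, 0))}])
        rel = community.relative_biomass(table)
        assert list(rel.iloc[0][GROUPS]) == pytest.approx([1, 0, 0, 0])

    def test_rows_sum_to_one_for_random_tables(self, rng):
        table = pd.DataFrame(rng.lognormal(0, 1, (30, 4)), columns=GROUPS)
        rel = community.relative_biomass(table)
        np.testing.assert_allclose(rel[GROUPS].sum(axis=1), 1.0)

    def test_all_zero_row_rejected(self):
        table = pd.DataFrame([{g: 0.0 for g in GROUPS}])
        with pytest.raises(UndefinedCompositionError):
            community.relative_biomass(table)


class TestBrayCurtis:
    def test_identical_rows_have_zero_dissimilarity(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert community.bray_curtis(X)[0, 1] == 0.0

    def test_disjoint_supports_have_unit_dissimilarity(self):
        X = np.array([[1.0, 0.0, 2.0], [0.0, 3.0, 0.0]])
        assert community.bray_curtis(X)[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 1.0]])
        assert community.bray_curtis(X)[0, 1] == pytest.approx(3 / 11)

    def test_matrix_properties_on_random_input(self, rng):
        X = rng.lognormal(0, 1, (12, 4))
        D = community.bray_curtis(X)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert (D >= 0).all() and (D <= 1).all()

    def test_negative_entries_rejected(self):
        with pytest.raises(InputError):
            community.bray_curtis(np.array([[1.0, -1.0], [0.5, 0.5]]))


class TestAnosim:
    def test_complete_separation_gives_r_one(self, rng):
        X = np.vstack([rng.random((3, 4)), 50 + rng.random((4, 4))])
        D = community.bray_curtis(X)
        labels = np.array(["a"] * 3 + ["b"] * 4)
        assert community.anosim(D, labels, method="exact").R == (
            pytest.approx(1.0)
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_mode_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6 if seed % 2 else 7
        X = rng.lognormal(0, 0.8, (n, 4))
        labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        D = community.bray_curtis(X)
        res = community.anosim(D, labels, method="exact")
        r_oracle, p_oracle = anosim_oracle(D, labels)
        assert res.R == pytest.approx(r_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        X = rng.lognormal(0, 1, (10, 4))
        D = community.bray_curtis(X)
        labels = ["a"] * 5 + ["b"] * 5
        res = community.anosim(D, np.array(labels), n_perm=99, seed=0)
        ref = skbio_anosim(DistanceMatrix(D), grouping=labels, permutations=0)
        assert res.R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_null_r_centered_on_zero(self, rng):
        rs = []
        for _ in range(100):
            X = rng.lognormal(0, 1, (10, 4))
            D = community.bray_curtis(X)
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            rs.append(community.anosim(D, labels, n_perm=49,
                                       seed=int(rng.integers(2**31))).R)
        assert abs(np.mean(rs)) < 0.05

    def test_seed_determinism(self, rng):
        X = rng.lognormal(0, 1, (10, 4))
        D = community.bray_curtis(X)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        p1 = community.anosim(D, labels, n_perm=199, seed=5).p_value
        p2 = community.anosim(D, labels, n_perm=199, seed=5).p_value
        assert p1 == p2

    def test_degenerate_grouping_rejected(self, rng):
        D = community.bray_curtis(rng.random((4, 3)) + 0.1)
        with pytest.raises(InputError):
            community.anosim(D, np.array(["a", "a", "a", "b"]))


class TestTypeThreeAnova:
    def test_balanced_design_equals_type_one(self, rng):
        season = np.repeat(["winter", "summer"], 12)
        region = np.tile(np.repeat(["inner", "mid", "outer"], 4), 2)
        y = rng.normal(size=24) + (season == "winter") * 1.0
        t3 = community.two_way_anova_type3(y, season, region)
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = pd.DataFrame({"y": y, "season": season, "region": region})
        t1 = sm.stats.anova_lm(
            ols("y ~ C(season, Sum) * C(region, Sum)", df).fit(), typ=1
        )
        for term_t3, term_t1 in (
            ("season", "C(season, Sum)"),
            ("region", "C(region, Sum)"),
        ):
            assert t3.loc[term_t3, "sum_sq"] == pytest.approx(
                t1.loc[term_t1, "sum_sq"]
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unbalanced_design_matches_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_w, n_s = 11, 14
        season = np.array(["winter"] * n_w + ["summer"] * n_s)
        region = rng.choice(["inner", "mid", "outer"], n_w + n_s)
        # guarantee every cell occupied
        region[:3] = ["inner", "mid", "outer"]
        region[n_w:n_w + 3] = ["inner", "mid", "outer"]
        y = rng.normal(size=n_w + n_s) + (season == "winter") * 0.8
        table = community.two_way_anova_type3(y, season, region)
        oracle = anova_projection_oracle(y, season, region)
        for term in ("season", "region", "season:region"):
            f_o, p_o = oracle[term]
            assert table.loc[term, "F"] == pytest.approx(f_o, rel=1e-8)
            assert table.loc[term, "PR(>F)"] == pytest.approx(p_o, rel=1e-8)

    def test_outlier_exclusion_changes_fit(self, rng):
        season = np.repeat(["winter", "summer"], 9)
        region = np.tile(["inner", "mid", "outer"], 6)
        y = rng.normal(size=18)
        y[0] = 40.0
        flags = np.zeros(18, bool)
        flags[0] = True
        with_out = community.two_way_anova_type3(
            y, season, region, exclude_outliers=False
        )
        without = community.two_way_anova_type3(
            y, season, region, exclude_outliers=True, outlier_flags=flags
        )
        assert without.loc["Residual", "sum_sq"] < with_out.loc[
            "Residual", "sum_sq"
        ]


class TestPearsonScreen:
    def test_duplicated_columns_keep_exactly_one(self, rng):
        x = rng.normal(size=30)
        env_df = pd.DataFrame({"a": x, "b": x.copy(),
                               "c": rng.normal(size=30)})
        resp = pd.DataFrame({"y": x + rng.normal(0, 0.5, 30)})
        res = community.pearson_screen(env_df, resp)
        assert sum(c in res.retained for c in ("a", "b")) == 1
        assert "c" in res.retained

    def test_orthogonal_columns_all_retained(self, rng):
        env_df = pd.DataFrame(rng.normal(size=(40, 4)),
                              columns=list("abcd"))
        resp = pd.DataFrame({"y": rng.normal(size=40)})
        res = community.pearson_screen(env_df, resp)
        assert res.retained == list("abcd")

    def test_cluster_member_with_highest_response_correlation_retained(
        self, rng
    ):
        a = rng.normal(size=50)
        env_df = pd.DataFrame(
            {"A": a, "B": a + rng.normal(0, 0.05, 50),
             "C": rng.normal(size=50)}
        )
        resp = pd.DataFrame({"y": a + rng.normal(0, 0.2, 50)})
        # make A strictly more correlated with the response than B
        resp["y"] = 0.9 * a + 0.1 * env_df["B"] + rng.normal(0, 0.1, 50)
        res = community.pearson_screen(env_df, resp)
        assert "C" in res.retained
        assert len(res.retained) == 2

    def test_too_few_complete_rows_rejected(self):
        env_df = pd.DataFrame({"a": [1.0, np.nan, 3.0, 4.0]})
        resp = pd.DataFrame({"y": [1.0, 2.0, np.nan, 4.0]})
        with pytest.raises(InputError):
            community.pearson_screen(env_df, resp)


class TestZScore:
    def test_standardizes_columns(self, rng):
        df = pd.DataFrame({"a": rng.normal(3, 7, 50),
                           "b": rng.uniform(0, 100, 50)})
        z = community.zscore(df)
        assert abs(z["a"].mean()) < 1e-12
        assert z["a"].std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        x = pd.DataFrame({"a": rng.normal(size=40)})
        z1 = community.zscore(x)
        z2 = community.zscore(x * 3.5 + 11.0)
        pd.testing.assert_frame_equal(z1, z2)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ConstantColumnError, match="flat"):
            community.zscore(df)


class TestRda:
    def test_linear_response_fully_constrained(self, rng):
        X = rng.normal(size=(20, 3))
        Y = X @ rng.normal(size=(3, 4))
        res = community.rda(Y, X, n_perm=99, seed=0)
        assert res.constrained_fraction == pytest.approx(1.0)

    def test_orthogonal_response_unconstrained(self, rng):
        n = 24
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        X = (X - X.mean(0))[:, 1:]
        # response orthogonal to X by explicit residualization
        Y = rng.normal(size=(n, 3))
        Y = Y - X @ np.linalg.lstsq(X, Y, rcond=None)[0]
        res = community.rda(Y, X, n_perm=199, seed=0)
        assert res.constrained_fraction == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_constrained_fraction_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m, q = 15, 4, 3
        X = rng.normal(size=(n, q))
        Y = rng.normal(size=(n, m)) + X @ rng.normal(size=(q, m)) * 0.5
        res = community.rda(Y, X, n_perm=49, seed=0)
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        H = Xc @ np.linalg.solve(Xc.T @ Xc, Xc.T)
        r2 = np.trace(Yc.T @ H @ Yc) / np.trace(Yc.T @ Yc)
        assert res.constrained_fraction == pytest.approx(r2, abs=1e-10)

    def test_axis_scores_match_direct_eigendecomposition(self, rng):
        n, m, q = 18, 4, 2
        X = rng.normal(size=(n, q))
        Y = X @ rng.normal(size=(q, m)) + rng.normal(size=(n, m)) * 0.3
        res = community.rda(Y, X, n_perm=49, seed=0)
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        Yhat = Xc @ np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        evals = np.linalg.eigvalsh(Yhat.T @ Yhat / (n - 1))[::-1]
        np.testing.assert_allclose(res.eigenvalues, evals[: res.n_axes],
                                   atol=1e-10)

    def test_invariant_to_affine_recoding_of_explanatory(self, rng):
        n, q = 20, 3
        X = rng.normal(size=(n, q))
        Y = rng.normal(size=(n, 4))
        A = rng.normal(size=(q, q)) + np.eye(q) * 2
        b = rng.normal(size=q)
        r1 = community.rda(Y, X, n_perm=49, seed=0)
        r2 = community.rda(Y, X @ A + b, n_perm=49, seed=0)
        assert r1.constrained_fraction == pytest.approx(
            r2.constrained_fraction, abs=1e-10
        )

    def test_rank_deficient_explanatory_rejected(self, rng):
        X = rng.normal(size=(15, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.raises(RankDeficientError):
            community.rda(rng.normal(size=(15, 3)), X)

    def test_eigenvalues_non_increasing_and_fraction_bounded(self, rng):
        X = rng.normal(size=(25, 3))
        Y = rng.normal(size=(25, 4))
        res = community.rda(Y, X, n_perm=49, seed=1)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert 0 <= res.constrained_fraction <= 1


class TestRdaOutliers:
    def _scores(self):
        winter = np.array([[1.0, 0.0], [1.2, 0.1], [0.8, -0.1], [1.1, 0.0]])
        summer = np.array([[-1.0, 0.0], [-1.2, 0.1], [-0.8, -0.1],
                           [-1.1, 0.0]])
        return np.vstack([winter, summer]), np.array(
            ["winter"] * 4 + ["summer"] * 4
        )

    def test_point_at_own_centroid_not_outlier(self):
        S, labels = self._scores()
        report = community.rda_outliers(S, labels)
        assert not report["outlier"].iloc[1]

    def test_point_near_opposite_centroid_flagged(self):
        S, labels = self._scores()
        S = np.vstack([S, [[-1.05, 0.0]]])  # a "winter" point in summer space
        labels = np.append(labels, "winter")
        report = community.rda_outliers(S, labels)
        assert report["closer_to_opposite"].iloc[-1]
        assert report["outlier"].iloc[-1]

    def test_far_point_beyond_sd_threshold_flagged(self, rng):
        # a tight own-season cloud so the planted point cannot mask itself
        winter = rng.normal([1.0, 0.0], 0.1, size=(12, 2))
        summer = rng.normal([-1.0, 0.0], 0.1, size=(12, 2))
        S = np.vstack([winter, summer, [[2.5, 0.0]]])
        labels = np.array(["winter"] * 12 + ["summer"] * 12 + ["winter"])
        report = community.rda_outliers(S, labels)
        assert report["beyond_sd"].iloc[-1]
        assert report["outlier"].iloc[-1]
        assert not report["beyond_sd"].iloc[:12].any()

    def test_flags_invariant_under_rotation(self, rng):
        S, labels = self._scores()
        S = np.vstack([S, [[-1.05, 0.0], [4.0, 3.0]]])
        labels = np.append(labels, ["winter", "winter"])
        theta = 0.7
        Q = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        r1 = community.rda_outliers(S, labels)
        r2 = community.rda_outliers(S @ Q, labels)
        assert (r1["outlier"] == r2["outlier"]).all()
        np.testing.assert_allclose(r1["d_own"], r2["d_own"])

    def test_missing_season_rejected(self):
        S = np.zeros((4, 2))
        with pytest.raises(InputError):
            community.rda_outliers(S, np.array(["winter"] * 4))


class TestSummaries:
    def test_zero_noise_summary_recovers_scenario_means(self):
        scenario = synthetic.default_scenario(sigma=0.0, n_years=3, seed=0)
        table = synthetic.gen_community_table(scenario)
        summary = community.season_region_summary(table,
                                                  exclude_outliers=False)
        for (season, region), row in summary.by_stratum.iterrows():
            total = scenario.mean_total[(season, region)]
            assert row["total_mean"] == pytest.approx(total)
            for g in GROUPS:
                assert row[f"{g}_mean"] == pytest.approx(
                    total * scenario.proportions[(season, region)][g]
                )

    def test_single_row_stratum_reports_nan_sd(self):
        scenario = synthetic.default_scenario(sigma=0.0, n_years=1, seed=0)
        table = synthetic.gen_community_table(scenario)
        summary = community.season_region_summary(table,
                                                  exclude_outliers=False)
        assert summary.by_stratum["total_sd"].isna().all()

    def test_outliers_excluded_from_means(self, default_scenario_table):
        _, table = default_scenario_table
        table = table.copy()
        table["outlier"] = False
        idx = table.index[table["season"] == "winter"][0]
        table.loc[idx, GROUPS[0]] = 1e6
        table.loc[idx, "outlier"] = True
        summary = community.season_region_summary(table)
        assert summary.n_excluded == 1
        assert summary.by_stratum["total_mean"].max() < 1e5


class TestGrazingCorrelation:
    def test_perfectly_proportional_rates_give_r_one(
        self, default_scenario_table
    ):
        _, table = default_scenario_table
        table = table.copy()
        table["grazing_rate"] = synthetic.gen_grazing_rates(
            table, noise_sd=0.0, seed=0
        )
        corr = community.grazing_biomass_correlation(table)
        winter_total = corr[(corr["stratum"] == "winter")
                            & (corr["biomass"] == "total")]
        assert winter_total["r"].iloc[0] == pytest.approx(1.0)

    def test_anti_proportional_rates_give_r_minus_one(
        self, default_scenario_table
    ):
        _, table = default_scenario_table
        table = table.copy()
        total = table[GROUPS].sum(axis=1)
        table["grazing_rate"] = 2.0 - 0.01 * total
        corr = community.grazing_biomass_correlation(table)
        winter_total = corr[(corr["stratum"] == "winter")
                            & (corr["biomass"] == "total")]
        assert winter_total["r"].iloc[0] == pytest.approx(-1.0)

    def test_undetermined_rates_dropped(self, default_scenario_table):
        _, table = default_scenario_table
        table = table.copy()
        table["grazing_rate"] = synthetic.gen_grazing_rates(table, seed=0)
        table.loc[table.index[:4], "grazing_rate"] = np.nan
        corr = community.grazing_biomass_correlation(table)
        assert corr["n"].sum() == (len(table) - 4) * corr["biomass"].nunique()
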