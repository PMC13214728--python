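"""Statistical battery: RM-ANOVA with GG correction, post hocs, effect
sizes, correlations — cross-checked against independent oracles."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from gazestate import reference_tables as ref
from gazestate.stats_analysis import (
    DegenerateDataError,
    IncompleteDesignError,
    cohens_d,
    correlation_table,
    gg_epsilon,
    mauchly_w,
    pearson_with_p,
    posthoc_bonferroni,
    rm_anova,
    run_battery,
    stars,
)
from gazestate.synthetic import sessions_to_long


def long_from_wide(Y):
    n, k = Y.shape
    return pd.DataFrame(
        {
            "participant_id": np.repeat([f"P{i}" for i in range(n)], k),
            "state": np.tile(np.arange(k), n),
            "measure": "m",
            "value": Y.ravel(),
        }
    )


def oracle_rm_anova(Y):
    """Independent textbook sum-of-squares decomposition (loops, no reuse)."""
    n, k = Y.shape
    gm = Y.mean()
    ss_between = sum(n * (Y[:, j].mean() - gm) ** 2 for j in range(k))
    ss_subject = sum(k * (Y[i, :].mean() - gm) ** 2 for i in range(n))
    ss_total = sum((Y[i, j] - gm) ** 2 for i in range(n) for j in range(k))
    ss_error = ss_total - ss_between - ss_subject
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_between / df1) / (ss_error / df2)
    eta = ss_between / (ss_between + ss_error)
    return F, df1, df2, eta


class TestRmAnova:
    def random_table(self, seed, n=26, k=3):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) + rng.normal(size=k)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_sum_of_squares_oracle(self, seed):
        Y = self.random_table(seed, n=8)
        res = rm_anova(long_from_wide(Y), "m")
        F, df1, df2, eta = oracle_rm_anova(Y)
        assert res.F == pytest.approx(F, abs=1e-8)
        assert (res.df1, res.df2) == (df1, df2)
        assert res.eta_p2 == pytest.approx(eta, abs=1e-8)

    def test_df_structure_for_study_design(self):
        res = rm_anova(long_from_wide(self.random_table(5)), "m")
        assert (res.df1, res.df2) == (2, 50)

    def test_matches_pingouin(self):
        Y = self.random_table(7)
        res = rm_anova(long_from_wide(Y), "m")
        df = long_from_wide(Y)
        pgr = pg.rm_anova(
            data=df, dv="value", within="state", subject="participant_id",
            correction=True, detailed=True, effsize="np2",
        ).iloc[0]
        assert res.F == pytest.approx(pgr["F"], rel=1e-9)
        assert res.p_uncorrected == pytest.approx(pgr["p_unc"], rel=1e-9)
        assert res.p_gg == pytest.approx(pgr["p_GG_corr"], rel=1e-6)
        assert res.eps_gg == pytest.approx(pgr["eps"], rel=1e-9)
        assert res.eta_p2 == pytest.approx(pgr["np2"], rel=1e-9)
        W, p_sph = mauchly_w(np.cov(Y, rowvar=False), Y.shape[0])
        sph = pg.sphericity(df, dv="value", within="state", subject="participant_id")
        assert W == pytest.approx(sph.W, rel=1e-9)
        assert p_sph == pytest.approx(sph.pval, rel=1e-9)

    def test_identical_columns_give_zero_effect(self):
        col = np.random.default_rng(0).normal(size=10)
        Y = np.column_stack([col, col, col])
        res = rm_anova(long_from_wide(Y), "m")
        assert res.F == 0.0 and res.eta_p2 == 0.0

    def test_missing_cell_rejected(self):
        long = long_from_wide(self.random_table(0, n=6)).iloc[:-1]
        with pytest.raises(IncompleteDesignError):
            rm_anova(long, "m")


class TestGgEpsilon:
    def test_compound_symmetry_gives_one(self):
        S = 0.3 * np.ones((3, 3)) + 0.7 * np.eye(3)
        assert gg_epsilon(S) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_lower_bound_k3(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(10, 3))
        eps = gg_epsilon(np.cov(A, rowvar=False))
        assert 0.5 <= eps <= 1.0

    def test_gg_and_uncorrected_p_agree_as_eps_to_one(self):
        """Compound-symmetric data: the GG correction becomes a no-op."""
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(200, 3)) + rng.normal(size=(200, 1)) + [0, 0.1, 0.2]
        res = rm_anova(long_from_wide(Y), "m")
        assert res.eps_gg > 0.95
        assert res.p_gg == pytest.approx(res.p_uncorrected, rel=0.3)


class TestPosthoc:
    def test_identical_conditions_degenerate(self):
        col = np.random.default_rng(1).normal(size=8)
        Y = np.column_stack([col, col, col])
        for ph in posthoc_bonferroni(long_from_wide(Y), "m"):
            assert ph.p_bonf == 1.0 and ph.degenerate

    def test_swap_flips_t_keeps_p(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(12, 3)) + [0, 1, 2]
        a = posthoc_bonferroni(long_from_wide(Y), "m")
        b = posthoc_bonferroni(long_from_wide(Y[:, [1, 0, 2]]), "m")
        assert a[0].t == pytest.approx(-b[0].t)
        assert a[0].p_bonf == pytest.approx(b[0].p_bonf)

    def test_paired_t_matches_difference_score_oracle(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(10, 3))
        results = posthoc_bonferroni(long_from_wide(Y), "m")
        pairs = [(0, 1), (0, 2), (1, 2)]
        for (i, j), ph in zip(pairs, results):
            t_oracle, p_oracle = sps.ttest_1samp(Y[:, i] - Y[:, j], 0.0)
            assert ph.t == pytest.approx(t_oracle, abs=1e-10)
            assert ph.p_bonf == pytest.approx(min(1.0, 3 * p_oracle), abs=1e-10)
            assert ph.d >= 0


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d(5.0, 1.0, 5.0, 2.0) == 0.0

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(DegenerateDataError):
            cohens_d(1.0, 0.0, 2.0, 1.0)

    @pytest.mark.parametrize(
        "scale, s1, s2, printed",
        [
            ("nasa_tlx", 1, 0, 0.897),
            ("distractibility", 2, 1, 3.04),
        ],
    )
    def test_reproduces_printed_effect_sizes(self, scale, s1, s2, printed):
        (m1, sd1), (m2, sd2) = (
            ref.QUESTIONNAIRE_STATS[scale][s1],
            ref.QUESTIONNAIRE_STATS[scale][s2],
        )
        assert cohens_d(m1, sd1, m2, sd2) == pytest.approx(printed, abs=0.005)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_with_p(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_with_p(x, -x).r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=78), rng.normal(size=78)
        r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert pearson_with_p(x, y).r == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_with_p(np.ones(10), np.arange(10.0))


class TestBattery:
    def test_il_metric_correlations_positive(self, study_dataset):
        """Intrinsic load couples positively with all four metrics through
        the shared state structure (sign check only)."""
        long = sessions_to_long(study_dataset)
        corr = correlation_table(long)
        il = corr[corr["scale"] == "il"]
        assert (il["r"] > 0).all()
        assert (il["n"] == 78).all()

    def test_run_battery_outputs(self, small_dataset, tmp_path):
        tables = run_battery(sessions_to_long(small_dataset), out_dir=tmp_path / "out")
        assert set(tables) == {"anova", "posthoc", "correlations"}
        assert len(tables["anova"]) == 10  # 4 metrics + 6 scales
        assert len(tables["posthoc"]) == 30
        assert (tmp_path / "out" / "anova.csv").exists()
        assert (tmp_path / "out" / "report.txt").exists()

    def test_stars_thresholds(self):
        assert [stars(p) for p in (0.0005, 0.005, 0.04, 0.2)] == ["***", "**", "*", ""]
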