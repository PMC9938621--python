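import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fluidert import degstats
from fluidert.degstats import DesignError

from conftest import make_dataset, balanced_stages


def brute_force_oneway(groups):
    """Independent sums-of-squares oracle: explicit loops, no linear algebra."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_stage = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_error = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_stage = len(groups) - 1
    df_error = len(all_vals) - len(groups)
    F = (ss_stage / df_stage) / (ss_error / df_error)
    return ss_stage, ss_error, F, sps.f.sf(F, df_stage, df_error)


def bh_oracle(p):
    """Reference BH step-up: sort, scale by m/i, cumulative min from the top."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestAnova:
    def test_toy_layout_matches_hand_computation(self):
        ds = make_dataset([[1, 2, 2, 3, 3, 4]], balanced_stages(2))
        out = degstats.anova_per_gene(ds)
        row = out.iloc[0]
        assert row["ms_stage"] == pytest.approx(2.0)
        assert row["ms_error"] == pytest.approx(0.5)
        assert row["F"] == pytest.approx(4.0)
        # closed form for F(2, m): P(F > x) = (1 + 2x/m)^(-m/2), m = 3
        assert row["p_value"] == pytest.approx((1 + 8 / 3) ** -1.5, rel=1e-12)

    def test_constant_gene_flagged_degenerate(self):
        ds = make_dataset([[5.0] * 6], balanced_stages(2))
        row = degstats.anova_per_gene(ds).iloc[0]
        assert row["degenerate"] == "zero_variance"
        assert row["p_value"] == 1.0 and row["F"] == 0.0

    def test_zero_residual_gene(self):
        ds = make_dataset([[1, 1, 2, 2, 3, 3]], balanced_stages(2))
        row = degstats.anova_per_gene(ds).iloc[0]
        assert row["degenerate"] == "zero_residual"
        assert np.isinf(row["F"]) and row["p_value"] == 0.0

    def test_matches_brute_force_on_random_layouts(self, rng):
        for _ in range(100):
            reps = int(rng.integers(2, 7))
            vals = rng.normal(0, 1, 3 * reps)
            ds = make_dataset(vals[None, :], balanced_stages(reps))
            row = degstats.anova_per_gene(ds).iloc[0]
            groups = [vals[i * reps:(i + 1) * reps] for i in range(3)]
            ss_s, ss_e, F, p = brute_force_oneway(groups)
            assert row["ss_stage"] == pytest.approx(ss_s, rel=1e-10)
            assert row["ss_error"] == pytest.approx(ss_e, rel=1e-10)
            assert row["F"] == pytest.approx(F, rel=1e-10)
            assert row["p_value"] == pytest.approx(p, rel=1e-10)

    def test_decomposition_sums_to_total(self, rng):
        vals = rng.normal(0, 1, (50, 12))
        ds = make_dataset(vals, balanced_stages(4))
        out = degstats.anova_per_gene(ds)
        np.testing.assert_allclose(out["ss_stage"] + out["ss_error"],
                                   out["ss_total"], rtol=1e-8)

    def test_treatment_term_reduces_error_df(self, rng):
        vals = rng.normal(0, 1, (20, 12))
        protocols = (["natural", "HRT"] * 6)
        ds = make_dataset(vals, balanced_stages(4), protocols=protocols)
        one = degstats.anova_per_gene(ds, include_treatment=False)
        two = degstats.anova_per_gene(ds, include_treatment=True)
        assert two["df_error"].iloc[0] == one["df_error"].iloc[0] - 1
        np.testing.assert_allclose(
            two["ss_stage"] + two["ss_treatment"] + two["ss_error"],
            two["ss_total"], rtol=1e-8)

    def test_two_way_matches_statsmodels(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        vals = rng.normal(0, 1, 12)
        protocols = ["natural"] * 3 + ["HRT"] * 3 + ["natural"] * 3 + ["HRT"] * 3
        ds = make_dataset(vals[None, :], balanced_stages(4), protocols=protocols)
        row = degstats.anova_per_gene(ds, include_treatment=True).iloc[0]
        df = pd.DataFrame({"y": vals, "stage": balanced_stages(4), "proto": protocols})
        fit = ols("y ~ C(stage) + C(proto)", df).fit()
        tbl = sm.stats.anova_lm(fit, typ=2)
        assert row["ss_stage"] == pytest.approx(tbl.loc["C(stage)", "sum_sq"], rel=1e-8)
        assert row["ss_treatment"] == pytest.approx(tbl.loc["C(proto)", "sum_sq"], rel=1e-8)
        assert row["ss_error"] == pytest.approx(tbl.loc["Residual", "sum_sq"], rel=1e-8)

    def test_small_stage_rejected(self):
        ds = make_dataset(np.ones((2, 5)), ["PR", "PR", "RE", "RE", "PO"])
        with pytest.raises(DesignError):
            degstats.anova_per_gene(ds)


class TestBH:
    def test_hand_example(self):
        q = degstats.bh_fdr([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04], rtol=1e-12)

    @pytest.mark.parametrize("p,expected", [
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([0.123], [0.123]),
    ])
    def test_boundaries(self, p, expected):
        np.testing.assert_allclose(degstats.bh_fdr(p), expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(degstats.bh_fdr(p), bh_oracle(p), rtol=1e-12)

    def test_nan_policy(self):
        with pytest.raises(ValueError):
            degstats.bh_fdr([0.1, np.nan])
        q = degstats.bh_fdr([0.1, np.nan], propagate_nan=True)
        assert np.isnan(q[1]) and q[0] == pytest.approx(0.1)


class TestFoldChange:
    def test_direction_and_antisymmetry(self):
        ds = make_dataset([[5, 5, 7, 7, 6, 6]], balanced_stages(2))
        up = degstats.pairwise_log2fc(ds, "PR", "RE")
        assert up.iloc[0] == pytest.approx(2.0)  # 4-fold
        down = degstats.pairwise_log2fc(ds, "RE", "PR")
        assert down.iloc[0] == pytest.approx(-up.iloc[0])

    def test_missing_stage_rejected(self):
        ds = make_dataset([[1, 2]], ["PR", "PR"])
        with pytest.raises(DesignError):
            degstats.pairwise_log2fc(ds, "PR", "RE")


class TestVolcano:
    @pytest.mark.parametrize("p,lfc,expected", [
        (0.01, 1.5, "up"),
        (0.2, 3.0, "ns"),          # p fails
        (0.04, -1.0, "down"),      # |log2FC| boundary is inclusive
        (0.04, 0.99, "ns"),
        (0.05, 2.0, "ns"),         # p boundary is exclusive
    ])
    def test_classification_rules(self, p, lfc, expected):
        assert degstats.volcano_classify([p], [lfc])[0] == expected

    def test_fc_cut_must_exceed_one(self):
        with pytest.raises(ValueError):
            degstats.volcano_classify([0.1], [1.0], fc_cut=1.0)


class TestTukey:
    def test_equal_means_give_p_one(self):
        ds = make_dataset([[1, 2, 1, 2, 1, 2]], balanced_stages(2))
        row = degstats.tukey_hsd_per_gene(ds).iloc[0]
        for a, b in degstats.PAIRS:
            assert row[f"tukey_p_{a}_{b}"] > 0.99

    def test_huge_separation_all_significant(self, rng):
        vals = np.concatenate([rng.normal(0, 0.1, 5), rng.normal(10, 0.1, 5),
                               rng.normal(20, 0.1, 5)])
        ds = make_dataset(vals[None, :], balanced_stages(5))
        row = degstats.tukey_hsd_per_gene(ds).iloc[0]
        for a, b in degstats.PAIRS:
            assert row[f"tukey_p_{a}_{b}"] < 1e-6

    def test_matches_statsmodels_on_random_layouts(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        for _ in range(10):
            reps = int(rng.integers(3, 7))
            vals = rng.normal(0, 1, 3 * reps)
            ds = make_dataset(vals[None, :], balanced_stages(reps))
            row = degstats.tukey_hsd_per_gene(ds).iloc[0]
            sm = pairwise_tukeyhsd(vals, np.array(balanced_stages(reps)))
            ours = sorted([row[f"tukey_p_{a}_{b}"] for a, b in degstats.PAIRS])
            theirs = sorted(sm.pvalues)
            np.testing.assert_allclose(ours, theirs, rtol=1e-6, atol=1e-9)

    def test_monotone_in_separation(self, rng):
        resid = rng.normal(0, 1, 15)
        base = np.repeat([0.0, 1.0, 2.0], 5)
        p_prev = None
        for c in (1.0, 2.0, 4.0):
            ds = make_dataset((c * base + resid)[None, :], balanced_stages(5))
            row = degstats.tukey_hsd_per_gene(ds).iloc[0]
            ps = np.array([row[f"tukey_p_{a}_{b}"] for a, b in degstats.PAIRS])
            if p_prev is not None:
                assert (ps <= p_prev + 1e-12).all()
            p_prev = ps

    def test_degenerate_gene_gets_p_one(self):
        ds = make_dataset([[3.0] * 9], balanced_stages(3))
        row = degstats.tukey_hsd_per_gene(ds).iloc[0]
        assert all(row[f"tukey_p_{a}_{b}"] == 1.0 for a, b in degstats.PAIRS)

    def test_interpolated_path_matches_direct(self, rng):
        """The large-batch interpolation agrees with direct quadrature."""
        from fluidert.degstats import _sr_sf
        q = rng.uniform(0.05, 15, 500)
        direct = sps.studentized_range.sf(q[:40], 3, 141)
        batch = _sr_sf(q, 3, 141)[:40]
        np.testing.assert_allclose(batch, direct, rtol=5e-3, atol=1e-9)
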