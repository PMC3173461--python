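"""Differential-expression, clustering, enrichment and t-test contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pidiag import (
    DEParams,
    ExpressionMatrix,
    MEDIAN_SCALED,
    RAW_TWO_CHANNEL,
    SimDesign,
    anova_pvalues,
    bh_adjust,
    call_de,
    differential_expression,
    fold_changes,
    generate_timecourse,
    hierarchical_cluster,
    median_scale,
    symbolize_profile,
    term_enrichment,
    welch_ttest,
)
from pidiag.errors import DataError, DegenerateAnovaError, DomainError

from conftest import make_meta


def one_day_matrix(treated, control):
    meta = make_meta(days=(0,), replicates=len(treated))
    genes = pd.Index(["g1"], name="gene_id")
    cols = {}
    ti, ci = 0, 0
    for _, row in meta.iterrows():
        if row["treatment"] == "minus_P":
            cols[row["sample_id"]] = [treated[ti]]
            ti += 1
        else:
            cols[row["sample_id"]] = [control[ci]]
            ci += 1
    return ExpressionMatrix(pd.DataFrame(cols, index=genes), MEDIAN_SCALED), meta


class TestFoldChanges:
    def test_arithmetic(self):
        m, meta = one_day_matrix([3.0, 3.2, 2.8], [1.5, 1.5, 1.5])
        assert fold_changes(m, meta).loc["g1", 0] == pytest.approx(2.0)

    def test_identical_treatments_give_unit_fold(self):
        m, meta = one_day_matrix([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert fold_changes(m, meta).loc["g1", 0] == pytest.approx(1.0)

    def test_planted_fold_two_at_late_days(self):
        d = SimDesign(n_genes=30, frac_responsive=1.0, noise_sd=0.0,
                      frac_absent=0.0, frac_low_signal=0.0,
                      patterns=("- - - - ↑ ↑ -",), seed=2)
        matrix, meta, truth = generate_timecourse(d)
        scaled = median_scale(ExpressionMatrix(matrix.data, RAW_TWO_CHANNEL))
        fc = fold_changes(scaled, meta)
        g = truth.index[0]
        assert np.allclose(fc.loc[g], [1, 1, 1, 1, 2, 2, 1])

    def test_missing_treatment_arm_rejected(self):
        m, meta = one_day_matrix([1.0, 1.0], [1.0, 1.0])
        only_treated = meta[meta["treatment"] == "minus_P"]
        with pytest.raises(DataError):
            fold_changes(m.with_data(m.data[only_treated["sample_id"]]), only_treated)


class TestAnova:
    def test_constant_gene_gets_p_one(self, small_timecourse):
        _, matrix, meta, _ = small_timecourse
        data = matrix.data.copy()
        data.iloc[0] = 7.0  # one flat gene among noisy ones
        p = anova_pvalues(ExpressionMatrix(data, RAW_TWO_CHANNEL), meta)
        assert p.iloc[0] == pytest.approx(1.0)
        assert np.isfinite(p).all()

    def test_all_constant_raises(self):
        meta = make_meta(days=(0, 1), replicates=2)
        genes = pd.Index(["g1"], name="gene_id")
        df = pd.DataFrame(
            {sid: [4.0] for sid in meta["sample_id"]}, index=genes
        )
        with pytest.raises(DegenerateAnovaError):
            anova_pvalues(ExpressionMatrix(df, MEDIAN_SCALED), meta)

    def test_null_pvalues_uniform(self):
        d = SimDesign(n_genes=1000, frac_responsive=0.0, noise_sd=0.2,
                      frac_absent=0.0, frac_low_signal=0.0, seed=5)
        matrix, meta, _ = generate_timecourse(d)
        p = anova_pvalues(matrix, meta)
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05

    def test_strong_effect_detected(self):
        d = SimDesign(n_genes=20, frac_responsive=1.0, effect_fold=10.0,
                      noise_sd=0.1, frac_absent=0.0, frac_low_signal=0.0, seed=6)
        matrix, meta, _ = generate_timecourse(d)
        p = anova_pvalues(matrix, meta)
        assert (p < 1e-4).all()

    def test_matches_statsmodels_nested_anova(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        d = SimDesign(n_genes=5, frac_responsive=0.4, noise_sd=0.3, seed=8,
                      frac_absent=0.0, frac_low_signal=0.0)
        matrix, meta, _ = generate_timecourse(d)
        ours = anova_pvalues(matrix, meta)
        for g in matrix.genes:
            df = meta.assign(y=np.log2(matrix.data.loc[g, meta["sample_id"]].to_numpy()))
            full = smf.ols("y ~ C(day) * C(treatment)", df).fit()
            red = smf.ols("y ~ C(day)", df).fit()
            table = sm.stats.anova_lm(red, full)
            assert ours[g] == pytest.approx(float(table["Pr(>F)"].iloc[1]), rel=1e-6)


def bh_oracle(p):
    """Hand step-up: q(i) = min_{j>=i} m*p(j)/j on the sorted scale."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = min(running, 1.0)
    return q


class TestBHAdjust:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_hand_step_up_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40))
    def test_never_below_raw_and_monotone_in_sorted_order(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallDE:
    def fc_table(self, rows):
        return pd.DataFrame(
            rows, index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id"),
            columns=[0, 1, 3, 7, 17, 29, 31],
        )

    def test_up_call_rule(self):
        fc = self.fc_table([[2, 2, 1, 1, 1, 1, 1]])
        p = pd.Series([0.005], index=fc.index)
        out = call_de(fc, p)
        assert bool(out["up"].iloc[0]) and not bool(out["down"].iloc[0])

    def test_gene_can_carry_both_calls_counted_once(self):
        fc = self.fc_table([[2, 2, 0.4, 0.4, 1, 1, 1]])
        p = pd.Series([0.005], index=fc.index)
        out = call_de(fc, p)
        assert bool(out["up"].iloc[0]) and bool(out["down"].iloc[0])
        assert int(out["de"].sum()) == 1

    def test_set_identity_up_plus_down_minus_overlap(self):
        rng = np.random.default_rng(0)
        fc = self.fc_table(np.exp2(rng.normal(0, 1, size=(200, 7))))
        p = pd.Series(rng.uniform(0, 0.02, 200), index=fc.index)
        out = call_de(fc, p)
        n_up, n_down = int(out["up"].sum()), int(out["down"].sum())
        n_both = int((out["up"] & out["down"]).sum())
        assert n_up + n_down - n_both == int(out["de"].sum())

    @pytest.mark.parametrize("param,values", [
        ("fc_threshold", [1.2, 1.5, 2.0, 3.0]),
        ("min_timepoints", [1, 2, 3, 5]),
    ])
    def test_de_count_monotone_nonincreasing(self, param, values):
        rng = np.random.default_rng(1)
        fc = self.fc_table(np.exp2(rng.normal(0, 1, size=(300, 7))))
        p = pd.Series(rng.uniform(0, 0.02, 300), index=fc.index)
        counts = [
            int(call_de(fc, p, DEParams(**{param: v}))["de"].sum()) for v in values
        ]
        assert counts == sorted(counts, reverse=True)


class TestClustering:
    def test_anticorrelated_families_separate(self):
        up = np.array([0, 0, 1, 2, 2, 1, 0], float)
        rng = np.random.default_rng(3)
        profiles = pd.DataFrame(
            [up + rng.normal(0, 0.05, 7) for _ in range(10)]
            + [-up + rng.normal(0, 0.05, 7) for _ in range(10)],
            index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"),
        )
        groups, _ = hierarchical_cluster(profiles, n_groups=2)
        assert groups.iloc[:10].nunique() == 1
        assert groups.iloc[10:].nunique() == 1
        assert groups.iloc[0] != groups.iloc[-1]

    def test_single_group(self):
        profiles = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 7)))
        groups, _ = hierarchical_cluster(profiles, n_groups=1)
        assert groups.nunique() == 1

    def test_duplicates_co_cluster(self):
        base = np.array([1, 2, 3, 2, 1, 0, 1], float)
        profiles = pd.DataFrame(
            [base, base, -base + 1, [5, 4, 3, 2, 1, 0, -1]],
            index=pd.Index(list("abcd"), name="gene_id"),
        )
        groups, _ = hierarchical_cluster(profiles, n_groups=3)
        assert groups["a"] == groups["b"]

    def test_too_many_groups_rejected(self):
        profiles = pd.DataFrame(np.eye(3))
        with pytest.raises(DomainError):
            hierarchical_cluster(profiles, n_groups=4)


class TestSymbolize:
    def test_group_signature(self):
        assert symbolize_profile([1.0, 1.0, 1.0, 1.0, 1.8, 1.9, 1.2]) == "- - - - ↑ ↑ -"

    def test_down_threshold(self):
        assert symbolize_profile([0.6]) == "↓"
        assert symbolize_profile([0.7]) == "-"  # 0.7 > 1/1.5

    def test_all_flat(self):
        assert symbolize_profile([1.0] * 7) == "- - - - - - -"

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(DomainError):
            symbolize_profile([1.0, 0.0, 2.0])


class TestEnrichment:
    def annotation(self):
        rows = [("g%02d" % i, "T1") for i in range(5)]
        rows += [("g%02d" % i, "T2") for i in range(20)]
        return pd.DataFrame(rows, columns=["gene_id", "term"])

    def test_exact_hypergeometric_example(self):
        universe = ["g%02d" % i for i in range(20)]
        selected = universe[:10]  # contains all 5 genes of T1
        out = term_enrichment(selected, self.annotation(), universe).set_index("term")
        assert out.loc["T1", "p"] == pytest.approx(3003 / 184756, rel=1e-12)

    def test_term_annotating_everything_has_p_one(self):
        universe = ["g%02d" % i for i in range(20)]
        out = term_enrichment(universe[:10], self.annotation(), universe).set_index("term")
        assert out.loc["T2", "p"] == pytest.approx(1.0)

    def test_empty_selection_returns_no_rows(self):
        universe = ["g%02d" % i for i in range(20)]
        assert term_enrichment([], self.annotation(), universe).empty

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(DataError):
            term_enrichment(["zz"], self.annotation(), ["g00"])


class TestWelch:
    def test_equal_means_p_one(self):
        assert welch_ttest(5.0, 0.3, 6, 5.0, 0.5, 3).pvalue == pytest.approx(1.0)

    def test_extreme_separation(self):
        assert welch_ttest(0.0, 0.1, 5, 100.0, 0.1, 5).pvalue < 1e-6

    def test_small_groups_rejected(self):
        with pytest.raises(DomainError):
            welch_ttest(1.0, 0.1, 1, 2.0, 0.1, 5)

    def test_matches_scipy_from_raw_data(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 5)
        ours = welch_ttest(
            a.mean(), a.std(ddof=1) / np.sqrt(len(a)), len(a),
            b.mean(), b.std(ddof=1) / np.sqrt(len(b)), len(b),
        )
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-9)


class TestPlantedRecovery:
    def test_planted_genes_called_nulls_not(self):
        from pidiag.benchmarks import de_recovery

        res = de_recovery(seed=2, n_genes=2000, frac_responsive=0.1)
        assert res["sensitivity"] >= 0.95
        assert res["false_positive_rate"] <= 0.01

    def test_symbolized_patterns_match_truth_noiseless(self):
        d = SimDesign(n_genes=60, frac_responsive=0.5, noise_sd=0.0,
                      frac_absent=0.0, frac_low_signal=0.0, seed=9)
        matrix, meta, truth = generate_timecourse(d)
        scaled = median_scale(ExpressionMatrix(matrix.data, RAW_TWO_CHANNEL))
        fc = fold_changes(scaled, meta)
        for g in truth.index:
            assert symbolize_profile(fc.loc[g].to_numpy()) == truth.loc[g, "pattern"]
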