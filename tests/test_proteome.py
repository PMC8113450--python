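"""Peptide normalization, moderated testing, and protein roll-up."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from conftest import make_peptide_matrix
from wobblelab import proteome
from wobblelab.proteome import (NormalizationError, ProteinDETable,
                                SpikeInError, bh_adjust, classify_de,
                                estimate_technical_variance,
                                fit_moderated_model, normalize_peptides,
                                rollup_proteins, simes_p, squeeze_variances,
                                trimmed_mean_fc)


def brute_force_simes(p):
    p = sorted(p)
    n = len(p)
    return min(n * p[k] / (k + 1) for k in range(n))


def brute_force_bh(p):
    """Step-up BH adjusted p-values by the textbook definition."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, n * p[i] / rank)
        adj[i] = running
    return adj


class TestNormalization:
    def test_constant_offset_removed(self):
        rng = np.random.default_rng(0)
        a = rng.normal(20, 2, size=500)
        vals = np.column_stack([a, a + 0.7, a, a, a, a])
        pm = make_peptide_matrix(vals)
        norm, diag = normalize_peptides(pm)
        x = norm.intensities.to_numpy()
        assert abs(np.median(x[:, 1] - x[:, 0])) < 0.01
        assert {"cycle", "pair", "median_m"} <= set(diag.columns)

    def test_identical_samples_are_fixed_point(self):
        rng = np.random.default_rng(1)
        a = rng.normal(20, 2, size=300)
        vals = np.tile(a[:, None], (1, 6))
        pm = make_peptide_matrix(vals)
        norm, _ = normalize_peptides(pm)
        assert np.allclose(norm.intensities.to_numpy(), vals, atol=1e-9)

    def test_intensity_dependent_distortion_removed(self):
        rng = np.random.default_rng(2)
        a = rng.normal(20, 2, size=2000)
        distort = 0.3 / (1 + np.exp(-(a - 20)))  # M = 0.3*sigmoid(A)
        vals = np.column_stack([a + distort, a, a, a, a, a])
        pm = make_peptide_matrix(vals)
        norm, _ = normalize_peptides(pm)
        x = norm.intensities.to_numpy()
        m = x[:, 0] - x[:, 1]
        deciles = pd.qcut(a, 10, labels=False)
        for d in range(10):
            assert abs(np.median(m[deciles == d])) < 0.05

    def test_sparse_sample_rejected(self):
        vals = np.full((20, 6), 20.0)
        vals[5:, 0] = np.nan
        pm = make_peptide_matrix(vals)
        with pytest.raises(NormalizationError, match="finite"):
            normalize_peptides(pm)

    def test_raw_scale_input_log_transformed(self):
        rng = np.random.default_rng(3)
        vals = 2.0 ** rng.normal(20, 1, size=(200, 6))
        pm = make_peptide_matrix(vals)
        norm, _ = normalize_peptides(pm, already_log2=False)
        assert norm.intensities.to_numpy().mean() == pytest.approx(20, abs=0.5)


class TestTechnicalVariance:
    def test_constant_spikes_give_zero(self):
        vals = np.full((3, 6), 18.0)
        pm = make_peptide_matrix(vals, spikes=[True, True, True])
        assert estimate_technical_variance(pm) == 0.0

    def test_hand_variance_example(self):
        # one spike {1,2,3}: variance with n-1 denominator = 1.0
        vals = np.array([[1.0, 2.0, 3.0, np.nan, np.nan, np.nan]])
        pm = make_peptide_matrix(vals, spikes=[True])
        assert estimate_technical_variance(pm) == pytest.approx(1.0)

    def test_no_spikes_raises_with_override_hint(self):
        pm = make_peptide_matrix(np.full((3, 6), 20.0))
        with pytest.raises(SpikeInError, match="sigma2_tech=0"):
            estimate_technical_variance(pm)

    def test_pooled_across_spikes(self):
        vals = np.array([[1.0, 2.0, 3.0, 2.0, 2.0, 2.0],
                         [5.0, 5.0, 5.0, 5.0, 5.0, 5.0]])
        pm = make_peptide_matrix(vals, spikes=[True, True])
        ss = np.sum((vals[0] - vals[0].mean()) ** 2)
        assert estimate_technical_variance(pm) == pytest.approx(ss / 10)


class TestModeratedModel:
    def test_d0_zero_recovers_classical_t(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(20, 1, size=(200, 6))
        pm = make_peptide_matrix(vals)
        fit = fit_moderated_model(pm, sigma2_tech=0.0, d0=0)
        ref = stats.ttest_ind(vals[:, :3], vals[:, 3:], axis=1)
        assert np.allclose(fit.table["t"], ref.statistic, atol=1e-9)
        assert np.allclose(fit.table["p"], ref.pvalue, atol=1e-9)

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(5)
        n = 400
        fc = 1.0
        base = rng.normal(20, 1, size=(n, 1))
        noise = rng.normal(0, 0.2, size=(n, 6))
        vals = base + noise
        vals[:, :3] += fc
        pm = make_peptide_matrix(vals)
        fit = fit_moderated_model(pm, sigma2_tech=0.0)
        assert 0.9 < fit.table["log2fc"].mean() < 1.1

    def test_variance_subtraction_floor(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(20, 0.05, size=(50, 6))
        pm = make_peptide_matrix(vals)
        fit = fit_moderated_model(pm, sigma2_tech=10.0)
        tested = fit.table[fit.table["tested"]]
        assert (tested["s2_corr"] >= proteome.VARIANCE_FLOOR).all()

    def test_underpowered_peptides_flagged_untested(self):
        vals = np.full((2, 6), 20.0)
        vals[0, [0, 1]] = np.nan  # one mutant obs only
        vals[1] += np.arange(6) * 0.1
        pm = make_peptide_matrix(vals)
        fit = fit_moderated_model(pm, sigma2_tech=0.0)
        assert not fit.table["tested"].iloc[0]
        assert fit.table["tested"].iloc[1]

    def test_spikes_excluded_from_testing(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(20, 1, size=(10, 6))
        pm = make_peptide_matrix(vals, spikes=[True] * 3 + [False] * 7)
        fit = fit_moderated_model(pm, sigma2_tech=0.0)
        assert (~fit.table["tested"].iloc[:3]).all()

    def test_missing_values_use_pairwise_complete_fit(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(20, 1, size=(30, 6))
        vals[::3, 5] = np.nan
        pm = make_peptide_matrix(vals)
        fit = fit_moderated_model(pm, sigma2_tech=0.0, d0=0)
        row = fit.table.iloc[0]
        ref = stats.ttest_ind(vals[0, :3], vals[0, 3:5])
        assert row["t"] == pytest.approx(ref.statistic, abs=1e-9)
        assert row["df"] == 3

    def test_squeeze_variances_moment_fit_sane(self):
        rng = np.random.default_rng(9)
        true_s2 = 0.25
        s2 = true_s2 * rng.chisquare(4, size=3000) / 4
        post, s0_sq, d0 = squeeze_variances(s2, np.full(3000, 4.0))
        assert s0_sq == pytest.approx(true_s2, rel=0.15)
        assert d0 > 20  # homogeneous truth => strong shrinkage
        assert np.all(post > 0)


class TestSimesAndBH:
    def test_worked_example(self):
        assert simes_p([0.01, 0.02, 0.9]) == pytest.approx(0.03)

    def test_single_p_passthrough(self):
        assert simes_p([0.37]) == pytest.approx(0.37)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_matches_brute_force_and_bound(self, p):
        val = simes_p(p)
        assert val == pytest.approx(brute_force_simes(p), abs=1e-12)
        assert val >= min(p) - 1e-15
        assert val <= len(p) * min(p) + 1e-12

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_bh_matches_step_up_definition(self, p):
        assert np.allclose(bh_adjust(np.array(p)), brute_force_bh(p),
                           atol=1e-12)


class TestTrimmedMean:
    def test_worked_example_drops_two_per_tail(self):
        fcs = [-5, 1, 1, 1, 1, 1, 1, 1, 1, 9]
        assert trimmed_mean_fc(np.array(fcs, float), 0.20) == 1.0

    def test_small_n_untrimmed(self):
        assert trimmed_mean_fc(np.array([1.0, 2.0, 3.0, 10.0]), 0.20) == 4.0

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=40))
    def test_zero_trim_is_mean_and_permutation_invariant(self, fcs):
        arr = np.array(fcs)
        assert trimmed_mean_fc(arr, 0.0) == pytest.approx(np.mean(arr))
        rng = np.random.default_rng(0)
        assert trimmed_mean_fc(rng.permutation(arr), 0.20) == \
            pytest.approx(trimmed_mean_fc(arr, 0.20))

    def test_insensitive_to_inflating_the_maximum(self):
        arr = np.array([1.0, 2, 3, 4, 5, 6])
        assert trimmed_mean_fc(arr, 0.20) == \
            trimmed_mean_fc(np.array([1.0, 2, 3, 4, 5, 1e6]), 0.20)


class TestRollupAndClassification:
    def _stats_for(self, pvals, fcs, proteins):
        idx = pd.Index([f"pep{i}" for i in range(len(pvals))])
        table = pd.DataFrame({
            "log2fc": fcs, "p": pvals, "tested": True,
            "s2": 0.1, "df": 4.0, "s2_corr": 0.1, "s2_post": 0.1, "t": 1.0,
        }, index=idx)
        return proteome.ModeratedStats(
            table=table, sigma2_tech=0.0, s0_squared=0.1, d0=4.0,
            proteins=pd.Series(proteins, index=idx))

    def test_single_peptide_protein_passthrough(self):
        mod = self._stats_for([0.04], [1.5], ["A"])
        de = rollup_proteins(mod)
        assert de.table.loc["A", "simes_p"] == pytest.approx(0.04)
        assert de.table.loc["A", "log2fc"] == pytest.approx(1.5)

    def test_simes_and_trim_applied_per_protein(self):
        pvals = [0.01, 0.02, 0.9] + [0.5] * 10
        fcs = [0.0, 0.0, 0.0] + [-5, 1, 1, 1, 1, 1, 1, 1, 1, 9]
        proteins = ["A"] * 3 + ["B"] * 10
        de = rollup_proteins(self._stats_for(pvals, fcs, proteins))
        assert de.table.loc["A", "simes_p"] == pytest.approx(0.03)
        assert de.table.loc["B", "log2fc"] == pytest.approx(1.0)

    def test_classification_strict_threshold_and_signs(self):
        tab = pd.DataFrame({
            "n_peptides": 1, "log2fc": [1.0, 1.0, -2.0, 0.0],
            "simes_p": [0.01, 0.2, 0.01, 0.01],
            "q": [0.05, 0.2, 0.1, 0.05],
            "call": "ns",
        }, index=pd.Index(list("ABCD"), name="protein_id"))
        up, down = classify_de(ProteinDETable(tab, 0.1))
        assert up == {"A"}          # q 0.05 < 0.1, fc > 0
        assert down == set()        # C at exactly q = 0.1: not DE
        # D: significant but fc == 0 -> neither set

    def test_empty_table_gives_empty_sets(self):
        tab = pd.DataFrame(columns=["n_peptides", "log2fc", "simes_p",
                                    "q", "call"])
        up, down = classify_de(ProteinDETable(tab, 0.1))
        assert up == set() and down == set()

    def test_call_column_consistent_with_classify(self):
        rng = np.random.default_rng(10)
        n = 200
        mod = self._stats_for(rng.uniform(size=n) ** 3,
                              rng.normal(size=n),
                              [f"P{i//2}" for i in range(n)])
        de = rollup_proteins(mod)
        up, down = classify_de(de)
        assert up == set(de.table.index[de.table["call"] == "up"])
        assert down == set(de.table.index[de.table["call"] == "down"])
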