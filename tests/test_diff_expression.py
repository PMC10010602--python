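"""Moderated-t differential expression: fits, shrinkage, p-values, BH."""

import json
import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import lfqpipe as lp
from conftest import make_design, make_matrix


def bh_bruteforce(p):
    """Step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestFitGroupModel:
    def test_constant_groups_zero_variance(self):
        m = make_matrix([[10, 10, 10, 8, 8, 8]], ["H"] * 3 + ["L"] * 3, stage="imputed")
        d = make_design(m.sample_ids, ["H"] * 3 + ["L"] * 3)
        fit = lp.fit_group_model(m, d)
        assert fit.log2fc[0] == 2.0
        assert fit.s2[0] == 0.0
        assert fit.df_residual == 4

    def test_pooled_variance_hand_example(self):
        m = make_matrix([[10, 12, 7, 9]], ["H", "H", "L", "L"], stage="imputed")
        d = make_design(m.sample_ids, ["H", "H", "L", "L"])
        fit = lp.fit_group_model(m, d)
        assert fit.mean_a[0] == 11.0 and fit.mean_b[0] == 8.0
        assert fit.log2fc[0] == 3.0
        assert fit.s2[0] == 2.0  # ((-1)^2+1^2+(-1)^2+1^2)/2
        assert fit.df_residual == 2 and fit.v == 1.0

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(20, 1, (30, 6))
        groups = ["H"] * 3 + ["L"] * 3
        m = make_matrix(vals, groups, stage="imputed")
        d = make_design(m.sample_ids, groups)
        perm = [4, 1, 5, 0, 3, 2]
        m2 = lp.IntensityMatrix(values=m.values.iloc[:, perm],
                                groups=m.groups.iloc[perm], stage="imputed")
        fit, fit2 = lp.fit_group_model(m, d), lp.fit_group_model(m2, d)
        np.testing.assert_allclose(fit.log2fc, fit2.log2fc)
        np.testing.assert_allclose(fit.s2, fit2.s2)

    def test_small_group_rejected(self):
        m = make_matrix([[1, 2, 3]], ["H", "H", "L"], stage="imputed")
        d = make_design(m.sample_ids, ["H", "H", "L"])
        with pytest.raises(ValueError, match=">=2 samples"):
            lp.fit_group_model(m, d)

    def test_more_than_two_groups_needs_contrast(self):
        groups = ["A", "A", "B", "B", "C", "C"]
        m = make_matrix(np.ones((3, 6)), groups, stage="imputed")
        d = make_design(m.sample_ids, groups)
        with pytest.raises(ValueError, match="contrast"):
            lp.fit_group_model(m, d)
        fit = lp.fit_group_model(m, d, contrast=("A", "C"))
        assert fit.contrast == ("A", "C")


class TestSqueezeVariances:
    def test_equal_variances_give_infinite_prior(self):
        eb = lp.squeeze_variances(np.full(20, 0.5), d=4)
        assert math.isinf(eb.d0)
        np.testing.assert_allclose(eb.s2_post, eb.s0_sq)

    def test_prior_recovery_from_scaled_f_variances(self):
        rng = np.random.default_rng(7)
        d0, s0_sq, d = 4.0, 1.0, 4
        s2 = s0_sq * (d0 / rng.chisquare(d0, 5000)) * (rng.chisquare(d, 5000) / d)
        eb = lp.squeeze_variances(s2, d)
        assert abs(eb.d0 - d0) / d0 < 0.15
        assert abs(eb.s0_sq - s0_sq) / s0_sq < 0.05

    def test_matches_limma_squeezevar(self, tmp_path):
        """Independent oracle: Bioconductor limma's empirical-Bayes squeeze."""
        rng = np.random.default_rng(3)
        s2 = 0.5 * (6.0 / rng.chisquare(6.0, 200)) * (rng.chisquare(4, 200) / 4)
        d = 4
        eb = lp.squeeze_variances(s2, d)
        s2_file = tmp_path / "s2.txt"
        np.savetxt(s2_file, s2)
        script = (
            f's2 <- scan("{s2_file}", quiet=TRUE); '
            f"fit <- limma::squeezeVar(s2, df={d}); "
            'cat(jsonlite::toJSON(list(d0=fit$df.prior, s02=fit$var.prior, '
            "post=fit$var.post), digits=12))"
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout)
        assert abs(eb.d0 - ref["d0"][0]) / ref["d0"][0] < 1e-6
        assert abs(eb.s0_sq - ref["s02"][0]) / ref["s02"][0] < 1e-6
        np.testing.assert_allclose(eb.s2_post, np.array(ref["post"]), rtol=1e-8)

    def test_zero_variances_still_shrunk(self):
        rng = np.random.default_rng(1)
        # scaled-F draws guarantee enough dispersion for a finite prior
        s2 = np.r_[(4.0 / rng.chisquare(4.0, 50)) * (rng.chisquare(4, 50) / 4),
                   0.0, 0.0]
        eb = lp.squeeze_variances(s2, d=4)
        assert np.isfinite(eb.d0)
        expected = (eb.d0 * eb.s0_sq) / (eb.d0 + 4)
        np.testing.assert_allclose(eb.s2_post[-2:], expected)

    def test_too_few_finite_variances_is_error(self):
        with pytest.raises(ValueError, match="prior"):
            lp.squeeze_variances(np.array([0.0, 0.0, 1.0]), d=4)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000), st.integers(1, 10))
    def test_shrinkage_bounds_invariant(self, seed, d):
        rng = np.random.default_rng(seed)
        s2 = rng.chisquare(d, 200) / d
        eb = lp.squeeze_variances(s2, d)
        lo = np.minimum(s2, eb.s0_sq) - 1e-12
        hi = np.maximum(s2, eb.s0_sq) + 1e-12
        assert ((eb.s2_post >= lo) & (eb.s2_post <= hi)).all()


class TestModeratedT:
    def _fit(self, a, b):
        vals = np.array([a + b], dtype=float)
        groups = ["H"] * len(a) + ["L"] * len(b)
        m = make_matrix(vals, groups, stage="imputed")
        d = make_design(m.sample_ids, groups)
        return lp.fit_group_model(m, d)

    def test_no_shrinkage_limit_equals_pooled_t(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(20, 1, (100, 6))
        groups = ["H"] * 3 + ["L"] * 3
        m = make_matrix(vals, groups, stage="imputed")
        d = make_design(m.sample_ids, groups)
        fit = lp.fit_group_model(m, d)
        eb = lp.EBayesParams(d0=0.0, s0_sq=1.0, s2_post=fit.s2)
        t, p = lp.moderated_t(fit, eb)
        ref = stats.ttest_ind(vals[:, :3], vals[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(t, ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(p, ref.pvalue, rtol=1e-10)

    def test_hand_value(self):
        fit = self._fit([10.0, 12.0], [7.0, 9.0])
        eb = lp.EBayesParams(d0=2.0, s0_sq=2.0, s2_post=np.array([2.0]))
        t, _ = lp.moderated_t(fit, eb)
        assert t[0] == pytest.approx(3.0 / math.sqrt(2.0), rel=1e-12)

    def test_zero_difference_gives_unit_p(self):
        fit = self._fit([5.0, 7.0], [5.0, 7.0])
        eb = lp.EBayesParams(d0=2.0, s0_sq=1.0, s2_post=np.array([1.0]))
        t, p = lp.moderated_t(fit, eb)
        assert t[0] == 0.0 and p[0] == 1.0

    def test_infinite_prior_uses_normal_tail(self):
        fit = self._fit([10.0, 12.0], [7.0, 9.0])
        eb = lp.EBayesParams(d0=math.inf, s0_sq=2.0, s2_post=np.array([2.0]))
        t, p = lp.moderated_t(fit, eb)
        assert p[0] == pytest.approx(2 * stats.norm.sf(abs(t[0])), rel=1e-12)

    def test_degenerate_variance_flags_infinite_t(self):
        fit = self._fit([10.0, 10.0], [8.0, 8.0])
        eb = lp.EBayesParams(d0=0.0, s0_sq=0.0, s2_post=np.array([0.0]))
        t, p = lp.moderated_t(fit, eb)
        assert np.isinf(t[0]) and p[0] == 0.0


class TestAdjustBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            lp.adjust_bh(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert lp.adjust_bh(np.array([0.123]))[0] == 0.123

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lp.adjust_bh(np.array([0.5, 1.2]))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_equals_bruteforce_stepup(self, p):
        np.testing.assert_allclose(lp.adjust_bh(np.array(p)), bh_bruteforce(p),
                                   rtol=1e-12, atol=1e-12)

    def test_adjusted_at_least_raw(self, gaussian_null_de):
        t = gaussian_null_de.table
        assert (t["adj_p_value"] >= t["p_value"] - 1e-15).all()


class TestFindDep:
    def _two_group(self, seed=0, n=300, n_de=30):
        rng = np.random.default_rng(seed)
        vals = rng.normal(22, 0.5, (n, 6))
        vals[:n_de, 3:] += 3.0
        groups = ["H"] * 3 + ["L"] * 3
        m = make_matrix(vals, groups, stage="imputed")
        return m, make_design(m.sample_ids, groups)

    def test_clear_effects_are_significant_and_sorted(self):
        m, d = self._two_group()
        de = lp.find_dep(m, d)
        planted = {f"P{i}" for i in range(30)}
        assert planted <= set(de.significant_ids())
        assert de.n_significant <= 30 + 0.05 * 270  # few nulls slip through
        adj = de.table["adj_p_value"].to_numpy()
        assert (np.diff(adj) >= 0).all()

    def test_lfc_threshold_is_strict(self):
        # a protein with log2FC exactly 1.0 and tiny p must not be flagged
        vals = np.vstack([
            np.array([[23.0, 23.0, 23.0, 22.0, 22.0, 22.0]]),
            np.random.default_rng(0).normal(22, 0.5, (200, 6)),
        ])
        groups = ["H"] * 3 + ["L"] * 3
        m = make_matrix(vals, groups, stage="imputed")
        d = make_design(m.sample_ids, groups)
        de = lp.find_dep(m, d)
        row = de.table.set_index("protein_id").loc["P0"]
        assert row["log2FC"] == 1.0
        assert not row["significant"]

    def test_group_relabeling_negates_lfc_keeps_p(self):
        # same data, design listing L before H: the contrast flips sign
        m, d = self._two_group()
        rev_samples = m.sample_ids[3:] + m.sample_ids[:3]
        d_rev = make_design(rev_samples, ["L"] * 3 + ["H"] * 3)
        a = lp.find_dep(m, d).table.set_index("protein_id")
        b = lp.find_dep(m, d_rev).table.set_index("protein_id")
        b = b.loc[a.index]
        np.testing.assert_allclose(a["log2FC"], -b["log2FC"], rtol=1e-10)
        np.testing.assert_allclose(a["p_value"], b["p_value"], rtol=1e-10)

    def test_null_pvalues_uniform(self, gaussian_null_de):
        ks = stats.kstest(gaussian_null_de.table["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_power_and_fdr_over_seeds(self):
        recalls, fdrs = [], []
        for seed in range(5):
            p = lp.SimParams(n_proteins=500, n_de=50, bio_reps=3, tech_reps=1,
                             effect_log2=2.0, sigma_within=0.5, dropout=False,
                             seed=seed)
            table, design, truth = lp.simulate_lfq_experiment(p)
            raw = lp.create_intensity_frame(table, design)
            filt = lp.filter_by_group_na(raw)
            imp = lp.impute_minprob(filt, lp.ImputeParams(seed=seed))
            de = lp.find_dep(imp, design)
            sig = set(de.significant_ids())
            true = set(truth.is_de[truth.is_de].index)
            tp = len(sig & true)
            recalls.append(tp / len(true))
            fdrs.append((len(sig) - tp) / max(len(sig), 1))
        assert np.mean(recalls) >= 0.8
        assert np.mean(fdrs) <= 0.10

    def test_result_tsv_round_trip(self, tmp_path):
        m, d = self._two_group()
        de = lp.find_dep(m, d)
        lp.write_de_result(de, tmp_path / "de.tsv")
        de2 = lp.read_de_result(tmp_path / "de.tsv")
        assert de2.contrast == de.contrast
        assert de2.n_significant == de.n_significant
        np.testing.assert_allclose(de2.table["adj_p_value"], de.table["adj_p_value"])
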