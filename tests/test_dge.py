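"""Wald / LRT differential expression and BH correction."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import stressmito as sm
from stressmito.dge import adjust_bh, likelihood_ratio_test, run_dge, wald_test
from stressmito.glm import GlmFit, fit_nb_glm


def make_fit(beta, se, converged=True):
    k = len(beta)
    return GlmFit(
        coefficients=np.asarray(beta, dtype=float),
        standard_errors=np.asarray(se, dtype=float),
        log_likelihood=-10.0,
        deviance=5.0,
        dispersion=0.1,
        n_samples=20,
        converged=converged,
        design_columns=[f"b{i}" for i in range(k)],
    )


class TestWald:
    def test_zero_effect_gives_p_one(self):
        stat, p = wald_test(make_fit([1.0, 0.0], [0.1, 1.0]), "b1")
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_critical_value_gives_five_percent(self):
        stat, p = wald_test(make_fit([0.0, 1.959964], [1.0, 1.0]), "b1")
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_unconverged_fit_flagged(self):
        stat, p = wald_test(make_fit([0.0, 1.0], [1.0, 1.0], converged=False), "b1")
        assert np.isnan(stat) and np.isnan(p)


class TestLrt:
    def test_same_size_designs_rejected(self):
        f = make_fit([1.0, 0.5], [0.1, 0.1])
        with pytest.raises(ValueError, match="more coefficients"):
            likelihood_ratio_test(f, f)

    def test_chi2_critical_value(self):
        full = make_fit([1.0, 0.5], [0.1, 0.1])
        red = make_fit([1.0], [0.1])
        full.log_likelihood = -10.0
        red.log_likelihood = -10.0 - 3.841459 / 2.0
        stat, p = likelihood_ratio_test(full, red)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_null_p_values_are_uniform(self):
        # full model adds a pure-noise covariate; p should be U(0,1)
        rng = np.random.default_rng(8)
        n, g, alpha = 30, 500, 0.02
        r = 1 / alpha
        Y = rng.negative_binomial(r, r / (r + 50.0), size=(g, n))
        noise = rng.normal(size=n)
        Xf = np.column_stack([np.ones(n), noise])
        Xr = np.ones((n, 1))
        ps = []
        from stressmito.glm import fit_nb_glm_many

        full = fit_nb_glm_many(Y, Xf, alpha=alpha)
        red = fit_nb_glm_many(Y, Xr, alpha=alpha)
        stat = np.maximum(2 * (full.log_likelihood - red.log_likelihood), 0)
        ps = scipy.stats.chi2.sf(stat, 1)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


def bh_oracle(p):
    """Brute-force step-up BH, independent of the implementation."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ecdf = np.arange(1, n + 1) / n
    raw = ranked / ecdf
    out = np.empty(n)
    running = np.inf
    for i in range(n - 1, -1, -1):
        running = min(running, raw[i])
        out[i] = min(running, 1.0)
    result = np.empty(n)
    result[order] = out
    return result


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    @pytest.mark.parametrize("p,expected", [([0.2], [0.2]), ([1.0, 1.0, 1.0], [1.0] * 3)])
    def test_edge_cases(self, p, expected):
        np.testing.assert_allclose(adjust_bh(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    def test_nan_passthrough(self):
        out = adjust_bh([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_array_equal(adjust_bh(p), bh_oracle(p))


class TestRunDge:
    def test_null_simulation_type_one_error(self, cohort, scored):
        _, truth = cohort
        gt = sm.make_gene_truth(n_nuclear=800, frac_treatment=0, frac_zscore=0, seed=2)
        cm = sm.simulate_counts(gt, truth, seed=3)
        res = run_dge(cm, scored, design="~ group")
        frac = (res.p_value < 0.05).mean()
        assert 0.02 < frac < 0.08

    def test_effects_are_detected_with_correct_sign(self, small_counts, scored):
        cm, gt = small_counts
        res = run_dge(cm, scored, design="~ group").set_index("gene_id")
        up = gt[(gt["class"] == "treatment") & (gt.log2_effect > 0)].gene_id
        up = [g for g in up if g in res.index]
        assert (res.loc[up, "p_adjusted"] < 0.05).mean() > 0.8
        assert (res.loc[up, "log2_fold_change"] > 0).all()

    def test_sample_permutation_invariance(self, small_counts, scored):
        cm, _ = small_counts
        res1 = run_dge(cm, scored, design="~ group")
        rng = np.random.default_rng(9)
        perm = rng.permutation(list(cm.sample_ids))
        cm2 = cm.subset_samples(perm)
        res2 = run_dge(cm2, scored, design="~ group")
        merged = res1.merge(res2, on="gene_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged.stat_a, merged.stat_b, rtol=1e-6)

    def test_wald_and_lrt_agree_asymptotically(self):
        rng = np.random.default_rng(10)
        n = 200
        group = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        meta = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)], "group": np.where(group > 0, "STRESS", "CTR")}
        )
        mu = 100.0 * 2 ** (rng.normal(0, 0.3, size=(150, 1)) * group)
        r = 1 / 0.1
        Y = rng.negative_binomial(r, r / (r + mu))
        cm = sm.CountMatrix(
            pd.DataFrame(Y, index=[f"g{i}" for i in range(150)], columns=meta.sample_id)
        )
        w = run_dge(cm, meta, design="~ group", test="wald").set_index("gene_id")
        l = run_dge(cm, meta, design="~ group", test="lrt").set_index("gene_id")
        both = w.join(l, lsuffix="_w", rsuffix="_l")
        d = np.abs(np.log10(both.p_value_w + 1e-300) - np.log10(both.p_value_l + 1e-300))
        assert np.nanmedian(d) < 0.1

    def test_all_filtered_raises(self, cohort, scored):
        _, truth = cohort
        gt = sm.make_gene_truth(n_nuclear=20, baseline_mean=0.01, mtdna_baseline=0.01, seed=4)
        cm = sm.simulate_counts(gt, truth, seed=5)
        with pytest.raises(ValueError):
            run_dge(cm, scored, design="~ group")
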