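"""BIC / Schwarz-weight model selection and set-level summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import stressmito as sm
from stressmito.model_selection import (
    bic,
    hs_ls_contrast,
    schwarz_weights,
    select_model_per_gene,
    setlevel_model_summary,
)


class TestBic:
    def test_worked_example(self):
        assert bic(-10.0, 2, 30) == pytest.approx(20 + 2 * np.log(30), abs=1e-9)

    def test_single_observation_has_no_complexity_penalty(self):
        assert bic(-3.0, 5, 1) == pytest.approx(6.0)

    def test_extra_parameter_costs_log_n(self):
        assert bic(-10.0, 3, 50) - bic(-10.0, 2, 50) == pytest.approx(np.log(50))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            bic(-1.0, 0, 10)


class TestSchwarzWeights:
    def test_equal_bics_give_uniform_weights(self):
        np.testing.assert_allclose(schwarz_weights([10.0, 10.0, 10.0]), [1 / 3] * 3)

    def test_worked_pair(self):
        np.testing.assert_allclose(schwarz_weights([0.0, 2 * np.log(3)]), [0.75, 0.25])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(-500, 500), min_size=2, max_size=5),
        st.floats(-100, 100),
    )
    def test_sum_one_and_shift_invariance(self, bics, shift):
        w = schwarz_weights(bics)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(schwarz_weights(np.array(bics) + shift), w, atol=1e-9)

    def test_all_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            schwarz_weights([np.inf, np.nan])


class TestSelectModel:
    def test_weights_sum_to_one_and_best_attains_max(self, small_counts, scored):
        cm, _ = small_counts
        rec = select_model_per_gene(cm, scored)
        s = rec[["BICW_null", "BICW_treatment", "BICW_zscore"]].sum(axis=1)
        np.testing.assert_allclose(s, 1.0, atol=1e-9)
        argmax = rec[["BICW_null", "BICW_treatment", "BICW_zscore"]].idxmax(axis=1)
        assert (argmax.str.replace("BICW_", "") == rec.best_model).all()

    def test_gene_classes_mostly_recovered(self, small_counts, scored):
        cm, gt = small_counts
        rec = select_model_per_gene(cm, scored).merge(gt, on="gene_id")
        for cls, floor_acc in [("null", 0.7), ("treatment", 0.7), ("zscore", 0.7)]:
            d = rec[rec["class"] == cls]
            assert (d.best_model == cls).mean() > floor_acc, cls

    def test_z_equal_to_group_indicator_ties_treatment_and_zscore(self, small_counts, scored):
        cm, _ = small_counts
        meta = scored.copy()
        meta["integrated_z"] = (meta.group == "STRESS").astype(float)
        rec = select_model_per_gene(cm, meta)
        np.testing.assert_allclose(rec.BIC_treatment, rec.BIC_zscore, atol=1e-6)

    def test_gene_and_sample_order_invariance(self, small_counts, scored):
        cm, _ = small_counts
        rec1 = select_model_per_gene(cm, scored).set_index("gene_id")
        rng = np.random.default_rng(1)
        cm2 = cm.subset_genes(rng.permutation(list(cm.gene_ids)))
        cm2 = cm2.subset_samples(rng.permutation(list(cm.sample_ids)))
        rec2 = select_model_per_gene(cm2, scored).set_index("gene_id")
        rec2 = rec2.loc[rec1.index]
        np.testing.assert_allclose(rec1.BICW_zscore, rec2.BICW_zscore, atol=1e-8)

    def test_consistency_improves_with_sample_size(self):
        accs = []
        for n in (10, 40, 160):
            hit = tot = 0
            for seed in range(3):
                table, truth = sm.simulate_cohort(n_ctr=n // 2, n_stress=n - n // 2, seed=seed)
                scored = sm.score_behavior(table)
                gt = sm.make_gene_truth(n_nuclear=200, seed=seed + 40)
                cm = sm.simulate_counts(
                    gt, truth, seed=seed + 80,
                    integrated_z=scored.set_index("animal_id")["integrated_z"],
                )
                rec = select_model_per_gene(cm, scored).merge(gt, on="gene_id")
                hit += (rec.best_model == rec["class"]).sum()
                tot += len(rec)
            accs.append(hit / tot)
        assert accs[0] <= accs[1] + 0.02 and accs[1] <= accs[2] + 0.02


class TestSetSummary:
    def make_records(self, n=20, z_better=None):
        z_better = z_better or []
        rec = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)]})
        rec["BICW_treatment"] = 0.4
        rec["BICW_zscore"] = [0.6 if g in z_better else 0.4 for g in rec.gene_id]
        rec["BICW_null"] = 1 - rec.BICW_treatment - rec.BICW_zscore
        return rec

    def test_ties_give_zero_fraction_and_p_one(self):
        rec = self.make_records()
        out = setlevel_model_summary(rec, {"s": [f"g{i}" for i in range(5)]})
        assert out.frac_zscore_better.iloc[0] == 0.0
        assert out.enrichment_p.iloc[0] == 1.0

    def test_enriched_set_detected(self):
        rec = self.make_records(n=100, z_better=[f"g{i}" for i in range(10)])
        out = setlevel_model_summary(
            rec, {"hit": [f"g{i}" for i in range(10)], "miss": [f"g{i}" for i in range(50, 60)]}
        ).set_index("set")
        assert out.loc["hit", "enrichment_p"] < 0.001
        assert out.loc["miss", "enrichment_p"] == 1.0

    def test_disjoint_set_skipped(self):
        rec = self.make_records()
        out = setlevel_model_summary(rec, {"none": ["absent1", "absent2"]})
        assert out.empty

    def test_mtdna_set_ranks_first_when_z_driven(self, small_counts, scored):
        cm, gt = small_counts
        rec = select_model_per_gene(cm, scored)
        null_genes = gt[gt["class"] == "null"].gene_id.tolist()
        sets = {
            "mtDNA": list(sm.MTDNA_OXPHOS),
            "decoy1": null_genes[:20],
            "decoy2": null_genes[20:40],
        }
        out = setlevel_model_summary(rec, sets).set_index("set")
        assert out.mean_BICW_zscore.idxmax() == "mtDNA"


class TestHsLsContrast:
    def test_hs_specific_effect_detected(self, scored):
        # counts driven by susceptibility class: mtDNA genes up in HS only
        rng = np.random.default_rng(12)
        meta = scored.set_index("animal_id")
        hs = (meta.susceptibility == "HS").to_numpy()
        genes = list(sm.MTDNA_OXPHOS) + [f"null_{i}" for i in range(100)]
        mu = np.full((len(genes), len(meta)), 200.0)
        mu[: len(sm.MTDNA_OXPHOS), hs] *= 2.0
        r = 1 / 0.05
        Y = rng.negative_binomial(r, r / (r + mu))
        cm = sm.CountMatrix(pd.DataFrame(Y, index=genes, columns=meta.index))
        out = hs_ls_contrast(cm, scored).set_index("gene_id")
        mt = [g for g in sm.MTDNA_OXPHOS if g in out.index]
        assert (out.loc[mt, "padj_HS_vs_CTR"] < 0.05).mean() > 0.9
        assert (out.loc[mt, "p_LS_vs_CTR"] > 0.05).mean() > 0.5

    def test_single_animal_class_skipped(self, small_counts, scored):
        cm, _ = small_counts
        meta = scored.copy()
        ls_ids = meta.index[meta.susceptibility == "LS"]
        meta.loc[ls_ids[1:], "susceptibility"] = "HS"  # leave one LS animal
        out = hs_ls_contrast(cm, meta)
        assert "p_LS_vs_CTR" not in out.columns
        assert "p_HS_vs_CTR" in out.columns
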