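# stressmito

Analysis toolkit linking chronic-stress behavioral phenotypes to
mitochondrial gene expression in brain tissue. It covers the full chain
used in chronic-restraint-stress mouse studies:

1. **Behavioral scoring** — per-test z-normalization against the control
   group, a four-parameter social-avoidance composite, the *integrated
   behavioral z-score* (mean of oriented SIT/FST/SaPT z-scores), and
   stratification of stressed animals into low- (LS) and high-susceptible
   (HS), defined by whether the integrated z falls within one control SD
   of the control mean.
2. **Differential expression** — negative-binomial GLMs with
   median-of-ratios size-factor offsets (log mu = Xβ + log s), Wald tests
   for two-group contrasts, likelihood-ratio tests for covariate-corrected
   designs, Benjamini–Hochberg correction.
3. **Competitive gene-set enrichment** — set-vs-rest z-tests on ranked
   statistics with the inter-gene-correlation variance-inflation factor
   VIF = 1 + (m−1)ρ̄, packaged catalogs of the 13 mtDNA-encoded OXPHOS
   genes, and barcode-plot export.
4. **Per-gene model selection** — the core procedure: for every gene,
   three NB GLMs (null; stress-treatment indicator; integrated behavioral
   z-score) are compared by BIC = −2 logL + k ln n, and Schwarz weights
   w_m = exp(−Δ_m/2)/Σ exp(−Δ/2) quantify per-gene model confidence.
   Gene-set summaries and HS/LS-vs-control contrasts follow.
5. **Motif activity** — promoter site counts (log-odds PWM scanning of
   TSS ± 500 bp windows, both strands) and per-sample transcription-factor
   activities A inferred by ridge regression E ≈ N·A, contrasted between
   groups by unpaired t-tests.

A first-class synthetic-data module generates seeded cohorts (behavior,
NB counts with null / treatment-driven / z-score-driven gene classes,
promoters with planted motifs) with ground truth, so every stage is
testable end-to-end without downloading any dataset.

## Worked example

```python
import stressmito as sm

table, truth = sm.simulate_cohort(n_ctr=11, n_stress=16, seed=1)
scored = sm.score_behavior(table)
gene_truth = sm.make_gene_truth(n_nuclear=1000, seed=4)
counts = sm.simulate_counts(
    gene_truth, truth, seed=5,
    integrated_z=scored.set_index("animal_id")["integrated_z"],
)
records = sm.select_model_per_gene(counts, scored)
print(records[records.gene_id == "mt-Nd1"].round(3).to_string(index=False))
```

prints

```
gene_id  BIC_null  BIC_treatment  BIC_zscore  BICW_null  BICW_treatment  BICW_zscore best_model  flagged
 mt-Nd1   516.676        484.811     454.768        0.0             0.0          1.0     zscore    False
```

`mt-Nd1` (an mtDNA-encoded complex-I subunit simulated as z-score-driven)
has essentially all Schwarz weight on the z-score model: its expression
tracks each animal's behavioral severity rather than mere stress
exposure. In the same run the summary

```python
sm.setlevel_model_summary(records, {"mtDNA-OXPHOS": list(sm.MTDNA_OXPHOS)})
```

reports `mean_BICW_zscore = 0.997` and `enrichment_p = 0.0002` for the
mtDNA OXPHOS catalog — the set is collectively better explained by the
behavioral profile. The scripts in `examples/` walk through each
capability (behavioral scoring, differential expression + enrichment,
model selection + HS/LS contrast, motif activity) and print annotated
output.

A thin CLI orchestrates the stages from one YAML config:

```sh
stressmito run-all --config cfg.yaml     # or: simulate | behavior | dge |
                                         # enrichment | select-model | motif
```

Each run writes versioned TSV outputs plus a JSON report (stage
statuses, sub-seeds, input hashes); identical configs reproduce
identical outputs.

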