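"""Motif-activity inference from promoter site counts.

Simulates promoters (TSS +/- 500 bp) with planted motif occurrences and
an expression shift driven by one causal motif, scans the promoters
with log-odds PWM matching, infers per-sample motif activities by ridge
regression of expression on site counts, and contrasts groups by
unpaired t-tests.  The causal motif should top the contrast table.
"""

import numpy as np

import stressmito as sm

rng = np.random.default_rng(7)
pwms = []
for i in range(6):
    cons = rng.integers(0, 4, 8)
    mat = np.full((4, 8), 0.04)
    mat[cons, np.arange(8)] = 0.88
    pwms.append(sm.PWM(f"motif_{i+1}", mat))

seqs, bed, truth = sm.simulate_promoters(300, pwms, seed=7)
expr, groups = sm.simulate_motif_expression(truth, {"motif_1": 1.0}, seed=8)

sites = sm.scan_promoters(seqs, bed, pwms)
print(f"scanned {sites.shape[0]} promoters x {sites.shape[1]} motifs; "
      f"mean sites/promoter: {sites.to_numpy().mean(axis=0).round(2)}")

activity = sm.infer_activities(expr, sites)
print(f"ridge penalty (GCV): {activity.penalty:.3g}; "
      f"normal-equation residual: {activity.residual_norm:.2e}")

contrast = sm.compare_activities(activity, groups)
print("\nper-motif group contrast (STRESS - CTR):")
print(contrast.round(4).to_string(index=False))
print("\nmotif_1 carries the planted activity difference; decoys should be null.")
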