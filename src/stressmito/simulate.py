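"""Seeded synthetic cohorts with known ground truth.

Three generators cover the pipeline's inputs:

* :func:`simulate_cohort` — per-animal behavioral raw measures (social
  interaction, forced swim, saccharin preference) driven by a latent
  per-animal stress-susceptibility severity.  Stressed animals draw
  their severity from a two-component mixture (a low component near the
  control range and a high component well outside it) so that LS/HS
  stratification has genuine structure; controls draw from a narrow
  reference distribution centered at zero.
* :func:`simulate_counts` — negative-binomial gene counts with three
  gene classes: null, treatment-driven (fold change on the STRESS
  indicator) and zscore-driven (fold change per unit of the latent
  severity), plus the packaged 13-gene mtDNA OXPHOS catalog.
* :func:`simulate_promoters` — promoter sequences with Poisson-planted
  motif occurrences, and :func:`simulate_motif_expression` to turn
  planted site counts and per-sample activities into expression
  changes.

Identical seeds and parameters yield identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogs import MTDNA_OXPHOS
from .counts import CountMatrix
from .motifs import PWM, WINDOW_HALF

__all__ = [
    "CohortTruth",
    "simulate_cohort",
    "make_gene_truth",
    "simulate_counts",
    "simulate_promoters",
    "simulate_motif_expression",
]

# Control-group reference distributions for the raw behavioral measures
# (times in seconds within the scored session, volumes in mL over the
# three test days) and the canonical per-unit-severity stress shifts.
BEHAVIOR_BASELINES = {
    "sit_interaction_time_present": (60.0, 12.0),
    "sit_interaction_time_absent": (45.0, 10.0),
    "sit_corner_time_present": (20.0, 6.0),
    "sit_corner_time_absent": (25.0, 6.0),
    "fst_immobility": (100.0, 25.0),
    "sapt_preference": (88.0, 5.0),
    "sapt_total_volume": (12.0, 1.5),
}
# shift per unit latent severity, scaled by the per-test effect size
BEHAVIOR_SHIFTS = {
    "sit_interaction_time_present": -12.0,
    "sit_corner_time_present": +6.0,
    "fst_immobility": +25.0,
    "sapt_preference": -6.0,
}
DEFAULT_EFFECT_SIZES = {"sit": 1.0, "fst": 1.0, "sapt": 1.0}
# STRESS severity mixture: (weight, mean, sd) per component
SUSCEPTIBILITY_MIXTURE = ((0.4, 0.7, 0.25), (0.6, 2.5, 0.35))
CTR_LATENT_SD = 0.25


@dataclass
class CohortTruth:
    """Ground truth per animal: group and latent severity."""

    table: pd.DataFrame  # animal_id, group, latent_susceptibility

    @property
    def latent(self) -> pd.Series:
        return self.table.set_index("animal_id")["latent_susceptibility"]

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("animal_id")["group"]


def simulate_cohort(
    n_ctr: int = 11,
    n_stress: int = 16,
    effect_sizes: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate raw behavioral measures for a CTR/STRESS cohort.

    ``effect_sizes`` scales the canonical per-test shifts (keys sit,
    fst, sapt; 1.0 = the default study conditions, 0 = no effect);
    ``noise_sd`` scales the within-group measurement noise.  Returns the
    raw behavioral table (ready for :func:`stressmito.behavior.
    score_behavior`) and the ground truth.
    """
    if n_ctr < 3 or n_stress < 3:
        raise ValueError("need at least 3 animals per group")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    eff = dict(DEFAULT_EFFECT_SIZES)
    eff.update(effect_sizes or {})
    if not all(np.isfinite(v) for v in eff.values()):
        raise ValueError("effect sizes must be finite")

    rng = np.random.default_rng(seed)
    ids = [f"CTR_{i+1:02d}" for i in range(n_ctr)] + [f"STR_{i+1:02d}" for i in range(n_stress)]
    groups = ["CTR"] * n_ctr + ["STRESS"] * n_stress

    latent = np.empty(n_ctr + n_stress)
    latent[:n_ctr] = rng.normal(0.0, CTR_LATENT_SD, n_ctr)
    weights = np.array([w for w, _, _ in SUSCEPTIBILITY_MIXTURE])
    comp = rng.choice(len(weights), size=n_stress, p=weights / weights.sum())
    means = np.array([m for _, m, _ in SUSCEPTIBILITY_MIXTURE])
    sds = np.array([s for _, _, s in SUSCEPTIBILITY_MIXTURE])
    latent[n_ctr:] = rng.normal(means[comp], sds[comp])

    test_of = {
        "sit_interaction_time_present": "sit",
        "sit_corner_time_present": "sit",
        "fst_immobility": "fst",
        "sapt_preference": "sapt",
    }
    cols: dict[str, np.ndarray] = {}
    for name, (mu, sd) in BEHAVIOR_BASELINES.items():
        x = rng.normal(mu, sd * noise_sd, n_ctr + n_stress)
        shift = BEHAVIOR_SHIFTS.get(name, 0.0)
        if shift:
            x = x + shift * eff[test_of[name]] * latent
        cols[name] = x

    pref = np.clip(cols.pop("sapt_preference"), 0.0, 100.0)
    total = np.maximum(cols.pop("sapt_total_volume"), 0.5)
    table = pd.DataFrame({"animal_id": ids, "group": groups})
    for name in (
        "sit_interaction_time_present",
        "sit_interaction_time_absent",
        "sit_corner_time_present",
        "sit_corner_time_absent",
        "fst_immobility",
    ):
        table[name] = np.maximum(cols[name], 0.0)
    table["sapt_saccharin_volume"] = pref / 100.0 * total
    table["sapt_water_volume"] = total - table["sapt_saccharin_volume"]

    truth = CohortTruth(
        pd.DataFrame({"animal_id": ids, "group": groups, "latent_susceptibility": latent})
    )
    return table, truth


def make_gene_truth(
    n_nuclear: int = 2000,
    frac_treatment: float = 0.05,
    frac_zscore: float = 0.05,
    log2_effect_treatment: float = 1.0,
    log2_effect_zscore: float = 0.5,
    baseline_mean: float = 200.0,
    baseline_log_sd: float = 0.5,
    dispersion: float = 0.1,
    mtdna_class: str = "zscore",
    mtdna_log2_effect: float = 0.5,
    mtdna_baseline: float = 2000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Default gene catalog: nuclear genes of three classes + the 13
    mtDNA OXPHOS genes (class ``mtdna_class``).

    Baselines are log-normal around ``baseline_mean`` with log-SD
    ``baseline_log_sd`` (0 for fixed baselines); dispersion is shared.
    Treatment and zscore effects alternate in sign (up- and
    down-regulation) so size-factor normalization is not systematically
    distorted; NB parameterization: Var = mu + alpha mu^2.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    n_tr = int(round(n_nuclear * frac_treatment))
    n_z = int(round(n_nuclear * frac_zscore))
    n_null = n_nuclear - n_tr - n_z
    classes = ["null"] * n_null + ["treatment"] * n_tr + ["zscore"] * n_z
    effects = (
        [0.0] * n_null
        + [log2_effect_treatment * (1 if i % 2 == 0 else -1) for i in range(n_tr)]
        + [log2_effect_zscore * (1 if i % 2 == 0 else -1) for i in range(n_z)]
    )
    base = baseline_mean * np.exp(rng.normal(0.0, baseline_log_sd, n_nuclear))
    rows = pd.DataFrame(
        {
            "gene_id": [f"gene_{i+1:04d}" for i in range(n_nuclear)],
            "class": classes,
            "log2_effect": effects,
            "baseline_mean": base,
            "dispersion": dispersion,
            "encoding": "nDNA",
            "complex": "none",
        }
    )
    mt = pd.DataFrame(
        {
            "gene_id": list(MTDNA_OXPHOS),
            "class": mtdna_class,
            "log2_effect": mtdna_log2_effect,
            "baseline_mean": mtdna_baseline,
            "dispersion": dispersion,
            "encoding": "mtDNA",
            "complex": [MTDNA_OXPHOS[g] for g in MTDNA_OXPHOS],
        }
    )
    return pd.concat([rows, mt], ignore_index=True)


def simulate_counts(
    gene_truth: pd.DataFrame,
    cohort: CohortTruth,
    library_size_range: tuple[float, float] = (0.7, 1.3),
    seed: int = 0,
    integrated_z: pd.Series | None = None,
) -> CountMatrix:
    """NB counts with mean = baseline * depth * 2^(effect * predictor).

    The predictor is the STRESS indicator for treatment-class genes and
    the latent severity (or ``integrated_z`` when supplied, closing the
    loop with the behavioral module) for zscore-class genes; null genes
    have no effect.  Depth factors are uniform on
    ``library_size_range``.
    """
    if gene_truth.empty:
        raise ValueError("gene_truth is empty")
    if (gene_truth["baseline_mean"] <= 0).any():
        raise ValueError("baseline means must be positive")
    lo, hi = library_size_range
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError("library size range must be positive and ordered")
    animals = cohort.table["animal_id"].to_numpy()
    if len(animals) == 0:
        raise ValueError("cohort is empty")

    rng = np.random.default_rng(seed)
    depth = rng.uniform(lo, hi, len(animals))
    group = (cohort.table["group"].to_numpy() == "STRESS").astype(float)
    severity = (
        integrated_z.loc[animals].to_numpy(dtype=float)
        if integrated_z is not None
        else cohort.table["latent_susceptibility"].to_numpy(dtype=float)
    )

    pred = np.zeros((len(gene_truth), len(animals)))
    cls = gene_truth["class"].to_numpy()
    pred[cls == "treatment"] = group
    pred[cls == "zscore"] = severity

    base = gene_truth["baseline_mean"].to_numpy(dtype=float)[:, None]
    effect = gene_truth["log2_effect"].to_numpy(dtype=float)[:, None]
    mu = base * depth[None, :] * np.exp2(effect * pred)

    alpha = gene_truth["dispersion"].to_numpy(dtype=float)[:, None]
    r = 1.0 / np.maximum(alpha, 1e-8)
    # NB2 via Gamma-Poisson mixture: lambda ~ Gamma(r, mu/r)
    lam = rng.gamma(np.broadcast_to(r, mu.shape), mu / r)
    counts = rng.poisson(lam)

    ann = gene_truth.set_index("gene_id")[["encoding", "complex"]]
    return CountMatrix(
        pd.DataFrame(counts, index=gene_truth["gene_id"].to_numpy(), columns=animals),
        annotations=ann,
    )


def simulate_promoters(
    n_genes: int,
    pwms: list[PWM],
    occurrence_rate: float | np.ndarray = 1.0,
    seed: int = 0,
    gc: float = 0.5,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Promoter sequences with Poisson-planted motif occurrences.

    Each gene gets a 1001-bp window (TSS +/- 500) on its own contig;
    each motif is planted Poisson(``occurrence_rate``) times (scalar or
    per-motif array) at non-overlapping positions, sampling each site
    from the PWM.  Returns (sequences, BED table, planted site-count
    truth).
    """
    if n_genes < len(pwms):
        raise ValueError("need at least as many genes as motifs")
    width = 2 * WINDOW_HALF + 1
    for pwm in pwms:
        if pwm.width > width:
            raise ValueError(f"motif {pwm.motif_id} wider than the promoter window")
    rng = np.random.default_rng(seed)
    rate = np.broadcast_to(np.asarray(occurrence_rate, dtype=float), (len(pwms),))

    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    bed_rows = []
    truth = np.zeros((n_genes, len(pwms)), dtype=np.int64)

    for i in range(n_genes):
        gene = f"gene_{i+1:04d}"
        seq = rng.choice(bases, size=width, p=p_bg)
        occupied = np.zeros(width, dtype=bool)
        for j, pwm in enumerate(pwms):
            k = rng.poisson(rate[j])
            for _ in range(k):
                for _try in range(50):
                    pos = rng.integers(0, width - pwm.width + 1)
                    if not occupied[pos : pos + pwm.width].any():
                        break
                else:
                    continue
                site = [bases[rng.choice(4, p=pwm.matrix[:, c])] for c in range(pwm.width)]
                seq[pos : pos + pwm.width] = site
                occupied[pos : pos + pwm.width] = True
                truth[i, j] += 1
        contig = f"chr_{gene}"
        seqs[contig] = "".join(seq)
        bed_rows.append((contig, 0, width, gene, 0, "+"))

    bed = pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    truth_df = pd.DataFrame(truth, index=bed["name"].to_numpy(), columns=[p.motif_id for p in pwms])
    return seqs, bed, truth_df


def simulate_motif_expression(
    site_counts: pd.DataFrame,
    activity_diff: dict[str, float] | pd.Series,
    n_per_group: int = 15,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression changes E = N A + noise for a two-group design.

    ``activity_diff`` gives each motif's activity difference between
    STRESS and CTR samples (unlisted motifs: 0); per-gene expected
    change is sum over motifs of sites x activity.  Returns (genes x
    samples expression, sample -> group labels).
    """
    rng = np.random.default_rng(seed)
    diff = pd.Series(0.0, index=site_counts.columns)
    for k, v in pd.Series(activity_diff).items():
        diff.loc[k] = v
    samples = [f"CTR_{i+1:02d}" for i in range(n_per_group)] + [
        f"STR_{i+1:02d}" for i in range(n_per_group)
    ]
    groups = pd.Series(["CTR"] * n_per_group + ["STRESS"] * n_per_group, index=samples)
    A = np.outer(diff.to_numpy(), (groups == "STRESS").to_numpy(dtype=float))
    A = A + rng.normal(0.0, 0.05, A.shape)  # small per-sample activity noise
    E = site_counts.to_numpy(dtype=float) @ A + rng.normal(
        0.0, noise_sd, (len(site_counts), len(samples))
    )
    return pd.DataFrame(E, index=site_counts.index, columns=samples), groups
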