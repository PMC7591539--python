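"""Per-gene model selection: does expression track the treatment or the
individual behavioral profile?

For each gene three NB GLMs are fitted with shared size-factor offsets
and a shared per-gene dispersion:

    null       log mu = b0                    (k = 1)
    treatment  log mu = b0 + b1 * 1[STRESS]   (k = 2)
    zscore     log mu = b0 + b1 * z           (k = 2)

where ``z`` is the animal's integrated behavioral z-score.  Models are
compared by the Bayesian information criterion, BIC = -2 logL + k ln n
(n = animals entering the fit), optionally computed from the deviance
(which differs per gene only by the saturated-model constant, cancelling
in the within-gene BIC differences).  Schwarz weights — the softmax of
-BIC/2 — quantify per-gene model confidence and sum to one across the
three candidates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .counts import CountMatrix, estimate_dispersion, filter_low_expression, size_factors
from .dge import adjust_bh, _wald_batch
from .glm import fit_nb_glm_many

log = logging.getLogger(__name__)

__all__ = [
    "bic",
    "schwarz_weights",
    "select_model_per_gene",
    "setlevel_model_summary",
    "hs_ls_contrast",
]

MODELS = ("null", "treatment", "zscore")


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian information criterion, -2 logL + k ln(n)."""
    if n < 1 or k < 1:
        raise ValueError("k and n must be >= 1")
    return -2.0 * float(log_likelihood) + k * np.log(n)


def schwarz_weights(bics) -> np.ndarray:
    """Schwarz weights: softmax of -BIC/2, min-shifted for overflow safety.

    Non-finite BICs receive weight 0 (at least two finite values are
    required).  Weights sum to one and are invariant to adding any
    constant to all BICs.
    """
    b = np.asarray(bics, dtype=float)
    finite = np.isfinite(b)
    if finite.sum() < 2:
        raise ValueError("need at least two finite BICs")
    shifted = b - b[finite].min()
    w = np.where(finite, np.exp(-0.5 * np.where(finite, shifted, 0.0)), 0.0)
    return w / w.sum()


def select_model_per_gene(
    cm: CountMatrix,
    metadata: pd.DataFrame,
    *,
    min_mean: float = 5.0,
    use_deviance: bool = False,
    count_dispersion_param: bool = False,
    dispersion_policy: str = "shrink",
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Fit the three candidate models per gene and score them by BICW.

    Animals without an integrated z-score are dropped (logged).  The
    per-gene dispersion is estimated once under the union design
    (intercept + group + z) and shared across the three fits so their
    likelihoods are comparable; BIC differences of order ln(n) are
    sensitive to dispersion noise, so the default policy moderates the
    moment estimates toward the mean-dispersion trend
    (``dispersion_policy="shrink"``; "mom" uses the raw per-gene
    estimates, or pass ``dispersions`` directly).  ``use_deviance``
    computes BIC from the deviance instead of -2 logL (identical
    Schwarz weights); ``count_dispersion_param`` adds one to every
    model's k (cancels in the weights as well).
    """
    meta = metadata.copy()
    for key in ("sample_id", "animal_id"):
        if key in meta.columns:
            meta = meta.set_index(key)
            break
    meta = meta.loc[[s for s in cm.sample_ids if s in meta.index]]
    has_z = meta["integrated_z"].notna()
    dropped = meta.index[~has_z]
    for aid in dropped:
        log.info("animal %s dropped from model selection: no integrated z", aid)
    meta = meta[has_z]
    if len(meta) < 4:
        raise ValueError("too few animals with an integrated z-score")
    cm = cm.subset_samples(meta.index)

    factors = size_factors(cm, allow_pseudo_reference=True)
    filtered = filter_low_expression(cm, factors, min_mean=min_mean)
    n = len(meta)
    offsets = np.log(factors.loc[filtered.sample_ids].to_numpy(dtype=float))
    group = (meta["group"].astype(str) != "CTR").to_numpy(dtype=float)
    z = meta["integrated_z"].to_numpy(dtype=float)

    ones = np.ones(n)
    X_union = np.column_stack([ones, group, z])
    if np.linalg.matrix_rank(X_union) < 3:
        # z collinear with group (e.g. z IS the indicator): drop to 2 cols
        X_disp = np.column_stack([ones, group])
    else:
        X_disp = X_union
    if dispersions is None:
        if dispersion_policy not in ("shrink", "mom"):
            raise ValueError(f"unknown dispersion policy: {dispersion_policy!r}")
        dispersions = estimate_dispersion(
            filtered, X_disp, factors, shrink_to_trend=dispersion_policy == "shrink"
        )
    alpha = dispersions.loc[filtered.gene_ids].to_numpy(dtype=float)
    usable = np.isfinite(alpha)
    filtered = filtered.subset_genes(filtered.gene_ids[usable])
    alpha = alpha[usable]
    Y = filtered.counts.to_numpy(dtype=float)

    designs = {
        "null": ones[:, None],
        "treatment": np.column_stack([ones, group]),
        "zscore": np.column_stack([ones, z]),
    }
    k_extra = 1 if count_dispersion_param else 0
    ks = {"null": 1 + k_extra, "treatment": 2 + k_extra, "zscore": 2 + k_extra}

    bics = {}
    flagged = np.zeros(len(filtered.gene_ids), dtype=bool)
    for name, X in designs.items():
        fit = fit_nb_glm_many(Y, X, offsets, alpha)
        score = fit.deviance if use_deviance else -2.0 * fit.log_likelihood
        bics[name] = score + ks[name] * np.log(n)
        flagged |= ~fit.converged

    B = np.column_stack([bics[m] for m in MODELS])
    shifted = B - B.min(axis=1, keepdims=True)
    W = np.exp(-0.5 * shifted)
    W /= W.sum(axis=1, keepdims=True)
    best = np.array(MODELS)[W.argmax(axis=1)]

    rec = pd.DataFrame({"gene_id": filtered.gene_ids})
    for j, m in enumerate(MODELS):
        rec[f"BIC_{m}"] = B[:, j]
    for j, m in enumerate(MODELS):
        rec[f"BICW_{m}"] = W[:, j]
    rec["best_model"] = best
    rec["flagged"] = flagged
    return rec


def setlevel_model_summary(records: pd.DataFrame, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Gene-set summaries of the model-selection calls.

    Per set: mean BICW for the zscore and treatment models, the fraction
    of set genes with BICW_zscore > BICW_treatment, and a one-sided
    hypergeometric enrichment p of that binarized call in the set versus
    the remaining analyzed genes.  Sets with no analyzed genes are
    skipped with a warning.
    """
    universe = records["gene_id"]
    zwin = (records["BICW_zscore"] > records["BICW_treatment"]).to_numpy()
    idx = pd.Series(np.arange(len(universe)), index=universe)
    N, K = len(universe), int(zwin.sum())

    rows = []
    for name, members in gene_sets.items():
        hit = idx.index.intersection(pd.Index(members).unique())
        if len(hit) == 0:
            log.warning("gene set %r has no overlap with analyzed genes; skipped", name)
            continue
        sel = idx.loc[hit].to_numpy()
        m, k = len(sel), int(zwin[sel].sum())
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, m)) if k > 0 else 1.0
        rows.append(
            {
                "set": name,
                "n_genes": m,
                "mean_BICW_zscore": float(records["BICW_zscore"].to_numpy()[sel].mean()),
                "mean_BICW_treatment": float(records["BICW_treatment"].to_numpy()[sel].mean()),
                "frac_zscore_better": k / m,
                "enrichment_p": p,
            }
        )
    return pd.DataFrame(rows)


def hs_ls_contrast(
    cm: CountMatrix,
    metadata: pd.DataFrame,
    *,
    min_mean: float = 5.0,
) -> pd.DataFrame:
    """Per-gene HS-vs-CTR and LS-vs-CTR Wald contrasts.

    Fits one NB GLM per gene on the three-level susceptibility class
    (CTR reference) and reports both stressed-class contrasts.  A class
    with fewer than two animals is skipped with a warning.
    """
    meta = metadata.copy()
    for key in ("sample_id", "animal_id"):
        if key in meta.columns:
            meta = meta.set_index(key)
            break
    meta = meta.loc[[s for s in cm.sample_ids if s in meta.index]]
    meta = meta[meta["susceptibility"].isin(["CTR", "LS", "HS"])]
    counts_by_class = meta["susceptibility"].value_counts()
    if counts_by_class.get("CTR", 0) < 2:
        raise ValueError("need at least two CTR animals")
    classes = [c for c in ("HS", "LS") if counts_by_class.get(c, 0) >= 2]
    for c in ("HS", "LS"):
        if c not in classes:
            log.warning("susceptibility class %s has <2 animals; contrast skipped", c)
    if not classes:
        raise ValueError("no stressed class with >= 2 animals")
    keep = meta["susceptibility"].isin(["CTR"] + classes)
    meta = meta[keep]
    cm = cm.subset_samples(meta.index)

    factors = size_factors(cm, allow_pseudo_reference=True)
    filtered = filter_low_expression(cm, factors, min_mean=min_mean)
    offsets = np.log(factors.loc[filtered.sample_ids].to_numpy(dtype=float))
    cols = ["Intercept"] + [f"class[{c}]" for c in classes]
    X = np.column_stack(
        [np.ones(len(meta))] + [(meta["susceptibility"] == c).to_numpy(dtype=float) for c in classes]
    )
    alpha = estimate_dispersion(filtered, X, factors)
    usable = np.isfinite(alpha.to_numpy())
    filtered = filtered.subset_genes(filtered.gene_ids[usable])
    Y = filtered.counts.to_numpy(dtype=float)
    fit = fit_nb_glm_many(Y, X, offsets, alpha.to_numpy()[usable], design_columns=cols)

    out = pd.DataFrame({"gene_id": filtered.gene_ids})
    for c in classes:
        stat, p = _wald_batch(fit, f"class[{c}]")
        j = cols.index(f"class[{c}]")
        out[f"log2fc_{c}_vs_CTR"] = fit.coefficients[:, j] / np.log(2.0)
        out[f"stat_{c}_vs_CTR"] = stat
        out[f"p_{c}_vs_CTR"] = p
        out[f"padj_{c}_vs_CTR"] = adjust_bh(p)
    return out
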