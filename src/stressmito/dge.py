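"""Differential expression on NB GLM fits.

Two-group contrasts use a Wald test on the group coefficient; designs
with nuisance covariates (age, RNA quality, medication status, ...) use
a likelihood-ratio test between nested fits.  Multiple testing is
controlled by Benjamini-Hochberg across tested genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix, estimate_dispersion, filter_low_expression, size_factors
from .design import build_design, parse_formula
from .glm import GlmFit, NbGlmBatch, fit_nb_glm_many

log = logging.getLogger(__name__)

__all__ = ["wald_test", "likelihood_ratio_test", "adjust_bh", "run_dge"]


def wald_test(fit: GlmFit, coefficient: str) -> tuple[float, float]:
    """Wald z-statistic beta/SE and two-sided normal p for one coefficient.

    Returns (nan, nan) for unconverged fits or non-positive SEs; such
    genes are excluded from BH correction downstream.
    """
    if not fit.converged:
        return float("nan"), float("nan")
    beta, se = fit.coef(coefficient), fit.se(coefficient)
    if not np.isfinite(se) or se <= 0:
        return float("nan"), float("nan")
    stat = beta / se
    return float(stat), float(2.0 * scipy.stats.norm.sf(abs(stat)))


def likelihood_ratio_test(full: GlmFit, reduced: GlmFit) -> tuple[float, float]:
    """LRT between nested fits: 2*(ll_full - ll_reduced) ~ chi2(dk)."""
    df = len(full.coefficients) - len(reduced.coefficients)
    if df <= 0:
        raise ValueError("full model must have more coefficients than the reduced model")
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < -1e-6:
        raise ValueError(f"negative LRT statistic ({stat:.3g}); fits not converged?")
    stat = max(stat, 0.0)
    return float(stat), float(scipy.stats.chi2.sf(stat, df))


def adjust_bh(p_values) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(out, index=p_values.index, name="p_adjusted")
    return out


def _wald_batch(batch: NbGlmBatch, coefficient: str) -> tuple[np.ndarray, np.ndarray]:
    j = batch.design_columns.index(coefficient)
    beta = batch.coefficients[:, j]
    se = batch.standard_errors[:, j]
    ok = batch.converged & np.isfinite(se) & (se > 0)
    stat = np.where(ok, beta / np.where(se > 0, se, 1.0), np.nan)
    p = np.where(ok, 2.0 * scipy.stats.norm.sf(np.abs(stat)), np.nan)
    return stat, p


def run_dge(
    cm: CountMatrix,
    metadata: pd.DataFrame,
    design: str = "~ group",
    test: str = "wald",
    *,
    reduced: str | None = None,
    coefficient: str | None = None,
    min_mean: float = 5.0,
    dispersion_policy: str = "shrink",
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression table, sorted by p-value.

    ``metadata`` rows are matched to count-matrix samples by the
    ``animal_id``/``sample_id`` column or the index.  For ``test="wald"``
    the tested coefficient defaults to the last design column; for
    ``test="lrt"`` a ``reduced`` formula nested in ``design`` is
    required (default: the design minus its last term).  Dispersions
    default to moment estimates moderated toward the mean-dispersion
    trend (``dispersion_policy="shrink"``; "mom" for raw estimates).
    """
    meta = metadata.copy()
    for key in ("sample_id", "animal_id"):
        if key in meta.columns:
            meta = meta.set_index(key)
            break
    missing = [s for s in cm.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing samples: {missing}")
    meta = meta.loc[list(cm.sample_ids)]

    factors = size_factors(cm, allow_pseudo_reference=True)
    filtered = filter_low_expression(cm, factors, min_mean=min_mean)
    if len(filtered.gene_ids) == 0:
        raise ValueError("all genes removed by the low-expression filter")

    X = build_design(meta, design)
    offsets = np.log(factors.loc[filtered.sample_ids].to_numpy(dtype=float))
    if dispersions is None:
        if dispersion_policy not in ("shrink", "mom"):
            raise ValueError(f"unknown dispersion policy: {dispersion_policy!r}")
        dispersions = estimate_dispersion(
            filtered, X.to_numpy(), factors, shrink_to_trend=dispersion_policy == "shrink"
        )
    alpha = dispersions.loc[filtered.gene_ids].to_numpy(dtype=float)
    usable = np.isfinite(alpha)
    filtered = filtered.subset_genes(filtered.gene_ids[usable])
    alpha = alpha[usable]

    Y = filtered.counts.to_numpy(dtype=float)
    full = fit_nb_glm_many(Y, X.to_numpy(), offsets, alpha, design_columns=list(X.columns))

    if test == "wald":
        coef = coefficient or X.columns[-1]
        stat, p = _wald_batch(full, coef)
        lfc = full.coefficients[:, X.columns.get_loc(coef)] / np.log(2.0)
    elif test == "lrt":
        reduced_formula = reduced
        if reduced_formula is None:
            terms = parse_formula(design)
            reduced_formula = "~ " + " + ".join(terms[:-1]) if len(terms) > 1 else "~ 1"
        Xr = build_design(meta, reduced_formula)
        if not set(Xr.columns) < set(X.columns):
            raise ValueError("reduced design must be nested in the full design")
        red = fit_nb_glm_many(Y, Xr.to_numpy(), offsets, alpha, design_columns=list(Xr.columns))
        df = X.shape[1] - Xr.shape[1]
        stat = 2.0 * (full.log_likelihood - red.log_likelihood)
        ok = full.converged & red.converged
        stat = np.where(ok, np.maximum(stat, 0.0), np.nan)
        p = np.where(ok, scipy.stats.chi2.sf(stat, df), np.nan)
        extra = [c for c in X.columns if c not in Xr.columns]
        lfc = full.coefficients[:, X.columns.get_loc(extra[0])] / np.log(2.0)
    else:
        raise ValueError(f"unknown test: {test!r}")

    res = pd.DataFrame(
        {
            "gene_id": filtered.gene_ids,
            "log2_fold_change": lfc,
            "stat": stat,
            "p_value": p,
            "p_adjusted": adjust_bh(p),
            "test": test,
        }
    )
    n_failed = int(np.isnan(p).sum())
    if n_failed:
        log.warning("%d genes flagged (unconverged or degenerate); excluded from BH", n_failed)
    return res.sort_values("p_value", kind="stable").reset_index(drop=True)
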