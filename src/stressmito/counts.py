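"""Count-matrix container, I/O, normalization and dispersion estimation.

The container is a thin wrapper around a genes x samples integer
DataFrame plus per-gene annotations (nuclear vs mitochondrial encoding
and OXPHOS complex).  Normalization follows the median-of-ratios
size-factor convention: each sample is scaled by the median, over
reference genes, of its counts relative to the per-gene geometric mean
across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .glm import ALPHA_FLOOR, fit_nb_glm_many

log = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "read_counts",
    "write_counts",
    "size_factors",
    "estimate_dispersion",
    "log_norm_transform",
    "filter_low_expression",
]


@dataclass
class CountMatrix:
    """Integer genes x samples counts with optional gene annotations.

    ``annotations`` carries ``encoding`` ({nDNA, mtDNA}) and ``complex``
    ({I..V, none}) columns indexed by gene id.
    """

    counts: pd.DataFrame
    annotations: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        self.counts = df.astype(np.int64)
        if self.annotations is not None:
            missing = self.counts.index.difference(self.annotations.index)
            if len(missing):
                extra = pd.DataFrame(
                    {"encoding": "nDNA", "complex": "none"}, index=missing
                )
                self.annotations = pd.concat([self.annotations, extra])
            self.annotations = self.annotations.loc[self.counts.index]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes) -> "CountMatrix":
        ann = self.annotations.loc[genes] if self.annotations is not None else None
        return CountMatrix(self.counts.loc[genes], ann)

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.annotations)


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write counts as TSV (genes x samples) or MatrixMarket triplet.

    The MTX form writes ``<stem>.mtx`` plus ``<stem>.rows.txt`` and
    ``<stem>.cols.txt`` sidecars holding gene and sample ids.
    """
    path = Path(path)
    if format == "tsv":
        cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        stem = path.with_suffix("")
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts.to_numpy()))
        Path(f"{stem}.rows.txt").write_text("\n".join(cm.gene_ids) + "\n")
        Path(f"{stem}.cols.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix written by :func:`write_counts`."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.name is None:
            raise ValueError("malformed header: first column must name the gene id")
        df.index.name = None
        return CountMatrix(df)
    if format == "mtx":
        stem = path.with_suffix("")
        mat = scipy.io.mmread(str(path))
        genes = Path(f"{stem}.rows.txt").read_text().splitlines()
        samples = Path(f"{stem}.cols.txt").read_text().splitlines()
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))
    raise ValueError(f"unknown format: {format!r}")


def size_factors(cm: CountMatrix | pd.DataFrame, *, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with strictly positive counts in every
    sample; each sample's factor is the median over reference genes of
    count / per-gene geometric mean.  With ``allow_pseudo_reference``
    the reference relaxes to genes positive in >= 50% of samples, with
    the geometric mean taken over their positive entries.
    """
    df = cm.counts if isinstance(cm, CountMatrix) else cm
    arr = df.to_numpy(dtype=float)
    positive = np.all(arr > 0, axis=1)
    if positive.any():
        ref = arr[positive]
        log_geomean = np.log(ref).mean(axis=1)
        ratios = np.log(ref) - log_geomean[:, None]
    elif allow_pseudo_reference:
        frac_pos = (arr > 0).mean(axis=1)
        keep = frac_pos >= 0.5
        if not keep.any():
            raise ValueError("no usable reference genes even for the pseudo-reference")
        ref = arr[keep]
        with np.errstate(divide="ignore"):
            logs = np.where(ref > 0, np.log(ref), np.nan)
        log_geomean = np.nanmean(logs, axis=1)
        ratios = logs - log_geomean[:, None]
    else:
        raise ValueError(
            "no gene has positive counts in all samples; "
            "retry with allow_pseudo_reference=True"
        )
    sf = np.exp(np.nanmedian(ratios, axis=0))
    return pd.Series(sf, index=df.columns, name="size_factor")


def log_norm_transform(
    cm: CountMatrix | pd.DataFrame,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount); for visualisation and
    correlation estimation only, never inference."""
    df = cm.counts if isinstance(cm, CountMatrix) else cm
    if factors is None:
        factors = size_factors(df)
    s = factors.loc[df.columns].to_numpy(dtype=float)
    if np.any(s <= 0):
        raise ValueError("size factors must be positive")
    return pd.DataFrame(
        np.log2(df.to_numpy(dtype=float) / s + pseudocount),
        index=df.index,
        columns=df.columns,
    )


def filter_low_expression(
    cm: CountMatrix, factors: pd.Series | None = None, min_mean: float = 5.0
) -> CountMatrix:
    """Drop genes whose mean normalized count is below ``min_mean``.

    Mirrors the exclusion of genes expressed too low to be reliably
    detected; the threshold is explicit and configurable.
    """
    if factors is None:
        factors = size_factors(cm, allow_pseudo_reference=True)
    norm = cm.counts.to_numpy(dtype=float) / factors.loc[cm.sample_ids].to_numpy()
    keep = norm.mean(axis=1) >= min_mean
    log.info("low-expression filter: kept %d / %d genes", int(keep.sum()), len(keep))
    return cm.subset_genes(cm.gene_ids[keep])


def estimate_dispersion(
    cm: CountMatrix | pd.DataFrame,
    design: np.ndarray,
    factors: pd.Series | None = None,
    *,
    shrink_to_trend: bool = False,
    floor: float = ALPHA_FLOOR,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments around GLM means.

    Fits a Poisson-limit GLM per gene (dispersion at the floor) to get
    fitted means ``mu`` under the design, then solves the moment
    identity ``E[(y - mu)^2] = mu + alpha mu^2``:

        alpha = sum((y - mu)^2 - mu) / sum(mu^2)

    floored at ``floor``.

    With ``shrink_to_trend`` the raw moment estimates are moderated by
    an empirical-Bayes step: a mean-dispersion trend a0 + a1/mu is
    fitted across genes, the sampling variance of the raw estimator is
    measured by an internal parametric NB simulation under the same
    design and depths, and each gene is pulled toward its trend value
    with weight tau^2 / (tau^2 + s^2), where tau^2 is the excess
    (true) spread of dispersions around the trend and s^2 the sampling
    variance.  When genes share one dispersion the weight approaches
    zero and the estimate approaches the pooled trend.
    """
    df = cm.counts if isinstance(cm, CountMatrix) else cm
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than design columns to estimate dispersion")
    if factors is None:
        factors = size_factors(df, allow_pseudo_reference=True)
    off = np.log(factors.loc[df.columns].to_numpy(dtype=float))
    Y = df.to_numpy(dtype=float)

    all_zero = Y.sum(axis=1) == 0
    Yfit = np.where(all_zero[:, None], 1.0, Y)  # placeholder rows; flagged below
    batch = fit_nb_glm_many(Yfit, X, off, floor)
    mu = np.exp(np.clip(batch.coefficients @ X.T + off, -300, 300))

    def raw_mom(y: np.ndarray, m: np.ndarray, Xl: np.ndarray) -> np.ndarray:
        # first pass with a global n/(n-p) dof correction, then refine
        # with per-observation GLM leverages under the implied weights
        num = ((y - m) ** 2 - m).sum(axis=1)
        den = (m**2).sum(axis=1)
        a0 = np.maximum(num / den * n / (n - p), floor)
        W = m / (1.0 + a0[:, None] * m)
        XtWX = np.einsum("np,gn,nq->gpq", Xl, W, Xl)
        cov = np.linalg.inv(XtWX + 1e-12 * np.eye(p))
        h = W * np.einsum("gpq,np,nq->gn", cov, Xl, Xl)
        h = np.clip(h, 0.0, 0.99)
        num = ((y - m) ** 2 / (1.0 - h) - m).sum(axis=1)
        return num / den

    alpha_raw = raw_mom(Y, mu, X)
    alpha = np.maximum(alpha_raw, floor)
    alpha[all_zero] = np.nan

    if shrink_to_trend and (~all_zero).sum() >= 20:
        keep = ~all_zero
        mu_bar = mu.mean(axis=1)
        # robust trend alpha ~ a0 + a1/mu (MoM structure), trimmed fit
        A = np.column_stack([np.ones(keep.sum()), 1.0 / np.maximum(mu_bar[keep], 1e-8)])
        r = alpha_raw[keep]
        lo_q, hi_q = np.quantile(r, [0.05, 0.95])
        trim = (r >= lo_q) & (r <= hi_q)
        coef, *_ = np.linalg.lstsq(A[trim], r[trim], rcond=None)
        trend = np.maximum(A @ coef, floor)

        # sampling variance of the raw estimator: parametric simulation
        # of NB genes at the trend dispersion under the same design.
        # Gene subset and sample order are canonicalized (sorted ids)
        # so the estimate is invariant to input row/column order.
        rng = np.random.default_rng(0)
        kept_idx = np.flatnonzero(keep)
        gene_order = np.argsort(df.index.to_numpy().astype(str)[kept_idx], kind="stable")
        n_sim = min(200, keep.sum())
        pick_local = gene_order[:: max(1, len(gene_order) // n_sim)][:n_sim]
        sample_order = np.argsort(df.columns.to_numpy().astype(str), kind="stable")
        mu_sim = mu[kept_idx[pick_local]][:, sample_order]
        a_sim = trend[pick_local]
        rr = 1.0 / a_sim[:, None]
        lam = rng.gamma(np.broadcast_to(rr, mu_sim.shape), mu_sim / rr)
        y_sim = rng.poisson(lam).astype(float)
        X_s, off_s = X[sample_order], off[sample_order]
        b_sim = fit_nb_glm_many(y_sim, X_s, off_s, floor)
        mu_fit = np.exp(np.clip(b_sim.coefficients @ X_s.T + off_s, -300, 300))
        s2 = float(np.var(raw_mom(y_sim, mu_fit, X_s) - a_sim))

        resid = alpha_raw[keep] - trend
        tau2 = max(float(np.var(resid[trim])) - s2, 0.0)
        w = tau2 / (tau2 + s2) if (tau2 + s2) > 0 else 0.0
        shrunk = trend + w * resid
        alpha[keep] = np.maximum(shrunk, floor)
        alpha[all_zero] = np.nan

    return pd.Series(alpha, index=df.index, name="dispersion")
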