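"""Negative-binomial GLM engine (log link, known dispersion).

This is the shared fitting core used by differential expression and
per-gene model selection.  Counts are modelled as NB2,

    y_ij ~ NB(mu_ij, alpha_i),   Var = mu + alpha * mu^2,
    log mu_ij = x_j' beta_i + offset_j,

with the per-gene dispersion ``alpha`` treated as known (estimated
beforehand, see :mod:`stressmito.counts`).  Fitting is iteratively
reweighted least squares with step-halving, vectorised across genes:
all genes share the design matrix and offsets, so the per-iteration
cost is a batch of tiny (p x p) solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

# Dispersion below this is numerically Poisson; also the floor used by
# the moment estimator so that 1/alpha stays finite.
ALPHA_FLOOR = 1e-8

__all__ = ["GlmFit", "NbGlmBatch", "fit_nb_glm", "fit_nb_glm_many", "nb_log_likelihood", "nb_deviance"]


@dataclass
class GlmFit:
    """Fitted per-gene NB GLM."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    deviance: float
    dispersion: float
    n_samples: int
    converged: bool
    design_columns: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.design_columns.index(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.design_columns.index(name)])


@dataclass
class NbGlmBatch:
    """Vectorised fit results for G genes sharing one design.

    Arrays are indexed (gene, coefficient) or (gene,).
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: np.ndarray
    deviance: np.ndarray
    dispersion: np.ndarray
    n_samples: int
    converged: np.ndarray
    design_columns: list[str]

    def __getitem__(self, i: int) -> GlmFit:
        return GlmFit(
            coefficients=self.coefficients[i].copy(),
            standard_errors=self.standard_errors[i].copy(),
            log_likelihood=float(self.log_likelihood[i]),
            deviance=float(self.deviance[i]),
            dispersion=float(self.dispersion[i]),
            n_samples=self.n_samples,
            converged=bool(self.converged[i]),
            design_columns=list(self.design_columns),
        )


def nb_log_likelihood(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood summed over samples; shapes (G, n) and (G,)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    alpha = np.maximum(np.asarray(alpha, dtype=float), ALPHA_FLOOR)
    r = 1.0 / alpha[..., None] if alpha.ndim == y.ndim - 1 else 1.0 / alpha
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=-1)


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 deviance (twice the saturated-minus-fitted log-likelihood)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    alpha = np.maximum(np.asarray(alpha, dtype=float), ALPHA_FLOOR)
    r = 1.0 / alpha[..., None] if alpha.ndim == y.ndim - 1 else 1.0 / alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    term2 = (y + r) * np.log((y + r) / (mu + r))
    dev = 2.0 * (term1 - term2).sum(axis=-1)
    return np.maximum(dev, 0.0)


def _check_design(design: np.ndarray) -> None:
    if design.ndim != 2:
        raise ValueError("design must be a 2-D matrix")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")


def fit_nb_glm_many(
    counts: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray | None = None,
    alpha: np.ndarray | float = ALPHA_FLOOR,
    *,
    design_columns: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NbGlmBatch:
    """Fit one NB GLM per gene, vectorised over genes.

    Parameters
    ----------
    counts
        (G, n) non-negative counts.
    design
        (n, p) full-column-rank design matrix, shared by all genes.
    offsets
        (n,) log offsets (log size factors); zeros if omitted.
    alpha
        Per-gene NB dispersion, scalar or (G,).
    """
    Y = np.atleast_2d(np.asarray(counts, dtype=float))
    X = np.asarray(design, dtype=float)
    _check_design(X)
    G, n = Y.shape
    p = X.shape[1]
    if X.shape[0] != n:
        raise ValueError(f"design has {X.shape[0]} rows but counts have {n} samples")
    if n <= 0:
        raise ValueError("no samples")
    off = np.zeros(n) if offsets is None else np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(off)):
        raise ValueError("offsets must be finite")
    a = np.broadcast_to(np.maximum(np.asarray(alpha, dtype=float), ALPHA_FLOOR), (G,)).copy()
    if design_columns is None:
        design_columns = [f"x{j}" for j in range(p)]

    # Initialise from a one-step least-squares fit on the log scale.
    z0 = np.log(Y + 0.5) - off
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ z0.T).T  # (G, p)

    eta = beta @ X.T + off
    eta = np.clip(eta, -300, 300)
    mu = np.exp(eta)
    ll = nb_log_likelihood(Y, mu, a)

    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Ya, mua, aa, ba, lla = Y[idx], mu[idx], a[idx], beta[idx], ll[idx]

        W = mua / (1.0 + aa[:, None] * mua)  # IRLS weights, (g, n)
        z = (np.clip(np.log(np.maximum(mua, 1e-300)), -300, 300)) + (Ya - mua) / np.maximum(mua, 1e-300)
        # Normal equations per gene: (X' W X) beta = X' W (z - off)
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X)
        XtWz = np.einsum("np,gn->gp", X, W * (z - off))
        try:
            beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            XtWX = XtWX + 1e-10 * np.eye(p)
            beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]

        # Step-halving on genes whose likelihood got worse.
        step = beta_new - ba
        frac = np.ones(len(idx))
        for _half in range(20):
            cand = ba + frac[:, None] * step
            eta_c = np.clip(cand @ X.T + off, -300, 300)
            mu_c = np.exp(eta_c)
            ll_c = nb_log_likelihood(Ya, mu_c, aa)
            bad = ll_c < lla - 1e-12
            if not bad.any():
                break
            frac[bad] *= 0.5
        cand = ba + frac[:, None] * step
        eta_c = np.clip(cand @ X.T + off, -300, 300)
        mu_c = np.exp(eta_c)
        ll_c = nb_log_likelihood(Ya, mu_c, aa)

        delta = np.abs(cand - ba).max(axis=1)
        beta[idx], mu[idx], ll[idx] = cand, mu_c, ll_c
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False

    # Standard errors from the Fisher information at the optimum.
    W = mu / (1.0 + a[:, None] * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, W, X)
    se = np.full((G, p), np.nan)
    ok = np.zeros(G, dtype=bool)
    try:
        cov = np.linalg.inv(XtWX)
        diag = np.einsum("gpp->gp", cov)
        good = np.all(diag > 0, axis=1)
        se[good] = np.sqrt(diag[good])
        ok = good
    except np.linalg.LinAlgError:
        for g in range(G):
            try:
                c = np.linalg.inv(XtWX[g])
                d = np.diag(c)
                if np.all(d > 0):
                    se[g] = np.sqrt(d)
                    ok[g] = True
            except np.linalg.LinAlgError:
                pass
    converged = converged & ok

    dev = nb_deviance(Y, mu, a)
    return NbGlmBatch(
        coefficients=beta,
        standard_errors=se,
        log_likelihood=ll,
        deviance=dev,
        dispersion=a,
        n_samples=n,
        converged=converged,
        design_columns=design_columns,
    )


def fit_nb_glm(
    gene_counts: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray | None = None,
    alpha: float = ALPHA_FLOOR,
    **kwargs,
) -> GlmFit:
    """Fit a single gene's NB GLM; see :func:`fit_nb_glm_many`."""
    batch = fit_nb_glm_many(
        np.asarray(gene_counts, dtype=float)[None, :], design, offsets, alpha, **kwargs
    )
    return batch[0]
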