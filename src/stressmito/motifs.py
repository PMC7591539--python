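"""Promoter motif scanning and motif-activity inference.

Transcription-factor binding sites are counted in promoter windows
(TSS +/- 500 bp) by log-odds scanning of position weight matrices on
both strands.  Per-sample motif activities A are then inferred from the
linear model E ~ N A by ridge regression, where E is row-centered
log-normalized expression change and N the column-centered site-count
matrix, and finally contrasted between groups by unpaired t-tests.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq

from .dge import adjust_bh

log = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "read_meme",
    "write_meme",
    "read_bed",
    "scan_promoters",
    "ActivityTable",
    "infer_activities",
    "compare_activities",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_THRESHOLD_BITS = 10.0
WINDOW_HALF = 500  # promoter window is TSS +/- 500 bp -> 1001 bases


@dataclass
class PWM:
    """Position weight matrix: (4, width) base probabilities, rows ACGT."""

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (ACGT)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
        """log2 odds scores vs background, probabilities smoothed by
        ``pseudocount`` (added then renormalized per column)."""
        p = (self.matrix + pseudocount) / (1.0 + 4.0 * pseudocount)
        bg = self.background / self.background.sum()
        return np.log2(p / bg[:, None])

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1], self.background[::-1])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


def read_meme(path: str | Path) -> list[PWM]:
    """Read PWMs from a minimal-MEME motif file."""
    with open(path) as handle:
        record = bio_motifs.parse(handle, "minimal")
    bg = np.array([record.background.get(b, 0.25) for b in BASES], dtype=float)
    out = []
    for m in record:
        mat = np.array([list(m.pwm[b]) for b in BASES], dtype=float)
        out.append(PWM(m.name or m.base_id or f"motif_{len(out)}", mat, bg.copy()))
    return out


def write_meme(pwms: list[PWM], path: str | Path) -> None:
    """Write PWMs in minimal-MEME format."""
    buf = io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    buf.write("Background letter frequencies\n")
    buf.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
    for pwm in pwms:
        buf.write(f"MOTIF {pwm.motif_id}\n")
        # large nsites so probability -> count -> probability round trips
        # survive the integer-count representation of MEME readers
        buf.write(f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 1000000 E= 0\n")
        for col in pwm.matrix.T:
            buf.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file of TSS windows (0-based, half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _count_hits(encoded: np.ndarray, scores: np.ndarray, threshold: float) -> int:
    w = scores.shape[1]
    L = len(encoded)
    if L < w:
        return 0
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    valid = np.all(windows >= 0, axis=1)
    if not valid.any():
        return 0
    win = windows[valid]
    s = scores[np.maximum(win, 0), np.arange(w)].sum(axis=1)
    return int((s >= threshold).sum())


def scan_promoters(
    promoters: str | Path | dict[str, str],
    tss: pd.DataFrame | str | Path,
    pwms: list[PWM],
    threshold: float = DEFAULT_THRESHOLD_BITS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Count motif occurrences in TSS +/- 500 bp windows.

    ``promoters`` is a FASTA path or {contig id: sequence} dict; ``tss``
    a BED table whose ``chrom`` values name FASTA records and whose
    intervals are the (0-based half-open) windows, reflected for
    minus-strand genes.  Positions on either strand scoring at least
    ``threshold`` bits are counted; windows overhanging a contig end are
    clipped with a warning.  Returns a genes x motifs integer DataFrame.
    """
    if isinstance(promoters, (str, Path)):
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(promoters), "fasta")}
    else:
        seqs = dict(promoters)
    bed = read_bed(tss) if isinstance(tss, (str, Path)) else tss

    missing = sorted(set(bed["chrom"]) - set(seqs))
    if missing:
        raise ValueError(f"BED contigs missing from FASTA: {missing}")

    score_pairs = []
    for pwm in pwms:
        fwd = pwm.log_odds(pseudocount)
        rev = pwm.reverse_complement().log_odds(pseudocount)
        score_pairs.append((fwd, rev))

    counts = np.zeros((len(bed), len(pwms)), dtype=np.int64)
    for i, row in enumerate(bed.itertuples(index=False)):
        contig = seqs[row.chrom]
        start, end = int(row.start), int(row.end)
        if start < 0 or end > len(contig):
            log.warning("window %s on %s clipped to contig bounds", row.name, row.chrom)
            start, end = max(start, 0), min(end, len(contig))
        window = contig[start:end]
        if getattr(row, "strand", "+") == "-":
            window = str(Seq(window).reverse_complement())
        enc = _encode(window)
        for j, (fwd, rev) in enumerate(score_pairs):
            counts[i, j] = _count_hits(enc, fwd, threshold) + _count_hits(enc, rev, threshold)

    return pd.DataFrame(counts, index=bed["name"].to_numpy(), columns=[p.motif_id for p in pwms])


@dataclass
class ActivityTable:
    """Inferred motif x sample activities plus fit diagnostics."""

    activities: pd.DataFrame
    penalty: float
    residual_norm: float
    zero_motifs: list[str] = field(default_factory=list)


def _gcv_lambda(d: np.ndarray, UtE: np.ndarray, n_genes: int, grid: np.ndarray) -> float:
    best_lam, best_gcv = grid[0], np.inf
    tol = (d.max() if len(d) else 0.0) * 1e-12
    for lam in grid:
        with np.errstate(divide="ignore", invalid="ignore"):
            shrink = np.where(d > tol, d**2 / (d**2 + lam), 0.0)
        # residual sum of squares in the rotated basis
        rss = ((1.0 - shrink)[:, None] ** 2 * UtE**2).sum()
        edf = shrink.sum()
        denom = max(n_genes - edf, 1e-9)
        gcv = (rss / n_genes) / (denom / n_genes) ** 2
        if gcv < best_gcv:
            best_gcv, best_lam = gcv, lam
    return float(best_lam)


def infer_activities(
    delta_expression: pd.DataFrame,
    site_counts: pd.DataFrame,
    penalty: float | str = "gcv",
    center: bool = True,
) -> ActivityTable:
    """Ridge-regression motif activities per sample.

    Solves, per sample s, ``min_A || E_s - N A_s ||^2 + lambda ||A_s||^2``
    via the normal equations, by default after column-centering N and
    row-centering E across samples (absorbing the intercept; disable
    with ``center=False`` when inputs are already centered or raw
    solutions are wanted).  ``penalty`` is a fixed lambda >= 0 or "gcv"
    for generalized cross-validation on a log-spaced grid.  All-zero
    motif columns get activity 0 and are flagged.
    """
    genes = delta_expression.index.intersection(site_counts.index)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes shared between expression and site counts")
    E = delta_expression.loc[genes].to_numpy(dtype=float)
    N = site_counts.loc[genes].to_numpy(dtype=float)

    zero = N.sum(axis=0) == 0
    zero_motifs = [m for m, z in zip(site_counts.columns, zero) if z]
    for m in zero_motifs:
        log.warning("motif %s has no sites in any promoter; activity set to 0", m)

    if center:
        E = E - E.mean(axis=1, keepdims=True)  # row-center expression
        Nc = N - N.mean(axis=0, keepdims=True)  # column-center sites
    else:
        Nc = N.copy()
    Nc[:, zero] = 0.0

    U, d, Vt = np.linalg.svd(Nc, full_matrices=False)
    UtE = U.T @ E

    if penalty == "gcv":
        dmax = d.max() if len(d) else 1.0
        grid = np.concatenate([[0.0], np.geomspace(1e-4, 1e4, 33) * max(dmax**2, 1e-12)])
        lam = _gcv_lambda(d, UtE, len(genes), grid)
    else:
        lam = float(penalty)
        if lam < 0:
            raise ValueError("penalty must be >= 0")

    tol = (d.max() if len(d) else 0.0) * 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.where(d > tol, d / (d**2 + lam), 0.0)
    A = Vt.T @ (shrink[:, None] * UtE)
    A[zero, :] = 0.0

    resid = np.linalg.norm((Nc.T @ Nc + lam * np.eye(Nc.shape[1])) @ A - Nc.T @ E)
    activities = pd.DataFrame(A, index=site_counts.columns, columns=delta_expression.columns)
    return ActivityTable(activities, penalty=lam, residual_norm=float(resid), zero_motifs=zero_motifs)


def compare_activities(activities: ActivityTable | pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-motif unpaired two-sided t-test of activities between groups.

    ``groups`` maps sample id -> group label (exactly two levels, each
    with >= 2 samples).  Motifs constant within both groups get a
    flagged NaN p.  P-values are BH-adjusted across motifs.
    """
    A = activities.activities if isinstance(activities, ActivityTable) else activities
    g = pd.Series(groups).loc[A.columns]
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a_cols, b_cols = (g == levels[0]).to_numpy(), (g == levels[1]).to_numpy()
    if a_cols.sum() < 2 or b_cols.sum() < 2:
        raise ValueError("each group needs >= 2 samples")

    Xa, Xb = A.to_numpy()[:, a_cols], A.to_numpy()[:, b_cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = scipy.stats.ttest_ind(Xb, Xa, axis=1)
    constant = (Xa.std(axis=1) == 0) & (Xb.std(axis=1) == 0)
    t = np.where(constant, np.nan, t)
    p = np.where(constant, np.nan, p)
    out = pd.DataFrame(
        {
            "motif": A.index,
            "mean_" + levels[0]: Xa.mean(axis=1),
            "mean_" + levels[1]: Xb.mean(axis=1),
            "t_stat": t,
            "p_value": p,
            "p_adjusted": adjust_bh(p),
            "flagged": constant,
        }
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
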