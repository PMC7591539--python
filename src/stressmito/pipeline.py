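"""Pipeline orchestration: run the headline analyses from one config.

Stages (dependency order): simulate -> behavior -> dge -> enrichment ->
select_model -> motif.  One seed key fans out to per-stage sub-seeds by
fixed offsets, so re-running an identical config reproduces identical
outputs while stages stay independently seeded.  Each run writes a
machine-readable JSON report with stage statuses, seeds, row counts and
input file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as behavior_mod
from .catalogs import MTDNA_OXPHOS
from .counts import read_counts, write_counts
from .dge import run_dge
from .enrichment import directional_mito_enrichment, read_gmt
from .model_selection import hs_ls_contrast, select_model_per_gene, setlevel_model_summary
from .motifs import compare_activities, infer_activities, read_meme, scan_promoters
from .simulate import (
    make_gene_truth,
    simulate_cohort,
    simulate_counts,
    simulate_motif_expression,
    simulate_promoters,
)

log = logging.getLogger(__name__)

STAGES = ["simulate", "behavior", "dge", "enrichment", "select_model", "motif"]
STAGE_SEED_OFFSETS = {s: 1000 * (i + 1) for i, s in enumerate(STAGES)}


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2)."""


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream output (exit code 3)."""


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    counts_path: Path | None = None
    metadata_path: Path | None = None
    sets_path: Path | None = None
    motifs_path: Path | None = None
    design: str = "~ group"
    test: str = "wald"
    min_mean: float = 5.0
    simulate_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {
            "out_dir", "seed", "counts_path", "metadata_path", "sets_path",
            "motifs_path", "design", "test", "min_mean", "simulate_params",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ConfigError("config must set out_dir")
        for key in ("counts_path", "metadata_path", "sets_path", "motifs_path"):
            if raw.get(key) is not None:
                p = Path(raw[key])
                if not p.exists():
                    raise ConfigError(f"{key} does not exist: {p}")
                raw[key] = p
        raw["out_dir"] = Path(raw["out_dir"])
        return cls(**raw)


def _hash(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order; return the report."""
    stages = [s for s in STAGES if s in (stages or STAGES)]
    unknown = set(stages or []) - set(STAGES)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, status: str, **info) -> None:
        report["stages"][stage] = {
            "status": status,
            "seed": config.seed + STAGE_SEED_OFFSETS[stage],
            **info,
        }

    def need(stage: str, path: Path) -> Path:
        if not path.exists():
            raise DependencyError(f"stage {stage!r} needs missing input {path}")
        return path

    if "simulate" in stages:
        seed = config.seed + STAGE_SEED_OFFSETS["simulate"]
        params = dict(config.simulate_params)
        cohort_keys = ("n_ctr", "n_stress", "effect_sizes", "noise_sd")
        gene_keys = (
            "n_nuclear", "frac_treatment", "frac_zscore", "log2_effect_treatment",
            "log2_effect_zscore", "baseline_mean", "baseline_log_sd", "dispersion",
            "mtdna_class", "mtdna_log2_effect", "mtdna_baseline",
        )
        unknown = set(params) - set(cohort_keys) - set(gene_keys)
        if unknown:
            raise ConfigError(f"unknown simulate_params keys: {sorted(unknown)}")
        table, truth = simulate_cohort(
            seed=seed, **{k: params[k] for k in cohort_keys if k in params}
        )
        gene_truth = make_gene_truth(
            seed=seed + 1, **{k: params[k] for k in gene_keys if k in params}
        )
        cm = simulate_counts(gene_truth, truth, seed=seed + 2)
        table.to_csv(out / "metadata_raw.tsv", sep="\t", index=False)
        truth.table.to_csv(out / "cohort_truth.tsv", sep="\t", index=False)
        gene_truth.to_csv(out / "gene_truth.tsv", sep="\t", index=False)
        write_counts(cm, out / "counts.tsv")
        record("simulate", "ok", n_animals=len(table), n_genes=len(gene_truth))

    if "behavior" in stages:
        meta_path = config.metadata_path or need("behavior", out / "metadata_raw.tsv")
        raw = pd.read_csv(meta_path, sep="\t")
        scored = behavior_mod.score_behavior(raw)
        scored.to_csv(out / "metadata_scored.tsv", sep="\t", index=False)
        record("behavior", "ok", n_animals=len(scored), input_md5=_hash(Path(meta_path)))

    counts_path = config.counts_path or out / "counts.tsv"
    scored_path = out / "metadata_scored.tsv"

    if "dge" in stages:
        cm = read_counts(need("dge", Path(counts_path)))
        meta = pd.read_csv(need("dge", scored_path), sep="\t")
        res = run_dge(cm, meta, design=config.design, test=config.test, min_mean=config.min_mean)
        res.to_csv(out / "dge.tsv", sep="\t", index=False)
        record("dge", "ok", n_genes_tested=len(res), input_md5=_hash(Path(counts_path)))

    if "enrichment" in stages:
        dge_path = need("enrichment", out / "dge.tsv")
        res = pd.read_csv(dge_path, sep="\t")
        catalogs = {"mtDNA": list(MTDNA_OXPHOS)}
        if config.sets_path is not None:
            catalogs.update(read_gmt(config.sets_path).sets)
        enr = directional_mito_enrichment(res, catalogs)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        record("enrichment", "ok", n_sets=len(enr), input_md5=_hash(dge_path))

    if "select_model" in stages:
        cm = read_counts(need("select_model", Path(counts_path)))
        meta = pd.read_csv(need("select_model", scored_path), sep="\t")
        rec = select_model_per_gene(cm, meta, min_mean=config.min_mean)
        rec.to_csv(out / "model_selection.tsv", sep="\t", index=False)
        sets = {"mtDNA-OXPHOS": list(MTDNA_OXPHOS)}
        if config.sets_path is not None:
            sets.update(read_gmt(config.sets_path).sets)
        summary = setlevel_model_summary(rec, sets)
        summary.to_csv(out / "model_selection_sets.tsv", sep="\t", index=False)
        contrast = hs_ls_contrast(cm, meta, min_mean=config.min_mean)
        contrast.to_csv(out / "hs_ls_contrast.tsv", sep="\t", index=False)
        record("select_model", "ok", n_genes=len(rec))

    if "motif" in stages:
        seed = config.seed + STAGE_SEED_OFFSETS["motif"]
        if config.motifs_path is not None:
            pwms = read_meme(config.motifs_path)
        else:
            pwms = _default_demo_pwms()
        seqs, bed, truth = simulate_promoters(max(60, 10 * len(pwms)), pwms, seed=seed)
        E, groups = simulate_motif_expression(truth, {pwms[0].motif_id: 1.0}, seed=seed + 1)
        sites = scan_promoters(seqs, bed, pwms)
        act = infer_activities(E, sites)
        contrast = compare_activities(act, groups)
        sites.to_csv(out / "site_counts.tsv", sep="\t", index_label="gene_id")
        act.activities.to_csv(out / "motif_activities.tsv", sep="\t", index_label="motif")
        contrast.to_csv(out / "motif_contrasts.tsv", sep="\t", index=False)
        record("motif", "ok", n_motifs=len(pwms), penalty=act.penalty)

    report["ok"] = all(v["status"] == "ok" for v in report["stages"].values())
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report


def _default_demo_pwms(n: int = 6, width: int = 8, seed: int = 7) -> list:
    """Sharp random PWMs used when no MEME file is configured."""
    from .motifs import PWM

    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n):
        consensus = rng.integers(0, 4, width)
        mat = np.full((4, width), 0.04)
        mat[consensus, np.arange(width)] = 0.88
        pwms.append(PWM(f"motif_{i+1}", mat))
    return pwms
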