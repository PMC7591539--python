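"""Behavioral scoring: z-normalization, composites and susceptibility.

Each behavioral readout is z-normalized against the unstressed control
(CTR) group, z = (x - mean_CTR) / SD_CTR.  Three test-level scores —
social avoidance (SIT), forced-swim immobility (FST) and negated
saccharin preference (SaPT) — are averaged into the integrated
behavioral z-score, oriented so that higher means more affected by
stress.  Stressed animals whose integrated z falls within one control
SD of the control mean are low-susceptible (LS), the rest
high-susceptible (HS); the boundary is inclusive.

Expected metadata columns
-------------------------
animal_id, group ({CTR, STRESS}), sit_interaction_time_present,
sit_interaction_time_absent, sit_corner_time_present,
sit_corner_time_absent, fst_immobility, sapt_saccharin_volume,
sapt_water_volume.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "z_normalize",
    "saccharin_preference",
    "social_avoidance_score",
    "integrated_zscore",
    "classify_susceptibility",
    "score_behavior",
]

RAW_COLUMNS = [
    "sit_interaction_time_present",
    "sit_interaction_time_absent",
    "sit_corner_time_present",
    "sit_corner_time_absent",
    "fst_immobility",
    "sapt_saccharin_volume",
    "sapt_water_volume",
]


class DegenerateReferenceError(ValueError):
    """Control group cannot serve as a z-score reference (SD = 0)."""


def z_normalize(values: pd.Series, ctr_ids) -> pd.Series:
    """Control-referenced z-score, controls included in the output.

    Missing values propagate as missing.  Raises
    :class:`DegenerateReferenceError` when the control SD is zero and
    ``ValueError`` with fewer than two finite control values.
    """
    values = pd.Series(values, dtype=float)
    ctr = values.loc[values.index.intersection(pd.Index(list(ctr_ids)))].dropna()
    if len(ctr) < 2:
        raise ValueError("need at least two finite control values for z-normalization")
    mu, sd = ctr.mean(), ctr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateReferenceError("control SD is zero; z-scores undefined")
    return (values - mu) / sd


def saccharin_preference(saccharin_volume: float, water_volume: float) -> float:
    """Percent saccharin consumed of total fluid; NaN when total is 0."""
    if saccharin_volume < 0 or water_volume < 0:
        raise ValueError("volumes must be non-negative")
    total = saccharin_volume + water_volume
    if total == 0:
        return float("nan")
    return 100.0 * saccharin_volume / total


def social_avoidance_score(table: pd.DataFrame, ctr_ids) -> pd.Series:
    """Social-avoidance composite from the four SIT parameters.

    Parameters per animal: interaction-zone time with target present,
    corner-zone time with target present, the interaction ratio
    (present/absent) and the corner ratio (present/absent).  Each is
    z-normalized against controls and the composite is the mean after
    orienting every parameter so larger = more avoidant (interaction
    time and interaction ratio are negated).  Animals with a zero
    target-absent denominator are excluded (NaN) with a logged reason.
    """
    df = table.set_index("animal_id") if "animal_id" in table.columns else table
    inter_p = df["sit_interaction_time_present"].astype(float)
    inter_a = df["sit_interaction_time_absent"].astype(float)
    corner_p = df["sit_corner_time_present"].astype(float)
    corner_a = df["sit_corner_time_absent"].astype(float)

    bad = (inter_a == 0) | (corner_a == 0)
    for aid in df.index[bad]:
        log.warning("animal %s excluded from avoidance score: zero target-absent time", aid)

    with np.errstate(divide="ignore", invalid="ignore"):
        inter_ratio = (inter_p / inter_a).where(~bad)
        corner_ratio = (corner_p / corner_a).where(~bad)

    z_inter = z_normalize(inter_p.where(~bad), ctr_ids)
    z_corner = z_normalize(corner_p.where(~bad), ctr_ids)
    z_iratio = z_normalize(inter_ratio, ctr_ids)
    z_cratio = z_normalize(corner_ratio, ctr_ids)

    composite = (-z_inter + z_corner - z_iratio + z_cratio) / 4.0
    composite.name = "avoidance_score"
    return composite


def integrated_zscore(z_sit, z_fst, z_sapt) -> float | pd.Series:
    """Mean of the three oriented test z-scores; missing if any is missing.

    ``z_sapt`` must already be oriented (preference z negated) before
    calling; :func:`score_behavior` handles the orientation.
    """
    parts = [np.asarray(z, dtype=float) for z in (z_sit, z_fst, z_sapt)]
    stacked = np.stack(np.broadcast_arrays(*parts))
    out = stacked.mean(axis=0)  # NaN propagates -> animal dropped downstream
    if np.ndim(out) == 0:
        return float(out)
    index = next((z.index for z in (z_sit, z_fst, z_sapt) if isinstance(z, pd.Series)), None)
    return pd.Series(out, index=index, name="integrated_z")


def classify_susceptibility(table: pd.DataFrame) -> pd.Series:
    """Label animals CTR / LS / HS / NA from their integrated z-score.

    Stressed animals inside [mu_CTR - sd_CTR, mu_CTR + sd_CTR] of the
    control integrated-z distribution are LS (boundary inclusive),
    outside HS; stressed animals without an integrated z are NA.
    """
    df = table.set_index("animal_id") if "animal_id" in table.columns else table
    is_ctr = df["group"] == "CTR"
    if is_ctr.sum() < 2:
        raise ValueError("need at least two control animals to classify susceptibility")
    z = df["integrated_z"].astype(float)
    ctr_z = z[is_ctr].dropna()
    if len(ctr_z) < 2:
        raise ValueError("need at least two control animals with integrated z")
    mu, sd = ctr_z.mean(), ctr_z.std(ddof=1)

    labels = pd.Series("NA", index=df.index, name="susceptibility")
    labels[is_ctr] = "CTR"
    stressed = ~is_ctr & z.notna()
    inside = (z >= mu - sd) & (z <= mu + sd)
    labels[stressed & inside] = "LS"
    labels[stressed & ~inside] = "HS"
    return labels


def score_behavior(table: pd.DataFrame) -> pd.DataFrame:
    """Full behavioral scoring pipeline on a raw metadata table.

    Adds derived columns: social_interaction_ratio, corner_zone_ratio,
    avoidance_score, sapt_preference, z_sit, z_fst, z_sapt (oriented),
    integrated_z and susceptibility.
    """
    df = table.copy()
    if "animal_id" in df.columns:
        df = df.set_index("animal_id")
    ctr_ids = df.index[df["group"] == "CTR"]

    with np.errstate(divide="ignore", invalid="ignore"):
        denom_i = df["sit_interaction_time_absent"].astype(float)
        denom_c = df["sit_corner_time_absent"].astype(float)
        df["social_interaction_ratio"] = (
            df["sit_interaction_time_present"] / denom_i
        ).where(denom_i != 0)
        df["corner_zone_ratio"] = (
            df["sit_corner_time_present"] / denom_c
        ).where(denom_c != 0)

    df["avoidance_score"] = social_avoidance_score(df.reset_index(), ctr_ids)
    df["sapt_preference"] = [
        saccharin_preference(s, w)
        for s, w in zip(df["sapt_saccharin_volume"], df["sapt_water_volume"])
    ]

    df["z_sit"] = z_normalize(df["avoidance_score"], ctr_ids)
    df["z_fst"] = z_normalize(df["fst_immobility"], ctr_ids)
    # preference enters negated: anhedonia (lower preference) raises the score
    df["z_sapt"] = -z_normalize(df["sapt_preference"], ctr_ids)
    df["integrated_z"] = integrated_zscore(df["z_sit"], df["z_fst"], df["z_sapt"])
    df["susceptibility"] = classify_susceptibility(df)
    return df.reset_index()
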