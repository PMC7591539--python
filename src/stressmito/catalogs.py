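"""Packaged mitochondrial gene catalogs.

The mammalian mitochondrial genome encodes exactly 13 protein-coding
genes, all of them subunits of the oxidative-phosphorylation (OXPHOS)
machinery: seven complex-I subunits, one complex-III subunit
(cytochrome b), three complex-IV subunits and two complex-V (ATP
synthase) subunits.  Complex II is entirely nuclear-encoded.

In bulk prefrontal-cortex data only seven of the 13 are typically
expressed highly enough to test reliably; that detected subset is
packaged alongside the full catalog.
"""

from __future__ import annotations

MTDNA_OXPHOS: dict[str, str] = {
    "mt-Nd1": "I",
    "mt-Nd2": "I",
    "mt-Nd3": "I",
    "mt-Nd4": "I",
    "mt-Nd4l": "I",
    "mt-Nd5": "I",
    "mt-Nd6": "I",
    "mt-Cytb": "III",
    "mt-Co1": "IV",
    "mt-Co2": "IV",
    "mt-Co3": "IV",
    "mt-Atp6": "V",
    "mt-Atp8": "V",
}
"""The 13 mtDNA-encoded OXPHOS protein-coding genes -> complex."""

MTDNA_DETECTED: frozenset[str] = frozenset(
    {"mt-Nd1", "mt-Nd2", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb", "mt-Co1"}
)
"""Subset reliably detected in bulk PFC expression data."""

# Human ortholog symbols for the same 13 genes (simple 1:1 map).
MTDNA_HUMAN_SYMBOLS: dict[str, str] = {
    "mt-Nd1": "MT-ND1",
    "mt-Nd2": "MT-ND2",
    "mt-Nd3": "MT-ND3",
    "mt-Nd4": "MT-ND4",
    "mt-Nd4l": "MT-ND4L",
    "mt-Nd5": "MT-ND5",
    "mt-Nd6": "MT-ND6",
    "mt-Cytb": "MT-CYB",
    "mt-Co1": "MT-CO1",
    "mt-Co2": "MT-CO2",
    "mt-Co3": "MT-CO3",
    "mt-Atp6": "MT-ATP6",
    "mt-Atp8": "MT-ATP8",
}


def mtdna_genes(complex_: str | None = None) -> list[str]:
    """Return mtDNA OXPHOS gene ids, optionally restricted to one complex."""
    if complex_ is None:
        return list(MTDNA_OXPHOS)
    return [g for g, c in MTDNA_OXPHOS.items() if c == complex_]


def undetected_mtdna_genes() -> list[str]:
    """The mtDNA OXPHOS genes expressed too low for reliable detection."""
    return [g for g in MTDNA_OXPHOS if g not in MTDNA_DETECTED]


def _validate() -> None:
    assert len(MTDNA_OXPHOS) == 13
    assert not mtdna_genes("II"), "complex II has no mtDNA-encoded subunits"
    assert MTDNA_DETECTED <= set(MTDNA_OXPHOS)
    assert len(MTDNA_DETECTED) == 7


_validate()
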