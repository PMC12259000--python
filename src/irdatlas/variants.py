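"""Per-gene pathogenic-variant spectrum profiling.

Pathogenic/likely-pathogenic (PLP) records are selected by clinical
significance; loss-of-function (LoF) is defined as canonical splice-site,
stopgain, or frameshift indel. Each gene falls into exactly one of four
categories:

    rare             fewer than 5 PLP variants (precedence over the rest)
    mostly_lof       LoF / (LoF + missense) > 0.75
    mostly_missense  missense / (LoF + missense) > 0.75
    mixed            everything in between (boundaries 0.25 and 0.75 inclusive)

Fractions are computed over LoF + missense only; other PLP consequence types
count toward the rare threshold but not the fraction. Counting is per ALT
allele (one VCF line with two ALTs contributes two variants).
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable

import pandas as pd

from . import vocab
from .io import VariantRecord

logger = logging.getLogger(__name__)

SPECTRUM_RARE = "rare"
SPECTRUM_MOSTLY_LOF = "mostly_lof"
SPECTRUM_MIXED = "mixed"
SPECTRUM_MOSTLY_MISSENSE = "mostly_missense"
SPECTRUM_CATEGORIES = (
    SPECTRUM_MOSTLY_LOF, SPECTRUM_MIXED, SPECTRUM_MOSTLY_MISSENSE, SPECTRUM_RARE,
)

#: genes with fewer PLP variants than this are "rare"
RARE_THRESHOLD = 5
#: strict fraction bound for the mostly-LoF / mostly-missense calls
MOSTLY_FRACTION = 0.75


@dataclasses.dataclass(frozen=True)
class GeneVariantSpectrum:
    gene: str
    n_lof: int
    n_missense: int
    n_other_plp: int
    category: str

    @property
    def n_plp_total(self) -> int:
        return self.n_lof + self.n_missense + self.n_other_plp

    @property
    def lof_fraction(self) -> float | None:
        denom = self.n_lof + self.n_missense
        return self.n_lof / denom if denom > 0 else None


def select_plp(
    records: Iterable[VariantRecord],
    include_combined: bool = True,
    include_conflicting: bool = False,
) -> list[VariantRecord]:
    """Keep pathogenic / likely-pathogenic records.

    ``include_combined`` controls the ClinVar "Pathogenic/Likely_pathogenic"
    combined assertion (kept by default); ``include_conflicting`` controls
    conflicting-interpretation records (dropped by default).
    """
    keep = set(vocab.PLP_SIGNIFICANCE)
    if not include_combined:
        keep.discard("pathogenic_likely_pathogenic")
    out = []
    for r in records:
        sig = r.clinical_significance
        if sig in keep:
            out.append(r)
        elif include_conflicting and "conflicting" in sig:
            out.append(r)
    return out


def is_lof(consequence: str) -> bool:
    """True iff the consequence is canonical splice, stopgain or frameshift indel."""
    return consequence in vocab.LOF_CONSEQUENCES


def classify_spectrum(n_lof: int, n_missense: int, n_other_plp: int) -> str:
    """4-way category from per-gene PLP counts (the rule, without records)."""
    total = n_lof + n_missense + n_other_plp
    if total < RARE_THRESHOLD:
        return SPECTRUM_RARE
    denom = n_lof + n_missense
    if denom == 0:
        logger.warning(
            "gene with %d PLP variants but no LoF/missense: fraction undefined, "
            "categorized as mixed", total,
        )
        return SPECTRUM_MIXED
    fraction = n_lof / denom
    if fraction > MOSTLY_FRACTION:
        return SPECTRUM_MOSTLY_LOF
    if 1 - fraction > MOSTLY_FRACTION:
        return SPECTRUM_MOSTLY_MISSENSE
    return SPECTRUM_MIXED


def gene_spectrum(plp_records: Iterable[VariantRecord], gene: str | None = None) -> GeneVariantSpectrum:
    """Spectrum of one gene from its (already PLP-filtered) records."""
    records = list(plp_records)
    genes = {r.gene_symbol for r in records}
    if gene is None:
        if len(genes) != 1:
            raise ValueError(f"records span {len(genes)} genes; pass gene= explicitly")
        gene = next(iter(genes))
    elif genes - {gene}:
        raise ValueError(f"records for {sorted(genes - {gene})} mixed into gene {gene}")
    n_lof = sum(1 for r in records if is_lof(r.consequence))
    n_missense = sum(1 for r in records if r.consequence == "missense")
    n_other = len(records) - n_lof - n_missense
    return GeneVariantSpectrum(
        gene=gene,
        n_lof=n_lof,
        n_missense=n_missense,
        n_other_plp=n_other,
        category=classify_spectrum(n_lof, n_missense, n_other),
    )


def spectrum_table(
    records: Iterable[VariantRecord],
    gene_symbols: Iterable[str] | None = None,
    include_combined: bool = True,
    include_conflicting: bool = False,
) -> pd.DataFrame:
    """Per-gene spectrum table from raw (unfiltered) variant records.

    When ``gene_symbols`` is given, every listed gene appears in the output;
    genes without any PLP record get zero counts (hence "rare").
    """
    plp = select_plp(records, include_combined, include_conflicting)
    by_gene: dict[str, list[VariantRecord]] = {}
    for r in plp:
        by_gene.setdefault(r.gene_symbol, []).append(r)
    genes = list(gene_symbols) if gene_symbols is not None else sorted(by_gene)
    rows = []
    for g in genes:
        s = gene_spectrum(by_gene.get(g, []), gene=g)
        rows.append(
            {
                "gene": g,
                "n_lof": s.n_lof,
                "n_missense": s.n_missense,
                "n_other_plp": s.n_other_plp,
                "n_plp_total": s.n_plp_total,
                "lof_fraction": s.lof_fraction,
                "category": s.category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "n_lof", "n_missense", "n_other_plp", "n_plp_total",
                 "lof_fraction", "category"],
    ).set_index("gene")
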