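"""Seeded generators for every pipeline input, with planted recoverable truth.

Expression matrices get multiplicative log-normal noise parameterized by its
coefficient of variation (CV) — expression values are non-negative and
heteroscedastic, so additive Gaussian noise would be the wrong model. With
``noise_cv = 0`` every downstream classification is analytically predictable,
which is the primary test harness. All generators are fully deterministic
under a fixed seed.

The ``published_atlas`` constructor plants the printed marginal structure of
the curated atlas (status counts, Venn partition, inheritance distribution,
per-subset counts, discovery-rate periods, functional-category design) into a
synthetic gene table + category mapping, so the summary stages can be checked
end-to-end without the real curated tables. Gene symbols and all per-gene
details not pinned by those marginals are synthetic.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab
from .curation import EvidenceRecord
from .functional import CategoryMapping
from .io import ExpressionMatrix, GeneRecord
from .schemes import CellGroupScheme, TissueGroupScheme


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the requested CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=shape)


# ---------------------------------------------------------------------------
# Bulk tissue matrix
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class BulkSimSpec:
    """Planted-truth design of a synthetic bulk tissue matrix.

    Planted genes sit at ``baseline_level * fold_change`` in the retina
    sample(s) and ``baseline_level`` elsewhere; a ``low_expression_fraction``
    of the remaining genes is drawn uniformly in (0, 1] nTPM across all
    columns so the expression floor rule always fires for them.
    """

    n_genes: int
    planted_prevalent: frozenset[int] = frozenset()
    fold_change: float = 10.0
    baseline_level: float = 5.0
    noise_cv: float = 0.1
    low_expression_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.fold_change <= 1:
            raise ValueError("fold_change must be > 1")
        if not 0 <= self.low_expression_fraction <= 1:
            raise ValueError("low_expression_fraction must be in [0, 1]")
        if self.planted_prevalent and max(self.planted_prevalent) >= self.n_genes:
            raise ValueError("planted index out of range")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _low_expression_rows(
    rng: np.random.Generator, n_genes: int, fraction: float, planted: frozenset[int]
) -> np.ndarray:
    eligible = np.array(sorted(set(range(n_genes)) - planted), dtype=int)
    n_low = int(round(fraction * n_genes))
    n_low = min(n_low, len(eligible))
    return rng.choice(eligible, size=n_low, replace=False) if n_low else np.array([], int)


def generate_bulk_matrix(
    spec: BulkSimSpec,
    scheme: TissueGroupScheme | None = None,
) -> tuple[ExpressionMatrix, frozenset[int]]:
    """Synthetic bulk matrix over the scheme's full sample-name set.

    Returns the matrix and the set of low-expression row indices (the planted
    set is already in the spec).
    """
    scheme = scheme or TissueGroupScheme.builtin()
    rng = np.random.default_rng(spec.seed)
    samples = scheme.sample_names
    retina_cols = [i for i, s in enumerate(samples)
                   if scheme.membership[s] == scheme.target_group]
    values = np.full((spec.n_genes, len(samples)), spec.baseline_level, dtype=float)
    for g in spec.planted_prevalent:
        values[g, retina_cols] = spec.baseline_level * spec.fold_change
    low = _low_expression_rows(rng, spec.n_genes, spec.low_expression_fraction,
                               spec.planted_prevalent)
    if len(low):
        # (0, 1] uniform across all columns: guaranteed under the floor rule
        values[low, :] = 1.0 - rng.random((len(low), len(samples)))
    values *= _lognormal_noise(rng, spec.noise_cv, values.shape)
    frame = pd.DataFrame(values, index=_gene_ids(spec.n_genes), columns=samples)
    return ExpressionMatrix(frame), frozenset(int(i) for i in low)


# ---------------------------------------------------------------------------
# Single-cell matrix
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ScSimSpec:
    """Planted-truth design of a synthetic 53-subtype single-cell matrix.

    ``planted`` maps gene row index -> candidate category name (any of the 19
    major or 5 broader groups); every subtype column of the candidate's member
    major groups is elevated by ``fold_change``.
    """

    n_genes: int
    planted: Mapping[int, str] = dataclasses.field(default_factory=dict)
    fold_change: float = 10.0
    baseline_level: float = 5.0
    noise_cv: float = 0.1
    low_expression_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.fold_change <= 1:
            raise ValueError("fold_change must be > 1")
        if self.planted and max(self.planted) >= self.n_genes:
            raise ValueError("planted index out of range")


def generate_sc_matrix(
    spec: ScSimSpec,
    scheme: CellGroupScheme | None = None,
) -> tuple[ExpressionMatrix, frozenset[int]]:
    """Synthetic single-cell matrix over the scheme's 53 subtype columns."""
    scheme = scheme or CellGroupScheme.builtin()
    rng = np.random.default_rng(spec.seed)
    subtypes = scheme.subtype_names
    col_index = {s: i for i, s in enumerate(subtypes)}
    values = np.full((spec.n_genes, len(subtypes)), spec.baseline_level, dtype=float)
    for g, candidate in spec.planted.items():
        cols = [
            col_index[s]
            for major in scheme.members_of(candidate)
            for s in scheme.subtypes_of(major)
        ]
        values[g, cols] = spec.baseline_level * spec.fold_change
    low = _low_expression_rows(rng, spec.n_genes, spec.low_expression_fraction,
                               frozenset(spec.planted))
    if len(low):
        values[low, :] = 1.0 - rng.random((len(low), len(subtypes)))
    values *= _lognormal_noise(rng, spec.noise_cv, values.shape)
    frame = pd.DataFrame(values, index=_gene_ids(spec.n_genes), columns=subtypes)
    return ExpressionMatrix(frame), frozenset(int(i) for i in low)


# ---------------------------------------------------------------------------
# ClinVar-dialect VCF
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class VcfSimSpec:
    """Per-gene variant composition: gene -> (n_LoF, n_missense, n_other_PLP, n_benign)."""

    per_gene_composition: Mapping[str, tuple[int, int, int, int]]
    seed: int = 0

    def __post_init__(self):
        for gene, comp in self.per_gene_composition.items():
            if len(comp) != 4 or any(c < 0 for c in comp):
                raise ValueError(f"{gene}: composition must be 4 non-negative counts")


_LOF_MC = (
    "SO:0001587|nonsense",
    "SO:0001575|splice_donor_variant",
    "SO:0001589|frameshift_variant",
)
_MISSENSE_MC = "SO:0001583|missense_variant"
_OTHER_MC = "SO:0001822|inframe_deletion"
_PLP_CLNSIG = ("Pathogenic", "Likely_pathogenic", "Pathogenic/Likely_pathogenic")

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Clinical significance">
##INFO=<ID=GENEINFO,Number=1,Type=String,Description="Gene symbol:GeneID pairs">
##INFO=<ID=MC,Number=.,Type=String,Description="Molecular consequence">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def generate_clinvar_vcf(spec: VcfSimSpec, path: str | Path) -> int:
    """Write a ClinVar-dialect VCF realizing the per-gene composition exactly.

    Returns the number of records written. PLP clinical-significance strings
    cycle through the three PLP spellings (including the combined assertion);
    benign records carry CLNSIG=Benign. One record per variant (single ALT).
    """
    lines = [_VCF_HEADER]
    pos = 1000
    n = 0
    for gene_id, (gene, comp) in enumerate(sorted(spec.per_gene_composition.items())):
        n_lof, n_missense, n_other, n_benign = comp
        plan = (
            [("lof", _LOF_MC[i % 3]) for i in range(n_lof)]
            + [("mis", _MISSENSE_MC)] * n_missense
            + [("oth", _OTHER_MC)] * n_other
            + [("ben", _MISSENSE_MC)] * n_benign
        )
        for i, (kind, mc) in enumerate(plan):
            pos += 7
            clnsig = "Benign" if kind == "ben" else _PLP_CLNSIG[i % 3]
            if "frameshift" in mc:
                ref, alt = "AT", "A"
            else:
                ref, alt = "A", "G"
            info = f"CLNSIG={clnsig.replace(' ', '_')};GENEINFO={gene}:{1000 + gene_id};MC={mc}"
            lines.append(f"1\t{pos}\t{n + 1}\t{ref}\t{alt}\t.\t.\t{info}\n")
            n += 1
    Path(path).write_text("".join(lines), encoding="utf-8")
    return n


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GeneTableCell:
    """One design cell: ``count`` genes sharing subsets/mode/year/status."""

    phenotype_subsets: frozenset[str]
    inheritance_mode: str
    discovery_year: int | None
    count: int
    status: str = vocab.STATUS_DISEASE


def generate_gene_table(
    cells: Sequence[GeneTableCell],
    seed: int = 0,
    symbol_prefix: str = "GENE",
) -> list[GeneRecord]:
    """Expand a design into gene records; marginals equal the design exactly.

    Record order is shuffled deterministically by seed (the marginal counts
    are order-invariant).
    """
    records = []
    i = 0
    for cell in cells:
        for _ in range(cell.count):
            i += 1
            records.append(
                GeneRecord(
                    symbol=f"{symbol_prefix}{i:04d}",
                    status=cell.status,
                    phenotype_subsets=cell.phenotype_subsets,
                    inheritance_modes=frozenset({cell.inheritance_mode}),
                    discovery_year=cell.discovery_year,
                )
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return [records[j] for j in order]


# -- published-design construction -------------------------------------------

# printed marginal structure of the curated atlas; every number here is a
# published aggregate, the per-gene assignment realizing them is synthetic
_N_DISEASE, _N_CANDIDATE, _N_EXCLUDED = 468, 196, 16
_N_NONSYNDROMIC, _N_SYNDROMIC, _N_BOTH = 202, 322, 56

_NS_SUBSET_COUNTS = {
    "RP": 103, "CD-CRD": 37, "MD": 30, "other-nonsyndromic": 24, "LCA": 22,
    "OA": 19, "CSNB": 14, "EVR": 12, "CVD": 9,
}
_SYN_SUBSET_COUNTS = {
    "other-syndromic": 158, "syndromic-OA": 97, "BBS": 22, "Joubert": 20,
    "OCA": 18, "USH": 12, "SLS-NPHP": 8,
}
# 52 genes carry >1 non-syndromic subset: 4 with four, 8 with three, 40 with two
_NS_MULTI_SIZES = [4] * 4 + [3] * 8 + [2] * 40 + [1] * 150
# 13 genes carry two syndromic subsets
_SYN_MULTI_SIZES = [2] * 13 + [1] * 309

_INHERITANCE_COUNTS = {"AR": 323, "AD": 70, "AD-AR": 36, "X-linked": 22,
                       "mitochondrial": 17}

# annual discovery counts: 11/yr through 2009, NGS-era plateau, 8/yr from 2018
# (6 genes in the final year)
_ANNUAL_DISCOVERIES = (
    {y: 11 for y in range(1988, 2010)}
    | {2010: 22, 2011: 21, 2012: 21, 2013: 21, 2014: 21, 2015: 21, 2016: 21, 2017: 22}
    | {2018: 9, 2019: 8, 2020: 8, 2021: 8, 2022: 8, 2023: 9, 2024: 6}
)

_LOCI = ("RP17", "MCDR1", "MCDR3", "Xq27.1")

#: one representative GO term per functional category (synthetic mapping table)
CATEGORY_GO_TERMS: dict[str, str] = {
    "Cilium": "GO:0005929",
    "Cytoskeleton": "GO:0005856",
    "Transmembrane transport": "GO:0055085",
    "Lipid metabolism": "GO:0006629",
    "Visual cycle and phototransduction": "GO:0007603",
    "Mitochondria": "GO:0005739",
    "Nucleotide metabolism": "GO:0009117",
    "Melanosome": "GO:0042470",
    "Synaptic signaling": "GO:0099536",
    "Autophagic and endolysosomal pathway": "GO:0061919",
    "Extracellular matrix": "GO:0031012",
    "Cell adhesion": "GO:0007155",
    "Transcriptional regulation": "GO:0006355",
    "Retinal development": "GO:0060041",
    "RNA splicing and processing": "GO:0008380",
    "Protein folding and degradation": "GO:0006457",
    "Signal transduction": "GO:0007165",
    "DNA repair": "GO:0006281",
    "Glycosylation": "GO:0006486",
    "Ion channels": "GO:0005216",
}
#: a generic term deliberately absent from the mapping (visual perception);
#: genes carrying only this term need an override or fall into "Others"
GENERIC_GO_TERM = "GO:0007601"

# functional design over the 464 non-locus disease genes: 165 two-category
# genes (pairs, count) + 299 single-category genes, realizing the printed
# sizes Cilium 83, Transmembrane transport 68, Lipid 61, phototransduction 32,
# Cilium x Cytoskeleton overlap 20, and single/multi split 299/165
_CATEGORY_PAIRS = (
    ("Cilium", "Cytoskeleton", 20),
    ("Cilium", "Melanosome", 8),
    ("Cilium", "Transmembrane transport", 15),
    ("Mitochondria", "Nucleotide metabolism", 10),
    ("Lipid metabolism", "Visual cycle and phototransduction", 9),
    ("Lipid metabolism", "Autophagic and endolysosomal pathway", 10),
    ("Lipid metabolism", "Transmembrane transport", 11),
    ("Cytoskeleton", "Synaptic signaling", 7),
    ("Mitochondria", "Transmembrane transport", 12),
    ("Nucleotide metabolism", "Transmembrane transport", 16),
    ("Autophagic and endolysosomal pathway", "Melanosome", 7),
    ("Synaptic signaling", "Transmembrane transport", 14),
    ("Extracellular matrix", "Cell adhesion", 10),
    ("Transcriptional regulation", "Retinal development", 8),
    ("RNA splicing and processing", "Protein folding and degradation", 8),
)
_OVERRIDE_MARKER = "__override__"
_CATEGORY_SINGLES = (
    ("Cilium", 40),
    ("Lipid metabolism", 31),
    ("Visual cycle and phototransduction", 20),
    (_OVERRIDE_MARKER, 3),  # generic-term genes rescued by manual override
    (vocab.OTHERS_CATEGORY, 25),
    ("Cytoskeleton", 10),
    ("Synaptic signaling", 10),
    ("Mitochondria", 15),
    ("Nucleotide metabolism", 5),
    ("Melanosome", 5),
    ("Autophagic and endolysosomal pathway", 10),
    ("Extracellular matrix", 8),
    ("Cell adhesion", 8),
    ("Transcriptional regulation", 20),
    ("Retinal development", 10),
    ("RNA splicing and processing", 12),
    ("Protein folding and degradation", 12),
    ("Signal transduction", 20),
    ("DNA repair", 10),
    ("Glycosylation", 8),
    ("Ion channels", 17),
)


def _allocate_subsets(tokens: dict[str, int], sizes: list[int]) -> list[frozenset[str]]:
    """Deal subset tokens onto genes: gene k gets ``sizes[k]`` distinct subsets.

    Greedy most-abundant-first keeps rare subsets available; the design is
    infeasible only if a token count exceeds the number of genes, which the
    trailing assertion would catch.
    """
    remaining = dict(tokens)
    order = {t: i for i, t in enumerate(tokens)}
    out = []
    for k in sizes:
        picks = sorted(
            (t for t in remaining if remaining[t] > 0),
            key=lambda t: (-remaining[t], order[t]),
        )[:k]
        if len(picks) < k:
            raise ValueError("subset design infeasible")
        for t in picks:
            remaining[t] -= 1
        out.append(frozenset(picks))
    if any(v != 0 for v in remaining.values()):
        raise ValueError("subset design leaves unplaced tokens")
    return out


def _functional_assignments() -> list[frozenset[str] | None]:
    """The 464 planned category sets; None marks an override-rescued gene."""
    plan: list[frozenset[str] | None] = []
    for a, b, n in _CATEGORY_PAIRS:
        plan.extend([frozenset({a, b})] * n)
    for cat, n in _CATEGORY_SINGLES:
        if cat == _OVERRIDE_MARKER:
            plan.extend([None] * n)
        else:
            plan.extend([frozenset({cat})] * n)
    return plan


def published_atlas(seed: int = 0) -> tuple[list[GeneRecord], CategoryMapping]:
    """Synthetic curated gene table + category mapping with the published marginals.

    Returns 680 gene records (468 disease incl. 4 loci, 196 candidates, 16
    excluded) whose derived aggregates reproduce the printed atlas numbers,
    and the GO-term mapping (with manual overrides) that the annotation stage
    needs to recover the planned functional categories. Per-gene assignments
    beyond the planted marginals are synthetic and seed-shuffled.
    """
    rng = np.random.default_rng(seed)

    ns_sets = _allocate_subsets(dict(_NS_SUBSET_COUNTS), list(_NS_MULTI_SIZES))
    syn_sets = _allocate_subsets(dict(_SYN_SUBSET_COUNTS), list(_SYN_MULTI_SIZES))

    # disease gene i: non-syndromic subsets for i < 202, syndromic subsets for
    # i >= 146 -> overlap of 56 genes carries both
    subsets: list[frozenset[str]] = []
    for i in range(_N_DISEASE):
        s: frozenset[str] = frozenset()
        if i < _N_NONSYNDROMIC:
            s |= ns_sets[i]
        if i >= _N_NONSYNDROMIC - _N_BOTH:
            s |= syn_sets[i - (_N_NONSYNDROMIC - _N_BOTH)]
        subsets.append(s)

    modes = [m for m, n in _INHERITANCE_COUNTS.items() for _ in range(n)]
    rng.shuffle(modes)
    years = [y for y, n in sorted(_ANNUAL_DISCOVERIES.items()) for _ in range(n)]
    rng.shuffle(years)

    # loci: four single-subset, non-syndromic-only genes (indices 52-55 are
    # outside both the multi-phenotype block and the both-classes block)
    locus_indices = {52 + k: name for k, name in enumerate(_LOCI)}

    categories = _functional_assignments()
    rng.shuffle(categories)

    records: list[GeneRecord] = []
    overrides: dict[str, frozenset[str]] = {}
    provenance: dict[str, str] = {}
    cat_iter = iter(categories)
    for i in range(_N_DISEASE):
        is_locus = i in locus_indices
        symbol = locus_indices.get(i, f"GENE{i + 1:04d}")
        go_terms: frozenset[str] = frozenset()
        if not is_locus:
            planned = next(cat_iter)
            if planned is None:
                # generic annotation only; manual override assigns the real class
                go_terms = frozenset({GENERIC_GO_TERM})
                overrides[symbol] = frozenset({"Visual cycle and phototransduction"})
                provenance[symbol] = "synthetic curator reclassification"
            elif planned == frozenset({vocab.OTHERS_CATEGORY}):
                go_terms = frozenset({GENERIC_GO_TERM})
            else:
                go_terms = frozenset(CATEGORY_GO_TERMS[c] for c in planned)
        records.append(
            GeneRecord(
                symbol=symbol,
                status=vocab.STATUS_DISEASE,
                phenotype_subsets=subsets[i],
                inheritance_modes=frozenset({modes[i]}),
                discovery_year=years[i],
                go_terms=go_terms,
                is_locus=is_locus,
            )
        )

    all_subsets = list(vocab.PHENOTYPE_SUBSETS)
    all_modes = list(vocab.INHERITANCE_MODES)
    for j in range(_N_CANDIDATE):
        records.append(
            GeneRecord(
                symbol=f"CAND{j + 1:04d}",
                status=vocab.STATUS_CANDIDATE,
                phenotype_subsets=frozenset({all_subsets[j % len(all_subsets)]}),
                inheritance_modes=frozenset({all_modes[j % len(all_modes)]}),
            )
        )
    for j in range(_N_EXCLUDED):
        records.append(
            GeneRecord(
                symbol=f"EXCL{j + 1:04d}",
                status=vocab.STATUS_EXCLUDED,
                phenotype_subsets=frozenset({all_subsets[j % len(all_subsets)]}),
                inheritance_modes=frozenset({all_modes[j % len(all_modes)]}),
            )
        )

    mapping = CategoryMapping(
        term_to_category={t: frozenset({c}) for c, t in CATEGORY_GO_TERMS.items()},
        manual_overrides=overrides,
        provenance=provenance,
    )
    return records, mapping


# ---------------------------------------------------------------------------
# Evidence tables (for exercising the curation engine end to end)
# ---------------------------------------------------------------------------


def generate_evidence_table(
    records: Sequence[GeneRecord], seed: int = 0
) -> list[EvidenceRecord]:
    """Evidence records whose curation outcome equals each gene's status.

    Disease genes get two unrelated consistent families with distinct
    variants (criterion i); loci additionally flag a known causative variant;
    candidates get a single family; excluded genes carry conflicting evidence.
    """
    out: list[EvidenceRecord] = []
    for r in records:
        if r.status == vocab.STATUS_DISEASE:
            for k in (1, 2):
                out.append(
                    EvidenceRecord(
                        gene=r.symbol,
                        family_id=f"{r.symbol}_F{k}",
                        variant_id=f"{r.symbol}_V{k}",
                        is_locus=r.is_locus,
                        locus_has_causative_variant=r.is_locus,
                    )
                )
        elif r.status == vocab.STATUS_CANDIDATE:
            out.append(
                EvidenceRecord(gene=r.symbol, family_id=f"{r.symbol}_F1",
                               variant_id=f"{r.symbol}_V1")
            )
        else:
            out.append(
                EvidenceRecord(gene=r.symbol, family_id=f"{r.symbol}_F1",
                               variant_id=f"{r.symbol}_V1", conflicting_evidence=True)
            )
    return out
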