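"""Readers and writers for the tabular and variant formats of the atlas pipeline.

All tabular formats are UTF-8, tab-separated text; multi-valued cells are
";"-delimited with no surrounding whitespace. Variant input is a ClinVar-dialect
VCF 4.x (INFO keys CLNSIG, GENEINFO, MC), parsed with cyvcf2; coordinates stay
1-based as in VCF and indels are not normalized (downstream spectrum
classification consumes only consequence labels).
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Iterator, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violates the schema of its format (names the offending row/column)."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """A genes x samples (or genes x cell-groups) non-negative expression matrix.

    Values are nTPM for bulk tissue tables or library-normalized transcripts
    per 10,000 for single-cell tables. Backed by a pandas DataFrame with unique
    gene ids as the index and unique sample/group names as columns.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        if frame.columns.has_duplicates:
            dup = frame.columns[frame.columns.duplicated()][0]
            raise FormatError(f"duplicate column identifier: {dup!r}")
        values = frame.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            bad = frame.index[np.where(~np.isfinite(values))[0][0]]
            raise FormatError(f"non-finite expression value in gene {bad!r}")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative expression value at gene {frame.index[r]!r}, "
                f"column {frame.columns[c]!r}"
            )
        self.frame = frame.astype(float)

    # -- container-ish surface ------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.frame.index

    def row(self, gene_id: str) -> pd.Series:
        return self.frame.loc[gene_id]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self.frame.equals(other.frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} columns)"


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression table.

    First column holds gene identifiers, the header row holds sample or
    cell-group names. Duplicate genes, duplicate columns and negative values
    are rejected with an error naming the offender.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # malformed header / unreadable file
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise FormatError(f"expression matrix {path} has no sample columns")
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression value in {path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return ExpressionMatrix(frame)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.frame.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One ALT allele of a ClinVar-style variant, tied to a single gene symbol.

    ``clinical_significance`` is stored normalized (lowercase, separators
    collapsed to "_"); ``consequence`` is one of the closed molecular
    consequence vocabulary. Coordinates are 1-based as in VCF.
    """

    gene_symbol: str
    clinical_significance: str
    consequence: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.consequence not in vocab.CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")


#: substring -> canonical consequence; checked in order, first match wins
_MC_PATTERNS: tuple[tuple[str, str], ...] = (
    ("nonsense", "stopgain"),
    ("stop_gained", "stopgain"),
    ("stopgain", "stopgain"),
    ("splice_donor", "canonical_splice"),
    ("splice_acceptor", "canonical_splice"),
    ("canonical_splice", "canonical_splice"),
    ("frameshift", "frameshift_indel"),
    ("missense", "missense"),
    # recognized non-LoF, non-missense consequences: "other" without a warning
    ("inframe", "other"),
    ("synonymous", "other"),
    ("utr", "other"),
    ("intron", "other"),
    ("splice_region", "other"),
    ("no_sequence_alteration", "other"),
    ("genic_upstream", "other"),
    ("genic_downstream", "other"),
)


def map_consequence(raw: str | None) -> str:
    """Map a ClinVar MC consequence string into the closed vocabulary.

    Unknown strings map to "other" with a warning (e.g. in-frame indels,
    synonymous and UTR consequences are all "other" for spectrum purposes).
    """
    if raw is None:
        return "other"
    low = raw.lower()
    for pattern, canonical in _MC_PATTERNS:
        if pattern in low:
            return canonical
    if low and low != "other":
        logger.warning("unknown molecular consequence %r mapped to 'other'", raw)
    return "other"


class ParsedVcf(Sequence):
    """Sequence of :class:`VariantRecord` plus parse-side counters."""

    def __init__(self, records: list[VariantRecord], n_skipped_no_gene: int,
                 n_multi_gene: int = 0):
        self.records = records
        self.n_skipped_no_gene = n_skipped_no_gene
        self.n_multi_gene = n_multi_gene

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)


def read_clinvar_vcf(path: str | Path) -> ParsedVcf:
    """Parse a ClinVar-dialect VCF into one VariantRecord per ALT allele.

    Uses INFO keys CLNSIG (clinical significance), GENEINFO (gene symbol,
    ``SYMBOL:GeneID`` pairs "|"-separated) and MC (molecular consequence).
    Records without GENEINFO are skipped and counted; multi-gene GENEINFO
    entries resolve to the first listed gene and are counted separately.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc

    records: list[VariantRecord] = []
    n_skipped = 0
    n_multi = 0
    for v in vcf:
        geneinfo = v.INFO.get("GENEINFO")
        if not geneinfo:
            n_skipped += 1
            continue
        genes = str(geneinfo).split("|")
        if len(genes) > 1:
            n_multi += 1
        gene = genes[0].split(":")[0]
        clnsig = vocab.normalize_significance(str(v.INFO.get("CLNSIG") or "not_provided"))
        mc = v.INFO.get("MC")
        consequence = map_consequence(str(mc).split(",")[0] if mc is not None else None)
        for alt in v.ALT:
            records.append(
                VariantRecord(
                    gene_symbol=gene,
                    clinical_significance=clnsig,
                    consequence=consequence,
                    chrom=str(v.CHROM),
                    pos=int(v.POS),
                    ref=str(v.REF),
                    alt=str(alt),
                )
            )
    if n_skipped:
        logger.info("skipped %d VCF records without GENEINFO", n_skipped)
    if n_multi:
        logger.info("resolved %d multi-gene GENEINFO entries to first listed gene", n_multi)
    return ParsedVcf(records, n_skipped, n_multi)


# ---------------------------------------------------------------------------
# Gene records
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """One curated gene (or locus) of the atlas.

    ``broad_classes`` is always derived from ``phenotype_subsets`` via the
    fixed subset -> broad-class mapping; it is never stored or read from disk,
    which makes the non-syndromic/syndromic Venn partition consistent by
    construction.
    """

    symbol: str
    status: str
    phenotype_subsets: frozenset[str] = frozenset()
    inheritance_modes: frozenset[str] = frozenset()
    discovery_year: int | None = None
    go_terms: frozenset[str] = frozenset()
    functional_categories: frozenset[str] = frozenset()
    is_locus: bool = False

    def __post_init__(self):
        if self.status not in vocab.GENE_STATUSES:
            raise ValueError(f"{self.symbol}: unknown status {self.status!r}")
        bad = set(self.phenotype_subsets) - set(vocab.PHENOTYPE_SUBSETS)
        if bad:
            raise ValueError(f"{self.symbol}: unknown phenotype subset(s) {sorted(bad)}")
        bad = set(self.inheritance_modes) - set(vocab.INHERITANCE_MODES)
        if bad:
            raise ValueError(f"{self.symbol}: unknown inheritance mode(s) {sorted(bad)}")
        if (
            self.discovery_year is not None
            and self.status == vocab.STATUS_DISEASE
            and self.discovery_year < vocab.FIRST_DISCOVERY_YEAR
        ):
            raise ValueError(
                f"{self.symbol}: discovery year {self.discovery_year} predates "
                f"{vocab.FIRST_DISCOVERY_YEAR}"
            )

    @property
    def broad_classes(self) -> frozenset[str]:
        return frozenset(vocab.SUBSET_BROAD_CLASS[s] for s in self.phenotype_subsets)

    def with_categories(self, categories: Iterable[str]) -> "GeneRecord":
        return dataclasses.replace(self, functional_categories=frozenset(categories))


_GENE_COLUMNS = (
    "symbol",
    "status",
    "phenotype_subsets",
    "inheritance_modes",
    "discovery_year",
    "go_terms",
    "functional_categories",
    "is_locus",
)


def _join(values: Iterable[str]) -> str:
    return ";".join(sorted(values))


def _split(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(str(cell).split(";"))


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a curated gene table (TSV; multi-valued cells ";"-delimited).

    Broad classes are recomputed from phenotype subsets (a ``broad_classes``
    column, if present, is ignored). Unknown labels raise a
    :class:`FormatError` naming the label and line.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _GENE_COLUMNS if c not in frame.columns and c != "is_locus"]
    if missing:
        raise FormatError(f"gene table {path} missing column(s) {missing}")
    records: list[GeneRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        year_cell = getattr(row, "discovery_year", "")
        year = int(float(year_cell)) if str(year_cell) not in ("", "NA") else None
        locus_cell = str(getattr(row, "is_locus", "False")).strip().lower()
        try:
            records.append(
                GeneRecord(
                    symbol=row.symbol,
                    status=row.status,
                    phenotype_subsets=_split(row.phenotype_subsets),
                    inheritance_modes=_split(row.inheritance_modes),
                    discovery_year=year,
                    go_terms=_split(getattr(row, "go_terms", "")),
                    functional_categories=_split(getattr(row, "functional_categories", "")),
                    is_locus=locus_cell in ("true", "1", "yes"),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {i}: {exc}") from exc
    return records


def write_atlas_table(records: Sequence[GeneRecord], path: str | Path) -> None:
    """Write the curated gene table, with derived broad classes for readability."""
    rows = []
    for r in records:
        rows.append(
            {
                "symbol": r.symbol,
                "status": r.status,
                "phenotype_subsets": _join(r.phenotype_subsets),
                "broad_classes": _join(r.broad_classes),
                "inheritance_modes": _join(r.inheritance_modes),
                "discovery_year": "" if r.discovery_year is None else r.discovery_year,
                "go_terms": _join(r.go_terms),
                "functional_categories": _join(r.functional_categories),
                "is_locus": r.is_locus,
            }
        )
    pd.DataFrame(rows, columns=_GENE_COLUMNS[:3] + ("broad_classes",) + _GENE_COLUMNS[3:]
                 ).to_csv(path, sep="\t", index=False)
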