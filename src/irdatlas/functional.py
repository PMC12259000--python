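"""GO-term based functional category assignment.

Each gene's Gene Ontology terms are matched (exact term ids, no ontology
traversal) against a mapping table into 20 functional categories; genes whose
terms map nowhere fall into "Others". Manual per-gene overrides take
precedence over term mapping — they capture curator reclassifications, e.g.
phototransduction genes annotated only under a generic visual-perception term.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab
from .io import FormatError, GeneRecord
from .summary import CooccurrenceMatrix


@dataclasses.dataclass(frozen=True)
class CategoryMapping:
    """GO term -> category mapping plus manual per-gene overrides."""

    term_to_category: Mapping[str, frozenset[str]]
    manual_overrides: Mapping[str, frozenset[str]] = dataclasses.field(default_factory=dict)
    provenance: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        valid = set(vocab.ALL_CATEGORIES)
        for source in (self.term_to_category, self.manual_overrides):
            for key, cats in source.items():
                bad = set(cats) - valid
                if bad:
                    raise ValueError(f"{key}: unknown categories {sorted(bad)}")


def assign_categories(gene: GeneRecord, mapping: CategoryMapping) -> frozenset[str]:
    """Functional categories of one gene: override, else term union, else Others."""
    override = mapping.manual_overrides.get(gene.symbol)
    if override:
        return frozenset(override)
    cats: set[str] = set()
    for term in gene.go_terms:
        cats |= mapping.term_to_category.get(term, frozenset())
    return frozenset(cats) if cats else frozenset({vocab.OTHERS_CATEGORY})


def annotate_genes(
    records: Iterable[GeneRecord],
    mapping: CategoryMapping,
    skip_loci: bool = True,
) -> list[GeneRecord]:
    """Fill ``functional_categories`` on gene records (loci stay unannotated)."""
    out = []
    for r in records:
        if skip_loci and r.is_locus:
            out.append(r)
        else:
            out.append(r.with_categories(assign_categories(r, mapping)))
    return out


def membership_summary(assignments: Iterable[frozenset[str]]) -> tuple[int, int]:
    """(genes in exactly one category, genes in more than one)."""
    n_single = n_multiple = 0
    for cats in assignments:
        if len(cats) == 1:
            n_single += 1
        elif len(cats) > 1:
            n_multiple += 1
    return n_single, n_multiple


def overlap_matrix(
    assignments: Mapping[str, frozenset[str]],
    categories: Sequence[str] | None = None,
) -> CooccurrenceMatrix:
    """Symmetric category x category gene-count matrix; diagonal = sizes."""
    cats = list(categories) if categories is not None else list(vocab.ALL_CATEGORIES)
    index = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((len(cats), len(cats)), dtype=int)
    for gene_cats in assignments.values():
        present = [index[c] for c in gene_cats if c in index]
        for i in present:
            for j in present:
                counts[i, j] += 1
    return CooccurrenceMatrix(
        row_labels=tuple(cats),
        col_labels=tuple(cats),
        counts=counts,
        axis_semantics="functional category x functional category (shared genes)",
    )


# -- TSV plumbing ------------------------------------------------------------


def read_category_mapping(path: str | Path) -> CategoryMapping:
    """Read a mapping table: kind (term|override), key, categories, provenance."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    terms: dict[str, frozenset[str]] = {}
    overrides: dict[str, frozenset[str]] = {}
    provenance: dict[str, str] = {}
    for i, row in enumerate(frame.to_dict(orient="records"), start=2):
        cats = frozenset(row["categories"].split(";")) if row["categories"] else frozenset()
        if row["kind"] == "term":
            terms[row["key"]] = terms.get(row["key"], frozenset()) | cats
        elif row["kind"] == "override":
            overrides[row["key"]] = overrides.get(row["key"], frozenset()) | cats
        else:
            raise FormatError(f"{path} line {i}: unknown kind {row['kind']!r}")
        if row.get("provenance"):
            provenance[row["key"]] = row["provenance"]
    return CategoryMapping(terms, overrides, provenance)


def write_category_mapping(mapping: CategoryMapping, path: str | Path) -> None:
    rows = []
    for term, cats in mapping.term_to_category.items():
        rows.append({"kind": "term", "key": term, "categories": ";".join(sorted(cats)),
                     "provenance": mapping.provenance.get(term, "")})
    for gene, cats in mapping.manual_overrides.items():
        rows.append({"kind": "override", "key": gene, "categories": ";".join(sorted(cats)),
                     "provenance": mapping.provenance.get(gene, "")})
    pd.DataFrame(rows, columns=["kind", "key", "categories", "provenance"]).to_csv(
        path, sep="\t", index=False
    )
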