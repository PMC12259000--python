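"""Evidence-based gene curation rules.

A gene enters the atlas as a disease gene when either inclusion criterion
holds over its evidence records:

  (i)  distinct pathogenic variants in two or more unrelated families with
       consistent phenotype and inheritance pattern; or
  (ii) the same variant in at least two unrelated families, supported by
       strong functional evidence of pathogenicity.

Exclusion is definitive and takes precedence: conflicting evidence, proven
non-association, or a locus without a known causative variant. Genes meeting
neither criterion are candidates. Phenotype/inheritance consistency and
relatedness judgments are expert calls supplied on the records, not computed
here.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

from . import vocab

RULE_EXCL_CONFLICT = "exclusion:conflicting-evidence"
RULE_EXCL_NON_ASSOC = "exclusion:proven-non-association"
RULE_EXCL_LOCUS = "exclusion:locus-without-causative-variant"
RULE_INCLUSION_I = "inclusion:i-distinct-variants-unrelated-families"
RULE_INCLUSION_II = "inclusion:ii-same-variant-functional-evidence"
RULE_CANDIDATE = "default:candidate"

FUNCTIONAL_EVIDENCE_LEVELS = ("none", "weak", "strong")


@dataclasses.dataclass(frozen=True)
class EvidenceRecord:
    """One reported family/variant observation for a gene.

    ``families_unrelated`` asserts the family is unrelated to the other
    families reported for the same gene; ``locus_has_causative_variant`` only
    matters when ``is_locus`` is set.
    """

    gene: str
    family_id: str
    variant_id: str
    phenotype_consistent: bool = True
    inheritance_consistent: bool = True
    functional_evidence: str = "none"
    families_unrelated: bool = True
    conflicting_evidence: bool = False
    proven_non_association: bool = False
    is_locus: bool = False
    locus_has_causative_variant: bool = False

    def __post_init__(self):
        if self.functional_evidence not in FUNCTIONAL_EVIDENCE_LEVELS:
            raise ValueError(
                f"functional_evidence must be one of {FUNCTIONAL_EVIDENCE_LEVELS}"
            )


@dataclasses.dataclass(frozen=True)
class CurationResult:
    gene: str
    status: str
    rule: str


def _consistent(r: EvidenceRecord) -> bool:
    return r.phenotype_consistent and r.inheritance_consistent


def _unrelated_pair(a: EvidenceRecord, b: EvidenceRecord) -> bool:
    return a.family_id != b.family_id and a.families_unrelated and b.families_unrelated


def evaluate_gene(records: Sequence[EvidenceRecord]) -> CurationResult:
    """Evaluate all evidence records of one gene into a status + fired rule."""
    records = list(records)
    if not records:
        raise ValueError("no evidence records supplied")
    genes = {r.gene for r in records}
    if len(genes) != 1:
        raise ValueError(f"records span multiple genes: {sorted(genes)}")
    gene = next(iter(genes))

    # exclusion flags are definitive and take precedence over inclusion
    if any(r.conflicting_evidence for r in records):
        return CurationResult(gene, vocab.STATUS_EXCLUDED, RULE_EXCL_CONFLICT)
    if any(r.proven_non_association for r in records):
        return CurationResult(gene, vocab.STATUS_EXCLUDED, RULE_EXCL_NON_ASSOC)
    if any(r.is_locus for r in records) and not any(
        r.locus_has_causative_variant for r in records
    ):
        return CurationResult(gene, vocab.STATUS_EXCLUDED, RULE_EXCL_LOCUS)

    # criterion (i): distinct variants, >=1 unrelated family pair, consistent
    consistent = [r for r in records if _consistent(r)]
    for a, b in itertools.combinations(consistent, 2):
        if a.variant_id != b.variant_id and _unrelated_pair(a, b):
            return CurationResult(gene, vocab.STATUS_DISEASE, RULE_INCLUSION_I)

    # criterion (ii): same variant in >=2 unrelated families + strong evidence
    by_variant: dict[str, list[EvidenceRecord]] = {}
    for r in records:
        by_variant.setdefault(r.variant_id, []).append(r)
    for group in by_variant.values():
        if not any(r.functional_evidence == "strong" for r in group):
            continue
        if any(_unrelated_pair(a, b) for a, b in itertools.combinations(group, 2)):
            return CurationResult(gene, vocab.STATUS_DISEASE, RULE_INCLUSION_II)

    return CurationResult(gene, vocab.STATUS_CANDIDATE, RULE_CANDIDATE)


def evaluate_all(records: Iterable[EvidenceRecord]) -> list[CurationResult]:
    by_gene: dict[str, list[EvidenceRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    return [evaluate_gene(rs) for _, rs in sorted(by_gene.items())]


# -- TSV plumbing ------------------------------------------------------------

_BOOL_FIELDS = (
    "phenotype_consistent", "inheritance_consistent", "families_unrelated",
    "conflicting_evidence", "proven_non_association", "is_locus",
    "locus_has_causative_variant",
)


def read_evidence_table(path: str | Path) -> list[EvidenceRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in frame.to_dict(orient="records"):
        kwargs = {
            "gene": row["gene"],
            "family_id": row["family_id"],
            "variant_id": row["variant_id"],
            "functional_evidence": row.get("functional_evidence", "none") or "none",
        }
        for f in _BOOL_FIELDS:
            if f in row and row[f] != "":
                kwargs[f] = row[f].strip().lower() in ("true", "1", "yes")
        out.append(EvidenceRecord(**kwargs))
    return out


def write_curation_results(results: Iterable[CurationResult], path: str | Path) -> None:
    """Audit-trail TSV: gene, status, fired rule."""
    pd.DataFrame(
        [{"gene": r.gene, "status": r.status, "rule": r.rule} for r in results]
    ).to_csv(path, sep="\t", index=False)
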