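"""Aggregate atlas statistics: Venn partition, distributions, co-occurrence
matrices and the discovery timeline.

Counting convention: a gene carrying several labels on an axis (e.g. both RP
and MD phenotypes) contributes to *each* of its labels. Per-label counts can
therefore sum to more than the number of genes — this multi-membership
convention matches how atlas figures tabulate genes and deliberately breaks
naive contingency-table intuitions.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Callable, Iterable, Sequence
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import vocab
from .io import GeneRecord

logger = logging.getLogger(__name__)


def percentage(n: int, total: int) -> float:
    """Percentage to one decimal, round half up (97.25% -> 97.3)."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(100 * n) / Decimal(total)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclasses.dataclass(frozen=True)
class CooccurrenceMatrix:
    """Gene counts cross-tabulated over two categorical gene attributes."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray
    axis_semantics: str = ""

    def __post_init__(self):
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match label counts")
        if (self.counts < 0).any():
            raise ValueError("negative count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="")


@dataclasses.dataclass(frozen=True)
class DiscoveryTimeline:
    years: tuple[int, ...]
    annual_counts: tuple[int, ...]
    cumulative_counts: tuple[int, ...]
    per_period_rates: dict[tuple[int, int], float]
    mean_annual_rate: float
    regression_slope: float


def _disease(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    return [r for r in records if r.status == vocab.STATUS_DISEASE]


def venn_partition(records: Iterable[GeneRecord]) -> tuple[int, int, int, int]:
    """(non-syndromic total, syndromic total, both, grand total) of disease genes.

    Computed from the derived broad classes, so the inclusion-exclusion
    identity n_nonsyn + n_syn - n_both = n_total holds by construction.
    """
    disease = _disease(records)
    n_non = sum(1 for r in disease if vocab.NON_SYNDROMIC in r.broad_classes)
    n_syn = sum(1 for r in disease if vocab.SYNDROMIC in r.broad_classes)
    n_both = sum(1 for r in disease if len(r.broad_classes) == 2)
    return n_non, n_syn, n_both, len(disease)


def inheritance_distribution(
    records: Iterable[GeneRecord],
) -> dict[str, tuple[int, float]]:
    """Per-mode gene counts with percentages over all disease genes.

    A gene contributes once per inheritance label it carries ("AD-AR" is its
    own label); for single-label records the counts sum to the gene total.
    """
    disease = _disease(records)
    total = len(disease)
    out: dict[str, tuple[int, float]] = {}
    for mode in vocab.INHERITANCE_MODES:
        n = sum(1 for r in disease if mode in r.inheritance_modes)
        if n:
            out[mode] = (n, percentage(n, total))
    return out


def subset_distribution(records: Iterable[GeneRecord]) -> dict[str, int]:
    """Gene count per phenotype subset (multi-membership) over disease genes."""
    disease = _disease(records)
    return {
        s: n
        for s in vocab.PHENOTYPE_SUBSETS
        if (n := sum(1 for r in disease if s in r.phenotype_subsets))
    }


#: named label extractors usable as co-occurrence axes
AXIS_EXTRACTORS: dict[str, Callable[[GeneRecord], frozenset[str]]] = {
    "phenotype_subsets": lambda r: r.phenotype_subsets,
    "broad_classes": lambda r: r.broad_classes,
    "inheritance_modes": lambda r: r.inheritance_modes,
    "functional_categories": lambda r: r.functional_categories,
}


def cooccurrence(
    records: Iterable[GeneRecord],
    axis1: str | Callable[[GeneRecord], frozenset[str]],
    axis2: str | Callable[[GeneRecord], frozenset[str]],
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> CooccurrenceMatrix:
    """Cross-tabulate disease genes over two label-set attributes.

    Axes are attribute names from :data:`AXIS_EXTRACTORS` or callables
    returning a label set per gene. A gene with labels {a1, a2} x {b} adds one
    count to both (a1, b) and (a2, b).
    """
    get1 = AXIS_EXTRACTORS[axis1] if isinstance(axis1, str) else axis1
    get2 = AXIS_EXTRACTORS[axis2] if isinstance(axis2, str) else axis2
    disease = _disease(records)
    if row_labels is None:
        row_labels = sorted({l for r in disease for l in get1(r)})
    if col_labels is None:
        col_labels = sorted({l for r in disease for l in get2(r)})
    ri = {l: i for i, l in enumerate(row_labels)}
    ci = {l: i for i, l in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    for r in disease:
        for a in get1(r):
            for b in get2(r):
                if a in ri and b in ci:
                    counts[ri[a], ci[b]] += 1
    name1 = axis1 if isinstance(axis1, str) else "axis1"
    name2 = axis2 if isinstance(axis2, str) else "axis2"
    return CooccurrenceMatrix(tuple(row_labels), tuple(col_labels), counts,
                              axis_semantics=f"{name1} x {name2}")


def discovery_timeline(
    records: Iterable[GeneRecord],
    period_breaks: Sequence[int] | None = None,
) -> DiscoveryTimeline:
    """Cumulative discovery curve and per-period mean discovery rates.

    Periods are half-open year intervals [start, end) over consecutive break
    points. Disease genes without a discovery year are excluded (logged).
    Alongside per-period rates, two overall rates are reported: the mean of
    annual counts and the OLS slope of the cumulative curve.
    """
    disease = _disease(records)
    years_list = [r.discovery_year for r in disease if r.discovery_year is not None]
    n_undated = len(disease) - len(years_list)
    if n_undated:
        logger.info("excluded %d disease genes without discovery year", n_undated)
    if not years_list:
        return DiscoveryTimeline((), (), (), {}, 0.0, 0.0)
    lo, hi = min(years_list), max(years_list)
    years = tuple(range(lo, hi + 1))
    annual = tuple(sum(1 for y in years_list if y == yr) for yr in years)
    cumulative = tuple(np.cumsum(annual).tolist())
    rates: dict[tuple[int, int], float] = {}
    if period_breaks is not None:
        for start, end in zip(period_breaks[:-1], period_breaks[1:]):
            n_new = sum(1 for y in years_list if start <= y < end)
            rates[(start, end)] = n_new / (end - start)
    slope = float(np.polyfit(years, cumulative, 1)[0]) if len(years) > 1 else 0.0
    return DiscoveryTimeline(
        years=years,
        annual_counts=annual,
        cumulative_counts=cumulative,
        per_period_rates=rates,
        mean_annual_rate=len(years_list) / len(years),
        regression_slope=slope,
    )


def multi_phenotype_genes(
    records: Iterable[GeneRecord],
    scope: str | None = None,
) -> int:
    """Disease genes carrying more than one phenotype subset within a scope.

    ``scope`` restricts which subsets are counted: "non-syndromic",
    "syndromic", or None for all 16. A gene with one subset per broad class
    (e.g. {RP, BBS}) is *not* multi-phenotype under either single-class scope.
    """
    if scope not in (None, vocab.NON_SYNDROMIC, vocab.SYNDROMIC):
        raise ValueError(f"unknown scope {scope!r}")
    n = 0
    for r in _disease(records):
        subsets = r.phenotype_subsets
        if scope is not None:
            subsets = {s for s in subsets if vocab.SUBSET_BROAD_CLASS[s] == scope}
        if len(subsets) > 1:
            n += 1
    return n


def status_counts(records: Iterable[GeneRecord]) -> dict[str, int]:
    out = {s: 0 for s in vocab.GENE_STATUSES}
    for r in records:
        out[r.status] += 1
    return out
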