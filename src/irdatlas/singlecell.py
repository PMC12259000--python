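"""Single-cell cell-type specificity classification.

The 53 cell-subtype columns are collapsed into 19 major groups (mean over
member subtypes); 5 broader groups are means over their member major groups.
Each of the 24 candidate categories is scored against the *remaining* major
groups — i.e. the major groups not covered by the candidate (18 for a major
group, 19 - |members| for a broader group), so a candidate's own signal never
contaminates its background:

    z_group     = (value - mean(remaining)) / sd(remaining)    (sample sd)
    ratio_group = value / mean(remaining)

(the ratio denominator is the MEAN of the background here, unlike the bulk
classifier where it is the MAX). A gene is "group specific" to a candidate
when z > 3 AND ratio > 3 AND value > 1. The per-candidate results collapse
into one of five overarching categories: rods_cones_rpe / other_cell /
not_cell_specific / low_expression / no_data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .bulk import SpecificityThresholds
from .io import ExpressionMatrix
from .schemes import CellGroupScheme

OVER_RODS_CONES_RPE = "rods_cones_rpe"
OVER_OTHER_CELL = "other_cell"
OVER_NOT_SPECIFIC = "not_cell_specific"
OVER_LOW = "low_expression"
OVER_NO_DATA = "no_data"
OVERARCHING_CATEGORIES = (
    OVER_RODS_CONES_RPE, OVER_OTHER_CELL, OVER_NOT_SPECIFIC, OVER_LOW, OVER_NO_DATA,
)

#: candidate categories whose specificity collapses to the photoreceptor/RPE label
PHOTORECEPTOR_CANDIDATES = frozenset(
    {"Rods", "Cones", "RPE", "Rods+Cones", "Rods+Cones+RPE"}
)


@dataclasses.dataclass(frozen=True)
class CellSpecificityResult:
    """Per-candidate (z, ratio, value) triples and the overarching label."""

    per_category_scores: dict[str, tuple[float, float, float]]
    specific_categories: frozenset[str]
    overarching: str


def collapse_subtypes(matrix: ExpressionMatrix, scheme: CellGroupScheme) -> ExpressionMatrix:
    """Collapse the 53 subtype columns into the 19 major groups (mean)."""
    missing = [s for s in scheme.subtype_names if s not in matrix.frame.columns]
    if missing:
        raise ValueError(f"missing subtype column(s): {missing[:5]}")
    cols = {
        major: matrix.frame[scheme.subtypes_of(major)].mean(axis=1)
        for major in scheme.major_groups
    }
    return ExpressionMatrix(pd.DataFrame(cols, columns=list(scheme.major_groups)))


def broader_group_values(major_row: pd.Series, scheme: CellGroupScheme) -> pd.Series:
    """Mean of member major-group values for each of the 5 broader groups."""
    return pd.Series(
        {name: float(major_row[list(members)].mean())
         for name, members in scheme.broader_groups.items()}
    )


def score_candidate(
    major_row: pd.Series,
    candidate: str,
    scheme: CellGroupScheme,
    ddof: int = 1,
) -> tuple[float, float, float]:
    """(z, ratio, value) of one candidate category for one gene.

    The background ("remaining groups") excludes every major group covered by
    the candidate. sd = 0 degenerates z to +/-inf preserving direction; a zero
    mean background gives ratio +inf when value > 0, 1 for 0/0.
    """
    members = scheme.members_of(candidate)
    value = float(major_row[list(members)].mean())
    remaining = major_row.drop(list(members)).to_numpy(dtype=float)
    mean = float(remaining.mean())
    sd = float(remaining.std(ddof=ddof))
    if sd > 0:
        z = (value - mean) / sd
    else:
        z = 0.0 if value == mean else (np.inf if value > mean else -np.inf)
    if mean > 0:
        ratio = value / mean
    else:
        ratio = np.inf if value > 0 else 1.0
    return z, ratio, value


def score_gene(
    major_row: pd.Series,
    scheme: CellGroupScheme,
    thresholds: SpecificityThresholds = SpecificityThresholds(),
    ddof: int = 1,
) -> CellSpecificityResult:
    """Score all 24 candidates for one gene and collapse to the overarching label."""
    scores: dict[str, tuple[float, float, float]] = {}
    specific: set[str] = set()
    for candidate in scheme.candidate_categories:
        z, ratio, value = score_candidate(major_row, candidate, scheme, ddof=ddof)
        scores[candidate] = (z, ratio, value)
        if z > thresholds.z and ratio > thresholds.ratio and value > thresholds.min_expression:
            specific.add(candidate)
    overarching = classify_cell(
        frozenset(specific),
        max_major_value=float(major_row.max()),
        in_dataset=True,
        thresholds=thresholds,
    )
    return CellSpecificityResult(scores, frozenset(specific), overarching)


def classify_cell(
    specific_categories: frozenset[str],
    max_major_value: float,
    in_dataset: bool = True,
    thresholds: SpecificityThresholds = SpecificityThresholds(),
) -> str:
    """Collapse per-candidate specificity into one of five overarching labels.

    Priority: no_data, then low expression (max over the 19 major-group values
    at or below the floor — the single-cell table has no single "retina"
    value), then photoreceptor/RPE specificity (which wins over other-cell
    specificity when a gene is specific in both camps), then other_cell, else
    not_cell_specific.
    """
    if not in_dataset:
        return OVER_NO_DATA
    if max_major_value <= thresholds.min_expression:
        return OVER_LOW
    if specific_categories & PHOTORECEPTOR_CANDIDATES:
        return OVER_RODS_CONES_RPE
    if specific_categories:
        return OVER_OTHER_CELL
    return OVER_NOT_SPECIFIC


def classify_genes(
    matrix: ExpressionMatrix,
    scheme: CellGroupScheme | None = None,
    gene_ids: list[str] | None = None,
    thresholds: SpecificityThresholds = SpecificityThresholds(),
    ddof: int = 1,
) -> pd.DataFrame:
    """Classify genes from a 53-subtype matrix.

    Returns a DataFrame indexed by gene with one column per candidate category
    holding "z|ratio|value" summaries plus ``specific_to`` (";"-joined) and
    ``overarching``. Genes listed but absent from the matrix are no_data.
    """
    scheme = scheme or CellGroupScheme.builtin()
    majors = collapse_subtypes(matrix, scheme)
    targets = gene_ids if gene_ids is not None else majors.gene_ids
    rows = []
    for gene in targets:
        if gene not in majors:
            rows.append({"gene": gene, "specific_to": "", "overarching": OVER_NO_DATA})
            continue
        result = score_gene(majors.row(gene), scheme, thresholds=thresholds, ddof=ddof)
        row: dict[str, object] = {
            "gene": gene,
            "specific_to": ";".join(sorted(result.specific_categories)),
            "overarching": result.overarching,
        }
        for cand, (z, ratio, value) in result.per_category_scores.items():
            row[f"z[{cand}]"] = z
            row[f"ratio[{cand}]"] = ratio
            row[f"value[{cand}]"] = value
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
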