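"""Bulk tissue-specificity scoring: the retina-prevalence classifier.

For each gene, tissue samples are first averaged into 13 groups. The retina
group value is then compared against the 12 non-retina groups:

    z_retina     = (v_retina - mean(others)) / sd(others)     (sample sd, n-1)
    ratio_retina = v_retina / max(others)

and the gene falls into exactly one of four categories:

    no_data             not present in the expression dataset
    low_expression      v_retina <= 1 nTPM
    retina_prevalent    z_retina > 3 AND ratio_retina > 3 AND v_retina > 1
    not_retina_prevalent  everything else with v_retina > 1

Degenerate cases: sd(others) = 0 makes z +/-inf (so the z > 3 condition
reduces to v_retina > mean(others)); ratio with a zero denominator is +inf
when v_retina > 0 and 1 for 0/0.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .schemes import TissueGroupScheme

CATEGORY_PREVALENT = "retina_prevalent"
CATEGORY_NOT_PREVALENT = "not_retina_prevalent"
CATEGORY_LOW = "low_expression"
CATEGORY_NO_DATA = "no_data"
BULK_CATEGORIES = (CATEGORY_PREVALENT, CATEGORY_NOT_PREVALENT, CATEGORY_LOW, CATEGORY_NO_DATA)


@dataclasses.dataclass(frozen=True)
class SpecificityThresholds:
    """Decision thresholds of the prevalence rule (defaults as published)."""

    z: float = 3.0
    ratio: float = 3.0
    min_expression: float = 1.0


@dataclasses.dataclass(frozen=True)
class SpecificityScore:
    z_retina: float
    ratio_retina: float
    ntpm_retina: float
    category: str | None = None


def aggregate_tissue_groups(
    matrix: ExpressionMatrix,
    scheme: TissueGroupScheme,
    agg: str = "mean",
) -> ExpressionMatrix:
    """Average (or max-pool) sample columns into the scheme's tissue groups.

    ``agg`` is "mean" (published behaviour) or "max"; every group must have at
    least one sample column present in the matrix.
    """
    if agg not in ("mean", "max"):
        raise ValueError(f"agg must be 'mean' or 'max', got {agg!r}")
    unknown = [c for c in matrix.column_ids if c not in scheme.membership]
    if unknown:
        raise ValueError(f"matrix columns not covered by scheme: {unknown[:5]}")
    cols = {}
    for group in scheme.group_names:
        present = [s for s in scheme.samples_of(group) if s in matrix.frame.columns]
        if not present:
            raise ValueError(f"tissue group {group!r} has no sample columns in matrix")
        sub = matrix.frame[present]
        cols[group] = sub.mean(axis=1) if agg == "mean" else sub.max(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols, columns=list(scheme.group_names)))


def _z_and_ratio(value: float, others: np.ndarray, ddof: int = 1) -> tuple[float, float]:
    """z and ratio of one value against a background vector.

    ratio denominator is max(others) here (bulk rule). sd = 0 degenerates z to
    +/-inf (or 0 when value equals the common background), preserving the
    direction of the comparison in downstream `z > threshold` tests.
    """
    mean = float(others.mean())
    sd = float(others.std(ddof=ddof))
    if sd > 0:
        z = (value - mean) / sd
    else:
        z = 0.0 if value == mean else (np.inf if value > mean else -np.inf)
    denom = float(others.max())
    if denom > 0:
        ratio = value / denom
    else:
        ratio = np.inf if value > 0 else 1.0
    return z, ratio


def retina_scores(
    grouped_row: pd.Series,
    scheme: TissueGroupScheme,
    ddof: int = 1,
) -> SpecificityScore:
    """Score one gene's 13 group values against the non-retina background."""
    if len(grouped_row) != len(scheme.group_names):
        raise ValueError(
            f"expected {len(scheme.group_names)} group values, got {len(grouped_row)}"
        )
    v_retina = float(grouped_row[scheme.target_group])
    others = grouped_row.drop(scheme.target_group).to_numpy(dtype=float)
    z, ratio = _z_and_ratio(v_retina, others, ddof=ddof)
    return SpecificityScore(z_retina=z, ratio_retina=ratio, ntpm_retina=v_retina)


def classify_bulk(
    score: SpecificityScore | None,
    in_dataset: bool = True,
    thresholds: SpecificityThresholds = SpecificityThresholds(),
) -> str:
    """Assign one of the four mutually exclusive bulk categories.

    Order of precedence: absent from dataset -> no_data; retina value at or
    below the expression floor -> low_expression; full conjunction -> retina
    prevalent; otherwise not retina prevalent (this closes the gap for mixed
    cases where only one of z/ratio exceeds its threshold, so the four
    categories always partition the gene set).
    """
    if not in_dataset or score is None:
        return CATEGORY_NO_DATA
    if score.ntpm_retina <= thresholds.min_expression:
        return CATEGORY_LOW
    if score.z_retina > thresholds.z and score.ratio_retina > thresholds.ratio:
        return CATEGORY_PREVALENT
    return CATEGORY_NOT_PREVALENT


def score_genes(
    matrix: ExpressionMatrix,
    scheme: TissueGroupScheme | None = None,
    gene_ids: list[str] | None = None,
    agg: str = "mean",
    thresholds: SpecificityThresholds = SpecificityThresholds(),
    ddof: int = 1,
) -> pd.DataFrame:
    """Score and classify genes; absent genes (if listed) come back as no_data.

    Returns a DataFrame indexed by gene with columns z_retina, ratio_retina,
    ntpm_retina, category.
    """
    scheme = scheme or TissueGroupScheme.builtin()
    grouped = aggregate_tissue_groups(matrix, scheme, agg=agg)
    targets = gene_ids if gene_ids is not None else grouped.gene_ids
    rows = []
    for gene in targets:
        if gene not in grouped:
            rows.append((gene, np.nan, np.nan, np.nan, CATEGORY_NO_DATA))
            continue
        s = retina_scores(grouped.row(gene), scheme, ddof=ddof)
        cat = classify_bulk(s, in_dataset=True, thresholds=thresholds)
        rows.append((gene, s.z_retina, s.ratio_retina, s.ntpm_retina, cat))
    return pd.DataFrame(
        rows, columns=["gene", "z_retina", "ratio_retina", "ntpm_retina", "category"]
    ).set_index("gene")
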