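"""End-to-end pipeline: simulate -> curate -> bulk-spec -> sc-spec ->
variant-spec -> annotate -> summarize, driven by one YAML config.

All randomness funnels through the single configured seed; a rerun with the
same config is bit-identical for every deterministic stage. A manifest
records the config hash, seed, package version and the stages executed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import yaml

from . import __version__, bulk, curation, functional, io, simulate, singlecell, summary
from . import variants as variants_mod
from . import vocab
from .bulk import SpecificityThresholds
from .schemes import CellGroupScheme, TissueGroupScheme

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "curate", "bulk-spec", "sc-spec", "variant-spec", "annotate", "summarize",
)


@dataclasses.dataclass
class PipelineConfig:
    """Tunable knobs of the pipeline; thresholds default to the published rule."""

    seed: int = 0
    # simulation sizes
    n_genes: int = 1000
    n_planted: int = 50
    fold_change: float = 10.0
    noise_cv: float = 0.1
    baseline_level: float = 5.0
    low_expression_fraction: float = 0.1
    # classifier thresholds
    z_threshold: float = 3.0
    ratio_threshold: float = 3.0
    min_expression: float = 1.0
    rare_threshold: int = 5
    mostly_fraction: float = 0.75
    aggregation: str = "mean"
    # optional user-supplied scheme files
    tissue_scheme: str | None = None
    cell_scheme: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @property
    def thresholds(self) -> SpecificityThresholds:
        return SpecificityThresholds(
            z=self.z_threshold, ratio=self.ratio_threshold,
            min_expression=self.min_expression,
        )


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run all stages on synthetic inputs; returns the report directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tissue_scheme = (TissueGroupScheme.from_yaml(config.tissue_scheme)
                     if config.tissue_scheme else TissueGroupScheme.builtin())
    cell_scheme = (CellGroupScheme.from_yaml(config.cell_scheme)
                   if config.cell_scheme else CellGroupScheme.builtin())
    rng_seed = config.seed

    # -- simulate ------------------------------------------------------------
    logger.info("[simulate] generating synthetic inputs (seed=%d)", rng_seed)
    planted = frozenset(range(config.n_planted))
    bulk_spec = simulate.BulkSimSpec(
        n_genes=config.n_genes, planted_prevalent=planted,
        fold_change=config.fold_change, baseline_level=config.baseline_level,
        noise_cv=config.noise_cv,
        low_expression_fraction=config.low_expression_fraction, seed=rng_seed,
    )
    bulk_matrix, _ = simulate.generate_bulk_matrix(bulk_spec, tissue_scheme)
    io.write_expression_matrix(bulk_matrix, out / "bulk_matrix.tsv")

    candidates = cell_scheme.candidate_categories
    sc_spec = simulate.ScSimSpec(
        n_genes=config.n_genes,
        planted={i: candidates[i % len(candidates)] for i in range(config.n_planted)},
        fold_change=config.fold_change, baseline_level=config.baseline_level,
        noise_cv=config.noise_cv,
        low_expression_fraction=config.low_expression_fraction, seed=rng_seed + 1,
    )
    sc_matrix, _ = simulate.generate_sc_matrix(sc_spec, cell_scheme)
    io.write_expression_matrix(sc_matrix, out / "sc_matrix.tsv")

    records, mapping = simulate.published_atlas(seed=rng_seed)
    io.write_atlas_table(records, out / "gene_table.tsv")
    functional.write_category_mapping(mapping, out / "category_mapping.tsv")

    vcf_spec = simulate.VcfSimSpec(
        per_gene_composition={
            "GENE0001": (8, 2, 0, 1), "GENE0002": (1, 9, 0, 0),
            "GENE0003": (5, 5, 0, 2), "GENE0004": (2, 1, 0, 3),
            "GENE0005": (0, 0, 6, 0),
        },
        seed=rng_seed,
    )
    simulate.generate_clinvar_vcf(vcf_spec, out / "clinvar.vcf")

    evidence = simulate.generate_evidence_table(records, seed=rng_seed)
    # evidence written through the curation TSV schema for the audit trail
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(e) for e in evidence]).to_csv(
        out / "evidence.tsv", sep="\t", index=False
    )

    # -- curate ---------------------------------------------------------------
    logger.info("[curate] evaluating %d evidence records", len(evidence))
    results = curation.evaluate_all(curation.read_evidence_table(out / "evidence.tsv"))
    curation.write_curation_results(results, out / "curation.tsv")

    # -- bulk-spec ------------------------------------------------------------
    logger.info("[bulk-spec] scoring %d genes", config.n_genes)
    bulk_scores = bulk.score_genes(
        io.read_expression_matrix(out / "bulk_matrix.tsv"), tissue_scheme,
        agg=config.aggregation, thresholds=config.thresholds,
    )
    bulk_scores.to_csv(out / "bulk_scores.tsv", sep="\t")

    # -- sc-spec --------------------------------------------------------------
    logger.info("[sc-spec] scoring %d genes over 24 candidates", config.n_genes)
    sc_scores = singlecell.classify_genes(
        io.read_expression_matrix(out / "sc_matrix.tsv"), cell_scheme,
        thresholds=config.thresholds,
    )
    sc_scores.to_csv(out / "sc_scores.tsv", sep="\t")

    # -- variant-spec ----------------------------------------------------------
    logger.info("[variant-spec] profiling variant spectra")
    parsed = io.read_clinvar_vcf(out / "clinvar.vcf")
    spectra = variants_mod.spectrum_table(parsed)
    spectra.to_csv(out / "variant_spectra.tsv", sep="\t")

    # -- annotate --------------------------------------------------------------
    logger.info("[annotate] assigning functional categories")
    table = io.read_gene_table(out / "gene_table.tsv")
    mapping = functional.read_category_mapping(out / "category_mapping.tsv")
    annotated = functional.annotate_genes(table, mapping)
    io.write_atlas_table(annotated, out / "gene_table_annotated.tsv")

    # -- summarize --------------------------------------------------------------
    logger.info("[summarize] computing atlas aggregates")
    report = summarize(annotated, out)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": list(STAGES),
        "config": config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def summarize(records, outdir: str | Path) -> dict[str, Any]:
    """Write the machine-readable summary report; returns its dict form."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    statuses = summary.status_counts(records)
    n_non, n_syn, n_both, n_total = summary.venn_partition(records)
    inheritance = summary.inheritance_distribution(records)
    subsets = summary.subset_distribution(records)
    timeline = summary.discovery_timeline(
        records, period_breaks=[1988, 2010, 2018, 2025]
    )
    annotated = [r for r in records
                 if r.status == vocab.STATUS_DISEASE and not r.is_locus]
    n_single, n_multiple = functional.membership_summary(
        [r.functional_categories for r in annotated if r.functional_categories]
    )
    overlap = functional.overlap_matrix(
        {r.symbol: r.functional_categories for r in annotated if r.functional_categories}
    )
    overlap.write_tsv(out / "category_overlap.tsv")
    summary.cooccurrence(records, "inheritance_modes", "broad_classes").write_tsv(
        out / "cooccurrence_inheritance_broad.tsv"
    )
    summary.cooccurrence(records, "phenotype_subsets", "inheritance_modes").write_tsv(
        out / "cooccurrence_phenotype_inheritance.tsv"
    )
    report = {
        "status_counts": statuses,
        "venn": {"non_syndromic": n_non, "syndromic": n_syn, "both": n_both,
                 "total": n_total},
        "inheritance": {m: {"n": n, "pct": pct} for m, (n, pct) in inheritance.items()},
        "phenotype_subsets": subsets,
        "multi_phenotype_nonsyndromic": summary.multi_phenotype_genes(
            records, scope=vocab.NON_SYNDROMIC
        ),
        "functional": {
            "n_single_category": n_single,
            "n_multiple_categories": n_multiple,
            "category_sizes": {
                c: int(overlap.to_frame().loc[c, c]) for c in overlap.row_labels
            },
        },
        "timeline": {
            "per_period_rates": {
                f"{a}-{b}": r for (a, b), r in timeline.per_period_rates.items()
            },
            "mean_annual_rate": timeline.mean_annual_rate,
            "regression_slope": timeline.regression_slope,
        },
    }
    (out / "summary.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
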