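"""Bulk retina-prevalence classifier: arithmetic oracles, rule enumeration,
invariants, parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from irdatlas import bulk, simulate
from irdatlas.bulk import SpecificityScore, SpecificityThresholds
from irdatlas.io import ExpressionMatrix


def grouped_row(scheme, retina, others):
    values = {}
    non_retina = [g for g in scheme.group_names if g != "retina"]
    for g, v in zip(non_retina, others):
        values[g] = v
    values["retina"] = retina
    return pd.Series(values)[list(scheme.group_names)]


class TestAggregation:
    def test_singleton_group_mean_is_identity(self, tissue_scheme):
        frame = pd.DataFrame({s: [5.0] for s in tissue_scheme.sample_names}, index=["GA"])
        frame["heart muscle"] = 7.5
        grouped = bulk.aggregate_tissue_groups(ExpressionMatrix(frame), tissue_scheme)
        assert grouped.row("GA")["heart"] == 7.5

    def test_constant_brain_members_give_constant_group(self, tissue_scheme):
        frame = pd.DataFrame({s: [1.0] for s in tissue_scheme.sample_names}, index=["GA"])
        for s in tissue_scheme.samples_of("brain_max"):
            frame[s] = 4.25
        grouped = bulk.aggregate_tissue_groups(ExpressionMatrix(frame), tissue_scheme)
        assert grouped.row("GA")["brain_max"] == 4.25

    def test_brain_mean_of_arithmetic_sequence(self, tissue_scheme):
        brain = tissue_scheme.samples_of("brain_max")
        assert len(brain) == 23
        frame = pd.DataFrame({s: [0.0] for s in tissue_scheme.sample_names}, index=["GA"])
        for i, s in enumerate(brain):
            frame[s] = float(i)  # 0..22 -> mean 11
        grouped = bulk.aggregate_tissue_groups(ExpressionMatrix(frame), tissue_scheme)
        assert grouped.row("GA")["brain_max"] == 11.0

    def test_thirteen_groups_emitted(self, tissue_scheme, small_matrix):
        frame = pd.DataFrame(
            {s: [1.0, 2.0] for s in tissue_scheme.sample_names}, index=["GA", "GB"]
        )
        grouped = bulk.aggregate_tissue_groups(ExpressionMatrix(frame), tissue_scheme)
        assert grouped.shape == (2, 13)

    def test_max_aggregation_option(self, tissue_scheme):
        frame = pd.DataFrame({s: [1.0] for s in tissue_scheme.sample_names}, index=["GA"])
        frame[tissue_scheme.samples_of("brain_max")[0]] = 9.0
        grouped = bulk.aggregate_tissue_groups(
            ExpressionMatrix(frame), tissue_scheme, agg="max"
        )
        assert grouped.row("GA")["brain_max"] == 9.0

    def test_group_without_samples_errors_by_name(self, tissue_scheme):
        frame = pd.DataFrame(
            {s: [1.0] for s in tissue_scheme.sample_names if s != "retina"},
            index=["GA"],
        )
        with pytest.raises(ValueError, match="retina"):
            bulk.aggregate_tissue_groups(ExpressionMatrix(frame), tissue_scheme)


class TestRetinaScores:
    def test_flat_profile_scores_zero_and_one(self, tissue_scheme):
        score = bulk.retina_scores(grouped_row(tissue_scheme, 4.0, [4.0] * 12),
                                   tissue_scheme)
        assert score.z_retina == 0.0
        assert score.ratio_retina == 1.0
        assert score.ntpm_retina == 4.0

    def test_hand_arithmetic_oracle(self, tissue_scheme):
        # retina 9 against {1 x11, 13}: mean 2, sample sd sqrt(12)
        score = bulk.retina_scores(
            grouped_row(tissue_scheme, 9.0, [1.0] * 11 + [13.0]), tissue_scheme
        )
        assert score.z_retina == pytest.approx(7 / math.sqrt(12), abs=1e-12)
        assert score.z_retina == pytest.approx(2.0207, abs=1e-4)
        assert score.ratio_retina == pytest.approx(9 / 13, abs=1e-12)

    def test_degenerate_sd_falls_back_to_direction(self, tissue_scheme):
        score = bulk.retina_scores(grouped_row(tissue_scheme, 10.0, [1.0] * 12),
                                   tissue_scheme)
        assert score.ratio_retina == 10.0
        assert score.z_retina > 3  # +inf: the z condition reduces to 10 > 1
        assert bulk.classify_bulk(score) == "retina_prevalent"

    def test_zero_denominator_ratio(self, tissue_scheme):
        score = bulk.retina_scores(grouped_row(tissue_scheme, 2.0, [0.0] * 12),
                                   tissue_scheme)
        assert score.ratio_retina == np.inf
        zero = bulk.retina_scores(grouped_row(tissue_scheme, 0.0, [0.0] * 12),
                                  tissue_scheme)
        assert zero.ratio_retina == 1.0

    def test_population_sd_option(self, tissue_scheme):
        row = grouped_row(tissue_scheme, 9.0, [1.0] * 11 + [13.0])
        score = bulk.retina_scores(row, tissue_scheme, ddof=0)
        sd_pop = math.sqrt(132 / 12)
        assert score.z_retina == pytest.approx(7 / sd_pop, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "z,ratio,ntpm,expected",
        [
            (5.0, 4.0, 2.0, "retina_prevalent"),
            (5.0, 4.0, 0.5, "low_expression"),  # expression floor wins
            (5.0, 2.0, 2.0, "not_retina_prevalent"),  # ratio fails
            (2.0, 4.0, 2.0, "not_retina_prevalent"),  # z fails
            (2.0, 2.0, 2.0, "not_retina_prevalent"),
            (3.0, 3.0, 2.0, "not_retina_prevalent"),  # strict inequalities
            (5.0, 4.0, 1.0, "low_expression"),  # floor is inclusive
            (-1.0, 0.5, 8.0, "not_retina_prevalent"),
        ],
    )
    def test_rule_table(self, z, ratio, ntpm, expected):
        score = SpecificityScore(z_retina=z, ratio_retina=ratio, ntpm_retina=ntpm)
        assert bulk.classify_bulk(score) == expected

    def test_absent_gene_is_no_data(self):
        assert bulk.classify_bulk(None, in_dataset=False) == "no_data"

    def test_partition_is_exhaustive_and_exclusive(self):
        # every (z, ratio, ntpm) combination lands in exactly one category
        for z in (-5.0, 0.0, 3.0, 5.0, np.inf):
            for ratio in (0.0, 1.0, 3.0, 5.0, np.inf):
                for ntpm in (0.0, 1.0, 2.0):
                    cat = bulk.classify_bulk(SpecificityScore(z, ratio, ntpm))
                    assert cat in bulk.BULK_CATEGORIES

    @given(
        c=st.floats(min_value=0.01, max_value=100),
        retina=st.floats(min_value=1.1, max_value=1000),
        others=st.lists(
            st.floats(min_value=1.1, max_value=1000), min_size=12, max_size=12
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, tissue_scheme, c, retina, others):
        """Multiplying all groups by c > 0 leaves z and ratio unchanged; while
        all values stay above the floor the category is unchanged too."""
        # a nearly-constant background makes sd cancel catastrophically; the
        # invariance holds mathematically but not in float64 there
        assume(np.std(others) == 0 or np.std(others) > 1e-6 * np.mean(others))
        row = grouped_row(tissue_scheme, retina, others)
        base = bulk.retina_scores(row, tissue_scheme)
        scaled = bulk.retina_scores(row * c, tissue_scheme)
        assert scaled.z_retina == pytest.approx(base.z_retina, rel=1e-6, abs=1e-9)
        assert scaled.ratio_retina == pytest.approx(base.ratio_retina, rel=1e-9)
        if min(retina, min(others)) * min(1, c) > 1:
            assert bulk.classify_bulk(scaled) == bulk.classify_bulk(base)


class TestBruteForceAgreement:
    def test_independent_arithmetic_path_on_random_genes(self, tissue_scheme):
        """Vectorized pipeline scores agree with a per-gene brute-force
        re-computation using plain Python arithmetic on 1,000 random genes."""
        rng = np.random.default_rng(42)
        samples = tissue_scheme.sample_names
        frame = pd.DataFrame(
            rng.gamma(shape=1.5, scale=4.0, size=(1000, len(samples))),
            index=[f"R{i:04d}" for i in range(1000)],
            columns=samples,
        )
        matrix = ExpressionMatrix(frame)
        scores = bulk.score_genes(matrix, tissue_scheme)

        group_samples = {g: tissue_scheme.samples_of(g) for g in tissue_scheme.group_names}
        for gene in matrix.gene_ids:
            row = frame.loc[gene]
            means = {g: sum(row[s] for s in ss) / len(ss) for g, ss in group_samples.items()}
            v = means["retina"]
            others = [means[g] for g in tissue_scheme.group_names if g != "retina"]
            m = sum(others) / 12
            sd = math.sqrt(sum((x - m) ** 2 for x in others) / 11)
            z = (v - m) / sd
            ratio = v / max(others)
            expect = ("low_expression" if v <= 1
                      else "retina_prevalent" if z > 3 and ratio > 3
                      else "not_retina_prevalent")
            assert scores.loc[gene, "z_retina"] == pytest.approx(z, rel=1e-9)
            assert scores.loc[gene, "ratio_retina"] == pytest.approx(ratio, rel=1e-9)
            assert scores.loc[gene, "category"] == expect


class TestParameterRecovery:
    def test_zero_noise_recovers_exactly_planted_set(self, tissue_scheme):
        planted = frozenset(range(50))
        spec = simulate.BulkSimSpec(
            n_genes=1000, planted_prevalent=planted, fold_change=10,
            baseline_level=5, noise_cv=0, low_expression_fraction=0.1, seed=1,
        )
        matrix, _ = simulate.generate_bulk_matrix(spec, tissue_scheme)
        scores = bulk.score_genes(matrix, tissue_scheme)
        called = {g for g, row in scores.iterrows() if row.category == "retina_prevalent"}
        assert called == {f"G{i:05d}" for i in planted}

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_noisy_recovery_at_least_95_percent(self, tissue_scheme, seed):
        planted = frozenset(range(50))
        spec = simulate.BulkSimSpec(
            n_genes=1000, planted_prevalent=planted, fold_change=10,
            baseline_level=5, noise_cv=0.1, low_expression_fraction=0.1, seed=seed,
        )
        matrix, _ = simulate.generate_bulk_matrix(spec, tissue_scheme)
        scores = bulk.score_genes(matrix, tissue_scheme)
        planted_ids = {f"G{i:05d}" for i in planted}
        called = {g for g, row in scores.iterrows() if row.category == "retina_prevalent"}
        recovery = len(called & planted_ids) / len(planted_ids)
        assert recovery >= 0.95


class TestThresholdMonotonicity:
    def test_relaxing_z_never_shrinks_prevalent_set(self, tissue_scheme):
        spec = simulate.BulkSimSpec(
            n_genes=300, planted_prevalent=frozenset(range(20)), fold_change=4,
            noise_cv=0.3, seed=8,
        )
        matrix, _ = simulate.generate_bulk_matrix(spec, tissue_scheme)
        strict = bulk.score_genes(matrix, tissue_scheme,
                                  thresholds=SpecificityThresholds(z=3))
        relaxed = bulk.score_genes(matrix, tissue_scheme,
                                   thresholds=SpecificityThresholds(z=2))
        s = set(strict.index[strict.category == "retina_prevalent"])
        r = set(relaxed.index[relaxed.category == "retina_prevalent"])
        assert s <= r
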