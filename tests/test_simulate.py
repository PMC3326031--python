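"""Synthetic cohort generators: determinism, marginals, band round-trips."""

import numpy as np
import pytest

from snprank import (
    Rank,
    SimulationConfig,
    Tool,
    deleterious_calls,
    generate_alignment_fixture,
    generate_cohort,
    generate_exact_margin_cohort,
    generate_validation_labels,
    simulate_rank_count_means,
    summarize_cohort,
)
from snprank.errors import ConfigError
from snprank.model import ValidationStatus


class TestConfig:
    def test_defaults_are_the_study_conditions(self):
        config = SimulationConfig()
        assert config.n_variants == 168
        assert config.p_deleterious == (0.25, 0.696, 0.678)
        assert config.p_validated_given_deleterious["sift"] == pytest.approx(26 / 42)
        assert config.p_validated_given_deleterious["polyphen"] == pytest.approx(79 / 117)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_variants": 0},
            {"p_deleterious": (0.5, 1.2, 0.5)},
            {"dependence": "copula"},
            {"dependence_strength": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)


class TestGenerateCohort:
    def test_fixed_seed_is_deterministic(self):
        a = generate_cohort(SimulationConfig(seed=5))
        b = generate_cohort(SimulationConfig(seed=5))
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_cohort(SimulationConfig(seed=5))
        b = generate_cohort(SimulationConfig(seed=6))
        assert a != b

    def test_degenerate_probabilities_give_all_rank_one(self):
        cohort = generate_cohort(SimulationConfig(n_variants=20, p_deleterious=(1, 1, 1)))
        summary = summarize_cohort(cohort)
        assert summary.rank_counts[Rank.I] == 20

    def test_scores_round_trip_to_intended_calls(self):
        """Scores drawn within a call's band must categorize back to the call."""
        config = SimulationConfig(n_variants=500, seed=9)
        cohort = generate_cohort(config)
        calls = np.array([deleterious_calls(av.scores) for av in cohort], dtype=bool)
        # marginals within 3 binomial standard errors of the configured p
        for j, p in enumerate(config.p_deleterious):
            se = np.sqrt(p * (1 - p) / len(cohort))
            assert abs(calls[:, j].mean() - p) <= 3 * se

    def test_latent_shared_full_strength_with_equal_marginals_is_comonotone(self):
        config = SimulationConfig(
            n_variants=300,
            p_deleterious=(0.4, 0.4, 0.4),
            dependence="latent_shared",
            dependence_strength=1.0,
            seed=4,
        )
        cohort = generate_cohort(config)
        for av in cohort:
            calls = deleterious_calls(av.scores)
            assert len(set(calls)) == 1  # all three calls identical per variant

    def test_latent_shared_raises_agreement_over_independence(self):
        kwargs = dict(n_variants=2000, p_deleterious=(0.5, 0.5, 0.5), seed=8)
        def agreement(dependence, strength):
            cohort = generate_cohort(
                SimulationConfig(dependence=dependence, dependence_strength=strength,
                                 **kwargs)
            )
            calls = np.array([deleterious_calls(av.scores) for av in cohort], dtype=bool)
            return np.mean(calls[:, 0] == calls[:, 1])
        assert agreement("latent_shared", 0.8) > agreement("independent", 0.0) + 0.1


class TestExactMargins:
    def test_counts_are_exact(self, margin_cohort):
        summary = summarize_cohort(margin_cohort)
        assert summary.tool_counts[Tool.SIFT]["deleterious"] == 42
        assert summary.tool_percent(Tool.SIFT)[0] == 25.0

    def test_zero_margins_give_all_rank_four(self):
        cohort = generate_exact_margin_cohort(10, (0, 0, 0), seed=1)
        summary = summarize_cohort(cohort)
        assert summary.rank_counts[Rank.IV] == 10

    def test_repeated_runs_reproduce_rank_multiset(self):
        a = summarize_cohort(generate_exact_margin_cohort(4, (2, 2, 2), seed=3))
        b = summarize_cohort(generate_exact_margin_cohort(4, (2, 2, 2), seed=3))
        assert a.rank_counts == b.rank_counts

    def test_count_above_n_rejected(self):
        with pytest.raises(ConfigError):
            generate_exact_margin_cohort(10, (11, 0, 0))


class TestValidationLabels:
    def test_certain_validation_gives_full_concordance(self, margin_cohort):
        config = SimulationConfig(p_validated_given_deleterious={"sift": 1.0}, seed=2)
        labelled = generate_validation_labels(margin_cohort, config, tool="sift")
        validated = [
            av for av in labelled
            if av.variant.validation_status is ValidationStatus.VALIDATED
        ]
        assert len(validated) == 42
        assert all(deleterious_calls(av.scores)[0] for av in validated)

    def test_impossible_validation_gives_none(self, margin_cohort):
        config = SimulationConfig(p_validated_given_deleterious={"sift": 0.0}, seed=2)
        labelled = generate_validation_labels(margin_cohort, config, tool="sift")
        assert not any(
            av.variant.validation_status is ValidationStatus.VALIDATED for av in labelled
        )

    def test_mean_concordance_approaches_configured_rate(self):
        # binomial mean: over repeated cohorts the validated share of the 42
        # SIFT-deleterious variants converges to 26/42 -> 61.9%
        config = SimulationConfig(seed=0)
        total = validated = 0
        for seed in range(40):
            cohort = generate_exact_margin_cohort(168, (42, 117, 114), seed=seed)
            labelled = generate_validation_labels(
                cohort, SimulationConfig(seed=seed), tool="sift"
            )
            for av in labelled:
                if deleterious_calls(av.scores)[0]:
                    total += 1
                    validated += (
                        av.variant.validation_status is ValidationStatus.VALIDATED
                    )
        p = 26 / 42
        se = np.sqrt(p * (1 - p) / total)
        assert abs(validated / total - p) <= 3 * se

    def test_unknown_tool_rejected(self, margin_cohort):
        with pytest.raises(ConfigError):
            generate_validation_labels(margin_cohort, SimulationConfig(), tool="imutant")


class TestVectorizedRankMeans:
    def test_matches_closed_form_product_of_marginals(self):
        config = SimulationConfig(seed=1)
        means = simulate_rank_count_means(config, 2000)
        p1, p2, p3 = config.p_deleterious
        n = config.n_variants
        assert means[Rank.I] == pytest.approx(n * p1 * p2 * p3, abs=0.5)
        assert means[Rank.IV] == pytest.approx(n * (1 - p1) * (1 - p2) * (1 - p3), abs=0.5)
        assert sum(means.values()) == pytest.approx(n)

    def test_agrees_with_object_path(self):
        """The batched indicator simulation and generate_cohort+summarize
        agree in distribution (same marginals, same rank rule)."""
        config = SimulationConfig(n_variants=400, seed=21)
        means = simulate_rank_count_means(config, 500)
        per_cohort = []
        for seed in range(30):
            summary = summarize_cohort(
                generate_cohort(SimulationConfig(n_variants=400, seed=seed))
            )
            per_cohort.append(summary.rank_counts[Rank.I])
        # 30-cohort mean vs large-batch mean: within 4 standard errors
        se = np.std(per_cohort, ddof=1) / np.sqrt(len(per_cohort))
        assert abs(np.mean(per_cohort) - means[Rank.I]) <= 4 * se


class TestAlignmentFixture:
    def test_conserved_and_gap_columns_by_construction(self):
        from snprank import ConservationSymbol, column_conservation

        aln = generate_alignment_fixture(
            5, 40, conserved_positions={7}, gap_positions={12}, seed=6
        )
        assert column_conservation(aln, 7).symbol == ConservationSymbol.IDENTICAL
        assert column_conservation(aln, 12).symbol == ConservationSymbol.GAP

    def test_seeded_runs_identical(self):
        a = generate_alignment_fixture(4, 25, {3}, {9}, seed=1)
        b = generate_alignment_fixture(4, 25, {3}, {9}, seed=1)
        assert [str(r.seq) for r in a] == [str(r.seq) for r in b]

    def test_overlapping_position_sets_rejected(self):
        with pytest.raises(ConfigError):
            generate_alignment_fixture(4, 25, {5}, {5}, seed=1)
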