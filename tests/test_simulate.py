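"""Monte Carlo simulator: samplers, closed-form oracles, invariants."""

import numpy as np
import pytest

from burdensim import (
    BiasDistribution,
    EmpiricalDistributions,
    RemainingLifeModel,
    SimulationConfig,
    estimate_rate,
    run_first_order,
    run_second_order,
    sample_occurrence_count,
    sample_victim,
    sample_victim_count,
)

POISONING_DALY = 0.611 * 0.0082  # acute-only injury, hand-evaluated


def degenerate_dists(injury="Poisoning", cause="SIM3", age=30.0, n_injuries=1):
    """Point-mass distributions so expectations have closed forms."""
    return EmpiricalDistributions(
        injury_dist={injury: 1.0},
        cause_dist={cause: 1.0},
        ages=(age,),
        injuries_per_victim={n_injuries: 1.0},
    )


class TestConfigFile:
    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text(
            "iterations: 500\n"
            "horizon_years: 2.0\n"
            "max_victims: 3\n"
            "seed: 9\n"
            "bias_distribution: {kind: uniform, lo: 1.0, hi: 11.0}\n"
            "outer_iterations: 10\n"
        )
        from burdensim import config_from_file

        config = config_from_file(path)
        assert config.iterations == 500
        assert config.horizon_years == 2.0
        assert config.bias_distribution == BiasDistribution("uniform", 1.0, 11.0)

    def test_json_accepted(self, tmp_path):
        path = tmp_path / "run.json"
        path.write_text('{"iterations": 10, "seed": 1}')
        from burdensim import config_from_file

        config = config_from_file(path)
        assert config.iterations == 10
        assert config.max_victims == 6  # defaults fill the rest

    def test_non_mapping_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("- 1\n- 2\n")
        from burdensim import config_from_file

        with pytest.raises(ValueError):
            config_from_file(path)


class TestSamplers:
    def test_zero_rate_never_produces_occurrences(self):
        rng = np.random.default_rng(0)
        assert all(sample_occurrence_count(0.0, 1.0, rng) == 0 for _ in range(100))

    def test_poisson_mean_recovered(self):
        rng = np.random.default_rng(42)
        lam = 796.9565
        draws = [sample_occurrence_count(lam, 1.0, rng) for _ in range(10_000)]
        se = np.sqrt(lam / 10_000)
        assert abs(np.mean(draws) - lam) < 3 * se

    def test_occurrence_count_deterministic_under_seed(self):
        a = [sample_occurrence_count(5.0, 1.0, np.random.default_rng(7))
             for _ in range(10)]
        b = [sample_occurrence_count(5.0, 1.0, np.random.default_rng(7))
             for _ in range(10)]
        assert a == b

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_occurrence_count(-1.0, 1.0, np.random.default_rng(0))

    def test_victim_count_zero_bound(self):
        rng = np.random.default_rng(0)
        assert all(sample_victim_count(0, rng) == 0 for _ in range(50))

    def test_victim_count_uniform_frequencies(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_victim_count(3, rng) for _ in range(10_000)])
        se = np.sqrt(0.25 * 0.75 / 10_000)
        for value in range(4):
            assert abs(np.mean(draws == value) - 0.25) < 3 * se
        assert abs(draws.mean() - 1.5) < 3 * draws.std() / 100

    def test_negative_bound_rejected(self):
        with pytest.raises(ValueError):
            sample_victim_count(-1, np.random.default_rng(0))


class TestSampleVictim:
    def test_certain_fatality_scores_remaining_life(self, catalogue, life44):
        dists = degenerate_dists(injury="Fatal injury")
        rng = np.random.default_rng(0)
        for _ in range(20):
            victim, daly = sample_victim(dists, catalogue, life44, 4, rng)
            assert victim.fatal
            assert daly == 44.4

    def test_no_injury_scores_zero(self, catalogue, life44):
        dists = degenerate_dists(injury="No Injury")
        victim, daly = sample_victim(dists, catalogue, life44, 4,
                                     np.random.default_rng(0))
        assert daly == 0.0

    def test_with_replacement_duplicates_each_scored(self, catalogue, life44):
        dists = degenerate_dists(injury="Poisoning", n_injuries=2)
        victim, daly = sample_victim(dists, catalogue, life44, 4,
                                     np.random.default_rng(0))
        assert len(victim.injuries) == 2
        assert daly == pytest.approx(2 * POISONING_DALY)

    def test_fatal_draw_discards_other_injuries(self, catalogue, life44):
        dists = EmpiricalDistributions(
            injury_dist={"Fatal injury": 0.5, "Concussion": 0.5},
            cause_dist={"SIM3": 1.0},
            ages=(30.0,),
            injuries_per_victim={4: 1.0},
        )
        rng = np.random.default_rng(5)
        for _ in range(50):
            victim, daly = sample_victim(dists, catalogue, life44, 4, rng)
            if victim.fatal:
                assert victim.injuries == ("Fatal injury",)
                assert daly == 44.4


class TestFirstOrder:
    def test_zero_rate_gives_zero_burden(self, catalogue, life44):
        est = estimate_rate(0, 0, T=1.0)
        config = SimulationConfig(iterations=50, seed=1)
        result = run_first_order(est, degenerate_dists(), catalogue, life44, config)
        assert (result.totals() == 0).all()

    def test_mean_matches_closed_form(self, catalogue, life44):
        # E[total] = lam * T * E[victims] * E[injuries per victim] * d
        # with victims ~ U{0,1} (M = 1) so E[victims] = 1/2
        lam = 30.0
        est = estimate_rate(30, 0, T=1.0)
        config = SimulationConfig(iterations=4000, seed=3, max_victims=1,
                                  max_injuries_per_victim=1)
        result = run_first_order(est, degenerate_dists(), catalogue, life44, config)
        totals = result.totals()
        expected = lam * 1.0 * 0.5 * 1 * POISONING_DALY
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - expected) < 3 * se

    def test_single_cause_receives_all_burden(self, catalogue, life44):
        est = estimate_rate(20, 0, T=1.0)
        config = SimulationConfig(iterations=200, seed=2, max_victims=2)
        result = run_first_order(est, degenerate_dists(cause="SIM2"),
                                 catalogue, life44, config)
        for it in result.iterations:
            assert it.dalys_by_cause["SIM2"] == it.total_dalys
            assert it.dalys_by_cause["SIM1"] == 0.0

    def test_cause_bucket_conservation_exact(self, catalogue, life44):
        est = estimate_rate(50, 10, T=1.0)
        config = SimulationConfig(iterations=300, seed=4, max_victims=3)
        dists = EmpiricalDistributions(
            injury_dist={"Poisoning": 0.4, "Concussion": 0.3, "Fatal injury": 0.05,
                         "Sprained or twisted": 0.25},
            cause_dist={"SIM1": 0.1, "SIM2": 0.3, "SIM3": 0.4, "RCNE": 0.2},
            ages=(10.0, 30.0, 60.0),
            injuries_per_victim={1: 0.7, 2: 0.2, 3: 0.1},
        )
        result = run_first_order(est, dists, catalogue, life44, config)
        for it in result.iterations:
            assert sum(it.dalys_by_cause.values()) == it.total_dalys
            assert all(v >= 0 for v in it.dalys_by_cause.values())

    def test_bit_identical_rerun_under_fixed_seed(self, catalogue, life44):
        est = estimate_rate(40, 5, T=1.0)
        config = SimulationConfig(iterations=100, seed=11, max_victims=3)
        dists = degenerate_dists()
        a = run_first_order(est, dists, catalogue, life44, config)
        b = run_first_order(est, dists, catalogue, life44, config)
        assert a.iterations == b.iterations

    def test_different_seeds_differ(self, catalogue, life44):
        est = estimate_rate(40, 5, T=1.0)
        dists = degenerate_dists()
        a = run_first_order(est, dists, catalogue, life44,
                            SimulationConfig(iterations=50, seed=1))
        b = run_first_order(est, dists, catalogue, life44,
                            SimulationConfig(iterations=50, seed=2))
        assert not np.array_equal(a.totals(), b.totals())

    def test_mean_burden_monotone_in_rate_victims_horizon(self, catalogue, life44):
        dists = degenerate_dists()

        def mean_total(lam, M, horizon):
            est = estimate_rate(int(lam), 0, T=1.0)
            config = SimulationConfig(iterations=3000, seed=9, max_victims=M,
                                      horizon_years=horizon,
                                      max_injuries_per_victim=1)
            return run_first_order(est, dists, catalogue, life44, config).totals().mean()

        by_lam = [mean_total(lam, 1, 1.0) for lam in (20, 40, 80)]
        assert by_lam == sorted(by_lam)
        by_m = [mean_total(40, M, 1.0) for M in (1, 3, 6)]
        assert by_m == sorted(by_m)
        by_h = [mean_total(40, 1, h) for h in (0.5, 1.0, 2.0)]
        assert by_h == sorted(by_h)


class TestSecondOrder:
    def test_point_mass_reduces_to_first_order(self, catalogue, life44):
        est = estimate_rate(40, 10, T=2.0)
        dists = degenerate_dists()
        config = SimulationConfig(iterations=80, seed=6, max_victims=2,
                                  bias_distribution=BiasDistribution("point", 1.0),
                                  outer_iterations=1)
        first = run_first_order(est, dists, catalogue, life44, config)
        second = run_second_order(est, dists, catalogue, life44, config)
        assert first.iterations == second.iterations

    def test_uniform_bias_scales_mean_linearly(self, catalogue, life44):
        # E[total | bias] is linear in bias, so the pooled mean over a
        # uniform bias on [1, 11] is E[bias] = 6 times the bias-1 mean.
        est = estimate_rate(30, 0, T=1.0)
        dists = degenerate_dists()
        config = SimulationConfig(
            iterations=150, seed=8, max_victims=1, max_injuries_per_victim=1,
            bias_distribution=BiasDistribution("uniform", 1.0, 11.0),
            outer_iterations=60,
        )
        result = run_second_order(est, dists, catalogue, life44, config)
        totals = result.totals()
        outer_means = totals.reshape(60, 150).mean(axis=1)
        expected = 6.0 * 30.0 * 0.5 * POISONING_DALY
        se = outer_means.std(ddof=1) / np.sqrt(len(outer_means))
        assert abs(outer_means.mean() - expected) < 3 * se

    def test_single_outer_draw_length(self, catalogue, life44):
        est = estimate_rate(10, 0, T=1.0)
        config = SimulationConfig(iterations=25, seed=3, outer_iterations=1)
        result = run_second_order(est, degenerate_dists(), catalogue, life44, config)
        assert len(result.iterations) == 25

    def test_outer_index_recorded(self, catalogue, life44):
        est = estimate_rate(10, 0, T=1.0)
        config = SimulationConfig(
            iterations=5, seed=3, outer_iterations=3,
            bias_distribution=BiasDistribution("uniform", 1.0, 5.0),
        )
        result = run_second_order(est, degenerate_dists(), catalogue, life44, config)
        assert [it.outer_index for it in result.iterations] == [0] * 5 + [1] * 5 + [2] * 5

    def test_invalid_bias_bounds_rejected(self):
        with pytest.raises(ValueError):
            BiasDistribution("uniform", 2.0, 1.0)
        with pytest.raises(ValueError):
            BiasDistribution("point", 0.5)
        with pytest.raises(ValueError):
            BiasDistribution("triangular", 1.0, 3.0, mode=5.0)
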