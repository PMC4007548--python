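"""Coalescent simulator: calibration, determinism, demography, balanced mode."""

import numpy as np
import pytest
from scipy import stats as sps

from balsel import sumstats
from balsel.coalsim import (
    DemographicModel,
    Event,
    Population,
    SimConfig,
    SimulationError,
    calibrated_human_3pop,
    null_distribution,
    simulate,
    simulate_balanced,
)
from balsel.haplotypes import write_ms


class TestNeutralCalibration:
    def test_pair_coalescence_time_is_2n(self):
        N = 5000
        cfg = SimConfig(n=[2], L=1000, theta=1.0, seed=11, iterations=3000)
        reps = simulate(cfg, DemographicModel.constant(N))
        t = np.array([r.tmrca_gens for r in reps])
        se = t.std(ddof=1) / np.sqrt(len(t))
        assert abs(t.mean() - 2 * N) < 3 * se

    def test_segregating_sites_match_watterson_expectation(self):
        theta = 5.0
        cfg = SimConfig(n=[10], L=5000, theta=theta, seed=12, iterations=2000)
        reps = simulate(cfg, DemographicModel.constant(10000))
        S = np.array([r.alignment.n_sites for r in reps])
        expect = theta * sumstats.harmonic(9)
        se = S.std(ddof=1) / np.sqrt(len(S))
        assert abs(S.mean() - expect) < 3 * se

    def test_tmrca_expectation_general_n(self):
        N = 8000
        cfg = SimConfig(n=[12], L=1000, theta=1.0, seed=13, iterations=2000)
        reps = simulate(cfg, DemographicModel.constant(N))
        t = np.array([r.tmrca_gens for r in reps])
        expect = 4 * N * (1 - 1 / 12)
        se = t.std(ddof=1) / np.sqrt(len(t))
        assert abs(t.mean() - expect) < 3 * se

    def test_site_positions_uniform(self):
        cfg = SimConfig(n=[8], L=10_000, theta=10.0, seed=14, iterations=200)
        reps = simulate(cfg, DemographicModel.constant(10000))
        pooled = np.concatenate(
            [r.alignment.positions / r.alignment.l_physical for r in reps]
        )
        assert sps.kstest(pooled, "uniform").pvalue > 0.01

    def test_pi_expectation_per_locus(self):
        theta = 4.0
        cfg = SimConfig(n=[10], L=2000, theta=theta, seed=15, iterations=2000)
        reps = simulate(cfg, DemographicModel.constant(10000))
        pi = np.array(
            [
                sumstats.nucleotide_diversity(r.alignment) * r.alignment.l_physical
                for r in reps
            ]
        )
        se = pi.std(ddof=1) / np.sqrt(len(pi))
        assert abs(pi.mean() - theta) < 3 * se


class TestDeterminism:
    def test_same_seed_byte_identical_ms(self):
        cfg = SimConfig(n=[10], L=5000, theta=5.0, seed=99, iterations=5)
        model = DemographicModel.constant(10000)
        a = write_ms([r.alignment for r in simulate(cfg, model)])
        b = write_ms([r.alignment for r in simulate(cfg, model)])
        assert a == b

    def test_different_seeds_differ(self):
        model = DemographicModel.constant(10000)
        a = simulate(SimConfig(n=[10], L=5000, theta=5.0, seed=1), model)
        b = simulate(SimConfig(n=[10], L=5000, theta=5.0, seed=2), model)
        assert not np.array_equal(a[0].alignment.positions, b[0].alignment.positions)


class TestRecombination:
    def test_mean_s_unchanged_by_recombination(self):
        # E(S) depends on theta only; recombination reduces its variance
        model = DemographicModel.constant(10000)
        cfg0 = SimConfig(n=[10], L=5000, theta=5.0, rho=0.0, seed=21, iterations=600)
        cfg5 = SimConfig(n=[10], L=5000, theta=5.0, rho=10.0, seed=22, iterations=600)
        S0 = np.array([r.alignment.n_sites for r in simulate(cfg0, model)])
        S5 = np.array([r.alignment.n_sites for r in simulate(cfg5, model)])
        se = np.sqrt(S0.var() / len(S0) + S5.var() / len(S5))
        assert abs(S0.mean() - S5.mean()) < 3 * se
        assert S5.var(ddof=1) < S0.var(ddof=1)


class TestDemography:
    def test_split_model_coalesces(self):
        model = DemographicModel(
            populations=[Population("A", 10000), Population("B", 10000)],
            events=[Event(time=4000, kind="split", pop=1, dest=0)],
        )
        reps = simulate(SimConfig(n=[5, 5], L=1000, theta=2.0, seed=31, iterations=50), model)
        assert all(r.tmrca_gens > 4000 for r in reps)

    def test_isolated_populations_error(self):
        model = DemographicModel(
            populations=[Population("A", 1000), Population("B", 1000)]
        )
        with pytest.raises(SimulationError, match="isolated"):
            simulate(SimConfig(n=[2, 2], L=1000, theta=1.0, seed=32), model)

    def test_bottleneck_shortens_trees(self):
        base = DemographicModel.constant(10000)
        bott = DemographicModel(
            populations=[Population("A", 10000)],
            events=[Event(time=100, kind="bottleneck", pop=0, strength=0.9)],
        )
        t_base = np.mean(
            [r.tmrca_gens for r in simulate(
                SimConfig(n=[10], L=1000, theta=1.0, seed=33, iterations=300), base)]
        )
        t_bott = np.mean(
            [r.tmrca_gens for r in simulate(
                SimConfig(n=[10], L=1000, theta=1.0, seed=34, iterations=300), bott)]
        )
        assert t_bott < 0.5 * t_base

    def test_calibrated_preset_structure(self):
        model = calibrated_human_3pop()
        assert [p.name for p in model.populations] == ["YRI", "CEU", "AS"]
        kinds = [e.kind for e in model.events]
        assert kinds.count("split") == 2
        assert kinds.count("bottleneck") == 4
        reps = simulate(
            SimConfig(n=[6, 6, 6], L=2000, theta=3.0, seed=35, iterations=20), model
        )
        assert all(r.tmrca_gens > 3500 for r in reps)  # all splits predate MRCA


class TestBalancedMode:
    model = DemographicModel.constant(18000)

    def test_root_at_least_allele_age(self):
        cfg = SimConfig(
            n=[40], L=4867, theta=8.0, seed=41, iterations=50,
            mode="balanced", balanced_age=160_000,
        )
        reps = simulate_balanced(cfg, self.model)
        t = np.array([r.tmrca_gens for r in reps])
        assert t.mean() >= 160_000
        assert all(r.focal_index is not None for r in reps)
        # focal column holds the allelic classes at the equilibrium frequency
        col = reps[0].alignment.H[:, reps[0].focal_index]
        assert col.sum() == 20

    def test_tajimas_d_exceeds_neutral(self):
        cfg_b = SimConfig(
            n=[40], L=4867, theta=8.0, seed=42, iterations=300,
            mode="balanced", balanced_age=160_000,
        )
        cfg_n = SimConfig(n=[40], L=4867, theta=8.0, seed=43, iterations=300)
        d_b = [sumstats.tajimas_d(r.alignment) for r in simulate_balanced(cfg_b, self.model)]
        d_n = [
            sumstats.tajimas_d(r.alignment)
            for r in simulate(cfg_n, self.model)
            if r.alignment.n_sites > 0
        ]
        assert np.mean(d_b) > np.mean(d_n)
        assert sps.mannwhitneyu(d_b, d_n, alternative="greater").pvalue < 0.01

    def test_fast_switching_limit_is_neutral(self):
        # switching far faster than coalescence erases the class structure
        cfg_b = SimConfig(
            n=[20], L=2000, theta=5.0, seed=44, iterations=300,
            mode="balanced", balanced_age=500_000, balanced_switch_rate=0.01,
        )
        cfg_n = SimConfig(n=[20], L=2000, theta=5.0, seed=45, iterations=300)
        d_b = [
            sumstats.tajimas_d(r.alignment)
            for r in simulate_balanced(cfg_b, self.model)
            if r.alignment.n_sites > 1
        ]
        d_n = [
            sumstats.tajimas_d(r.alignment)
            for r in simulate(cfg_n, self.model)
            if r.alignment.n_sites > 1
        ]
        assert sps.ks_2samp(d_b, d_n).pvalue > 0.01

    def test_allele_age_must_predate_splits(self):
        model = DemographicModel(
            populations=[Population("A", 10000), Population("B", 10000)],
            events=[Event(time=50_000, kind="split", pop=1, dest=0)],
        )
        cfg = SimConfig(
            n=[4, 4], L=1000, theta=1.0, seed=46,
            mode="balanced", balanced_age=10_000,
        )
        with pytest.raises(SimulationError, match="predate"):
            simulate_balanced(cfg, model)


class TestNullDistribution:
    model = DemographicModel.constant(10000)

    def test_zero_theta_rejected(self):
        cfg = SimConfig(n=[10], L=1000, theta=0.0, seed=51)
        with pytest.raises(SimulationError):
            null_distribution("tajimas_d", cfg, self.model, 10)

    def test_panel_size_and_redraw_of_undefined(self):
        # theta small enough that S=0 replicates occur and must be redrawn
        cfg = SimConfig(n=[10], L=1000, theta=0.5, seed=52)
        panel = null_distribution("tajimas_d", cfg, self.model, 200)
        assert len(panel) == 200
        assert np.all(np.isfinite(panel.values))

    def test_neutral_d_brackets_zero(self):
        cfg = SimConfig(n=[40], L=5000, theta=10.0, seed=53)
        panel = null_distribution("tajimas_d", cfg, self.model, 500)
        lo, hi = np.percentile(panel.values, [2.5, 97.5])
        assert lo < 0 < hi


class TestCrossValidation:
    def test_summary_distributions_match_established_simulator(self):
        """S distribution agrees with an independent coalescent simulator."""
        msprime = pytest.importorskip("msprime")
        n, theta, reps = 10, 5.0, 400
        cfg = SimConfig(n=[n], L=1000, theta=theta, seed=61, iterations=reps)
        mine = np.array(
            [r.alignment.n_sites for r in simulate(cfg, DemographicModel.constant(10000))]
        )
        other = []
        N = 10000
        # ploidy=2 with n/2 individuals gives n genomes on the 2N timescale
        for ts in msprime.sim_ancestry(
            samples=n // 2, ploidy=2, population_size=N, sequence_length=1,
            num_replicates=reps, random_seed=61,
        ):
            mts = msprime.sim_mutations(
                ts,
                rate=theta / (4 * N),
                random_seed=1000 + len(other),
                discrete_genome=False,
            )
            other.append(mts.num_sites)
        assert sps.ks_2samp(mine, np.array(other)).pvalue > 0.01
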