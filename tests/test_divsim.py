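"""Coalescent simulator: analytic moments, model collapse, misorientation,
and a cross-check against msprime under shared parameter settings."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from carotscan import divsim, sumstats
from carotscan.types import DivergenceModelParams, OrientedAlignment, SimConfig


class TestDeterminismAndDegeneracies:
    def test_seeded_determinism(self, single_pop_params, seq_config):
        a = divsim.simulate_sequence_tables(single_pop_params, seq_config,
                                            np.random.default_rng(42))
        b = divsim.simulate_sequence_tables(single_pop_params, seq_config,
                                            np.random.default_rng(42))
        assert np.array_equal(a.genotypes, b.genotypes)

    def test_zero_mutation_rate_monomorphic(self, seq_config, rng):
        params = DivergenceModelParams(N_W=100, N_E=100, N_A=100, T_d=10, mu_seq=0.0)
        sim = divsim.simulate_sequence_tables(params, seq_config, rng)
        assert sim.genotypes.shape[0] == 0
        aln, truth = divsim.simulate_sequence_locus(params, seq_config, rng)
        assert len(set(aln.sequences.values())) == 1

    def test_full_alignment_matches_tables_stats(self, rng):
        """The FASTA-materialised locus and the compact tables give the same S."""
        params = DivergenceModelParams(N_W=500, N_E=500, N_A=500, T_d=100, mu_seq=2e-6)
        cfg = SimConfig(n_west=8, n_east=8, length=2000)
        aln, truth = divsim.simulate_sequence_locus(params, cfg, rng)
        st = sumstats.basic_seq_stats(aln)
        assert st.S == truth.derived_counts.size


class TestWattersonExpectation:
    def test_single_population_segregating_sites(self):
        """One panmictic population, n = 10, theta = 5: mean S within 3 SE of
        theta * sum_{i<10} 1/i ~ 14.14 over 5000 replicates."""
        rng = np.random.default_rng(101)
        params = DivergenceModelParams(N_W=1000, N_E=1000, N_A=1000, T_d=0.0,
                                       mu_seq=1.25e-6)   # 4*N*mu*L = 5
        cfg = SimConfig(n_west=5, n_east=5, length=1000)
        s = [divsim.simulate_sequence_tables(params, cfg, rng).genotypes.shape[0]
             for _ in range(5000)]
        expect = 5.0 * sum(1.0 / i for i in range(1, 10))
        se = np.std(s) / math.sqrt(len(s))
        assert abs(np.mean(s) - expect) < 3 * se


class TestModelCollapse:
    def test_td_zero_equals_single_population(self):
        """Two populations at T_d = 0 with equal sizes are indistinguishable
        from one population (KS test on S, p > 0.01, 2000 reps each)."""
        rng = np.random.default_rng(202)
        two_pop = DivergenceModelParams(N_W=800, N_E=800, N_A=800, T_d=0.0,
                                        mu_seq=1.5e-6)
        cfg = SimConfig(n_west=5, n_east=5, length=1000)
        s_two = [divsim.simulate_sequence_tables(two_pop, cfg, rng).genotypes.shape[0]
                 for _ in range(2000)]
        # same model expressed as one ancestral population only
        one_pop_epochs = [(np.inf, {"A": 800.0}, {"W": "A", "E": "A"})]
        s_one = [divsim.simulate_sequence_tables(
            two_pop, cfg, rng, epochs=one_pop_epochs).genotypes.shape[0]
            for _ in range(2000)]
        assert sps.ks_2samp(s_two, s_one).pvalue > 0.01


class TestFstMonotonicity:
    def test_fst_increases_with_divergence_time(self):
        rng = np.random.default_rng(303)
        cfg = SimConfig(n_west=10, n_east=10, length=1000)
        means = []
        for td in (0.0, 500.0, 5000.0):
            params = DivergenceModelParams(N_W=1000, N_E=1000, N_A=1000, T_d=td,
                                           mu_seq=2.5e-6)
            vals = []
            for _ in range(500):
                sim = divsim.simulate_sequence_tables(params, cfg, rng)
                idx_w = np.where(sim.west)[0]
                idx_e = np.where(~sim.west)[0]
                cw = sim.genotypes[:, idx_w].sum(axis=1)
                ce = sim.genotypes[:, idx_e].sum(axis=1)
                f = sumstats.hudson_fst_from_site_counts(cw, ce, 10, 10)
                if np.isfinite(f):
                    vals.append(f)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestMicrosatGSM:
    def test_p_zero_means_unit_steps(self, rng):
        """With P_SSR = 0 every mutation moves exactly one repeat; allele
        parities then match the parity of the mutation-count path."""
        params = DivergenceModelParams(N_W=200, N_E=200, N_A=200, T_d=0,
                                       mu_seq=0, mu_ssr=5e-4, p_ssr=0.0)
        cfg = SimConfig(n_west=10, n_east=10, length=1, ploidy=2)
        # direct check on the step generator: geometric(1-0) degenerates to 1
        steps = rng.geometric(1.0, size=1000)
        assert (steps == 1).all()
        vals = divsim.simulate_microsat_values(params, cfg, (5, 60), rng)
        assert ((vals >= 5) & (vals <= 60)).all()

    def test_zero_rate_founder_allele(self, rng):
        params = DivergenceModelParams(N_W=200, N_E=200, N_A=200, T_d=0,
                                       mu_seq=0, mu_ssr=0.0, p_ssr=0.0)
        cfg = SimConfig(n_west=10, n_east=10, length=1, ploidy=2)
        vals = divsim.simulate_microsat_values(params, cfg, (10, 30), rng)
        assert (vals == 20).all()

    def test_smm_allele_size_variance(self):
        """Single population SMM far from range boundaries: the expected
        squared allele-size difference of a random pair is mu * E[pairwise
        branch length] = 4 N mu (unit steps, E[step^2] = 1)."""
        rng = np.random.default_rng(404)
        N = 200
        mu = 2.5e-4
        params = DivergenceModelParams(N_W=N, N_E=N, N_A=N, T_d=0,
                                       mu_seq=0, mu_ssr=mu, p_ssr=0.0)
        cfg = SimConfig(n_west=1, n_east=1, length=1, ploidy=2)
        theta = 4 * N * mu     # 0.2, keeps the walk inside a wide range
        sq = []
        for _ in range(4000):
            vals = divsim.simulate_microsat_values(params, cfg, (0, 2000), rng)
            sq.append((vals[0] - vals[1]) ** 2)
        se = np.std(sq) / math.sqrt(len(sq))
        assert abs(np.mean(sq) - theta) < 3 * se

    def test_reflection_into_range(self):
        vals = divsim.reflect_into_range(np.array([-3, 5, 12, 25, 40]), 10, 30)
        assert ((vals >= 10) & (vals <= 30)).all()
        assert divsim.reflect_into_range(np.array([31]), 10, 30)[0] == 29
        with pytest.raises(ValueError):
            divsim.reflect_into_range(np.array([5]), 10, 10)


class TestMisorientation:
    def test_zero_rate_identity(self, single_pop_params, seq_config, rng):
        sim = divsim.simulate_sequence_tables(single_pop_params, seq_config, rng)
        out = divsim.apply_misorientation_result(sim, 0.0, rng)
        dc0, n = sim.derived_counts()
        dc1, _ = out.derived_counts()
        assert np.array_equal(dc0, dc1)

    def test_full_rate_mirrors_sfs(self, single_pop_params, seq_config, rng):
        sim = divsim.simulate_sequence_tables(single_pop_params, seq_config, rng)
        out = divsim.apply_misorientation_result(sim, 1.0, rng)
        dc0, n = sim.derived_counts()
        dc1, _ = out.derived_counts()
        assert np.array_equal(np.sort(n - dc0), np.sort(dc1))

    def test_flip_fraction_binomial(self, rng):
        oriented = OrientedAlignment(n=10, derived_counts=np.full(10_000, 3))
        out = divsim.apply_misorientation(oriented, 0.1, rng)
        flipped = int((out.derived_counts == 7).sum())
        se = math.sqrt(0.1 * 0.9 * 10_000)
        assert abs(flipped - 1000) < 3 * se


class TestMsprimeCrossCheck:
    """Agreement with an established coalescent simulator on E[S], E[pi],
    E[FST] under the shared divergence-model parameterisation."""

    @pytest.fixture(scope="class")
    def shared(self):
        return dict(N=1000.0, T_d=1500.0, mu=2.5e-6, n_per=10, L=1000, reps=600)

    def _own_moments(self, shared):
        rng = np.random.default_rng(77)
        params = DivergenceModelParams(N_W=shared["N"], N_E=shared["N"],
                                       N_A=shared["N"], T_d=shared["T_d"],
                                       mu_seq=shared["mu"])
        cfg = SimConfig(n_west=shared["n_per"], n_east=shared["n_per"],
                        length=shared["L"])
        S, PI, F = [], [], []
        for _ in range(shared["reps"]):
            sim = divsim.simulate_sequence_tables(params, cfg, rng)
            dc, n = sim.derived_counts()
            S.append(dc.size)
            PI.append(sumstats.pi_from_counts(dc, n))
            idx_w = np.where(sim.west)[0]
            idx_e = np.where(~sim.west)[0]
            cw = sim.genotypes[:, idx_w].sum(axis=1)
            ce = sim.genotypes[:, idx_e].sum(axis=1)
            f = sumstats.hudson_fst_from_site_counts(cw, ce, len(idx_w), len(idx_e))
            if np.isfinite(f):
                F.append(f)
        return S, PI, F

    def _msprime_moments(self, shared):
        import msprime
        demography = msprime.Demography()
        # haploid msprime lineages coalesce at rate 1/initial_size; the
        # package's convention is 2N gene copies per diploid population of N
        demography.add_population(name="W", initial_size=2 * shared["N"])
        demography.add_population(name="E", initial_size=2 * shared["N"])
        demography.add_population(name="A", initial_size=2 * shared["N"])
        demography.add_population_split(time=shared["T_d"], derived=["W", "E"],
                                        ancestral="A")
        S, PI, F = [], [], []
        n_per = shared["n_per"]
        reps = msprime.sim_ancestry(
            samples={"W": n_per, "E": n_per}, demography=demography,
            sequence_length=shared["L"], ploidy=1, num_replicates=shared["reps"],
            random_seed=999)
        for ts in reps:
            mts = msprime.sim_mutations(ts, rate=shared["mu"], random_seed=None,
                                        model=msprime.BinaryMutationModel())
            geno = mts.genotype_matrix()
            counts = geno.sum(axis=1)
            poly = (counts > 0) & (counts < 2 * n_per)
            geno = geno[poly]
            S.append(geno.shape[0])
            PI.append(sumstats.pi_from_counts(geno.sum(axis=1), 2 * n_per))
            cw = geno[:, :n_per].sum(axis=1)
            ce = geno[:, n_per:].sum(axis=1)
            f = sumstats.hudson_fst_from_site_counts(cw, ce, n_per, n_per)
            if np.isfinite(f):
                F.append(f)
        return S, PI, F

    def test_moments_agree(self, shared):
        own = self._own_moments(shared)
        ref = self._msprime_moments(shared)
        for name, a, b in zip(("S", "pi", "FST"), own, ref):
            se = math.sqrt(np.var(a) / len(a) + np.var(b) / len(b))
            assert abs(np.mean(a) - np.mean(b)) < 3 * se, name
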