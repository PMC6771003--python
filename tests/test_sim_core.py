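"""Simulator unit tests: initialization, reproduction, IGC, conditioned
fixation, and CNV balancing, checked against minimal independent oracles."""

import numpy as np
import pytest
from scipy import stats as sps

import igcsim as ig
from igcsim import (FixationRestartError, ParameterError, PhaseSchedule,
                    SimParams, apply_igc, duplicate_and_fix, init_population,
                    introduce_cnv_and_balance, run_simulation, sample_alleles,
                    step_generation)
from igcsim.params import COPY1, COPY3, EQUAL_FRACTIONS


class TestInitAndParams:
    def test_initial_state_all_ancestral(self):
        pop = init_population(SimParams(N=100))
        assert pop.n_chrom == 200
        assert not pop.sites.any()
        assert not pop.has2.any() and not pop.has3.any()

    def test_minimal_population(self):
        assert init_population(SimParams(N=1)).n_chrom == 2

    @pytest.mark.parametrize("kw,name", [
        (dict(N=0), "N"),
        (dict(mu=-1e-3), "mu"),
        (dict(s=1.0), "s"),
        (dict(tract_len=2000), "tract_len"),
        (dict(L=100), "L"),
        (dict(igc_fractions=(1, 0, 0, 0, 0, 0.5)), "igc_fractions"),
        (dict(sel_strength=-1), "sel_strength"),
    ])
    def test_invalid_params_name_the_field(self, kw, name):
        with pytest.raises(ParameterError, match=name):
            SimParams(**kw)

    def test_phase_boundaries_must_increase(self):
        with pytest.raises(ParameterError, match="phase boundaries"):
            PhaseSchedule(5000, 3000, 16000, 26000)


class TestReproduction:
    def test_population_size_constant(self, tiny_params):
        pop = init_population(tiny_params)
        for _ in range(20):
            pop = step_generation(pop, tiny_params, "I")
            assert pop.n_chrom == 2 * tiny_params.N

    def test_same_seed_identical_after_100_generations(self, tiny_params):
        pops = []
        for _ in range(2):
            pop = init_population(tiny_params)
            for _ in range(100):
                pop = step_generation(pop, tiny_params, "I")
            pops.append(pop)
        assert np.array_equal(pops[0].state, pops[1].state)
        assert np.array_equal(pops[0].has2, pops[1].has2)

    def test_zero_rates_never_create_variation(self):
        params = SimParams(N=10, L=64, mu=0.0, R_c1=0, R_c2=0, R_c3=0,
                           R_s1=0, R_s2=0, C_total=0, tract_len=16,
                           s=0.0, seed=9)
        pop = init_population(params)
        pop.sites[0, 0, :10] = 1  # one pre-existing haplotype
        start = {r.tobytes() for r in pop.state}
        for _ in range(50):
            pop = step_generation(pop, params, "I")
        assert {r.tobytes() for r in pop.state} <= start

    def test_neutral_equilibrium_matches_bruteforce_oracle(self):
        """Single-block diversity agrees with an independent minimal
        Wright-Fisher simulator (same binary-site mutation convention)."""
        N, L, mu, burn, T, reps = 20, 200, 0.01, 500, 1500, 12
        params = SimParams(N=N, L=L, mu=mu, R_c1=0, R_c2=0, R_c3=0,
                           R_s1=0, R_s2=0, C_total=0, s=0.0, seed=50)

        def oracle_mean_pi(seed):
            rng = np.random.default_rng(seed)
            n = 2 * N
            mat = np.zeros((n, L), dtype=np.uint8)
            vals = []
            for g in range(T):
                mat = mat[rng.integers(0, n, n)]
                for _ in range(rng.poisson(n * mu)):
                    mat[rng.integers(n), rng.integers(L)] = 1
                if g >= burn and g % 10 == 0:
                    c = mat.sum(axis=0)
                    vals.append((2.0 * c * (n - c)).sum()
                                / (n * (n - 1)) / L)
            return np.mean(vals)

        def sim_mean_pi(seed):
            pop = init_population(params.replace(seed=seed))
            vals = []
            for g in range(T):
                pop = step_generation(pop, params.replace(seed=seed), "I")
                if g >= burn and g % 10 == 0:
                    vals.append(pop.block_pi()[COPY1])
            return np.mean(vals)

        a = np.array([oracle_mean_pi(100 + r) for r in range(reps)])
        b = np.array([sim_mean_pi(200 + r) for r in range(reps)])
        se = np.sqrt(a.var(ddof=1) / reps + b.var(ddof=1) / reps)
        assert abs(a.mean() - b.mean()) < 3 * se


class TestIGC:
    def test_zero_rate_is_identity(self, tiny_params):
        pop = init_population(tiny_params)
        pop.sites[:] = np.random.default_rng(0).integers(
            0, 2, pop.sites.shape).astype(np.uint8)
        pop.has2[:] = 1
        pop.has3[:] = 1
        before = pop.state.copy()
        apply_igc(pop, tiny_params.replace(C_total=0.0))
        assert np.array_equal(pop.state, before)

    def test_forced_fractions_touch_only_target_copy(self, tiny_params):
        params = tiny_params.replace(
            C_total=50.0, igc_fractions=(0, 0, 1, 0, 0, 0))  # only 1 -> 3
        pop = init_population(params)
        pop.sites[:, COPY1, :] = 1
        pop.has2[:] = 1
        pop.has3[:] = 1
        others = pop.sites[:, [1, 2, 3], :].copy()
        apply_igc(pop, params)
        assert np.array_equal(pop.sites[:, [1, 2, 3], :], others)
        assert pop.sites[:, COPY3, :].sum() > 0  # tracts did land on copy3

    def test_tract_truncates_at_block_end(self, tiny_params):
        from igcsim._kernels import convert_tract
        L = tiny_params.L
        pop = init_population(tiny_params)
        pop.sites[0, COPY1, :] = 1
        pop.has3[1] = 1
        n_copied = convert_tract(pop.state, 1, 0, COPY3, COPY1,
                                 L - 10, 100, L)
        assert n_copied == 10
        assert pop.sites[1, COPY3, :].sum() == 10
        assert pop.sites[1, COPY3, L - 10:].all()

    def test_event_with_no_carrier_is_skipped(self, tiny_params):
        params = tiny_params.replace(C_total=30.0,
                                     igc_fractions=(0, 0, 1, 0, 0, 0))
        pop = init_population(params)
        pop.has2[:] = 1  # copy3 absent everywhere
        before = pop.state.copy()
        skipped = apply_igc(pop, params)
        assert skipped > 0
        assert np.array_equal(pop.state, before)


class TestConditionedFixation:
    def test_fixed_copy_present_on_every_chromosome(self, tiny_params):
        pop = init_population(tiny_params)
        pop, restarts, gens = duplicate_and_fix(pop, tiny_params, "copy2")
        assert pop.has2.all()
        assert gens > 0 and restarts >= 0

    def test_seeded_copy_duplicates_donor_haplotype(self, tiny_params):
        params = tiny_params.replace(N=2, mu=0, R_c1=0, R_c2=0, R_c3=0,
                                     R_s1=0, R_s2=0, C_total=0)
        pop = init_population(params)
        pop.sites[:, COPY1, :7] = 1
        pop, _, _ = duplicate_and_fix(pop, params, "copy3")
        carriers = pop.sites[pop.has3.astype(bool), COPY3, :]
        assert carriers[:, :7].all() and not carriers[:, 7:].any()

    def test_fixation_time_distribution_matches_rejection_oracle(self):
        """Conditioned fixation times follow the neutral rejection-sampled
        Wright-Fisher trajectory (two-sample KS)."""
        N = 25
        params = SimParams(N=N, L=64, mu=0, R_c1=0, R_c2=0, R_c3=0,
                           R_s1=0, R_s2=0, C_total=0, tract_len=16, s=0.0,
                           schedule=PhaseSchedule(10, 20, 30, 40), seed=3)
        times = []
        for r in range(120):
            pop = init_population(params.replace(seed=1000 + r))
            _, _, gens = duplicate_and_fix(pop, params.replace(seed=1000 + r),
                                           "copy2")
            times.append(gens)

        rng = np.random.default_rng(99)
        n = 2 * N
        oracle = []
        while len(oracle) < 2000:
            k, t = 1, 0
            while 0 < k < n:
                k = rng.binomial(n, k / n)
                t += 1
            if k == n:
                oracle.append(t)
        assert sps.ks_2samp(times, oracle).pvalue > 0.01


class TestCNVBalancing:
    def _fixed_pop(self, params):
        pop = init_population(params)
        pop.has2[:] = 1
        pop.has3[:] = 1
        return pop

    def test_symmetric_frequency_means_no_selection(self):
        # at exactly 50% both class weights are 1: the expected next-gen
        # frequency equals the neutral expectation
        sigma = 2.0
        f = 0.5
        w1 = 1 + sigma * (0.5 - f)
        w0 = 1 + sigma * (0.5 - (1 - f))
        assert w1 == w0 == 1.0

    def test_one_generation_expectation_moves_toward_half(self):
        """Mean copy2 frequency after one selected generation matches the
        analytic expectation f*w1 / (f*w1 + (1-f)*w0)."""
        N, f0, sigma = 50, 0.3, 1.0
        params = SimParams(N=N, L=64, mu=0, R_c1=0, R_c2=0, R_c3=0,
                           R_s1=0, R_s2=0, C_total=0, tract_len=16, s=0.0,
                           sel_strength=sigma, seed=5)
        pop = init_population(params)
        k = int(f0 * 2 * N)
        pop.has2[:k] = 1
        pop.has3[:] = 1
        w1 = 1 + sigma * (0.5 - f0)
        w0 = 1 + sigma * (0.5 - (1 - f0))
        expected = f0 * w1 / (f0 * w1 + (1 - f0) * w0)
        outs = [step_generation(pop, params.replace(seed=s), "VI")
                .copy2_freq() for s in range(400)]
        se = np.std(outs, ddof=1) / np.sqrt(len(outs))
        assert expected > f0  # selection pushes up toward 1/2
        assert abs(np.mean(outs) - expected) < 4 * se

    def test_long_run_frequency_stays_near_half(self):
        params = SimParams(N=50, L=64, mu=0, R_c1=0, R_c2=0, R_c3=0,
                           R_s1=0, R_s2=0, C_total=0, tract_len=16, s=0.0,
                           sel_strength=2.0,
                           schedule=PhaseSchedule(10, 20, 30, 2000), seed=11)
        pop = self._fixed_pop(params)
        pop.generation = 30
        pop, restarts = introduce_cnv_and_balance(pop, params, until=2000)
        assert restarts == 0
        freqs = []
        pop2 = self._fixed_pop(params)
        pop2.generation = 30
        pop2.has2[0] = 0
        for _ in range(800):
            pop2 = step_generation(pop2, params, "VI")
            freqs.append(pop2.copy2_freq())
        assert 0.4 < np.mean(freqs[100:]) < 0.6

    def test_neutral_sel_strength_zero_drifts_like_oracle(self):
        """With sel_strength=0 the CNV classes drift neutrally: the loss
        probability of the seeded deletion matches the binomial-chain
        oracle."""
        N = 20
        params = SimParams(N=N, L=64, mu=0, R_c1=0, R_c2=0, R_c3=0,
                           R_s1=0, R_s2=0, C_total=0, tract_len=16, s=0.0,
                           sel_strength=0.0, seed=2)
        n = 2 * N
        lost = 0
        reps = 300
        for r in range(reps):
            pop = init_population(params.replace(seed=3000 + r))
            pop.has2[:] = 1
            pop.has2[0] = 0  # one deletion
            k = n - 1
            for _ in range(200):
                pop = step_generation(pop, params.replace(seed=3000 + r), "VI")
                k = int(pop.has2.sum())
                if k in (0, n):
                    break
            lost += k == n  # deletion class went extinct
        # neutral fixation prob of the n-1 class is (n-1)/n -> deletion is
        # lost with prob (n-1)/n
        p_hat = lost / reps
        se = np.sqrt(p_hat * (1 - p_hat) / reps)
        assert abs(p_hat - (n - 1) / n) < 4 * max(se, 0.01)


class TestRunSimulation:
    def test_two_copy_subset_reproduces_original_design(self):
        params = SimParams.two_copy(C=2.0, R=0.5, N=20, L=200, seed=6,
                                    schedule=PhaseSchedule(200, 600, 600, 600))
        res = run_simulation(params)
        assert res.population.has2.all()
        assert not res.population.has3.any()
        assert set(res.restarts) == {"II"}

    def test_bit_identical_replay(self, tiny_params):
        a = run_simulation(tiny_params)
        b = run_simulation(tiny_params)
        assert np.array_equal(a.pi, b.pi, equal_nan=True)
        assert np.array_equal(a.population.state, b.population.state)

    def test_divergence_grows_without_igc(self):
        """With C=0 and no inter-copy crossover, fixed differences between
        copy1 and copy3 increase with time on average."""
        params = SimParams(N=15, L=200, mu=0.02, R_c1=0, R_c2=0, R_c3=0,
                           R_s1=0, R_s2=0, C_total=0, s=0.0, seed=0)
        diffs = {200: [], 600: []}
        for r in range(6):
            pop = init_population(params.replace(seed=400 + r))
            pop.has2[:] = 1
            pop.has3[:] = 1
            g = 0
            for horizon in (200, 600):
                while g < horizon:
                    pop = step_generation(pop, params.replace(seed=400 + r),
                                          "V")
                    g += 1
                s = pop.sites
                fixed1 = s[:, 0, :].all(axis=0)
                none1 = ~s[:, 0, :].any(axis=0)
                fixed3 = s[:, 4, :].all(axis=0)
                none3 = ~s[:, 4, :].any(axis=0)
                diffs[horizon].append(
                    int((fixed1 & none3).sum() + (fixed3 & none1).sum()))
        assert np.mean(diffs[600]) > np.mean(diffs[200])

    def test_trajectory_covers_schedule(self, tiny_params):
        res = run_simulation(tiny_params, thin=10)
        assert res.gens[-1] == tiny_params.schedule.end
        assert np.isfinite(res.pi[:, 0]).all()
        # copy3 diversity defined only after its introduction
        assert np.isnan(res.pi[0, 4])
        assert np.isfinite(res.pi[-1, 4])


class TestSampling:
    def test_monomorphic_population_gives_empty_matrix(self, tiny_params):
        pop = init_population(tiny_params)
        pop.has2[:] = 1
        pop.has3[:] = 1
        m = sample_alleles(pop, 5, seed=1)
        assert m.n_sites == 0

    def test_full_sample_recovers_population_frequencies(self, tiny_params):
        rng = np.random.default_rng(8)
        pop = init_population(tiny_params)
        pop.sites[:, COPY1, :] = (rng.random((pop.n_chrom, tiny_params.L))
                                  < 0.3)
        pop.has2[:] = 1
        pop.has3[:] = 1
        m = sample_alleles(pop, pop.n_chrom, copies=("P1",), seed=2)
        truth = pop.sites[:, COPY1, :].sum(axis=0)
        seg = (truth > 0) & (truth < pop.n_chrom)
        assert np.array_equal(m.data.sum(axis=1), truth[seg])

    def test_sample_frequency_tracks_population_frequency(self, tiny_params):
        pop = init_population(tiny_params)
        pop.sites[:, COPY1, 0] = 0
        pop.sites[: pop.n_chrom // 4, COPY1, 0] = 1  # popn freq 0.25
        pop.sites[0, COPY1, 1] = 1  # keep another site segregating
        pop.has2[:] = 1
        pop.has3[:] = 1
        n = 20
        freqs = []
        for s in range(300):
            m = sample_alleles(pop, n, copies=("P1",), seed=s)
            row = np.flatnonzero(m.positions == 1)
            freqs.append(m.data[row[0]].sum() / n if len(row) else 0.0)
        se = np.sqrt(0.25 * 0.75 / n) / np.sqrt(300)
        assert abs(np.mean(freqs) - 0.25) < 5 * se

    def test_oversampling_raises(self, tiny_params):
        pop = init_population(tiny_params)
        with pytest.raises(ValueError, match="cannot sample"):
            sample_alleles(pop, pop.n_chrom + 1, copies=("P1",), seed=0)


def test_restart_cap_raises():
    # impossible balancing target: strength so large that weights clamp and
    # one class dies every attempt
    params = SimParams(N=10, L=64, mu=0, R_c1=0, R_c2=0, R_c3=0, R_s1=0,
                       R_s2=0, C_total=0, tract_len=16, s=0.0,
                       sel_strength=1000.0, restart_cap=5, seed=1)
    pop = init_population(params)
    pop.has2[:] = 1
    pop.has3[:] = 1
    with pytest.raises(FixationRestartError):
        introduce_cnv_and_balance(pop, params, until=500)
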