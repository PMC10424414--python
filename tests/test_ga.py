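import numpy as np
import pytest

from fmtforge import ga, synth
from fmtforge.ga import (
    CandidateDonor,
    GAConfig,
    convergence_generation,
    dominant_orders,
    expand_pool,
    fitness,
    init_population,
    mutate,
    recombine,
    select,
)
from fmtforge.tables_io import FeatureTable
from fmtforge.synth import generate_taxonomy


@pytest.fixture(scope="module")
def pool():
    cfg = synth.SynthConfig(n_donors=40, recipients_per_donor=1, seed=12)
    bundle = synth.generate_cohort(cfg)
    return expand_pool(bundle.donors, 300, seed=2)


class TestFitness:
    def test_direct_arithmetic(self):
        b = np.zeros(500)
        b[:100] = 1
        assert fitness(4.2, b, 0.01, "maximize") == pytest.approx(3.2, abs=1e-12)

    def test_zero_gamma_is_prediction(self):
        assert fitness(1.234, np.ones(50), 0.0) == pytest.approx(1.234, abs=1e-12)

    def test_minimize_sign_convention(self):
        b = np.zeros(20)
        b[:10] = 1
        assert fitness(0.3, b, 0.02, "minimize") == pytest.approx(-0.5, abs=1e-12)

    def test_affine_in_gamma_with_slope_minus_nnz(self, rng):
        b = (rng.random(200) > 0.5).astype(int)
        s = 3.7
        gammas = np.array([0.0, 0.003, 0.007, 0.02])
        vals = np.array([fitness(s, b, g) for g in gammas])
        slopes = np.diff(vals) / np.diff(gammas)
        np.testing.assert_allclose(slopes, -b.sum(), atol=1e-9)

    def test_zero_abundance_taxa_do_not_change_fitness(self):
        b = np.array([1, 1, 0])
        b_padded = np.array([1, 1, 0, 0, 0])
        assert fitness(2.0, b, 0.01) == fitness(2.0, b_padded, 0.01)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            fitness(1.0, np.ones(3), -0.1)


class TestSelect:
    def _pop(self, fits, nnzs=None):
        out = []
        for i, f in enumerate(fits):
            a = np.zeros(50)
            a[: (nnzs[i] if nnzs else 5)] = 1.0 / (nnzs[i] if nnzs else 5)
            c = CandidateDonor(a=a, lineage=i)
            c.fitness = f
            out.append(c)
        return out

    def test_matches_brute_force_sort(self, rng):
        fits = rng.random(100).tolist()
        pop = self._pop(fits)
        cfg = GAConfig(population_size=100, n_select=30)
        chosen = {c.lineage for c in select(pop, cfg)}
        expected = set(np.argsort(fits)[::-1][:30].tolist())
        assert chosen == expected

    def test_equal_fitness_prefers_sparser(self):
        pop = self._pop([1.0] * 40, nnzs=list(range(1, 41)))
        cfg = GAConfig(population_size=40, n_select=30)
        chosen = select(pop, cfg)
        assert max(c.nnz for c in chosen) == 30

    def test_elite_floor_above_rest(self, rng):
        pop = self._pop(rng.random(60).tolist())
        cfg = GAConfig(population_size=60, n_select=30)
        elites = select(pop, cfg)
        rest = [c for c in pop if c.lineage not in {e.lineage for e in elites}]
        assert min(c.fitness for c in elites) >= max(c.fitness for c in rest)


class TestOperators:
    def test_mutation_probability_zero_is_identity(self, pool, rng):
        cand = CandidateDonor(a=pool.values[0].copy(), lineage=0)
        out = mutate(cand, rng, pool.values, p_mutation=0.0)
        np.testing.assert_array_equal(out.a, cand.a)

    def test_mutant_stays_on_simplex_with_consistent_mask(self, pool, rng):
        cand = CandidateDonor(a=pool.values[0].copy(), lineage=0)
        for _ in range(50):
            out = mutate(cand, rng, pool.values, p_mutation=1.0)
            assert out.a.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_array_equal(out.b, (out.a > 0).astype(int))

    def test_mean_support_change_in_expected_band(self, pool, rng):
        # Monte-Carlo of the operator: with k ~ Poisson(3)+1 toggles the mean
        # absolute change in support size per applied mutation lies in [1, 4]
        cand = CandidateDonor(a=pool.values[0].copy(), lineage=0)
        changes = [
            abs(mutate(cand, rng, pool.values, p_mutation=1.0, rate_lambda=3.0).nnz
                - cand.nnz)
            for _ in range(1000)
        ]
        assert 1.0 <= np.mean(changes) <= 4.0

    def test_identical_parents_reproduce_themselves(self, pool, rng):
        p1 = CandidateDonor(a=pool.values[0].copy(), lineage=0)
        p2 = CandidateDonor(a=pool.values[0].copy(), lineage=1)
        out = recombine(p1, p2, rng, p_recombination=1.0, lineage=2)
        np.testing.assert_allclose(out.a, p1.a, atol=1e-12)

    def test_offspring_support_within_parent_union(self, pool, rng):
        p1 = CandidateDonor(a=pool.values[0].copy(), lineage=0)
        p2 = CandidateDonor(a=pool.values[1].copy(), lineage=1)
        for _ in range(20):
            out = recombine(p1, p2, rng, p_recombination=1.0, lineage=2)
            union = (p1.a > 0) | (p2.a > 0)
            assert np.all(out.a[~union] == 0)

    def test_disjoint_support_crossover_halves_union(self, rng):
        n = 200
        a = np.zeros(n)
        a[:100] = 0.01
        b = np.zeros(n)
        b[100:] = 0.01
        p1 = CandidateDonor(a=a, lineage=0)
        p2 = CandidateDonor(a=b, lineage=1)
        nnzs = [recombine(p1, p2, rng, 1.0, 2).nnz for _ in range(500)]
        assert np.mean(nnzs) == pytest.approx(100, rel=0.1)

    def test_axis_mismatch_rejected(self, rng):
        p1 = CandidateDonor(a=np.array([1.0]), lineage=0)
        p2 = CandidateDonor(a=np.array([0.5, 0.5]), lineage=1)
        with pytest.raises(ValueError):
            recombine(p1, p2, rng, 1.0, 2)


class TestExpandPool:
    def test_no_jitter_identity_limit(self):
        cfg = synth.SynthConfig(n_donors=10, recipients_per_donor=1, seed=1)
        donors = synth.generate_cohort(cfg).donors
        out = expand_pool(donors, 10, seed=0, jitter_sd=0.0)
        np.testing.assert_allclose(out.values, donors.values, atol=1e-12)

    def test_rows_on_simplex(self, pool):
        np.testing.assert_allclose(pool.values.sum(axis=1), 1.0, atol=1e-9)

    def test_prevalence_preserved(self, pool):
        cfg = synth.SynthConfig(n_donors=40, recipients_per_donor=1, seed=12)
        real = synth.generate_cohort(cfg).donors
        prev_real = (real.values > 0).mean(axis=0)
        prev_pool = (pool.values > 0).mean(axis=0)
        assert np.all(np.abs(prev_pool - prev_real) <= 0.10 + 1e-9)

    def test_undersized_request_rejected(self):
        cfg = synth.SynthConfig(n_donors=10, recipients_per_donor=1, seed=1)
        donors = synth.generate_cohort(cfg).donors
        with pytest.raises(ValueError):
            expand_pool(donors, 5)


class TestInitAndRun:
    def test_init_without_replacement_and_deterministic(self, pool):
        cfg = GAConfig(population_size=100, n_select=30, seed=0)
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        p1 = init_population(pool, cfg, rng1)
        p2 = init_population(pool, cfg, rng2)
        assert len(p1) == 100
        np.testing.assert_allclose(
            np.vstack([c.a for c in p1]), np.vstack([c.a for c in p2])
        )

    def test_entire_pool_used_when_sizes_match(self, pool):
        sub = FeatureTable(pool.sample_ids[:50], list(pool.taxa),
                           pool.values[:50], "relative")
        cfg = GAConfig(population_size=50, n_select=30)
        p = init_population(sub, cfg, np.random.default_rng(0))
        got = np.sort(np.vstack([c.a for c in p]), axis=0)
        np.testing.assert_allclose(got, np.sort(sub.values, axis=0), atol=1e-12)

    def test_small_pool_rejected(self, pool):
        sub = FeatureTable(pool.sample_ids[:10], list(pool.taxa),
                           pool.values[:10], "relative")
        with pytest.raises(ValueError, match="pool"):
            init_population(sub, GAConfig(), np.random.default_rng(0))

    def test_same_seed_identical_result(self, shannon_cnn, donor_pool):
        cfg = GAConfig(seed=9, max_generations=3)
        r1 = ga.run(cfg, shannon_cnn, donor_pool)
        r2 = ga.run(cfg, shannon_cnn, donor_pool)
        assert r1.best_fitness == r2.best_fitness
        np.testing.assert_allclose(r1.elite_profiles, r2.elite_profiles)

    def test_plateau_rule_stops_early(self, shannon_cnn, donor_pool):
        cfg = GAConfig(seed=1, max_generations=50, plateau_patience=3)
        res = ga.run(cfg, shannon_cnn, donor_pool)
        assert res.generations_run <= 50
        assert len(res.best_fitness) == res.generations_run


class TestSummaries:
    def test_dominant_orders_sum_below_one(self, ga_runs):
        table = dominant_orders(ga_runs[0], top_k=100)
        assert sum(table.values()) <= 1.0 + 1e-9

    def test_single_order_pool_dominates_fully(self):
        taxa = generate_taxonomy(10, 1, seed=0)
        profiles = np.random.default_rng(0).dirichlet(np.ones(10), size=5)
        res = ga.GAResult(
            best_fitness=[1.0], mean_elite_nnz=[10.0], elite_profiles=profiles,
            elite_fitness=np.ones(5), elite_predictions=np.ones(5), taxa=taxa,
            generations_run=1,
        )
        table = dominant_orders(res, top_k=3)
        assert list(table.values())[0] == pytest.approx(1.0)

    def test_triviality_scc_reported_low_or_none(self, ga_runs):
        for res in ga_runs:
            if res.triviality_scc is not None:
                assert -1.0 <= res.triviality_scc <= 1.0


class TestConvergenceMeasure:
    def test_flat_trajectory_converges_immediately(self):
        assert convergence_generation([2.0, 2.0, 2.0]) == 1

    def test_late_jump_delays_convergence(self):
        traj = [1.0] * 10 + [2.0, 2.0]
        assert convergence_generation(traj) == 11

    def test_small_drift_within_tolerance(self):
        traj = [1.0, 1.001, 1.002]
        assert convergence_generation(traj, rel_tol=0.01) == 1
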