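"""Life-cycle engine: initialization, dispersal, migration, selective
mating, full runs."""

import numpy as np
import pytest

from islandrad import (
    ParameterError,
    SimulationParams,
    build_geometry,
    dispersal_probability,
    fitness_weight,
    initialize_population,
    migrate,
    preset,
    reproduce,
    run_simulation,
    step_generation,
    validate_params,
)
from islandrad.engine import (
    MatingPools,
    PopulationState,
    _draw_parents_grouped,
    _maladapted_counts,
)


class TestInitializePopulation:
    def test_default_all_primitive(self, default_params):
        state = initialize_population(default_params)
        assert state.sizes() == (100, 100, 100)
        assert all((g == 0).all() for g in state.genotypes)
        p = dispersal_probability(0, default_params)
        assert p == 0.5  # primitive genotypes migrate at the baseline rate

    def test_island_sizes_honoured(self):
        params = validate_params(SimulationParams(N_A=50, N_B=10_000, N_C=50))
        assert initialize_population(params).sizes() == (50, 10_000, 50)

    @pytest.mark.parametrize("q,ploidy,cols", [(15, 1, 16), (1, 2, 4), (3, 2, 8)])
    def test_locus_layout(self, q, ploidy, cols):
        params = validate_params(SimulationParams(q=q, ploidy=ploidy))
        state = initialize_population(params)
        assert state.genotypes[0].shape == (100, cols)


class TestDispersalProbability:
    @pytest.mark.parametrize(
        "derived,q,expected",
        [(0, 1, 0.5), (1, 1, 0.0), (2, 5, 0.3), (5, 5, 0.0), (0, 15, 0.5)],
    )
    def test_linear_decrement(self, derived, q, expected):
        params = validate_params(SimulationParams(q=q))
        assert dispersal_probability(derived, params) == pytest.approx(expected)

    def test_diploid_per_copy_decrement(self):
        params = validate_params(SimulationParams(q=1, ploidy=2))
        assert dispersal_probability(1, params) == pytest.approx(0.25)
        assert dispersal_probability(2, params) == pytest.approx(0.0)

    def test_out_of_range_rejected(self, default_params):
        with pytest.raises(ValueError):
            dispersal_probability(2, default_params)  # q = 1


class TestFitnessWeight:
    def test_taxon_cycle_orientation(self, default_params):
        # allele 0 adapted on the low-altitude islands B, C; allele 1 on A
        assert fitness_weight(0, "B", default_params) == 1.0
        assert fitness_weight(0, "A", default_params) == pytest.approx(0.3)
        assert fitness_weight(1, "A", default_params) == 1.0
        assert fitness_weight(1, "C", default_params) == pytest.approx(0.3)

    def test_neutral_when_DS_zero(self):
        params = validate_params(SimulationParams(DS=0.0))
        for allele in (0, 1):
            for isl in "ABC":
                assert fitness_weight(allele, isl, params) == 1.0

    def test_diploid_additive(self):
        params = validate_params(SimulationParams(ploidy=2, DS=0.6))
        het = np.array([[0, 1]])
        assert fitness_weight(het, "B", params)[0] == pytest.approx(0.7)


class TestMigrate:
    def test_fully_derived_never_moves(self, default_geometry, rng):
        params = validate_params(SimulationParams(q=2))
        state = initialize_population(params)
        for g in state.genotypes:
            g[:, 1:] = 1  # every dispersal locus derived
        pools, counts = migrate(state, default_geometry, params, rng)
        assert counts.sum() == 0
        assert [len(g) for g in pools.genotypes] == [100, 100, 100]

    def test_destination_split_follows_geometry(self, rng):
        # A at (-1, 0): p_AB = 0.75; make only island A's residents mobile
        params = validate_params(SimulationParams(x=-1.0))
        geometry = build_geometry(-1.0, 0.0)
        state = initialize_population(params)
        state.genotypes[1][:, 1:] = 1
        state.genotypes[2][:, 1:] = 1
        to_b = to_c = 0
        n_rep = 3000
        for _ in range(n_rep):
            _, counts = migrate(state, geometry, params, rng)
            to_b += counts[0]
            to_c += counts[1]
        frac_b = to_b / (to_b + to_c)
        se = np.sqrt(0.75 * 0.25 / (to_b + to_c))
        assert abs(frac_b - 0.75) < 3 * se

    def test_extinction_flagged_when_island_empties(self, default_geometry, rng):
        # A's two residents always leave; B and C never move: A empties
        params = validate_params(SimulationParams(N_A=2, M=1.0))
        state = initialize_population(params)
        state.genotypes[1][:, 1:] = 1
        state.genotypes[2][:, 1:] = 1
        from islandrad import ExtinctionError

        with pytest.raises(ExtinctionError, match="island A"):
            migrate(state, default_geometry, params, rng)


class TestReproduce:
    def _pools(self, genotypes):
        return MatingPools(
            genotypes=[np.array(g, dtype=np.int8) for g in genotypes],
            natal=[np.zeros(len(g), dtype=np.int8) + i for i, g in enumerate(genotypes)],
        )

    def test_monomorphic_pool_breeds_true_without_mutation(self, rng):
        params = validate_params(SimulationParams(mu=0.0, N_A=20, N_B=20, N_C=20))
        pools = self._pools([np.ones((20, 2)), np.zeros((20, 2)), np.zeros((20, 2))])
        state, _ = reproduce(pools, params, rng)
        assert (state.genotypes[0] == 1).all()
        assert (state.genotypes[1] == 0).all()

    def test_certain_mutation_flips_every_allele(self, rng):
        params = validate_params(SimulationParams(mu=1.0, N_A=20, N_B=20, N_C=20))
        pools = self._pools([np.zeros((20, 2))] * 3)
        state, _ = reproduce(pools, params, rng)
        assert all((g == 1).all() for g in state.genotypes)

    def test_selection_weighted_parent_draws(self, rng):
        """Pool of 10 adapted + 10 maladapted at DS = 0.5: adapted share of
        draws is 10 / (10 + 10 * 0.5) = 2/3."""
        maladapted = np.array([0] * 10 + [1] * 10)
        n = 100_000
        idx = _draw_parents_grouped(maladapted, 0.5, 1, n, rng)
        share = (idx < 10).mean()
        expected = 2 / 3
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(share - expected) < 3 * se

    def test_maladaptation_counts(self, default_params):
        g = np.array([[0, 0], [1, 0]], dtype=np.int8)
        assert _maladapted_counts(g, "A", default_params).tolist() == [1, 0]
        assert _maladapted_counts(g, "B", default_params).tolist() == [0, 1]


class TestStepGeneration:
    def test_initial_census_is_fixed_primitive(self, default_params, default_geometry, rng):
        state = initialize_population(default_params)
        _, record = step_generation(state, default_params, default_geometry, rng)
        assert record.generation == 0
        assert record.adapt_freq == (1.0, 1.0, 1.0)
        assert record.dispersal_freq == (1.0, 1.0, 1.0)

    def test_population_sizes_conserved(self, default_geometry, rng):
        params = validate_params(SimulationParams(N_A=37, N_B=91, N_C=64))
        state = initialize_population(params)
        for _ in range(5):
            state, _ = step_generation(state, params, default_geometry, rng)
            assert state.sizes() == (37, 91, 64)

    def test_matched_seeds_reproduce_bitwise(self):
        p = preset("default", max_generations=200)
        runs = []
        for _ in range(2):
            records, result = run_simulation(
                p.replace(seed=77), engine="array"
            )
            runs.append((records, result))
        assert runs[0][1] == runs[1][1]
        for r0, r1 in zip(runs[0][0], runs[1][0]):
            assert r0 == r1


class TestRunSimulation:
    def test_default_preset_single_run(self):
        _, result = run_simulation(preset("default").replace(seed=5))
        assert not result.censored
        assert result.onset_second >= result.onset_first >= 50
        assert result.interval >= 0
        assert result.simultaneous  # default dynamics collapse together

    def test_run_cap_below_window_rejected(self):
        with pytest.raises(ParameterError):
            run_simulation(SimulationParams(max_generations=49))

    def test_no_mutational_input_censors(self):
        params = validate_params(
            SimulationParams(mu=0.0, DS=0.0, max_generations=120)
        )
        _, result = run_simulation(params)
        assert result.censored
        assert result.interval is None
        assert not result.simultaneous

    def test_counts_engine_refused_for_multilocus(self):
        with pytest.raises(ValueError):
            run_simulation(
                validate_params(SimulationParams(q=5)), engine="counts"
            )

    def test_record_free_run_matches_full_run(self):
        p = preset("default").replace(seed=9)
        records, res_full = run_simulation(p, engine="array")
        none_records, res_bare = run_simulation(p, keep_records=False, engine="array")
        assert none_records == []
        assert res_bare == res_full


class TestOptionalModes:
    def test_diploid_run_completes(self):
        params = validate_params(
            SimulationParams(ploidy=2, max_generations=150, N_A=40, N_B=40, N_C=40)
        )
        _, result = run_simulation(params)
        assert result.n_generations <= 150

    def test_three_environment_alleles_stay_triallelic(self, rng):
        params = validate_params(
            SimulationParams(n_env_types=3, mu=0.2, N_A=30, N_B=30, N_C=30)
        )
        geometry = build_geometry(0.0, 0.0)
        state = initialize_population(params)
        for _ in range(10):
            state, _ = step_generation(state, params, geometry, rng)
        adapt = np.concatenate([g[:, 0] for g in state.genotypes])
        assert set(np.unique(adapt)) <= {0, 1, 2}
        disp = np.concatenate([g[:, 1:].ravel() for g in state.genotypes])
        assert set(np.unique(disp)) <= {0, 1}
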