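"""Liquid construction: placement, E/I split, topology, weights, quantization."""

import numpy as np
import pytest

from elsm.liquid import (
    GridSpec,
    LiquidSpec,
    NeuronPopulation,
    assign_time_constants,
    build_input_synapses,
    build_liquid,
    build_recurrent_synapses,
    connection_probability,
    default_grid_dims,
    place_on_grid,
    quantize_weights,
    sample_recurrent_weight,
    split_ei,
    weight_upper_bounds,
)


class TestPlacement:
    def test_exhaustive_fill_of_unit_cube(self):
        pos = place_on_grid(8, GridSpec((2, 2, 2), 8))
        assert pos.shape == (8, 3)
        assert len({tuple(p) for p in pos}) == 8
        assert pos.min() == 0 and pos.max() == 1

    def test_line_grid_positions_and_distances(self):
        pos = place_on_grid(5, GridSpec((1, 1, 5), 5))
        np.testing.assert_array_equal(pos, [[0, 0, i] for i in range(5)])
        d = np.linalg.norm(pos[None, 0] - pos, axis=-1)
        np.testing.assert_allclose(d, [0, 1, 2, 3, 4])

    def test_distinct_sites_within_bounds(self):
        pos = place_on_grid(2000, GridSpec((10, 10, 20), 2000))
        assert len({tuple(p) for p in pos}) == 2000
        assert (pos >= 0).all()
        assert (pos < [10, 10, 20]).all()

    def test_grid_too_small_names_counts(self):
        with pytest.raises(ValueError, match="9.*8"):
            place_on_grid(9, GridSpec((2, 2, 2), 8))

    def test_default_grid_dims(self):
        assert default_grid_dims(2000) == (10, 10, 20)
        dx, dy, dz = default_grid_dims(500)
        assert dx * dy * dz >= 500


class TestEISplit:
    @pytest.mark.parametrize(
        "n,frac,n_exc", [(2000, 0.8, 1600), (10, 1.0, 10), (5, 0.8, 4)]
    )
    def test_exact_counts(self, n, frac, n_exc):
        labels = split_ei(n, frac, np.random.default_rng(0))
        assert labels.sum() == n_exc

    def test_assignment_randomized_by_seed(self):
        a = split_ei(100, 0.8, np.random.default_rng(1))
        b = split_ei(100, 0.8, np.random.default_rng(2))
        assert a.sum() == b.sum() == 80
        assert not np.array_equal(a, b)


class TestConnectionProbability:
    def test_closed_form_values(self):
        C = {"EE": 0.3, "EI": 0.2, "IE": 0.4, "II": 0.1}
        assert connection_probability(0.0, "EE", 2.0, C) == pytest.approx(0.3)
        assert connection_probability(2.0, "EE", 2.0, C) == pytest.approx(
            0.3 * np.exp(-1.0)
        )
        assert connection_probability(1.0, "IE", 2.0, C) == pytest.approx(
            0.4 * np.exp(-0.25)
        )

    def test_unknown_type_raises(self):
        with pytest.raises(ValueError, match="synapse type"):
            connection_probability(1.0, "XX", 2.0, {"EE": 0.3})

    def test_clamped_to_unit_interval(self):
        assert connection_probability(0.0, "EE", 2.0, {"EE": 5.0}) == 1.0


class TestRecurrentSynapses:
    def test_zero_c_gives_empty_table(self):
        spec = LiquidSpec(n_neurons=8, grid_dims=(2, 2, 2), C={t: 0.0 for t in "EE EI IE II".split()})
        pop = NeuronPopulation(place_on_grid(8, spec.grid), np.ones(8, bool))
        table = build_recurrent_synapses(pop, spec, np.random.default_rng(0))
        assert table.n == 0

    def test_expected_count_matches_brute_force_enumeration(self):
        """Monte-Carlo mean synapse count vs. the exact pairwise-sum oracle."""
        spec = LiquidSpec(n_neurons=8, grid_dims=(2, 2, 2))
        pos = place_on_grid(8, spec.grid)
        pop = NeuronPopulation(pos, np.ones(8, bool))
        # oracle: sum of 0.3*exp(-(d/2)^2) over all 56 ordered pairs
        expected = 0.0
        variance = 0.0
        for i in range(8):
            for j in range(8):
                if i == j:
                    continue
                d = np.linalg.norm(pos[i] - pos[j])
                p = 0.3 * np.exp(-((d / 2.0) ** 2))
                expected += p
                variance += p * (1 - p)
        n_trials = 3000
        rng = np.random.default_rng(123)
        total = sum(
            build_recurrent_synapses(pop, spec, rng).n for _ in range(n_trials)
        )
        se = np.sqrt(variance / n_trials)
        assert abs(total / n_trials - expected) < 3 * se

    def test_two_neuron_realization_frequency(self):
        """Realized connection frequency matches the probability formula."""
        spec = LiquidSpec(n_neurons=2, grid_dims=(1, 1, 2))
        pop = NeuronPopulation(np.array([[0, 0, 0], [0, 0, 1]]), np.ones(2, bool))
        rng = np.random.default_rng(7)
        n_trials = 20_000
        hits = sum(build_recurrent_synapses(pop, spec, rng).n for _ in range(n_trials))
        p = 0.3 * np.exp(-0.25)
        se = np.sqrt(2 * n_trials * p * (1 - p))
        assert abs(hits - 2 * n_trials * p) < 3 * se

    def test_no_self_connections(self, demo_liquid):
        assert (demo_liquid.recurrent.pre != demo_liquid.recurrent.post).all()

    def test_delays_match_type(self, demo_liquid):
        t = demo_liquid.recurrent
        types = t.syn_type.astype(str)
        for name, delay in (("EE", 1.5), ("EI", 0.8), ("IE", 0.8), ("II", 0.8)):
            assert (t.delay_ms[types == name] == delay).all()


class TestWeights:
    def test_ee_draws_within_support_and_mean(self):
        spec = LiquidSpec()
        rng = np.random.default_rng(0)
        w = sample_recurrent_weight("EE", spec, rng, size=100_000)
        assert w.min() >= 0 and w.max() <= 0.6
        se = 0.6 / np.sqrt(12 * 100_000)
        assert abs(w.mean() - 0.3) < 3 * se

    def test_zero_upper_gives_zero_weight(self):
        spec = LiquidSpec(recurrent_weight_upper={"EE": 0.0, "EI": 0.4, "IE": 1.2, "II": 0.4})
        w = sample_recurrent_weight("EE", spec, np.random.default_rng(0), size=10)
        assert (np.asarray(w) == 0).all()

    def test_type_specific_supports(self, demo_liquid):
        t = demo_liquid.recurrent
        types = t.syn_type.astype(str)
        for name, upper in (("EE", 0.6), ("EI", 0.4), ("IE", 1.2), ("II", 0.4)):
            sel = t.weight[types == name]
            assert sel.min() >= 0 and sel.max() <= upper


class TestInputSynapses:
    def test_exact_in_degree_distinct_channels(self, demo_liquid):
        t = demo_liquid.inputs
        for post in range(demo_liquid.n_neurons):
            chans = t.pre[t.post == post]
            assert chans.size == 7
            assert np.unique(chans).size == 7

    def test_zero_in_degree_empty(self):
        spec = LiquidSpec(n_neurons=8, grid_dims=(2, 2, 2), input_in_degree=0)
        pop = NeuronPopulation(place_on_grid(8, spec.grid), np.ones(8, bool))
        assert build_input_synapses(10, pop, spec, np.random.default_rng(0)).n == 0

    def test_in_degree_exceeding_channels_raises(self):
        spec = LiquidSpec(n_neurons=8, grid_dims=(2, 2, 2), input_in_degree=7)
        pop = NeuronPopulation(place_on_grid(8, spec.grid), np.ones(8, bool))
        with pytest.raises(ValueError, match="in_degree"):
            build_input_synapses(3, pop, spec, np.random.default_rng(0))

    def test_inhibitory_target_weights_scaled_by_factor(self, demo_liquid):
        t = demo_liquid.inputs
        types = t.syn_type.astype(str)
        w_inh = t.weight[types == "input-I"]
        w_exc = t.weight[types == "input-E"]
        assert w_inh.max() <= 0.2 and w_exc.max() <= 0.4
        # with thousands of draws the empirical max approaches the bound
        assert w_inh.max() > 0.18 and w_exc.max() > 0.38

    def test_all_input_rows_excitatory_acting(self, demo_liquid):
        types = set(demo_liquid.inputs.syn_type.astype(str))
        assert types <= {"input-E", "input-I"}
        assert (demo_liquid.inputs.delay_ms == 1.0).all()


class TestTimeConstants:
    def _population(self, n):
        return NeuronPopulation(
            np.zeros((n, 3), dtype=np.int64),
            np.arange(n) < int(0.8 * n),
        )

    def test_fixed_mode(self):
        pop = assign_time_constants(
            self._population(100), LiquidSpec(tau_mode="fixed"), np.random.default_rng(0)
        )
        assert (pop.tau_m == 30.0).all()

    def test_uniform_mode_mean(self):
        pop = assign_time_constants(
            self._population(100_000),
            LiquidSpec(tau_mode="uniform"),
            np.random.default_rng(0),
        )
        assert pop.tau_m.min() >= 5 and pop.tau_m.max() <= 55
        se = 50 / np.sqrt(12 * 100_000)
        assert abs(pop.tau_m.mean() - 30.0) < 3 * se

    def test_sfa_off_leaves_thresholds_static(self):
        pop = assign_time_constants(
            self._population(100), LiquidSpec(sfa_mode="off"), np.random.default_rng(0)
        )
        assert np.isnan(pop.tau_sfa).all()

    def test_sfa_uniform_excitatory_only(self):
        pop = assign_time_constants(
            self._population(100),
            LiquidSpec(sfa_mode="uniform"),
            np.random.default_rng(0),
        )
        assert np.isfinite(pop.tau_sfa[pop.is_excitatory]).all()
        assert np.isnan(pop.tau_sfa[~pop.is_excitatory]).all()
        tau = pop.tau_sfa[pop.is_excitatory]
        assert tau.min() >= 50 and tau.max() <= 1050


class TestQuantization:
    def test_four_bits_at_most_16_levels_per_type(self, demo_liquid):
        q = demo_liquid.quantized(4)
        types = q.recurrent.syn_type.astype(str)
        for t in np.unique(types):
            assert np.unique(q.recurrent.weight[types == t]).size <= 16

    def test_idempotent(self, demo_liquid):
        uppers = weight_upper_bounds(demo_liquid.spec)
        once = quantize_weights(demo_liquid.recurrent, 4, uppers)
        twice = quantize_weights(once, 4, uppers)
        np.testing.assert_array_equal(once.weight, twice.weight)

    def test_half_step_error_bound(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 0.6, size=10_000)
        from elsm.liquid import SynapseTable

        table = SynapseTable(
            np.zeros(w.size), np.ones(w.size), w,
            np.full(w.size, 1.5), np.full(w.size, "EE", dtype=object),
        )
        q = quantize_weights(table, 4, {"EE": 0.6})
        bound = 0.6 / (2 * (2**4 - 1))
        assert np.abs(w - q.weight).max() <= bound + 1e-12

    def test_64_bit_path_identical(self, demo_liquid):
        q = demo_liquid.quantized(64)
        np.testing.assert_array_equal(q.recurrent.weight, demo_liquid.recurrent.weight)
        np.testing.assert_array_equal(q.inputs.weight, demo_liquid.inputs.weight)


class TestLiquidAssembly:
    def test_build_is_deterministic(self):
        spec = LiquidSpec(n_neurons=100, seed=0)
        a = build_liquid(spec, 20, seed=5)
        b = build_liquid(spec, 20, seed=5)
        np.testing.assert_array_equal(a.recurrent.weight, b.recurrent.weight)
        np.testing.assert_array_equal(a.inputs.pre, b.inputs.pre)
        np.testing.assert_array_equal(a.population.tau_m, b.population.tau_m)

    def test_with_inhib_factor_changes_only_input_inhibitory_weights(self, demo_liquid):
        scaled = demo_liquid.with_inhib_factor(2.0)
        np.testing.assert_array_equal(scaled.recurrent.weight, demo_liquid.recurrent.weight)
        np.testing.assert_array_equal(scaled.inputs.pre, demo_liquid.inputs.pre)
        np.testing.assert_array_equal(scaled.inputs.post, demo_liquid.inputs.post)
        types = demo_liquid.inputs.syn_type.astype(str)
        exc_rows = types == "input-E"
        np.testing.assert_array_equal(
            scaled.inputs.weight[exc_rows], demo_liquid.inputs.weight[exc_rows]
        )
        np.testing.assert_allclose(
            scaled.inputs.weight[~exc_rows], demo_liquid.inputs.weight[~exc_rows] * 4.0
        )

    def test_no_duplicate_input_synapse(self, demo_liquid):
        pairs = set(zip(demo_liquid.inputs.pre, demo_liquid.inputs.post))
        assert len(pairs) == demo_liquid.inputs.n

    def test_save_load_round_trip(self, demo_liquid, tmp_path):
        demo_liquid.save(tmp_path / "liq")
        from elsm.liquid import Liquid

        loaded = Liquid.load(tmp_path / "liq")
        np.testing.assert_array_equal(loaded.recurrent.weight, demo_liquid.recurrent.weight)
        np.testing.assert_array_equal(
            loaded.population.positions, demo_liquid.population.positions
        )
        assert loaded.spec.to_dict() == demo_liquid.spec.to_dict()
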