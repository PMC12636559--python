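import numpy as np
import pytest

from foxcircuit import (
    LifParams,
    SilenceSpec,
    StimulusSpec,
    generate_micro_fixture,
    oracle_simulate,
    run_trials,
    simulate_trial,
)
from foxcircuit.lif import SimulationError, poisson_train
from foxcircuit.synth import GeneratorConfig, generate_reference


def _explicit(graph, trains, **kw):
    return StimulusSpec(neurons=frozenset(trains), explicit_trains=trains,
                        **kw)


class TestBasicDynamics:
    def test_zero_rate_means_zero_spikes(self):
        g = generate_micro_fixture("chain3")
        trains = simulate_trial(g, LifParams(), StimulusSpec(
            neurons=frozenset({"A"}), rate=0.0), seed=1)
        assert all(len(t) == 0 for t in trains.spikes.values())

    def test_zero_coupling_confines_spikes_to_stimulated(self):
        g = generate_micro_fixture("chain3")
        trains = simulate_trial(g, LifParams(w_syn=0.0), StimulusSpec(
            neurons=frozenset({"A"}), rate=100.0), seed=1)
        assert len(trains.spikes["A"]) > 0
        assert len(trains.spikes["B"]) == 0
        assert len(trains.spikes["C"]) == 0

    def test_refractory_interval_everywhere(self):
        g = generate_micro_fixture("fanin")
        params = LifParams(w_syn=4.0, trial_duration=500.0)
        trains = simulate_trial(g, params, StimulusSpec(
            neurons=frozenset({"A1", "A2", "A3"}), rate=300.0), seed=5)
        for times in trains.spikes.values():
            if len(times) > 1:
                assert np.diff(times).min() >= params.t_refractory - 1e-9
            assert np.all(np.diff(times) > 0)

    def test_silenced_neuron_never_spikes(self):
        g = generate_micro_fixture("fanin")
        trains = simulate_trial(
            g, LifParams(w_syn=10.0), StimulusSpec(
                neurons=frozenset({"A1", "A2", "A3"}), rate=300.0),
            silenced=SilenceSpec(frozenset({"B"})), seed=2)
        assert len(trains.spikes["B"]) == 0

    def test_stimulated_and_silenced_overlap_rejected(self):
        g = generate_micro_fixture("chain3")
        with pytest.raises(SimulationError, match="stimulated and silenced"):
            simulate_trial(g, LifParams(), StimulusSpec(
                neurons=frozenset({"A"}), rate=10.0),
                silenced=SilenceSpec(frozenset({"A"})), seed=0)

    def test_inhibition_cannot_drive_spiking(self):
        g = generate_micro_fixture("inhibitory_pair")
        trains = simulate_trial(g, LifParams(w_syn=10.0), StimulusSpec(
            neurons=frozenset({"A"}), rate=300.0), seed=3)
        assert len(trains.spikes["A"]) > 0
        assert len(trains.spikes["B"]) == 0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            LifParams(v_thresh=-60.0)       # threshold below rest
        with pytest.raises(ValueError):
            LifParams(dt=2.0)               # dt exceeds spike delay
        with pytest.raises(ValueError):
            LifParams(tau_syn=0.0)


class TestDeterminismAndRates:
    def test_same_seed_identical_output(self):
        g = generate_micro_fixture("fanin")
        stim = StimulusSpec(neurons=frozenset({"A1", "A2", "A3"}), rate=150.0)
        a = simulate_trial(g, LifParams(w_syn=1.0), stim, seed=42)
        b = simulate_trial(g, LifParams(w_syn=1.0), stim, seed=42)
        for nid in g.neuron_ids:
            assert np.array_equal(a.spikes[nid], b.spikes[nid])

    def test_run_trials_seed_ladder_reproducible(self):
        g = generate_micro_fixture("fanin")
        stim = StimulusSpec(neurons=frozenset({"A1", "A2", "A3"}), rate=100.0)
        first = run_trials(g, LifParams(w_syn=1.0), stim, n_trials=5,
                           base_seed=9)
        second = run_trials(g, LifParams(w_syn=1.0), stim, n_trials=5,
                            base_seed=9)
        assert [t.rates for t in first] == [t.rates for t in second]
        assert [t.seed for t in first] == [9, 10, 11, 12, 13]

    def test_rate_is_count_over_window(self):
        g = generate_micro_fixture("chain3")
        # a single forced spike in the 1000 ms trial -> 1.0 Hz
        stim = _explicit(g, {"A": [500.0]})
        (summary,) = run_trials(g, LifParams(w_syn=0.0), stim, n_trials=1,
                                base_seed=0)
        assert summary.rates["A"] == pytest.approx(1.0)
        assert summary.rates["B"] == 0.0


class TestPoissonStimulation:
    def test_low_rate_count_matches_nominal(self, rng):
        counts = [len(poisson_train(rng, 20.0, (0.0, 1000.0), 2.2))
                  for _ in range(200)]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        # 20 Hz: refractory thinning is ~4%, within the 3 SE band of n=200
        assert abs(mean - 20.0) < 3 * se + 20.0 * 0.045

    def test_high_rate_count_matches_thinned_expectation(self, rng):
        rate, t_ref = 150.0, 2.2
        counts = [len(poisson_train(rng, rate, (0.0, 1000.0), t_ref))
                  for _ in range(200)]
        expected = rate / (1.0 + rate * t_ref / 1000.0)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_trains_respect_refractory(self, rng):
        for _ in range(20):
            t = poisson_train(rng, 400.0, (0.0, 500.0), 2.2)
            if len(t) > 1:
                assert np.diff(t).min() >= 2.2


class TestMonotonicity:
    def test_fanin_response_monotone_in_weight_and_rate(self):
        g = generate_micro_fixture("fanin")
        stim_ids = frozenset({"A1", "A2", "A3"})
        weights = (0.0, 0.6, 2.0)
        rates = (50.0, 300.0)
        p = {}
        for w in weights:
            for r in rates:
                hits = 0
                for k in range(20):
                    trains = simulate_trial(
                        g, LifParams(w_syn=w, trial_duration=500.0),
                        StimulusSpec(neurons=stim_ids, rate=r),
                        seed=1000 + k)
                    hits += len(trains.spikes["B"]) > 0
                p[(w, r)] = hits / 20
        tol = 0.05
        for r in rates:
            for w0, w1 in zip(weights, weights[1:]):
                assert p[(w1, r)] >= p[(w0, r)] - tol
        for w in weights:
            assert p[(w, 300.0)] >= p[(w, 50.0)] - tol
        assert p[(0.0, 300.0)] == 0.0 and p[(2.0, 300.0)] == 1.0


SPACED = np.arange(5.0, 500.0, 20.0)


class TestOracleEquivalence:
    """Coarse engine vs fine-step independent integrator.

    Verification cases use robustly supra- or sub-threshold drive, where
    every postsynaptic spike is locked to a discrete input event: there the
    two resolutions must agree spike for spike.
    """

    CASES = [
        ("chain3", 6.0, {"A": SPACED}, frozenset()),
        ("chain3", 0.39, {"A": np.arange(0.0, 500.0, 10.0)}, frozenset()),
        ("fanin", 4.0, {f"A{i}": SPACED for i in (1, 2, 3)}, frozenset()),
        ("diamond", 6.0, {"A": SPACED}, frozenset({"C"})),
        ("inhibitory_pair", 6.0, {"A": SPACED}, frozenset()),
    ]

    @pytest.mark.parametrize("name,w,trains,silenced", CASES,
                             ids=[c[0] + f"-w{c[1]}" for c in CASES])
    def test_spike_counts_exact_and_times_within_one_step(
            self, name, w, trains, silenced):
        g = generate_micro_fixture(name)
        params = LifParams(w_syn=w, trial_duration=500.0)
        sil = SilenceSpec(silenced)
        eng = simulate_trial(g, params, _explicit(g, trains), sil, seed=0)
        ora = oracle_simulate(g, params, trains, sil)
        for nid in g.neuron_ids:
            if nid in trains:
                continue
            e, o = eng.spikes[nid], ora.spikes[nid]
            assert len(e) == len(o), nid
            if len(e):
                assert np.max(np.abs(e - o)) <= params.dt + 1e-9, nid

    def test_oracle_zero_input_zero_spikes(self):
        g = generate_micro_fixture("chain3")
        out = oracle_simulate(g, LifParams(trial_duration=200.0), {"A": []})
        assert all(len(t) == 0 for t in out.spikes.values())

    def test_oracle_rejects_large_graphs(self):
        graph, _ = generate_reference(GeneratorConfig())
        with pytest.raises(SimulationError, match="50"):
            oracle_simulate(graph, LifParams(), {"GRN_L_00": [1.0]})

    def test_oracle_inhibitory_pair_silent(self):
        g = generate_micro_fixture("inhibitory_pair")
        out = oracle_simulate(g, LifParams(w_syn=10.0,
                                           trial_duration=200.0),
                              {"A": np.arange(1.0, 200.0, 5.0)})
        assert len(out.spikes["B"]) == 0
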