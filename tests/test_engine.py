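import numpy as np
import pytest

from condnet import engine
from condnet.compiler import compile_network
from condnet.engine import get_backend, initialize, run
from condnet.network import Network
from condnet.types import (
    Gate,
    ChannelType,
    channel_neuron,
    electrical_synapse,
    nonspiking_neuron,
    nonspiking_synapse,
    sodium_channel,
    spiking_neuron,
    spiking_synapse,
)


def single_neuron_model(ntype, dt=0.1, with_input=True):
    net = Network()
    net.add_population(ntype, 1, "n")
    if with_input:
        net.add_input("n", width=1)
    net.add_output("n", "voltage")
    return compile_network(net, dt)


class TestInitialize:
    def test_initial_voltage_defaults_to_vrest(self):
        model = single_neuron_model(nonspiking_neuron("n", Vrest=-60.0))
        state = initialize(model)
        assert state.V[0] == -60.0
        assert state.V_last[0] == -60.0

    def test_dynamic_gate_starts_at_steady_state(self):
        # K = 1 and V0 = E gives exponent zero -> z_inf = 0.5
        nap = sodium_channel("NaP", Kh=1.0, Eh=-60.0)
        nt = channel_neuron("c", channels=(nap,), Vrest=-60.0)
        model = single_neuron_model(nt)
        state = initialize(model)
        assert state.gate_b[0] == pytest.approx(0.5)

    def test_threshold_starts_at_theta0(self):
        model = single_neuron_model(spiking_neuron("s", theta0=2.5))
        state = initialize(model)
        assert state.theta[0] == pytest.approx(2.5)
        assert not state.delta.any()
        assert not state.buffer.any()


class TestApplyInputs:
    def test_routing(self, ns_type):
        net = Network()
        for k in range(3):
            net.add_population(ns_type, 1, f"n{k}")
        net.add_input("n1", width=1)
        model = compile_network(net, 0.1)
        np.testing.assert_allclose(engine.apply_inputs(model, [2.0]), [0, 2, 0])

    def test_no_inputs_zero(self, ns_type):
        net = Network()
        net.add_population(ns_type, 2, "p")
        model = compile_network(net, 0.1)
        np.testing.assert_allclose(engine.apply_inputs(model, []), [0, 0])

    def test_permutation_preserved(self, ns_type):
        net = Network()
        for k in range(2):
            net.add_population(ns_type, 1, f"n{k}")
        net.add_input("n1", width=1)
        net.add_input("n0", width=1)
        model = compile_network(net, 0.1)
        np.testing.assert_allclose(engine.apply_inputs(model, [5.0, 7.0]), [7.0, 5.0])

    def test_length_mismatch(self, ns_type):
        net = Network()
        net.add_population(ns_type, 1, "n")
        net.add_input("n")
        model = compile_network(net, 0.1)
        with pytest.raises(ValueError):
            engine.apply_inputs(model, [1.0, 2.0])


class TestGradedConductance:
    @pytest.fixture
    def model(self, ns_type):
        net = Network()
        net.add_population(ns_type, 1, "pre").add_population(ns_type, 1, "post")
        net.add_connection(
            "pre", "post", nonspiking_synapse(Gmax=1.0, Elo=0.0, Ehi=20.0)
        )
        return compile_network(net, 0.1)

    def test_linear_interpolation(self, model):
        G = engine.update_nonspiking_conductances(model, np.array([10.0, 0.0]))
        assert G[1, 0] == pytest.approx(0.5)

    def test_lower_clamp(self, model):
        G = engine.update_nonspiking_conductances(model, np.array([-5.0, 0.0]))
        assert G[1, 0] == 0.0

    def test_upper_clamp(self, model):
        G = engine.update_nonspiking_conductances(model, np.array([25.0, 0.0]))
        assert G[1, 0] == pytest.approx(1.0)


class TestSpikingConductance:
    @pytest.fixture
    def model(self, spk_type):
        net = Network()
        net.add_population(spk_type, 1, "pre").add_population(spk_type, 1, "post")
        net.add_connection("pre", "post", spiking_synapse(Gmax=1.0, tau_syn=1.0))
        return compile_network(net, 0.1)  # T_syn = 0.1

    def test_decay(self, model):
        state = initialize(model)
        state.G_spike[1, 0] = 1.0
        G = engine.decay_and_trigger_spiking_conductances(model, state)
        assert G[1, 0] == pytest.approx(0.9)

    def test_delayed_spike_resets_to_gmax(self, model):
        state = initialize(model)
        state.G_spike[1, 0] = 0.9
        state.buffer[0, 0] = -1.0  # delay is 0 -> read row 0
        G = engine.decay_and_trigger_spiking_conductances(model, state)
        assert G[1, 0] == pytest.approx(1.0)

    def test_geometric_decay_to_zero(self, model):
        state = initialize(model)
        state.G_spike[1, 0] = 1.0
        for _ in range(400):
            state.G_spike = engine.decay_and_trigger_spiking_conductances(model, state)
        assert state.G_spike[1, 0] < 1e-10


class TestChemicalCurrents:
    def test_zero_conductance_zero_current(self, two_neuron_net):
        model = compile_network(two_neuron_net, 0.1)
        I = engine.compute_chemical_currents(
            model, np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(2)
        )
        np.testing.assert_allclose(I, 0.0)

    def test_single_synapse_current(self, two_neuron_net):
        two_neuron_net.add_connection(
            "a", "b", nonspiking_synapse(Gmax=1.0, Esyn=-40.0, Elo=-60, Ehi=-40)
        )
        model = compile_network(two_neuron_net, 0.1)
        G = np.zeros((2, 2))
        G[1, 0] = 0.5
        V_last = np.array([0.0, -60.0])
        I = engine.compute_chemical_currents(model, G, np.zeros((2, 2)), V_last)
        assert I[1] == pytest.approx(0.5 * (-40.0 - (-60.0)))  # +10 nA

    def test_reversal_potential_nulls_current(self, two_neuron_net):
        two_neuron_net.add_connection(
            "a", "b", nonspiking_synapse(Gmax=1.0, Esyn=-40.0, Elo=-60, Ehi=-40)
        )
        model = compile_network(two_neuron_net, 0.1)
        G = np.zeros((2, 2))
        G[1, 0] = 0.5
        I = engine.compute_chemical_currents(
            model, G, np.zeros((2, 2)), np.array([0.0, -40.0])
        )
        assert I[1] == pytest.approx(0.0)


class TestElectricalCurrents:
    def test_bidirectional_pair(self, two_neuron_net):
        two_neuron_net.add_connection("a", "b", electrical_synapse(Gmax=0.5))
        model = compile_network(two_neuron_net, 0.1)
        I = engine.compute_electrical_currents(model, np.array([-40.0, -60.0]))
        np.testing.assert_allclose(I, [-10.0, 10.0])
        assert I.sum() == pytest.approx(0.0, abs=1e-12)

    def test_rectified_forward(self, two_neuron_net):
        two_neuron_net.add_connection(
            "a", "b", electrical_synapse(Gmax=0.5, rectified=True)
        )
        model = compile_network(two_neuron_net, 0.1)
        I = engine.compute_electrical_currents(model, np.array([-40.0, -60.0]))
        assert I[1] == pytest.approx(0.5 * 20.0)
        assert I[0] == pytest.approx(-0.5 * 20.0)

    def test_rectified_blocked(self, two_neuron_net):
        two_neuron_net.add_connection(
            "a", "b", electrical_synapse(Gmax=0.5, rectified=True)
        )
        model = compile_network(two_neuron_net, 0.1)
        I = engine.compute_electrical_currents(model, np.array([-60.0, -40.0]))
        np.testing.assert_allclose(I, 0.0)


class TestIonicCurrents:
    def test_all_gates_disabled_is_ohmic(self):
        ch = ChannelType("leaky", Gion=0.5, Eion=-20.0)
        nt = channel_neuron("c", channels=(ch,), Vrest=-60.0)
        model = single_neuron_model(nt)
        I = engine.compute_ionic_currents(
            model, np.array([-60.0]), np.zeros(1), np.zeros(1)
        )
        assert I[0] == pytest.approx(0.5 * (-20.0 + 60.0))

    def test_activation_half_at_gate_reversal(self):
        # a_inf(V=Ea) with Ka=1 is exactly 0.5
        assert engine.gate_steady_state(-40.0, 1.0, 0.05, -40.0) == pytest.approx(0.5)

    def test_nap_plugin_values(self):
        # Gna=2, m_inf=0.5, h=0.4, Ena=50, V=-60 -> 2*0.5*0.4*110 = 44 nA
        nap = sodium_channel("NaP", Gna=2.0, Ena=50.0, Km=1.0, Em=-60.0)
        nt = channel_neuron("c", channels=(nap,), Vrest=-60.0)
        model = single_neuron_model(nt)
        I = engine.compute_ionic_currents(
            model, np.array([-60.0]), np.array([0.4]), np.zeros(1)
        )
        # m_inf(-60) with Km=1, Em=-60 -> 0.5
        assert I[0] == pytest.approx(2.0 * 0.5 * 0.4 * 110.0)


class TestGating:
    def _model(self, tau_max=100.0, K=1.0, S=0.05, E=-60.0):
        ch = ChannelType(
            "g", Gion=1.0, Eion=50.0,
            gate_b=Gate(p=1.0, K=K, S=S, E=E, tau_max=tau_max),
        )
        nt = channel_neuron("c", channels=(ch,), Vrest=-60.0)
        return single_neuron_model(nt)

    def test_fixed_point(self):
        model = self._model()
        V = np.array([-50.0])
        zinf = engine.gate_steady_state(-50.0, 1.0, 0.05, -60.0)
        b, c = engine.update_gating(model, V, np.array([zinf]), np.zeros(1))
        assert b[0] == pytest.approx(zinf)

    def test_tau_at_gate_reversal(self):
        # V = E, K = 1: z_inf = 0.5 and tau = tau_max / 2
        tau = engine.gate_time_constant(-60.0, 1.0, 0.05, -60.0, 100.0)
        assert tau == pytest.approx(50.0)

    def test_euler_converges_to_analytic_relaxation(self):
        # at fixed V the gate relaxes exponentially; Euler at shrinking dt
        # converges to the closed form
        K, S, E, tau_max = 1.0, 0.05, -60.0, 100.0
        V = -55.0
        zinf = engine.gate_steady_state(V, K, S, E)
        tau = engine.gate_time_constant(V, K, S, E, tau_max)
        T = 40.0  # ms
        z0 = 0.1
        exact = zinf + (z0 - zinf) * np.exp(-T / tau)
        errors = []
        for dt in (0.1, 0.05, 0.025):
            ch = ChannelType(
                "g", Gion=1.0, Eion=50.0,
                gate_b=Gate(p=1.0, K=K, S=S, E=E, tau_max=tau_max),
            )
            nt = channel_neuron("c", channels=(ch,), Vrest=-60.0)
            model = single_neuron_model(nt, dt=dt)
            z = np.array([z0])
            for _ in range(int(round(T / dt))):
                z, _ = engine.update_gating(model, np.array([V]), z, np.zeros(1))
            errors.append(abs(z[0] - exact))
        assert errors[0] < 1e-3
        assert errors[2] < errors[0]  # first-order convergence


class TestMembraneIntegration:
    def test_hand_euler_step(self):
        nt = nonspiking_neuron("n", Cm=5.0, Gm=1.0, Vrest=0.0)
        model = single_neuron_model(nt, dt=0.1)
        V = engine.integrate_membrane(
            model, np.zeros(1), np.zeros(1), np.zeros(1), np.array([2.0])
        )
        assert V[0] == pytest.approx(0.04)

    def test_equilibrium_is_fixed(self):
        nt = nonspiking_neuron("n", Cm=5.0, Gm=1.0, Vrest=-55.0)
        model = single_neuron_model(nt, dt=0.1)
        V = engine.integrate_membrane(
            model, np.array([-55.0]), np.zeros(1), np.zeros(1), np.zeros(1)
        )
        assert V[0] == pytest.approx(-55.0)

    def test_charging_matches_closed_form(self):
        # V(t) = (I/Gm) * (1 - exp(-t/tau)), tau = Cm/Gm
        nt = nonspiking_neuron("n", Cm=5.0, Gm=1.0, Vrest=0.0)
        dt = 0.001
        model = single_neuron_model(nt, dt=dt)
        out = run(model, np.array([2.0]), n_steps=5000)
        t = np.arange(1, 5001) * dt
        exact = 2.0 * (1.0 - np.exp(-t / 5.0))
        assert np.max(np.abs(out[:, 0] - exact)) < 1e-3

    def test_nonfinite_guard(self):
        nt = nonspiking_neuron("n", Cm=5.0, Gm=1.0, Vrest=0.0)
        model = single_neuron_model(nt)
        with pytest.raises(FloatingPointError, match="neuron 0"):
            engine.integrate_membrane(
                model, np.array([np.nan]), np.zeros(1), np.zeros(1), np.zeros(1)
            )


class TestThresholdAndSpikes:
    def test_m_zero_threshold_constant(self):
        nt = spiking_neuron("s", theta0=1.0, m=0.0, tau_theta=5.0)
        model = single_neuron_model(nt)
        out = run(model, np.array([2.0]), n_steps=2000)
        state = initialize(model)
        be = get_backend(model)
        for _ in range(100):
            state, _ = be.step(state, [2.0])
        assert state.theta[0] == pytest.approx(1.0)

    def test_spike_resets_to_vrest(self):
        nt = spiking_neuron("s", Vrest=-10.0, theta0=1.0)
        model = single_neuron_model(nt)
        state = initialize(model)
        theta, delta, V = engine.update_thresholds_and_spikes(
            model, state, np.array([1.2])
        )
        assert delta[0] == -1.0
        assert V[0] == pytest.approx(-10.0)

    def test_subthreshold_no_spike(self):
        nt = spiking_neuron("s", theta0=1.0)
        model = single_neuron_model(nt)
        state = initialize(model)
        theta, delta, V = engine.update_thresholds_and_spikes(
            model, state, np.array([0.8])
        )
        assert delta[0] == 0.0
        assert V[0] == pytest.approx(0.8)


class TestDelaySchedule:
    def _two_spikers(self, delay):
        # presynaptic neuron driven hard so it spikes at a known step
        pre = spiking_neuron("pre", Cm=1.0, Gm=1.0, Vrest=0.0, theta0=1.0)
        post = spiking_neuron("post", Cm=1.0, Gm=1.0, Vrest=0.0, theta0=50.0)
        net = Network()
        net.add_population(pre, 1, "pre").add_population(post, 1, "post")
        net.add_input("pre", width=1)
        net.add_connection(
            "pre", "post", spiking_synapse(Gmax=1.0, tau_syn=100.0, delay=delay)
        )
        return compile_network(net, 0.1)

    @pytest.mark.parametrize("delay", [0, 3])
    def test_reset_happens_at_spike_plus_one_plus_delay(self, delay):
        model = self._two_spikers(delay)
        be = get_backend(model)
        state = be.initialize()
        spike_step = None
        reset_step = None
        for step in range(1, 100):
            state, _ = be.step(state, [20.0])
            if spike_step is None and state.delta[0] == -1.0:
                spike_step = step
            if reset_step is None and state.G_spike[1, 0] > 0.5:
                reset_step = step
                break
        assert spike_step is not None and reset_step is not None
        assert reset_step == spike_step + 1 + delay

    def test_no_spikes_buffer_stays_zero(self, ns_type):
        net = Network()
        net.add_population(ns_type, 2, "p")
        model = compile_network(net, 0.1)
        be = get_backend(model)
        state = be.initialize()
        for _ in range(50):
            state, _ = be.step(state)
        assert not state.buffer.any()


class TestRun:
    def test_empty_network_empty_output(self):
        net = Network()
        model = compile_network(net, 0.1)
        out = run(model, None, n_steps=5)
        assert out.shape == (5, 0)

    def test_zero_steps(self, ns_type):
        net = Network()
        net.add_population(ns_type, 1, "n")
        net.add_output("n", "voltage")
        model = compile_network(net, 0.1)
        assert run(model, None, n_steps=0).shape == (0, 1)

    def test_constant_equals_explicit_series(self, ns_type):
        net = Network()
        net.add_population(ns_type, 1, "n")
        net.add_input("n")
        net.add_output("n", "voltage")
        model = compile_network(net, 0.1)
        const = run(model, np.array([1.5]), n_steps=50)
        series = run(model, np.full((50, 1), 1.5))
        np.testing.assert_array_equal(const, series)

    def test_shape_1000_steps(self, ns_type):
        net = Network()
        for k in range(10):
            net.add_population(ns_type, 1, f"n{k}")
        net.add_output("n0", "voltage")
        model = compile_network(net, 0.1)
        assert run(model, None, n_steps=1000).shape == (1000, 1)

    def test_short_series_rejected(self, ns_type):
        net = Network()
        net.add_population(ns_type, 1, "n")
        net.add_input("n")
        model = compile_network(net, 0.1)
        with pytest.raises(ValueError, match="rows"):
            run(model, np.zeros((5, 1)), n_steps=10)
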