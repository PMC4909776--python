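import numpy as np
import pytest

from respsnn.snn_core import (
    DT_S,
    Connection,
    DEFAULT_KINETICS,
    LifParams,
    Network,
    NeuronState,
    derive_kinetic_constants,
    kinetic_step,
    membrane_spike_step,
    run_network,
    total_postsynaptic_potential,
)

# The five kinetic sets of the hardware design: (set, alpha, beta) and the
# published derived constants.
KINETIC_TABLE = [
    # set, alpha, beta, r_inf, tau_ms, A, B, C
    (5, 900, 100, 0.90, 1.0, 0.4500, 0.5000, 0.9500),
    (4, 450, 50, 0.90, 2.0, 0.2250, 0.7500, 0.9750),
    (3, 230, 20, 0.92, 4.0, 0.1150, 0.8750, 0.9900),
    (2, 115, 10, 0.92, 8.0, 0.0575, 0.9375, 0.9950),
    (1, 58, 5, 0.92, 15.9, 0.0290, 0.9685, 0.9975),
]


class TestKineticConstants:
    @pytest.mark.parametrize("idx,a,b,r_inf,tau,A,B,C", KINETIC_TABLE)
    def test_published_table_reproduced(self, idx, a, b, r_inf, tau, A, B, C):
        k = derive_kinetic_constants(a, b)
        assert round(k.r_inf, 2) == r_inf
        assert round(k.tau_r_ms, 1) == tau
        assert round(k.A, 4) == A
        assert round(k.B, 4) == B
        assert round(k.C, 4) == C

    def test_default_table_matches(self):
        for idx, a, b, *_ in KINETIC_TABLE:
            assert DEFAULT_KINETICS[idx] == derive_kinetic_constants(a, b)

    def test_no_binding_limit(self):
        k = derive_kinetic_constants(0.0, 100.0)
        assert k.A == 0.0 and k.r_inf == 0.0
        assert k.C == 1.0 - DT_S * 100.0

    def test_unstable_set_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            derive_kinetic_constants(1500.0, 600.0)  # dt*(a+b) > 1


class TestKineticStep:
    def test_rising_from_zero_matches_euler_oracle(self):
        k = DEFAULT_KINETICS[5]
        # one forward-Euler step of dr/dt = alpha(1-r) - beta r from r=0
        oracle = 0.0 + DT_S * (k.alpha * (1 - 0.0) - k.beta * 0.0)
        assert kinetic_step(0.0, True, k) == pytest.approx(oracle)
        assert kinetic_step(0.0, True, k) == pytest.approx(0.45)

    def test_decay_fixed_point_is_zero(self):
        for k in DEFAULT_KINETICS.values():
            assert kinetic_step(0.0, False, k) == 0.0

    def test_rising_converges_to_r_inf(self):
        k = DEFAULT_KINETICS[5]
        r = 0.0
        for _ in range(20):
            r = kinetic_step(r, True, k)
        assert abs(r - k.r_inf) < 1e-3
        assert abs(k.A / (1 - k.B) - k.r_inf) < 1e-12

    def test_decay_is_geometric_with_ratio_c(self):
        k = DEFAULT_KINETICS[2]
        r = 0.8
        for _ in range(10):
            r = kinetic_step(r, False, k)
        assert r == pytest.approx(0.8 * k.C**10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kinetic_step(1.5, True, DEFAULT_KINETICS[1])


class TestTpp:
    def test_empty_sum(self):
        assert total_postsynaptic_potential("a", [], np.array([])) == 0.0

    def test_single_connection(self):
        conns = [Connection("x", "a", 1, 1280.0)]
        assert total_postsynaptic_potential("a", conns, np.array([0.5])) == 640.0

    def test_exact_cancellation(self):
        conns = [Connection("x", "a", 1, 400.0), Connection("y", "a", 1, -500.0)]
        assert total_postsynaptic_potential("a", conns, np.array([1.0, 0.8])) == 0.0


class TestMembraneStep:
    def test_rest_is_fixed_point(self):
        out = membrane_spike_step(NeuronState(v=0.0), 0.0, theta=100.0)
        assert out.v == 0.0 and not out.spike

    def test_leak_shift_three(self):
        out = membrane_spike_step(NeuronState(v=8.0), 0.0, theta=100.0, leak_shift=3)
        assert out.v == pytest.approx(7.0)  # 8 - 8/8

    def test_spike_then_refractory_reset(self):
        n = membrane_spike_step(NeuronState(v=99.0), 1e6, theta=100.0)
        assert n.spike and n.refractory
        n2 = membrane_spike_step(n, 1e6, theta=100.0)  # huge input ignored
        assert n2.v == 0.0 and not n2.spike and not n2.refractory

    def test_history_shifts_every_step(self):
        n = NeuronState(spike_history=[1] + [0] * 19)
        out = membrane_spike_step(n, 0.0, theta=100.0)
        assert len(out.spike_history) == 20
        assert out.spike_history == [0] * 20


def two_neuron_net(backend="float", theta=50.0, **kw):
    conns = [Connection("a", "b", 5, 1000.0), Connection("b", "a", 5, -500.0)]
    return Network(["a", "b"], conns, LifParams(theta=theta), backend=backend, **kw)


class TestNetwork:
    def test_quiescence(self):
        net = two_neuron_net()
        for _ in range(50):
            net.step()
        assert np.all(net.v == 0) and not net.spikes.any()

    @pytest.mark.parametrize("backend", ["fixed", "float"])
    def test_connection_order_is_irrelevant(self, backend):
        conns = [
            Connection("a", "b", 5, 1000.0),
            Connection("b", "a", 5, -500.0),
            Connection("a", "a", 3, 200.0),
            Connection("b", "b", 2, 300.0),
        ]
        lif = LifParams(theta=40.0)
        n1 = Network(["a", "b"], conns, lif, backend=backend)
        n2 = Network(["a", "b"], conns[::-1], lif, backend=backend)
        for t in range(500):
            ext = {"a": 400.0} if t < 100 else None
            n1.step(external=ext)
            n2.step(external=ext)
        assert np.array_equal(n1._r, n2._r)
        assert np.array_equal(n1._v, n2._v)
        assert np.array_equal(n1.spikes, n2.spikes)

    @pytest.mark.parametrize("backend", ["fixed", "float"])
    def test_r_bounded_under_random_rasters(self, backend, rng):
        net = two_neuron_net(backend=backend, theta=20.0)
        for _ in range(2000):
            forced = {"a": bool(rng.random() < 0.4), "b": bool(rng.random() < 0.4)}
            net.step(forced_spikes=forced)
            r = net.r
            assert np.all(r >= 0.0) and np.all(r <= 1.0)

    def test_no_two_consecutive_spikes(self, rng):
        net = two_neuron_net(theta=10.0)
        prev = np.zeros(2, dtype=bool)
        for _ in range(3000):
            net.step(external={"a": float(rng.uniform(0, 200)),
                               "b": float(rng.uniform(0, 200))})
            assert not np.any(net.spikes & prev)
            prev = net.spikes

    def test_lif_approaches_constant_input_geometrically(self):
        net = Network(["a"], [], LifParams(theta=1e9), backend="float")
        tpp = 100.0
        errs = []
        for _ in range(40):
            net.step(external={"a": tpp})
            errs.append(tpp - net.v[0])
        ratios = np.array(errs[1:]) / np.array(errs[:-1])
        assert np.allclose(ratios, 1 - 2.0**-3)

    def test_refractory_step_pins_membrane_to_rest(self):
        net = Network(["a"], [], LifParams(theta=50.0), backend="float")
        net.step(external={"a": 1000.0})
        assert net.spikes[0]
        net.step(external={"a": 1000.0})
        assert net.v[0] == 0.0 and not net.spikes[0]

    def test_fan_in_limit_enforced(self):
        pres = [f"n{i}" for i in range(9)]
        conns = [Connection(p, "post", 1, 10.0) for p in pres]
        with pytest.raises(ValueError, match="fan-in"):
            Network(pres + ["post"], conns, LifParams(theta=10.0))

    def test_unknown_kinetic_set_rejected(self):
        with pytest.raises(ValueError, match="kinetic"):
            Network(["a"], [Connection("a", "a", 9, 1.0)], LifParams(theta=1.0))

    def test_fixed_step_matches_quantized_constant_oracle(self, rng):
        """One fixed-point kinetic step from a shared quantized state agrees
        with exact arithmetic on the 14-bit-quantized constants to within
        one LSB of the r word."""
        net = two_neuron_net(backend="fixed")
        A14 = np.floor(np.array([DEFAULT_KINETICS[5].A] * 2) * 2**14) / 2**14
        B14 = np.floor(np.array([DEFAULT_KINETICS[5].B] * 2) * 2**14) / 2**14
        C14 = np.floor(np.array([DEFAULT_KINETICS[5].C] * 2) * 2**14) / 2**14
        for _ in range(200):
            raw = rng.integers(0, 1 << 18, 2)
            net._r = raw.astype(np.int64)
            r_before = net.r
            spike_a = bool(rng.random() < 0.5)
            net._pulse[:] = 0
            net._pulse[net.index["a"]] = 1 if spike_a else 0
            net.step()
            gate = np.array([spike_a if c.pre == "a" else False
                             for c in net.connections])
            exact = np.where(gate, B14 * r_before + A14, C14 * r_before)
            assert np.all(exact - net.r >= -1e-12)
            assert np.all(exact - net.r <= 2.0**-18 + 1e-12)


class TestRunNetwork:
    def test_no_probes_only_advances_time(self):
        net = two_neuron_net()
        out = run_network(net, 10)
        assert net.t == 10
        assert out["v"].shape == (10, 0)

    def test_two_thousand_steps_is_one_second(self):
        net = two_neuron_net()
        out = run_network(net, 2000, probes=["a"])
        assert out["time_s"][-1] == pytest.approx(1.0)

    def test_unknown_probe_rejected(self):
        net = two_neuron_net()
        with pytest.raises(KeyError):
            run_network(net, 5, probes=["nope"])

    def test_deterministic_rasters(self):
        outs = []
        for _ in range(2):
            net = two_neuron_net(backend="fixed", theta=30.0)
            outs.append(run_network(
                net, 1000, probes=["a", "b"],
                external_fn=lambda t: {"a": 300.0},
            ))
        assert np.array_equal(outs[0]["spike"], outs[1]["spike"])
        assert np.array_equal(outs[0]["v"], outs[1]["v"])

    def test_n_steps_must_be_positive(self):
        with pytest.raises(ValueError):
            run_network(two_neuron_net(), 0)
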