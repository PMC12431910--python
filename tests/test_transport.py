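"""Exchange terms: linear velocity transport, history buffer, delayed transport."""
import numpy as np
import pytest

from replinet.dynamics import ModelSpec
from replinet.integrator import IntegratorConfig, integrate
from replinet.network import build_inline, build_roundabout
from replinet.transport import (
    HistoryBuffer,
    TransportSpec,
    delayed_transport,
    interpolate_history,
    linear_transport,
)


class TestLinearTransport:
    def test_uniform_states_give_zero(self):
        G = build_inline(3)
        states = np.tile([0.3, 0.7], (3, 1))
        assert np.all(linear_transport(states, G, 0.4) == 0.0)

    def test_chain_example(self):
        G = build_inline(3)
        states = np.array([[0.5, 0.5], [0.0, 1.0], [0.0, 1.0]])
        out = linear_transport(states, G, 0.1)
        np.testing.assert_allclose(out[0], [-0.05, 0.05])
        np.testing.assert_allclose(out[1], [0.05, -0.05])

    def test_row_sums_vanish_on_simplex(self, rng):
        G = build_roundabout()
        states = rng.dirichlet(np.ones(3), size=6)
        out = linear_transport(states, G, 0.25)
        assert np.max(np.abs(out.sum(axis=1))) < 1e-14

    def test_global_species_conservation(self, rng):
        G = build_roundabout()
        states = rng.dirichlet(np.ones(3), size=6)
        out = linear_transport(states, G, 0.25)
        assert np.max(np.abs(out.sum(axis=0))) < 1e-14

    def test_negative_velocity_rejected(self):
        G = build_inline(2)
        with pytest.raises(ValueError, match="negative"):
            linear_transport(np.tile([0.5, 0.5], (2, 1)), G, -0.1)

    def test_pure_diffusion_conserves_totals_over_time(self):
        # zero game: transport alone; per-species totals constant over T=50
        G = build_inline(3)
        model = ModelSpec(G, np.zeros((2, 2)), TransportSpec(kind="linear", nu=0.25))
        x0 = np.array([[0.9, 0.1], [0.2, 0.8], [0.5, 0.5]])
        traj = integrate(model, x0, IntegratorConfig(dt=0.05, t_end=50.0))
        totals = traj.states.sum(axis=1)
        assert np.max(np.abs(totals - totals[0])) < 1e-10


class TestHistoryBuffer:
    def make_cubic_history(self, dt=0.25, t_end=2.0):
        # y(t) = t^3 per component
        H = HistoryBuffer(0.0, np.zeros((1, 2)), np.zeros((1, 2)))
        t = 0.0
        while t < t_end - 1e-12:
            t += dt
            H.append(t, np.full((1, 2), t**3), np.full((1, 2), 3 * t**2))
        return H

    def test_stored_times_exact(self):
        H = self.make_cubic_history()
        np.testing.assert_array_equal(H.interpolate(0.5), np.full((1, 2), 0.125))

    def test_pre_history_is_initial_state(self):
        H = self.make_cubic_history()
        np.testing.assert_array_equal(H.interpolate(-3.0), np.zeros((1, 2)))

    def test_hermite_reproduces_cubics_exactly(self):
        H = self.make_cubic_history()
        for t in (0.1, 0.37, 1.113, 1.99):
            np.testing.assert_allclose(H.interpolate(t), t**3, atol=1e-14)

    def test_query_beyond_extension_rejected(self):
        H = self.make_cubic_history(t_end=1.0)
        with pytest.raises(ValueError, match="history covers"):
            H.interpolate(5.0)

    def test_times_must_increase(self):
        H = self.make_cubic_history(t_end=1.0)
        with pytest.raises(ValueError, match="increase"):
            H.append(0.5, np.zeros((1, 2)), np.zeros((1, 2)))

    def test_functional_alias(self):
        H = self.make_cubic_history()
        np.testing.assert_array_equal(interpolate_history(H, 0.25), H.interpolate(0.25))


class TestDelayedTransport:
    def test_constant_identical_history_gives_zero(self):
        G = build_inline(3)
        state = np.tile([0.2, 0.8], (3, 1))
        H = HistoryBuffer(0.0, state, np.zeros_like(state))
        H.append(1.0, state, np.zeros_like(state))
        out = delayed_transport(H, 1.0, G, p=2.0, tau=0.5, states=state)
        assert np.max(np.abs(out)) < 1e-15

    def test_zero_delay_reduces_to_unit_linear_transport(self, rng):
        G = build_roundabout()
        states = rng.dirichlet(np.ones(3), size=6)
        H = HistoryBuffer(0.0, states, np.zeros_like(states))
        out = delayed_transport(H, 0.0, G, p=0.0, tau=0.0, states=states)
        np.testing.assert_allclose(out, linear_transport(states, G, 1.0), atol=1e-15)

    def test_attenuation_factor(self):
        # single edge, p=2, tau=1/2: prefactor e^{-1}
        G = build_inline(2)
        x0 = np.array([[1.0, 0.0], [0.0, 1.0]])
        H = HistoryBuffer(0.0, x0, np.zeros_like(x0))
        H.append(1.0, x0, np.zeros_like(x0))  # constant history
        out = delayed_transport(H, 1.0, G, p=2.0, tau=0.5, states=x0)
        expected = np.exp(-1.0) * (x0[1] - x0[0])
        np.testing.assert_allclose(out[0], expected, rtol=1e-12)

    def test_negative_parameters_rejected(self):
        G = build_inline(2)
        x0 = np.tile([0.5, 0.5], (2, 1))
        H = HistoryBuffer(0.0, x0, np.zeros_like(x0))
        with pytest.raises(ValueError, match="negative"):
            delayed_transport(H, 0.0, G, p=-1.0, tau=0.0, states=x0)

    def test_continuous_in_time(self):
        # linear-in-t history => transport continuous across a stored knot
        G = build_inline(2)
        x0 = np.array([[0.6, 0.4], [0.4, 0.6]])
        rate = np.array([[0.01, -0.01], [-0.01, 0.01]])
        H = HistoryBuffer(0.0, x0, rate)
        for step in range(1, 11):
            t = 0.1 * step
            H.append(t, x0 + t * rate, rate)
        vals = [
            delayed_transport(H, t, G, p=1.0, tau=0.35, states=x0 + t * rate)
            for t in (0.499999, 0.5, 0.500001)
        ]
        assert np.max(np.abs(vals[2] - vals[0])) < 1e-6


class TestTransportSpec:
    def test_validation(self):
        with pytest.raises(ValueError, match="kind"):
            TransportSpec(kind="teleport")
        with pytest.raises(ValueError, match="nonnegative"):
            TransportSpec(kind="linear", nu=-1.0)
        with pytest.raises(ValueError, match="nonnegative"):
            TransportSpec(kind="delayed", tau=-0.5)

    def test_per_edge_override_priority(self):
        G = build_inline(3)
        G.set_edge_params(1, 2, nu=0.7)
        spec = TransportSpec(kind="linear", nu=0.1, per_edge={(2, 3): {"nu": 0.3}})
        assert spec.edge_value(G, 1, 2, "nu") == 0.7  # graph attribute wins
        assert spec.edge_value(G, 3, 2, "nu") == 0.3  # per-edge, order-insensitive
        assert spec.edge_value(G, 2, 1, "nu") == 0.7
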