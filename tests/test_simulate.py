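"""Stimulus schedules, promoter updates and the PDMP integrator."""

import math

import numpy as np
import pandas as pd
import pytest

from gcgrn import (
    CellState,
    SimulationProtocol,
    StimulusSchedule,
    promoter_transition_prob,
    simulate_cell,
    simulate_dataset,
    step_cell,
    stimulus_value,
)
from gcgrn.network import DegenerateRatesError
from gcgrn.simulate import _Engine, default_schedules


class TestStimulusSchedule:
    def test_default_bcr_profile(self):
        bcr = default_schedules()[0]
        assert stimulus_value(bcr, 10.0) == 1.0      # plateau
        assert stimulus_value(bcr, 1.0) == 0.5       # ramp midpoint
        assert stimulus_value(bcr, 30.0) == 0.0      # after ramp-down
        assert stimulus_value(bcr, -5.0) == 0.0
        assert stimulus_value(bcr, 24.5) == 0.5      # ramp-down midpoint

    def test_default_cd40_window(self):
        cd40 = default_schedules()[1]
        assert cd40.ramp_up == (35.0, 36.0)
        assert stimulus_value(cd40, 50.0) == 1.0
        assert stimulus_value(cd40, 61.0) == 0.0

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            StimulusSchedule("BCR", (2.0, 1.0), 24.0, 25.0)
        with pytest.raises(ValueError):
            StimulusSchedule("BCR", (0.5, 1.5), 26.0, 25.0)


class TestPromoterTransition:
    def test_zero_dt_returns_current_state(self):
        assert promoter_transition_prob(1, 0.3, 0.7, 0.0) == 1.0
        assert promoter_transition_prob(0, 0.3, 0.7, 0.0) == 0.0

    def test_long_time_reaches_stationary(self):
        pi = promoter_transition_prob(0, 0.3, 0.7, 1e6)
        assert pi == pytest.approx(0.3)

    def test_hand_value(self):
        # E=0, kon=koff=1, dt=ln(2)/2: 0.5*(1 - e^{-2 dt}) = 0.25
        assert promoter_transition_prob(0, 1.0, 1.0, math.log(2) / 2) == pytest.approx(0.25)

    def test_degenerate_rates_rejected(self):
        with pytest.raises(DegenerateRatesError):
            promoter_transition_prob(0, 0.0, 0.0, 0.1)

    def test_probability_range(self):
        rng = np.random.default_rng(0)
        kon = rng.uniform(0, 5, 100)
        koff = rng.uniform(0, 5, 100) + 1e-6
        pi = promoter_transition_prob(rng.integers(0, 2, 100), kon, koff, 0.3)
        assert np.all((pi >= 0) & (pi <= 1))


class TestExactIntegrator:
    def test_pure_decay_matches_closed_form(self, no_interaction_model):
        """With the promoter held off, stepping any number of dt steps equals
        the closed-form exponential decay (the per-step update is exact)."""
        net = no_interaction_model.compile()
        engine = _Engine(net, dt=0.37)
        M = np.array([[5.0, 2.0, 9.0]])
        P = np.array([[4.0, 1.0, 0.5]])
        E = np.zeros((1, 3), dtype=np.int8)
        q = np.zeros(2)
        u = np.ones((1, 3))  # u >= pi keeps every promoter off
        m, p = M.copy(), P.copy()
        for _ in range(40):
            E, m, p = engine.step(E, m, p, q, u)
        T = 40 * 0.37
        m_exact = M[0] * np.exp(-net.d0 * T)
        # P(t) = P0 e^{-d1 t} + s1 M0 (e^{-d0 t} - e^{-d1 t})/(d1 - d0)
        p_exact = P[0] * np.exp(-net.d1 * T) + net.s1 * M[0] * (
            np.exp(-net.d0 * T) - np.exp(-net.d1 * T)
        ) / (net.d1 - net.d0)
        np.testing.assert_allclose(m[0], m_exact, rtol=1e-8)
        np.testing.assert_allclose(p[0], p_exact, rtol=1e-8)

    def test_promoter_on_reaches_saturation(self, no_interaction_model):
        net = no_interaction_model.compile()
        engine = _Engine(net, dt=0.5)
        E = np.ones((1, 3), dtype=np.int8)
        M = np.zeros((1, 3))
        P = np.zeros((1, 3))
        u = np.zeros((1, 3))  # u < pi keeps every promoter on
        for _ in range(200):
            E, M, P = engine.step(E, M, P, np.zeros(2), u)
        np.testing.assert_allclose(M[0], net.s0 / net.d0, rtol=1e-6)
        np.testing.assert_allclose(P[0], net.s1 * net.s0 / (net.d1 * net.d0), rtol=1e-4)

    def test_equal_degradation_rates_limit(self):
        """d0 == d1 uses the analytic limit of the protein update."""
        from gcgrn import GENES, GeneParameters, InteractionParams, NetworkModel

        genes = tuple(
            GeneParameters(gene_id=g, s0=4.0, d0=0.2, s1=3.0, d1=0.2,
                           kon_init=0.5, koff_init=0.5)
            for g in GENES
        )
        model = NetworkModel(genes, InteractionParams({}, {})).calibrate()
        net = model.compile()
        engine = _Engine(net, dt=0.25)
        M = np.array([[2.0, 0.0, 7.0]])
        P = np.array([[1.0, 0.0, 0.0]])
        E = np.zeros((1, 3), dtype=np.int8)
        m, p = M.copy(), P.copy()
        for _ in range(30):
            E, m, p = engine.step(E, m, p, np.zeros(2), np.ones((1, 3)))
        T, d = 30 * 0.25, 0.2
        np.testing.assert_allclose(m[0], M[0] * np.exp(-d * T), rtol=1e-8)
        p_exact = (P[0] + 3.0 * M[0] * T) * np.exp(-d * T)
        np.testing.assert_allclose(p[0], p_exact, rtol=1e-8)


class TestSimulation:
    def short_protocol(self, **kw):
        base = dict(burn_in=20.0, post_stimulus=20.0, dt=0.1, sample_every=0.5,
                    n_cells=4, seed=7)
        base.update(kw)
        return SimulationProtocol(**base)

    def test_trajectory_sample_count(self, no_interaction_model, schedules):
        proto = self.short_protocol()
        traj, snaps = simulate_cell(no_interaction_model, schedules, proto, 0)
        assert len(traj) == int((proto.burn_in + proto.post_stimulus) / proto.sample_every) + 1
        assert traj["time"].iloc[0] == -20.0 and traj["time"].iloc[-1] == 20.0
        assert set(snaps) == {"GC", "PB_PC"}

    def test_default_protocol_yields_2001_samples(self):
        proto = SimulationProtocol()
        assert int((proto.burn_in + proto.post_stimulus) / proto.sample_every) + 1 == 2001

    def test_nonnegative_output(self, model_III, schedules):
        ds = simulate_dataset(model_III, schedules, self.short_protocol(n_cells=6))
        assert (ds.frame[["BCL6", "IRF4", "BLIMP1"]].to_numpy() >= 0).all()

    def test_dataset_shape_and_labels(self, no_interaction_model, schedules):
        ds = simulate_dataset(no_interaction_model, schedules, self.short_protocol(n_cells=3))
        assert ds.n_cells("GC") == 3 and ds.n_cells("PB_PC") == 3
        ds1 = simulate_dataset(no_interaction_model, schedules, self.short_protocol(n_cells=1))
        assert len(ds1.frame) == 2

    def test_seed_determinism(self, no_interaction_model, schedules):
        a = simulate_dataset(no_interaction_model, schedules, self.short_protocol())
        b = simulate_dataset(no_interaction_model, schedules, self.short_protocol())
        pd.testing.assert_frame_equal(a.frame, b.frame)
        c = simulate_dataset(no_interaction_model, schedules, self.short_protocol(seed=8))
        assert not a.frame.equals(c.frame)

    def test_cell_substreams_stable_under_population_size(self, no_interaction_model, schedules):
        """Cell i's snapshot is identical whether 2 or 4 cells are simulated."""
        small = simulate_dataset(no_interaction_model, schedules, self.short_protocol(n_cells=2))
        large = simulate_dataset(no_interaction_model, schedules, self.short_protocol(n_cells=4))
        for stage in ("GC", "PB_PC"):
            s = small.frame[small.frame.stage == stage].iloc[:2][["BCL6", "IRF4", "BLIMP1"]]
            l = large.frame[large.frame.stage == stage].iloc[:2][["BCL6", "IRF4", "BLIMP1"]]
            np.testing.assert_array_equal(s.to_numpy(), l.to_numpy())

    def test_promoter_occupancy_matches_stationary_law(self, no_interaction_model, schedules):
        """Time-averaged occupancy over a long constant-rate run converges to
        kon/(kon+koff) within 3 standard errors."""
        proto = SimulationProtocol(burn_in=50.0, post_stimulus=950.0, dt=0.1,
                                   sample_every=0.5, n_cells=20, seed=3)
        ds = simulate_dataset(no_interaction_model, [], proto)
        g = no_interaction_model.gene("BCL6")
        target_m = g.s0 / g.d0 * g.kon_init / (g.kon_init + g.koff_init)
        values = ds.stage_values("BCL6", "PB_PC")
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - target_m) < 3 * se + 0.05 * target_m

    def test_step_cell_advances_time_and_preserves_validity(self, model_I, schedules):
        rng = np.random.default_rng(0)
        state = CellState.empty(t=0.0)
        out = step_cell(state, model_I, schedules, 0.1, rng)
        assert out.t == pytest.approx(0.1)
        assert np.all(out.M >= 0) and np.all(out.P >= 0)
        assert set(np.unique(out.E)).issubset({0, 1})

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            SimulationProtocol(dt=1.0, sample_every=0.5)
        with pytest.raises(ValueError):
            SimulationProtocol(sample_every=0.7, dt=0.2)
        with pytest.raises(ValueError):
            SimulationProtocol(n_cells=0)
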