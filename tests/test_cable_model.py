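"""Solver and channel-kinetics behaviour: resting stability, propagation,
passive closed forms, determinism, symmetry and refinement convergence."""

import numpy as np
import pytest

from ranvier.cable_model import (ChannelKinetics, RestingState,
                                 SimulationConfig, simulate, resting_state)
from ranvier.geometry import build_axon
from ranvier.experiments import conduction_speed


class TestKinetics:
    def test_rates_positive_and_states_bounded(self, kinetics):
        v = np.linspace(-120, 60, 361)
        for gate, (a, b) in kinetics.rates(v).items():
            assert np.all(a > 0), gate
            assert np.all(b > 0), gate
        for gate, x in kinetics.steady_state(v).items():
            assert np.all((x >= 0) & (x <= 1)), gate

    def test_resting_activation_is_partial(self, kinetics):
        ss = kinetics.steady_state(-82.0)
        assert 0 < ss["m"] < 1
        assert 0.3 < ss["h"] < 1          # most fast Na available at rest
        assert ss["s"] < 0.1              # slow K mostly closed at rest

    def test_activation_increases_with_depolarisation(self, kinetics):
        v = np.linspace(-100, 20, 121)
        for gate in ("m", "p"):
            x = kinetics.steady_state(v)[gate]
            assert np.all(np.diff(x) > 0), gate
        # the slow-K sigmoids are only monotone above ~-90 mV (the published
        # rate forms are not meaningful below their fitted voltage range)
        v = np.linspace(-85, 20, 106)
        s = kinetics.steady_state(v)["s"]
        assert np.all(np.diff(s) > 0)

    def test_temperature_speeds_rates_not_steady_states(self):
        cold = ChannelKinetics(temperature=30.0)
        warm = ChannelKinetics(temperature=37.0)
        v = -50.0
        assert warm.time_constant(v)["m"] < cold.time_constant(v)["m"]
        assert warm.steady_state(v)["m"] == pytest.approx(
            cold.steady_state(v)["m"], rel=1e-12)


class TestRestingState:
    def test_small_residual_near_nominal_rest(self, optic_chain, kinetics):
        rest = resting_state(optic_chain, kinetics)
        v = (rest.v_i - rest.v_p)[optic_chain.node_index]
        # stationary point sits within ~2 mV of the nominal -82 mV
        assert np.all(np.abs(v + 82.0) < 2.0)
        assert rest.residual_mv_per_ms < 0.1

    def test_leak_only_chain_rests_at_leak_reversal(self, optic, kinetics):
        passive = optic.with_(g_Na=1e-12, g_Ks=1e-12, g_Nap=1e-12)
        chain = build_axon(passive, n_nodes=5)
        rest = resting_state(chain, kinetics)
        assert np.allclose(rest.v_i - rest.v_p, passive.E_Lk, atol=1e-6)

    def test_no_stimulus_stationarity(self, optic_chain, kinetics):
        cfg = SimulationConfig(dt=1e-3, duration=10.0, stim_amplitude=0.0)
        r = simulate(optic_chain, kinetics, cfg)
        drift = np.abs(r.v_node - r.v_node[0]).max()
        assert drift < 0.5


class TestPassiveClosedForm:
    def test_isolated_compartment_exponential_relaxation(self, optic, kinetics):
        """An axially decoupled leak-only node relaxes to E_Lk with tau = c/g."""
        passive = optic.with_(g_Na=1e-12, g_Ks=1e-12, g_Nap=1e-12,
                              rho_ax=1e12)   # decouple the compartments
        chain = build_axon(passive, n_nodes=2, internodal_compartments=66)
        rest = resting_state(chain, kinetics)
        v0 = rest.v_i.copy()
        v0 += 10.0                      # perturb every compartment
        init = RestingState(v_i=v0, v_p=rest.v_p, gates=rest.gates,
                            residual_mv_per_ms=0.0)
        cfg = SimulationConfig(dt=2.5e-4, duration=0.06, stim_amplitude=0.0,
                               stim_onset=0.0, stim_width=0.01)
        r = simulate(chain, kinetics, cfg, initial=init)
        idx = chain.node_index[0]
        tau = chain.c_mem[idx] / chain.g_channels["leak"][idx]  # ms (~11 us)
        expected = passive.E_Lk + (v0[idx] - passive.E_Lk) * np.exp(-r.time / tau)
        assert np.allclose(r.v_node[:, 0], expected, atol=0.6)
        # measured time constant from a log-linear fit (first-order scheme
        # bias is ~dt/2tau ~ 1%)
        sel = r.time <= 2 * tau
        logv = np.log(r.v_node[sel, 0] - passive.E_Lk)
        slope = np.polyfit(r.time[sel], logv, 1)[0]
        assert -1.0 / slope == pytest.approx(tau, rel=0.03)


class TestSimulate:
    def test_suprathreshold_spike_propagates(self, optic_chain, kinetics):
        cfg = SimulationConfig(stim_amplitude=1.0, stop_after_node=35)
        r = simulate(optic_chain, kinetics, cfg)
        assert not r.propagation_failed
        assert r.v_node[:, 30].max() > 0.0
        # action potential amplitude on the order of 100 mV
        amp = r.v_node[:, 30].max() - r.v_node[0, 30]
        assert 80.0 < amp < 130.0

    def test_subthreshold_stimulus_no_spike(self, optic_chain, kinetics):
        cfg = SimulationConfig(stim_amplitude=0.01, duration=1.5)
        r = simulate(optic_chain, kinetics, cfg)
        assert r.propagation_failed
        assert r.v_node[:, 10].max() < -60.0

    def test_bitwise_reproducible(self, optic, kinetics):
        chain = build_axon(optic, n_nodes=11)
        cfg = SimulationConfig(duration=1.0)
        r1 = simulate(chain, kinetics, cfg)
        r2 = simulate(chain, kinetics, cfg)
        assert np.array_equal(r1.v_node, r2.v_node)

    def test_mirror_symmetry(self, optic, kinetics):
        chain = build_axon(optic, n_nodes=11)
        fwd = simulate(chain, kinetics,
                       SimulationConfig(stim_node=0, duration=1.2))
        bwd = simulate(chain, kinetics,
                       SimulationConfig(stim_node=10, duration=1.2))
        assert np.allclose(fwd.v_node, bwd.v_node[:, ::-1], atol=1e-6)

    def test_internodal_axolemma_sees_small_voltage_change(self, optic_chain,
                                                           kinetics):
        """Most of the spike drops across the myelin stack: the internodal
        axolemma is depolarised by only a few mV."""
        cfg = SimulationConfig(record="all", record_stride=4,
                               stop_after_node=30)
        r = simulate(optic_chain, kinetics, cfg)
        mid_internode = (optic_chain.node_index[14]
                         + optic_chain.node_index[15]) // 2
        assert optic_chain.kind[mid_internode] == 2
        v_m = r.v_membrane[:, mid_internode]
        depol = v_m.max() - v_m[0]
        node_amp = r.v_node[:, 15].max() - r.v_node[0, 15]
        assert depol < 0.15 * node_amp
        assert 2.0 < depol < 15.0

    def test_threshold_bisection_brackets_firing(self, optic, kinetics):
        from ranvier.cable_model import find_threshold
        chain = build_axon(optic, n_nodes=9)
        cfg = SimulationConfig(duration=1.2)
        thr = find_threshold(chain, kinetics, cfg, lo=0.05, hi=4.0,
                             tol=0.1, check_node=6)
        assert 0.05 < thr < 4.0
        spk = simulate(chain, kinetics, SimulationConfig(
            duration=1.2, stim_amplitude=1.2 * thr))
        sub = simulate(chain, kinetics, SimulationConfig(
            duration=1.2, stim_amplitude=0.8 * thr))
        assert spk.v_node[:, 6].max() > 0
        assert sub.v_node[:, 6].max() < 0

    def test_dt_refinement_convergence(self, optic_chain, kinetics):
        """Conduction delay converges under dt refinement (stable to 0.5%)."""
        delays = []
        for dt in (1e-3, 5e-4, 2.5e-4):
            cfg = SimulationConfig(dt=dt, stop_after_node=35)
            r = simulate(optic_chain, kinetics, cfg)
            speed = conduction_speed(r, chain=optic_chain)
            delays.append(1.0 / speed)
        d1, d2, d3 = delays
        assert abs(d3 - d2) < abs(d2 - d1)          # monotone shrinkage
        richardson = d3 + (d3 - d2)                 # first-order extrapolation
        assert abs(d3 - richardson) / richardson < 0.005
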