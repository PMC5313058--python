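"""Double-cable action-potential propagation.

Integrates the coupled equations for the intracellular potential and the
periaxonal potential (the thin conductive space between the axolemma and the
innermost myelin membrane) along a :class:`~ranvier.geometry.CompartmentChain`.
Nodes of Ranvier carry Hodgkin–Huxley-type fast Na⁺ (m³h), persistent Na⁺
(p³) and slow K⁺ (s) channels; the juxtaparanodal K⁺ channels are omitted,
as only a small fraction of the action potential's voltage excursion appears
across the internodal axolemma (the rest drops across the myelin stack).
The extracellular space is grounded.

Numerics: backward-Euler on the linear cable terms (pentadiagonal banded
solve over interleaved intracellular/periaxonal unknowns), with gating
variables advanced by the exponential (Rush–Larsen) update at the previous
step's nodal voltages.  Default time step 0.25 µs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .geometry import CompartmentChain

__all__ = [
    "ChannelKinetics",
    "SimulationConfig",
    "SimulationResult",
    "SolverBlowUpError",
    "resting_state",
    "simulate",
    "find_threshold",
]


class SolverBlowUpError(RuntimeError):
    pass


def _vtrap(x, y):
    """x/(1−exp(−x/y)) with the removable singularity at x=0 handled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    safe = np.where(small, 1.0, x)
    return np.where(small, y * (1 + x / (2 * y)), safe / (1 - np.exp(-safe / y)))


@dataclass(frozen=True)
class ChannelKinetics:
    """Voltage-dependent gating kinetics of the nodal channels.

    Rate functions (ms⁻¹, voltages in mV) for the fast Na⁺ gates m and h,
    the persistent Na⁺ gate p and the slow K⁺ gate s, in the form used by
    the standard mammalian-node compartment models.  The fast Na⁺ rates are
    the human-node voltage-clamp measurements as originally reported at
    20 °C; the persistent Na⁺ and slow K⁺ rates are the standard published
    set referenced to 36 °C.  Each gate is scaled to ``temperature`` with
    its own Q10 factor.
    """

    temperature: float = 37.0
    base_temperature_mh: float = 20.0
    base_temperature_ps: float = 36.0
    q10_m: float = 2.2
    q10_h: float = 2.9
    q10_p: float = 2.2
    q10_s: float = 3.0

    def _q(self, q10: float, base: float) -> float:
        return q10 ** ((self.temperature - base) / 10.0)

    def rates(self, v) -> dict:
        """alpha/beta for each gate at membrane potential ``v`` (mV)."""
        v = np.asarray(v, dtype=float)
        qm = self._q(self.q10_m, self.base_temperature_mh)
        qh = self._q(self.q10_h, self.base_temperature_mh)
        qp = self._q(self.q10_p, self.base_temperature_ps)
        qs = self._q(self.q10_s, self.base_temperature_ps)
        a_m = qm * 1.86 * _vtrap(v + 18.4, 10.3)
        b_m = qm * 0.086 * _vtrap(-(v + 22.7), 9.16)
        a_h = qh * 0.0336 * _vtrap(-(v + 111.0), 11.0)
        b_h = qh * 2.3 / (1 + np.exp(-(v + 28.8) / 13.4))
        a_p = qp * 0.0353 * _vtrap(v + 27.0, 10.2)
        b_p = qp * 0.000883 * _vtrap(-(v + 34.0), 10.0)
        a_s = qs * 0.3 / (1 + np.exp(-(v + 53.0) / 5.0))
        b_s = qs * 0.03 / (1 + np.exp(-(v + 90.0) / 1.0))
        return {"m": (a_m, b_m), "h": (a_h, b_h), "p": (a_p, b_p), "s": (a_s, b_s)}

    def steady_state(self, v) -> dict:
        return {g: a / (a + b) for g, (a, b) in self.rates(v).items()}

    def time_constant(self, v) -> dict:
        return {g: 1.0 / (a + b) for g, (a, b) in self.rates(v).items()}

    @staticmethod
    def open_fractions(gates: dict) -> dict:
        """Channel open probabilities from gate values: m³h, p³, s."""
        return {"na": gates["m"] ** 3 * gates["h"],
                "nap": gates["p"] ** 3,
                "ks": gates["s"]}


@dataclass
class SimulationConfig:
    """Plumbing for one simulation run.

    Times in ms, stimulus amplitude in nA.  ``stop_after_node``: end the run
    ``stop_margin`` ms after that node's membrane potential first exceeds
    0 mV (saves time in sweeps); None integrates the full duration.
    ``record`` is ``"nodes"`` (nodal membrane potential every step) or
    ``"all"`` (every compartment, every ``record_stride`` steps).
    """

    dt: float = 2.5e-4
    duration: float = 4.0
    stim_node: int = 0
    stim_amplitude: float = 2.0
    stim_onset: float = 0.02
    stim_width: float = 0.1
    record: str = "nodes"
    record_stride: int = 8
    stop_after_node: int | None = None
    stop_margin: float = 0.15
    blowup_mv: float = 500.0
    seed: int = 0   # reserved; the solver is deterministic

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= self.stim_onset + self.stim_width:
            raise ValueError("duration must exceed stimulus onset + width")


@dataclass
class SimulationResult:
    """Voltage traces and gating histories from one run."""

    time: np.ndarray                 # ms, nodal recordings
    v_node: np.ndarray               # (n_steps, n_nodes) nodal membrane potential, mV
    gate_history: dict               # gate -> (n_steps, n_nodes)
    v_all_time: np.ndarray | None    # strided time base for full recordings
    v_membrane: np.ndarray | None    # (n_rec, n_comp) axonal transmembrane potential
    v_periaxonal: np.ndarray | None  # (n_rec, n_comp)
    config: SimulationConfig = None
    geometry_hash: str = ""
    initial_residual_mv_per_ms: float = 0.0
    propagation_failed: bool = False


def _geometry_hash(chain: CompartmentChain) -> str:
    h = hashlib.sha256()
    for arr in (chain.kind, chain.length, chain.diameter, chain.c_mem,
                chain.c_my, chain.g_my, chain.r_ax, chain.r_p):
        h.update(np.ascontiguousarray(arr).tobytes())
    for g in chain.g_channels.values():
        h.update(np.ascontiguousarray(g).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# linear system assembly
# ---------------------------------------------------------------------------

class _System:
    """Precomputed banded backward-Euler system for one chain and dt.

    Unknowns are interleaved [v_i0, v_p0, v_i1, v_p1, ...]; node periaxonal
    rows are identity (clamped to ground).  Bandwidth (2, 2).
    """

    def __init__(self, chain: CompartmentChain, dt: float):
        n = chain.n_compartments
        self.n = n
        self.chain = chain
        self.dt = dt
        is_node = chain.kind == 0
        self.is_node = is_node
        self.node_idx = chain.node_index

        self._a = 1.0 / chain.r_ax                 # nS (1/GΩ)
        with np.errstate(divide="ignore"):
            self._b = np.where(chain.r_p > 0, 1.0 / chain.r_p, 0.0)

        self.cdt = chain.c_mem / dt                # pF/ms = nS
        self.cmydt = chain.c_my / dt
        g_leak = chain.g_channels["leak"]
        self.g_static = g_leak
        self.b_static = g_leak * chain.e_channels["leak"]
        self.ab_base = self._assemble(self.cdt, self.cmydt)

    def _assemble(self, cdt, cmydt) -> np.ndarray:
        """Banded matrix (5 × 2n, (l,u)=(2,2)) of the implicit linear system."""
        n = self.n
        chain = self.chain
        a, b = self._a, self._b
        ab = np.zeros((5, 2 * n))
        ii = np.arange(n)
        ri, rp = 2 * ii, 2 * ii + 1
        a_left = np.concatenate([[0.0], a])
        a_right = np.concatenate([a, [0.0]])
        b_left = np.concatenate([[0.0], b])
        b_right = np.concatenate([b, [0.0]])
        cg = cdt + self.g_static

        def put(rows, cols, vals):
            ab[2 + rows - cols, cols] = vals

        # intracellular rows: C/dt (v_m − V_m) + G v_m − axial = RHS
        put(ri, ri, cg + a_left + a_right)
        put(ri, rp, -cg)
        put(ri[1:], ri[:-1], -a)
        put(ri[:-1], ri[1:], -a)
        # periaxonal rows for myelinated compartments; identity rows at nodes
        my = ~self.is_node
        put(rp[my], rp[my], (cmydt + chain.g_my + cg + b_left + b_right)[my])
        put(rp[my], ri[my], -cg[my])
        msk = my[1:]
        put(rp[1:][msk], rp[:-1][msk], -b[msk])
        msk = my[:-1]
        put(rp[:-1][msk], rp[1:][msk], -b[msk])
        put(rp[self.is_node], rp[self.is_node], 1.0)
        return ab

    def solve_step(self, v_i, v_p, g_dyn, b_dyn, i_stim_pa):
        """Advance one backward-Euler step; returns (v_i, v_p)."""
        n = self.n
        v_m = v_i - v_p
        ab = self.ab_base.copy()
        cols = 2 * self.node_idx
        ab[2, cols] += g_dyn

        rhs = np.empty(2 * n)
        rhs[0::2] = self.cdt * v_m + self.b_static
        rhs[0::2][self.node_idx] += b_dyn
        rhs[0::2] += i_stim_pa
        peri = self.cmydt * v_p - self.cdt * v_m - self.b_static
        peri[self.is_node] = 0.0
        rhs[1::2] = peri

        u = solve_banded((2, 2), ab, rhs, check_finite=False)
        return u[0::2], u[1::2]

    def steady_solve(self, g_dyn, b_dyn):
        """Solve the pure-conductance (dt→∞) network for the stationary state."""
        zero = np.zeros(self.n)
        ab = self._assemble(zero, zero)
        cols = 2 * self.node_idx
        ab[2, cols] += g_dyn
        # node v_p coupling column must not zero the membrane term
        ab[1, cols + 1] = ab[1, cols + 1] - g_dyn
        rhs = np.zeros(2 * self.n)
        rhs[0::2] = self.b_static
        rhs[0::2][self.node_idx] += b_dyn
        rhs[1::2] = np.where(self.is_node, 0.0, -self.b_static)
        u = solve_banded((2, 2), ab, rhs, check_finite=False)
        return u[0::2], u[1::2]


# ---------------------------------------------------------------------------
# resting state
# ---------------------------------------------------------------------------

@dataclass
class RestingState:
    v_i: np.ndarray
    v_p: np.ndarray
    gates: dict                      # gate -> per-node array
    residual_mv_per_ms: float        # max |dV/dt| at the initial state


def _nodal_dynamic(chain: CompartmentChain, kinetics: ChannelKinetics, gates: dict):
    """Absolute gated conductance (nS) and current source (pA·mV⁻¹-free term)."""
    open_f = ChannelKinetics.open_fractions(gates)
    idx = chain.node_index
    g_na = chain.g_channels["na"][idx] * open_f["na"]
    g_nap = chain.g_channels["nap"][idx] * open_f["nap"]
    g_ks = chain.g_channels["ks"][idx] * open_f["ks"]
    g_dyn = g_na + g_nap + g_ks
    b_dyn = (g_na + g_nap) * chain.e_channels["na"] + g_ks * chain.e_channels["ks"]
    return g_dyn, b_dyn


def _dvdt(chain: CompartmentChain, sys: _System, kinetics: ChannelKinetics,
          v_i, v_p, gates) -> np.ndarray:
    """Membrane dV/dt (mV/ms) of every compartment at a given state."""
    n = chain.n_compartments
    v_m = v_i - v_p
    g_dyn, b_dyn = _nodal_dynamic(chain, kinetics, gates)
    i_ion = sys.g_static * v_m - sys.b_static
    i_ion[chain.node_index] += g_dyn * v_m[chain.node_index] - b_dyn
    a = 1.0 / chain.r_ax
    ax = np.zeros(n)
    ax[:-1] += a * (v_i[1:] - v_i[:-1])
    ax[1:] += a * (v_i[:-1] - v_i[1:])
    return (ax - i_ion) / chain.c_mem


def resting_state(chain: CompartmentChain, kinetics: ChannelKinetics | None = None,
                  n_iter: int = 8) -> RestingState:
    """Stationary state of the chain with no stimulus.

    Starts from the nominal resting potential with gates at their
    steady-state values, then fixed-point iterates the pure-conductance
    network (gates re-equilibrated to the local nodal voltage each round).
    The residual ``max |dV/dt|`` at the returned state is reported rather
    than silently re-tuned away: the leak reversal is calibrated by the
    source kinetics to make the resting potential near-stationary, not
    exactly so.
    """
    kinetics = kinetics or ChannelKinetics()
    sys = _System(chain, dt=1.0)
    e_r = chain.params.E_r
    v_node = np.full(chain.n_nodes, e_r)
    for _ in range(n_iter):
        gates = {g: np.asarray(x) for g, x in kinetics.steady_state(v_node).items()}
        g_dyn, b_dyn = _nodal_dynamic(chain, kinetics, gates)
        v_i, v_p = sys.steady_solve(g_dyn, b_dyn)
        v_node = (v_i - v_p)[chain.node_index]
    residual = float(np.max(np.abs(_dvdt(chain, sys, kinetics, v_i, v_p, gates))))
    return RestingState(v_i=v_i, v_p=v_p, gates=gates,
                        residual_mv_per_ms=residual)


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------

def step(state: tuple, sys: _System, kinetics: ChannelKinetics,
         i_stim_pa: np.ndarray):
    """Advance (v_i, v_p, gates) one time step of ``sys.dt``."""
    v_i, v_p, gates = state
    chain = sys.chain
    v_node = (v_i - v_p)[chain.node_index]
    rates = kinetics.rates(v_node)
    new_gates = {}
    for g, (a, b) in rates.items():
        inf = a / (a + b)
        tau = 1.0 / (a + b)
        new_gates[g] = inf + (gates[g] - inf) * np.exp(-sys.dt / tau)
    g_dyn, b_dyn = _nodal_dynamic(chain, kinetics, new_gates)
    v_i, v_p = sys.solve_step(v_i, v_p, g_dyn, b_dyn, i_stim_pa)
    return v_i, v_p, new_gates


def simulate(chain: CompartmentChain, kinetics: ChannelKinetics | None = None,
             config: SimulationConfig | None = None,
             initial: RestingState | None = None) -> SimulationResult:
    """Run one deterministic simulation of the chain.

    A suprathreshold stimulus at the target node elicits an action potential
    of ~100 mV amplitude that propagates along the chain; failure to reach
    the distal measurement region is flagged on the result, not raised.
    """
    kinetics = kinetics or ChannelKinetics()
    config = config or SimulationConfig()
    rest = initial or resting_state(chain, kinetics)
    sys = _System(chain, config.dt)

    n = chain.n_compartments
    n_steps = int(round(config.duration / config.dt))
    v_i = rest.v_i.copy()
    v_p = rest.v_p.copy()
    gates = {g: np.asarray(x, dtype=float).copy() for g, x in rest.gates.items()}

    stim_comp = chain.node_index[config.stim_node]
    i_stim = np.zeros(n)
    record_all = config.record == "all"
    times = np.empty(n_steps + 1)
    v_node_hist = np.empty((n_steps + 1, chain.n_nodes))
    gate_hist = {g: np.empty((n_steps + 1, chain.n_nodes)) for g in gates}
    if record_all:
        n_rec = n_steps // config.record_stride + 1
        v_all_t = np.empty(n_rec)
        v_m_all = np.empty((n_rec, n))
        v_p_all = np.empty((n_rec, n))

    def rec(i, t):
        times[i] = t
        v_node_hist[i] = (v_i - v_p)[chain.node_index]
        for g in gates:
            gate_hist[g][i] = gates[g]

    rec(0, 0.0)
    if record_all:
        v_all_t[0] = 0.0
        v_m_all[0] = v_i - v_p
        v_p_all[0] = v_p
        i_rec = 1

    stop_comp = (chain.node_index[config.stop_after_node]
                 if config.stop_after_node is not None else None)
    stop_time = None
    last = 0
    for i in range(1, n_steps + 1):
        t = i * config.dt
        on = config.stim_onset <= t - config.dt / 2 < config.stim_onset + config.stim_width
        i_stim[stim_comp] = config.stim_amplitude * 1e3 if on else 0.0
        v_i, v_p, gates = step((v_i, v_p, gates), sys, kinetics, i_stim)
        rec(i, t)
        if record_all and i % config.record_stride == 0:
            v_all_t[i_rec] = t
            v_m_all[i_rec] = v_i - v_p
            v_p_all[i_rec] = v_p
            i_rec += 1
        vmax = np.max(np.abs(v_i))
        if vmax > config.blowup_mv:
            comp = int(np.argmax(np.abs(v_i)))
            raise SolverBlowUpError(
                f"solution diverged at t={t:.4f} ms in compartment {comp} "
                f"(|V|={vmax:.0f} mV)"
            )
        if stop_comp is not None and stop_time is None and (v_i - v_p)[stop_comp] > 0:
            stop_time = t + config.stop_margin
        last = i
        if stop_time is not None and t >= stop_time:
            break

    sl = slice(0, last + 1)
    spiked = bool(np.max(v_node_hist[sl], axis=0)[chain.n_nodes * 3 // 5] > 0)
    result = SimulationResult(
        time=times[sl].copy(),
        v_node=v_node_hist[sl].copy(),
        gate_history={g: h[sl].copy() for g, h in gate_hist.items()},
        v_all_time=v_all_t[:i_rec].copy() if record_all else None,
        v_membrane=v_m_all[:i_rec].copy() if record_all else None,
        v_periaxonal=v_p_all[:i_rec].copy() if record_all else None,
        config=config,
        geometry_hash=_geometry_hash(chain),
        initial_residual_mv_per_ms=rest.residual_mv_per_ms,
        propagation_failed=not spiked,
    )
    return result


def find_threshold(chain: CompartmentChain, kinetics: ChannelKinetics | None = None,
                   config: SimulationConfig | None = None,
                   lo: float = 0.05, hi: float = 8.0, tol: float = 0.02,
                   check_node: int | None = None) -> float:
    """Threshold stimulus amplitude (nA) by bisection.

    A trial counts as suprathreshold when a spike (V > 0 mV) reaches
    ``check_node`` (default: 10 nodes past the stimulus).
    """
    kinetics = kinetics or ChannelKinetics()
    config = config or SimulationConfig()
    rest = resting_state(chain, kinetics)
    if check_node is None:
        check_node = min(config.stim_node + 10, chain.n_nodes - 1)

    def spikes(amp):
        cfg = SimulationConfig(**{**config.__dict__, "stim_amplitude": amp,
                                  "stop_after_node": check_node})
        r = simulate(chain, kinetics, cfg, initial=rest)
        return bool(np.max(r.v_node[:, check_node]) > 0)

    if not spikes(hi):
        raise ValueError(f"upper bracket {hi} nA is subthreshold")
    if spikes(lo):
        raise ValueError(f"lower bracket {lo} nA is suprathreshold")
    while hi - lo > tol * hi:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi
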