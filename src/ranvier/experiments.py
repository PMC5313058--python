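"""In-silico conduction-speed experiments.

Every experiment reduces to building a :class:`CompartmentChain`, running
:func:`~ranvier.cable_model.simulate`, and measuring the conduction speed
mid-axon (between nodes 20 and 30 of a 51-node chain, far from the stimulus
and the sealed ends).  Two channel-scaling assumptions are supported when
node length is varied:

``constant_density``
    nodal conductance densities are those of the preset, so the *number*
    of channels grows in proportion to node length;
``constant_number``
    the channel number is pinned at the value for the preset's mean node
    length, so densities scale as (mean length / length).

Repeated simulations with identical inputs are memoised per process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry import (CableParameters, CompartmentChain, build_axon,
                       load_preset, InvalidParameterError)
from .cable_model import (ChannelKinetics, SimulationConfig, SimulationResult,
                          simulate, resting_state)

__all__ = [
    "PropagationFailure",
    "SweepResult",
    "conduction_speed",
    "scale_nodal_channels",
    "axon_speed",
    "baseline_speed",
    "sweep_node_length",
    "sweep_internode_length",
    "sweep_wraps",
    "speed_matched_equivalents",
    "alternating_node_axon",
    "propagation_delay",
    "NODE_LENGTH_RANGE",
]

MEASURE_FIRST, MEASURE_LAST = 20, 30

#: measured node-length ranges (µm) per preset
NODE_LENGTH_RANGE = {"optic_nerve": (0.5, 2.2), "cortex": (0.43, 3.7)}


class PropagationFailure(RuntimeError):
    """No action potential reached a measurement node."""


@dataclass
class SweepResult:
    """Table of (varied parameter value, conduction speed) with metadata."""

    preset: str
    mode: str
    parameter: str
    values: np.ndarray
    speeds: np.ndarray            # m/s; NaN where propagation failed
    baseline_speed: float
    baseline_value: float

    @property
    def percent_change(self) -> np.ndarray:
        return 100.0 * (self.speeds / self.baseline_speed - 1.0)

    def max_spread_percent(self, relative_to: str = "min") -> float:
        """Largest speed spread across the sweep.

        ``relative_to='min'``: 100·(max−min)/min (max relative to min, the
        convention matching the published spread figures);
        ``relative_to='baseline'``: max−min of the percent changes.
        """
        ok = self.speeds[np.isfinite(self.speeds)]
        if ok.size < 2:
            raise PropagationFailure("not enough successful points in sweep")
        if relative_to == "min":
            return float(100.0 * (ok.max() - ok.min()) / ok.min())
        pc = self.percent_change
        pc = pc[np.isfinite(pc)]
        return float(pc.max() - pc.min())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "preset": self.preset, "mode": self.mode,
            "parameter": self.parameter, "value": self.values,
            "speed_mps": self.speeds, "pct_change": self.percent_change,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# speed measurement
# ---------------------------------------------------------------------------

def _spike_time(t: np.ndarray, v: np.ndarray, threshold: float = -20.0) -> float:
    """First upward crossing of ``threshold``, linearly interpolated (ms)."""
    above = v >= threshold
    if not above.any() or above[0]:
        raise PropagationFailure("no upward threshold crossing in trace")
    i = int(np.argmax(above))
    return float(np.interp(threshold, [v[i - 1], v[i]], [t[i - 1], t[i]]))


def conduction_speed(result: SimulationResult, first_node: int = MEASURE_FIRST,
                     last_node: int = MEASURE_LAST,
                     chain: CompartmentChain | None = None,
                     threshold: float = -20.0,
                     marker: str = "threshold") -> float:
    """Conduction speed (m/s) between two node centres.

    Spike time at each node is the linearly interpolated upward crossing of
    ``threshold`` mV (``marker='threshold'``) or the voltage-peak time
    (``marker='peak'``).  Raises :class:`PropagationFailure` when no spike
    reaches either node.
    """
    if chain is None:
        raise ValueError("chain is required to locate node centres")
    t = result.time
    if marker == "peak":
        times = []
        for node in (first_node, last_node):
            v = result.v_node[:, node]
            if v.max() < 0.0:
                raise PropagationFailure(f"no spike at node {node}")
            times.append(t[int(np.argmax(v))])
        t0, t1 = times
    else:
        t0 = _spike_time(t, result.v_node[:, first_node], threshold)
        t1 = _spike_time(t, result.v_node[:, last_node], threshold)
    if t1 <= t0:
        raise PropagationFailure("spike order inconsistent with propagation")
    dist_um = float(chain.node_positions[last_node]
                    - chain.node_positions[first_node])
    return dist_um / (t1 - t0) * 1e-3


def scale_nodal_channels(params: CableParameters, node_length: float,
                         mode: str) -> CableParameters:
    """Preset adjusted to a new node length under one channel-scaling mode.

    ``constant_density`` leaves conductance densities unchanged;
    ``constant_number`` multiplies the nodal densities (fast/persistent Na⁺,
    slow K⁺ and the nodal leak) by (mean node length / node_length), keeping
    the absolute channel number at its mean-node-length value.
    """
    if node_length <= 0:
        raise InvalidParameterError("node_length must be positive")
    if mode not in ("constant_density", "constant_number"):
        raise ValueError(f"unknown mode {mode!r}")
    changes = {"L_node": node_length}
    if mode == "constant_number":
        f = params.L_node / node_length
        changes.update(g_Na=params.g_Na * f, g_Ks=params.g_Ks * f,
                       g_Nap=params.g_Nap * f, g_L_node=params.g_L_node * f)
    return params.with_(**changes)


# ---------------------------------------------------------------------------
# one-shot speed runner (memoised)
# ---------------------------------------------------------------------------

_SPEED_CACHE: dict = {}


def _as_params(preset) -> CableParameters:
    return preset if isinstance(preset, CableParameters) else load_preset(preset)


def axon_speed(preset, node_length: float | None = None,
               mode: str = "constant_density",
               internode_length: float | None = None,
               n_wraps: int | None = None,
               na_density_factor: float = 1.0,
               node_lengths=None,
               n_nodes: int = 51,
               dt: float = 2.5e-4,
               kinetics: ChannelKinetics | None = None,
               stim_amplitude: float = 2.0,
               marker: str = "threshold") -> float:
    """Conduction speed (m/s) of one axon configuration.

    ``node_length`` changes every node (internode length held fixed);
    ``node_lengths`` gives per-node lengths instead (e.g. alternating
    axons); ``internode_length`` rescales the internodal region (the
    compartment count is re-derived to keep the compartment size, and hence
    the paranodal resolution, of the preset); ``n_wraps`` overrides the
    myelin wrap count; ``na_density_factor`` scales the nodal fast-Na⁺
    density only.  Channel-scaling ``mode`` applies to node-length changes.
    """
    params = _as_params(preset)
    key = (params, node_length, mode, internode_length, n_wraps,
           na_density_factor, None if node_lengths is None else tuple(node_lengths),
           n_nodes, dt, stim_amplitude, marker,
           kinetics if kinetics is not None else None)
    if key in _SPEED_CACHE:
        return _SPEED_CACHE[key]

    mean_length = params.L_node
    if node_length is not None:
        params = scale_nodal_channels(params, node_length, mode)
    if na_density_factor != 1.0:
        params = params.with_(g_Na=params.g_Na * na_density_factor)

    n_int = params.n_internodal_compartments
    if internode_length is not None:
        dl_ref = params.L_internode / n_int
        n_int = max(5, int(round(internode_length / dl_ref)))
        params = params.with_(L_internode=internode_length)

    density_scale = None
    if node_lengths is not None:
        node_lengths = np.asarray(node_lengths, dtype=float)
        if mode == "constant_number":
            density_scale = mean_length / node_lengths

    chain = build_axon(params, n_nodes=n_nodes,
                       internodal_compartments=n_int,
                       node_length_override=node_lengths,
                       nodal_density_scale=density_scale,
                       n_wraps=n_wraps)
    kin = kinetics or ChannelKinetics()
    cfg = SimulationConfig(dt=dt, stim_amplitude=stim_amplitude,
                           stop_after_node=min(MEASURE_LAST + 5, n_nodes - 1))
    result = simulate(chain, kin, cfg)
    if result.propagation_failed:
        raise PropagationFailure(
            f"no spike reached the measurement region ({params.name})")
    speed = conduction_speed(result, chain=chain, marker=marker)
    _SPEED_CACHE[key] = speed
    return speed


def baseline_speed(preset, **kw) -> float:
    """Speed at the preset's mean node length (identical in both modes)."""
    return axon_speed(preset, **kw)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def sweep_node_length(preset, lengths=None, mode: str = "constant_density",
                      **kw) -> SweepResult:
    """Speed as a function of node length, internodal region length fixed."""
    params = _as_params(preset)
    if lengths is None:
        lo, hi = NODE_LENGTH_RANGE.get(params.name, (0.5, 2.2))
        lengths = np.linspace(lo, hi, 25)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0) or np.any(lengths > 5.0):
        raise InvalidParameterError("node lengths must lie in (0, 5] µm")
    base = axon_speed(params, **kw)
    speeds = np.full(lengths.size, np.nan)
    for i, L in enumerate(lengths):
        try:
            speeds[i] = axon_speed(params, node_length=float(L), mode=mode, **kw)
        except PropagationFailure:
            pass
    return SweepResult(preset=params.name, mode=mode, parameter="node_length_um",
                       values=lengths, speeds=speeds, baseline_speed=base,
                       baseline_value=params.L_node)


def sweep_internode_length(preset, internode_lengths,
                           node_length: float | None = None,
                           mode: str = "constant_density", **kw) -> SweepResult:
    """Speed as a function of internode length at a given node length."""
    params = _as_params(preset)
    lengths = np.asarray(internode_lengths, dtype=float)
    base = axon_speed(params, node_length=node_length, mode=mode, **kw)
    speeds = np.full(lengths.size, np.nan)
    for i, L in enumerate(lengths):
        try:
            speeds[i] = axon_speed(params, node_length=node_length, mode=mode,
                                   internode_length=float(L), **kw)
        except PropagationFailure:
            pass
    return SweepResult(preset=params.name, mode=mode,
                       parameter="internode_length_um", values=lengths,
                       speeds=speeds, baseline_speed=base,
                       baseline_value=params.L_internode)


def sweep_wraps(preset, wraps_delta: int, **kw) -> SweepResult:
    """Speed change when the myelin wrap count changes by ``wraps_delta``.

    Paranode length (and its effective periaxonal width formula input) is
    unchanged; myelin admittance is recomputed for the new membrane count.
    """
    params = _as_params(preset)
    new_wraps = params.N_wraps + wraps_delta
    if new_wraps < 1:
        raise InvalidParameterError("resulting wrap count must be >= 1")
    base = axon_speed(params, **kw)
    speed = axon_speed(params, n_wraps=new_wraps, **kw) if wraps_delta else base
    return SweepResult(preset=params.name, mode="constant_density",
                       parameter="n_wraps",
                       values=np.array([params.N_wraps, new_wraps], dtype=float),
                       speeds=np.array([base, speed]), baseline_speed=base,
                       baseline_value=params.N_wraps)


# ---------------------------------------------------------------------------
# matched-speed comparisons and alternating axons
# ---------------------------------------------------------------------------

def speed_matched_equivalents(preset, target_percent_change: float,
                              tol_points: float = 0.2, **kw) -> dict:
    """Parameter changes that each produce the same speed change.

    Solves three knobs independently by root finding on the simulated
    percent speed change (vs the preset baseline): the nodal fast-Na⁺
    density factor, the internode length, and the node length (at constant
    channel density).  Returns ``{'density_change': %, 'internode_change': %,
    'node_length': µm}``; each knob matched within ``tol_points`` percentage
    points.  A target of 0 returns the baseline for every knob.
    """
    params = _as_params(preset)
    if target_percent_change == 0:
        return {"density_change": 0.0, "internode_change": 0.0,
                "node_length": params.L_node}
    base = axon_speed(params, **kw)

    def pct(**config):
        return 100.0 * (axon_speed(params, **config, **kw) / base - 1.0) \
            - target_percent_change

    xtol = tol_points / 100.0
    try:
        f = brentq(lambda x: pct(na_density_factor=x), 0.05, 1.0 if
                   target_percent_change < 0 else 4.0, xtol=xtol, rtol=1e-3)
    except ValueError as e:
        raise InvalidParameterError(f"density target unreachable: {e}") from None
    try:
        il = brentq(lambda x: pct(internode_length=x),
                    params.L_internode, 6.0 * params.L_internode
                    if target_percent_change < 0 else params.L_internode / 4,
                    xtol=params.L_internode * xtol, rtol=1e-3)
    except ValueError as e:
        raise InvalidParameterError(f"internode target unreachable: {e}") from None
    try:
        nl = brentq(lambda x: pct(node_length=x, mode="constant_density"),
                    0.1, params.L_node, xtol=0.002, rtol=1e-3) \
            if target_percent_change < 0 else \
            brentq(lambda x: pct(node_length=x, mode="constant_density"),
                   params.L_node, 5.0, xtol=0.002, rtol=1e-3)
    except ValueError as e:
        raise InvalidParameterError(f"node-length target unreachable: {e}") from None
    return {"density_change": 100.0 * (f - 1.0),
            "internode_change": 100.0 * (il / params.L_internode - 1.0),
            "node_length": nl}


def alternating_node_axon(preset, mean_length: float, delta: float,
                          mode: str = "constant_density", **kw) -> float:
    """Speed (m/s) of an axon whose node lengths alternate mean ± delta.

    In ``constant_number`` mode each node keeps the channel number of the
    mean node length, so the speed is essentially that of the uniform axon;
    in ``constant_density`` mode the concave speed-vs-length relation makes
    the alternating axon marginally slower.
    """
    if mean_length - delta <= 0:
        raise InvalidParameterError("mean_length - delta must be positive")
    params = _as_params(preset)
    n_nodes = kw.pop("n_nodes", 51)
    lengths = np.where(np.arange(n_nodes) % 2 == 0,
                       mean_length - delta, mean_length + delta)
    base_params = params.with_(L_node=mean_length)
    return axon_speed(base_params, node_lengths=lengths, mode=mode,
                      n_nodes=n_nodes, **kw)


def propagation_delay(axon_length_m: float, speed_mps: float) -> float:
    """Propagation delay (ms) over ``axon_length_m`` metres at ``speed_mps``."""
    if axon_length_m < 0 or speed_mps <= 0:
        raise InvalidParameterError("need non-negative length, positive speed")
    return axon_length_m / speed_mps * 1e3
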