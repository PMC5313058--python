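"""Recompute the headline quantities of the model from scratch.

Each entry is produced by running the package's own geometry and simulation
code at the shipped preset parameters; nothing is looked up.  Values are on
the scales conventionally reported: percentages as percentages, widths in
nm, speeds in m/s.
"""

from __future__ import annotations

import numpy as np

from .geometry import (load_preset, paranodal_effective_width,
                       nodal_capacitance_fraction, membrane_area_ledger)
from .experiments import axon_speed, sweep_node_length, sweep_wraps

#: node-length grid for the 154-µm-internode cortical spread (µm)
SPREAD_GRID = (0.43, 1.0, 1.6, 2.0, 2.4, 2.8, 3.2, 3.7)


def reproduce_all(seed: int = 1, dt: float = 2.5e-4) -> dict:
    """Run every headline computation; returns {name: {value, n}}.

    ``seed`` feeds any stochastic component (the physiology simulations are
    deterministic); ``dt`` is the solver time step in ms.
    """
    optic = load_preset("optic_nerve")
    cortex = load_preset("cortex")
    out = {}

    def put(name, value, n):
        out[name] = {"value": float(round(value, 4)), "n": n}

    # -- analytic geometry ------------------------------------------------
    put("paranodal_width_optic_nm",
        paranodal_effective_width(optic.spiral_area, optic.L_paranode,
                                  optic.d_axon_internode, optic.N_wraps),
        optic.N_wraps)
    put("paranodal_width_cortex_nm",
        paranodal_effective_width(cortex.spiral_area, cortex.L_paranode,
                                  cortex.d_axon_internode, cortex.N_wraps),
        cortex.N_wraps)
    put("nodal_capacitance_fraction_cortex_pct",
        100.0 * nodal_capacitance_fraction(cortex), 1)
    ledger = membrane_area_ledger(cortex, 1.5, 0.635, wraps_delta=1)
    put("area_ratio_cortex_fold", ledger["ratio"], 1)

    # -- baseline speeds --------------------------------------------------
    n_nodes = 51
    b_optic = axon_speed(optic, dt=dt)
    b_cortex = axon_speed(cortex, dt=dt)
    put("speed_optic_mps", b_optic, n_nodes)
    put("speed_cortex_mps", b_cortex, n_nodes)

    # -- node-length sweeps (percent changes vs the mean-length baseline) --
    def pct(preset, base, **kw):
        return 100.0 * (axon_speed(preset, dt=dt, **kw) / base - 1.0)

    put("optic_cn_2p2_pct_decrease",
        -pct(optic, b_optic, node_length=2.2, mode="constant_number"), n_nodes)
    put("optic_cn_0p5_pct_increase",
        pct(optic, b_optic, node_length=0.5, mode="constant_number"), n_nodes)
    put("optic_cd_0p5_pct_decrease",
        -pct(optic, b_optic, node_length=0.5, mode="constant_density"), n_nodes)
    put("cortex_cd_0p43_pct_decrease",
        -pct(cortex, b_cortex, node_length=0.43, mode="constant_density"),
        n_nodes)

    # -- one fewer myelin wrap -------------------------------------------
    sw = sweep_wraps(optic, -1, dt=dt)
    put("optic_minus_one_wrap_pct_decrease", -sw.percent_change[1], n_nodes)

    # -- cortical spread with 154 µm internodes ---------------------------
    spread = sweep_node_length(cortex, SPREAD_GRID, mode="constant_density",
                               internode_length=154.0, dt=dt)
    put("cortex_154um_internode_spread_pct",
        spread.max_spread_percent("min"), len(SPREAD_GRID))

    return out
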