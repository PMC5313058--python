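"""Electrical geometry of a myelinated axon.

Builds the discretised double-cable geometry of a single unbranched
myelinated axon: nodes of Ranvier alternating with internodal regions whose
end compartments represent the paranodes, where the myelin attaches to the
axon.  All derived electrical quantities are computed here — wrap counts
from the g-ratio, the effective periaxonal width of the paranodal spiral
pathway, per-compartment membrane capacitances and conductances, myelin
admittances (2·N_wraps membranes in series at their true lamella radii), and
intracellular / periaxonal axial resistances.

Unit conventions
----------------
Parameters are stored in the mixed units conventional for this model family
(conductance densities in mS/cm², capacitance densities in µF/cm²,
resistivities in Ω·cm, potentials in mV, lengths/diameters in µm, periaxonal
widths in nm).  Per-compartment absolute quantities use a consistent
electrical system: mV, ms, pF, nS, GΩ, pA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CableParameters",
    "CompartmentChain",
    "InvalidParameterError",
    "ConfigurationError",
    "load_preset",
    "available_presets",
    "paranodal_effective_width",
    "wraps_from_gratio",
    "build_axon",
    "membrane_area_ledger",
    "nodal_capacitance_fraction",
]

# unit conversion factors into the pF / nS / GΩ system
_CAP_PF_PER_UM2 = 1e-2     # µF/cm² × µm² -> pF
_COND_NS_PER_UM2 = 1e-2    # mS/cm² × µm² -> nS
_RES_GOHM_UM = 1e-5        # Ω·cm × µm / µm² -> GΩ

# compartment kind codes
NODE, PARANODE, INTERNODE = 0, 1, 2


class InvalidParameterError(ValueError):
    """A physical parameter is outside its valid domain."""


class ConfigurationError(ValueError):
    """A discretisation request cannot be realised."""


@dataclass(frozen=True)
class CableParameters:
    """Electrical and geometrical parameters of one axon model (one tissue preset).

    Conductance densities are in mS/cm², capacitances in µF/cm²,
    resistivities in Ω·cm, potentials in mV, lengths and diameters in µm,
    periaxonal widths in nm.
    """

    name: str
    # nodal channel conductance densities (mS/cm²)
    g_Na: float
    g_Ks: float
    g_Nap: float
    g_L_node: float
    g_L_internode: float
    g_my: float           # per myelin membrane (mS/cm²)
    c_ax: float           # axonal membrane capacitance (µF/cm²)
    c_my: float           # per myelin membrane (µF/cm²)
    rho_ax: float         # axoplasmic resistivity (Ω·cm)
    rho_p: float          # periaxonal resistivity (Ω·cm)
    E_r: float            # resting potential (mV)
    E_Lk: float           # leak reversal (mV)
    E_Na: float
    E_K: float
    d_node: float         # node diameter (µm)
    L_node: float         # mean node length (µm)
    L_paranode: float     # paranode length (µm)
    w_paranode: float     # effective paranodal periaxonal width (nm)
    d_axon_internode: float
    w_internode: float    # internodal periaxonal width (nm)
    g_ratio: float
    N_wraps: int
    L_internode: float    # µm
    spiral_area: float = 170.0    # paranodal spiral cross-section (nm²)
    periodicity: float = 15.6     # myelin wrap periodicity (nm)
    n_internodal_compartments: int = 66

    def __post_init__(self):
        positive = [
            "g_Na", "g_Ks", "g_Nap", "g_L_node", "g_L_internode", "g_my",
            "c_ax", "c_my", "rho_ax", "rho_p", "d_node", "L_node",
            "L_paranode", "w_paranode", "d_axon_internode", "w_internode",
            "L_internode", "spiral_area", "periodicity",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if not 0 < self.g_ratio < 1:
            raise InvalidParameterError("g_ratio must lie in (0, 1)")
        if self.N_wraps < 1:
            raise InvalidParameterError("N_wraps must be >= 1")
        if not (self.E_Na > self.E_r > self.E_K):
            raise InvalidParameterError("require E_Na > E_r > E_K")

    def with_(self, **changes) -> "CableParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    # -- derived sheath geometry (µm) ------------------------------------
    @property
    def inner_lamella_radius(self) -> float:
        """Radius of the innermost myelin membrane (axon radius + periaxonal space)."""
        return self.d_axon_internode / 2 + self.w_internode * 1e-3

    @property
    def outer_lamella_radius(self) -> float:
        """Radius of the outermost myelin membrane, from the g-ratio."""
        return self.d_axon_internode / (2 * self.g_ratio)

    def lamella_radii(self, n_wraps: int | None = None) -> np.ndarray:
        """Radii (µm) of the 2·N myelin membranes, evenly spaced across the sheath.

        When ``n_wraps`` differs from the preset value the sheath thickness is
        scaled proportionally (wraps are added/removed at constant periodicity).
        """
        n = self.N_wraps if n_wraps is None else int(n_wraps)
        if n < 1:
            raise InvalidParameterError("number of wraps must be >= 1")
        r_in = self.inner_lamella_radius
        thickness = (self.outer_lamella_radius - r_in) * n / self.N_wraps
        return np.linspace(r_in, r_in + thickness, 2 * n)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def available_presets() -> list[str]:
    root = resources.files("ranvier") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name_or_path: str | Path) -> CableParameters:
    """Load a parameter preset, either a packaged name (``optic_nerve``,
    ``cortex``) or a path to a YAML file with the same fields."""
    path = Path(str(name_or_path))
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        res = resources.files("ranvier") / "presets" / f"{name_or_path}.yaml"
        try:
            text = res.read_text()
        except FileNotFoundError:
            raise FileNotFoundError(
                f"unknown preset {name_or_path!r}; available: {available_presets()}"
            ) from None
    data = yaml.safe_load(text)
    return CableParameters(**data)


# ---------------------------------------------------------------------------
# derived scalar quantities
# ---------------------------------------------------------------------------

def paranodal_effective_width(A: float, L_paranode: float, d_axon: float,
                              N_wraps: int) -> float:
    """Effective periaxonal width (nm) equivalent to the paranodal spiral pathway.

    The periaxonal pathway at the paranode is a channel of cross-section
    ``A`` (nm²) spiralling around the axon for a total length π·d·N_wraps.
    A uniform periaxonal space of width w along a paranode of length L has
    the same resistance when ``w = A·L / [(π·d)²·N_wraps]``.

    Parameters are A in nm², L_paranode and d_axon in µm; the result is in nm.
    """
    if A <= 0 or L_paranode <= 0 or d_axon <= 0 or N_wraps <= 0:
        raise InvalidParameterError("all arguments must be positive")
    L_nm = L_paranode * 1e3
    d_nm = d_axon * 1e3
    return A * L_nm / ((math.pi * d_nm) ** 2 * N_wraps)


def wraps_from_gratio(d_axon: float, g_ratio: float, periodicity: float,
                      periaxonal_width: float) -> int:
    """Integral number of myelin wraps implied by the g-ratio.

    The radial space available for myelin is ``(d/g − d)/2`` minus the
    periaxonal width; the wrap count is the smallest integer whose sheath
    (at the given periodicity, nm) fills that space.  The g-ratios of the
    shipped presets were chosen to make this integral (7 wraps for the
    optic nerve, 5 for the cortex).
    """
    if not 0 < g_ratio < 1:
        raise InvalidParameterError("g_ratio must lie in (0, 1)")
    if d_axon <= 0 or periodicity <= 0 or periaxonal_width < 0:
        raise InvalidParameterError("invalid geometry argument")
    thickness_nm = (d_axon / g_ratio - d_axon) / 2 * 1e3 - periaxonal_width
    n = math.ceil(thickness_nm / periodicity - 1e-12)
    if n < 1:
        raise InvalidParameterError(
            f"g_ratio {g_ratio} leaves no room for a myelin wrap"
        )
    return n


def membrane_area_ledger(params: CableParameters, node_length_a: float,
                         node_length_b: float, wraps_delta: int = 1) -> dict:
    """Membrane-area cost of a speed change via the node versus via the sheath.

    Compares the axolemma area change from altering node length
    (``π·d_node·|ΔL|``) with the membrane area of ``|wraps_delta|`` added
    lamellae (two membranes each, at the outer sheath circumference) over one
    internode.  ``correction_factor`` (= 2·N_wraps·mean wrap radius / node
    radius) accounts for the sheath lengthening needed if the internode must
    elongate to compensate a node shortening; ``corrected_ratio`` divides it
    out.  All areas in µm².
    """
    if node_length_a <= 0 or node_length_b <= 0:
        raise InvalidParameterError("node lengths must be positive")
    dL = abs(node_length_a - node_length_b)
    if dL == 0:
        raise InvalidParameterError("node lengths are equal; ratio undefined")
    if wraps_delta == 0:
        raise InvalidParameterError("wraps_delta must be non-zero")
    node_area_change = math.pi * params.d_node * dL
    d_outer = 2 * params.outer_lamella_radius
    sheath_area_change = abs(wraps_delta) * 2 * math.pi * d_outer * params.L_internode
    ratio = sheath_area_change / node_area_change
    mean_wrap_radius = (params.inner_lamella_radius + params.outer_lamella_radius) / 2
    correction_factor = 2 * params.N_wraps * mean_wrap_radius / (params.d_node / 2)
    return {
        "node_area_change": node_area_change,
        "sheath_area_change": sheath_area_change,
        "ratio": ratio,
        "correction_factor": correction_factor,
        "corrected_ratio": ratio / correction_factor,
    }


def nodal_capacitance_fraction(params: CableParameters) -> float:
    """Fraction of membrane capacitance per repeating unit contributed by the node.

    The repeating unit is one node plus one internodal region.  The
    internodal contribution is the axolemma capacitance in series with the
    2·N_wraps myelin membranes (each at its own lamella radius), because a
    voltage change across the internodal wall must charge that whole series
    stack.  Returns a dimensionless fraction.
    """
    c_node = params.c_ax * math.pi * params.d_node * params.L_node
    inv_per_um = 1.0 / (params.c_ax * math.pi * params.d_axon_internode)
    inv_per_um += float(np.sum(1.0 / (params.c_my * 2 * math.pi * params.lamella_radii())))
    c_internode = params.L_internode / inv_per_um
    return c_node / (c_node + c_internode)


# ---------------------------------------------------------------------------
# compartment chain
# ---------------------------------------------------------------------------

@dataclass
class CompartmentChain:
    """Discretised axon: per-compartment electrical constants.

    Arrays are ordered along the axon.  ``kind`` is 0 (node), 1 (paranode)
    or 2 (internode).  Capacitances in pF, conductances in nS, axial
    resistances in GΩ (``r_ax``/``r_p`` have length ``n−1``; entry k couples
    compartments k and k+1).  A node compartment carries zero myelin
    admittance and its periaxonal potential is clamped to ground.
    """

    params: CableParameters
    kind: np.ndarray
    length: np.ndarray          # µm
    diameter: np.ndarray        # µm
    area: np.ndarray            # µm² axolemma
    c_mem: np.ndarray           # pF
    g_channels: dict            # name -> nS per compartment ('na','ks','nap','leak')
    e_channels: dict            # name -> reversal (mV)
    c_my: np.ndarray            # pF (0 at nodes)
    g_my: np.ndarray            # nS (0 at nodes)
    r_ax: np.ndarray            # GΩ, intracellular, len n−1
    r_p: np.ndarray             # GΩ, periaxonal, len n−1
    node_index: np.ndarray      # compartment indices of the nodes
    node_lengths: np.ndarray    # µm, per node
    n_wraps: int

    @property
    def n_compartments(self) -> int:
        return self.kind.size

    @property
    def n_nodes(self) -> int:
        return self.node_index.size

    @property
    def positions(self) -> np.ndarray:
        """Axial centre position of each compartment (µm)."""
        edges = np.concatenate([[0.0], np.cumsum(self.length)])
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def node_positions(self) -> np.ndarray:
        return self.positions[self.node_index]

    def total_length(self) -> float:
        return float(self.length.sum())

    def total_axolemma_area(self) -> float:
        return float(self.area.sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "kind": np.array(["node", "paranode", "internode"])[self.kind],
            "length_um": self.length,
            "diameter_um": self.diameter,
            "area_um2": self.area,
            "c_mem_pF": self.c_mem,
            "c_my_pF": self.c_my,
            "g_my_nS": self.g_my,
        })
        for name, g in self.g_channels.items():
            df[f"g_{name}_nS"] = g
        df["r_ax_next_GOhm"] = np.append(self.r_ax, np.nan)
        df["r_p_next_GOhm"] = np.append(self.r_p, np.nan)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _myelin_admittance_per_um(params: CableParameters, n_wraps: int) -> tuple[float, float]:
    """(capacitance pF/µm, conductance nS/µm) of the 2·n_wraps-membrane stack."""
    radii = params.lamella_radii(n_wraps)
    circumferences = 2 * math.pi * radii          # µm per µm length
    inv_c = np.sum(1.0 / (params.c_my * circumferences * _CAP_PF_PER_UM2))
    inv_g = np.sum(1.0 / (params.g_my * circumferences * _COND_NS_PER_UM2))
    return 1.0 / inv_c, 1.0 / inv_g


def build_axon(params: CableParameters, n_nodes: int = 51,
               internodal_compartments: int | None = None,
               node_length_override=None,
               nodal_density_scale=None,
               n_wraps: int | None = None,
               paranode_tol: float = 0.45) -> CompartmentChain:
    """Build the compartment chain for one axon.

    ``n_nodes`` node compartments alternate with ``n_nodes − 1`` internodal
    regions of fixed length ``params.L_internode``, each split into
    ``internodal_compartments`` equal compartments whose end runs represent
    the paranodes.  The paranode must be resolvable by an integral number of
    compartments: the count is ``round(L_paranode/dl)`` and a
    :class:`ConfigurationError` is raised if the residual mismatch exceeds
    ``paranode_tol`` compartment lengths or the count is zero.

    ``node_length_override`` is a scalar or per-node sequence of node lengths
    (µm); the internodal region length is unchanged.  ``nodal_density_scale``
    is an optional per-node factor applied to the nodal channel conductance
    densities (used for constant-channel-number simulations).
    ``n_wraps`` overrides the preset wrap count (myelin admittance and
    paranodal periaxonal width are recomputed; paranode length unchanged).
    """
    if n_nodes < 2:
        raise ConfigurationError("need at least 2 nodes")
    n_int = params.n_internodal_compartments if internodal_compartments is None \
        else int(internodal_compartments)
    wraps = params.N_wraps if n_wraps is None else int(n_wraps)
    if wraps < 1:
        raise InvalidParameterError("n_wraps must be >= 1")

    dl = params.L_internode / n_int
    n_para_f = params.L_paranode / dl
    n_para = int(round(n_para_f))
    if n_para < 1 or abs(n_para_f - n_para) > paranode_tol:
        raise ConfigurationError(
            f"paranode ({params.L_paranode} µm) not resolvable by an integral "
            f"number of {dl:.4g} µm compartments"
        )
    if n_int < 2 * n_para + 1:
        raise ConfigurationError("internodal compartment count too small")

    node_lengths = np.full(n_nodes, params.L_node)
    if node_length_override is not None:
        node_lengths = np.broadcast_to(
            np.asarray(node_length_override, dtype=float), (n_nodes,)
        ).copy()
    if np.any(node_lengths <= 0):
        raise InvalidParameterError("node lengths must be strictly positive")
    density_scale = np.ones(n_nodes)
    if nodal_density_scale is not None:
        density_scale = np.broadcast_to(
            np.asarray(nodal_density_scale, dtype=float), (n_nodes,)
        ).copy()

    # effective paranodal width for the (possibly overridden) wrap count
    if wraps == params.N_wraps:
        w_para = params.w_paranode
    else:
        w_para = paranodal_effective_width(
            params.spiral_area, params.L_paranode, params.d_axon_internode, wraps)

    n_total = n_nodes + (n_nodes - 1) * n_int
    kind = np.empty(n_total, dtype=np.int8)
    length = np.empty(n_total)
    diameter = np.empty(n_total)
    w_peri = np.zeros(n_total)      # nm; 0 at nodes (open to ground)
    g_scale = np.ones(n_total)      # nodal density scale per compartment
    node_index = np.empty(n_nodes, dtype=np.int64)

    i = 0
    for j in range(n_nodes):
        node_index[j] = i
        kind[i] = NODE
        length[i] = node_lengths[j]
        diameter[i] = params.d_node
        g_scale[i] = density_scale[j]
        i += 1
        if j == n_nodes - 1:
            break
        for k in range(n_int):
            is_para = k < n_para or k >= n_int - n_para
            kind[i] = PARANODE if is_para else INTERNODE
            length[i] = dl
            diameter[i] = params.d_axon_internode
            w_peri[i] = w_para if is_para else params.w_internode
            i += 1
    assert i == n_total

    area = math.pi * diameter * length
    c_mem = params.c_ax * area * _CAP_PF_PER_UM2

    is_node = kind == NODE
    g_leak_density = np.where(is_node, params.g_L_node * g_scale, params.g_L_internode)
    g_channels = {
        "na": np.where(is_node, params.g_Na * g_scale, 0.0) * area * _COND_NS_PER_UM2,
        "ks": np.where(is_node, params.g_Ks * g_scale, 0.0) * area * _COND_NS_PER_UM2,
        "nap": np.where(is_node, params.g_Nap * g_scale, 0.0) * area * _COND_NS_PER_UM2,
        "leak": g_leak_density * area * _COND_NS_PER_UM2,
    }
    e_channels = {"na": params.E_Na, "ks": params.E_K, "nap": params.E_Na,
                  "leak": params.E_Lk}

    c_my_per_um, g_my_per_um = _myelin_admittance_per_um(params, wraps)
    c_my = np.where(is_node, 0.0, c_my_per_um * length)
    g_my = np.where(is_node, 0.0, g_my_per_um * length)

    # axial resistances between compartment centres (half-segment sums)
    half_ax = _RES_GOHM_UM * params.rho_ax * (length / 2) / (math.pi * diameter ** 2 / 4)
    r_ax = half_ax[:-1] + half_ax[1:]

    # periaxonal: nodes contribute zero (their exterior is ground)
    peri_area = math.pi * diameter * w_peri * 1e-3     # µm² cross-section
    with np.errstate(divide="ignore"):
        half_p = np.where(
            is_node, 0.0,
            _RES_GOHM_UM * params.rho_p * (length / 2) / peri_area,
        )
    r_p = half_p[:-1] + half_p[1:]

    return CompartmentChain(
        params=params, kind=kind, length=length, diameter=diameter, area=area,
        c_mem=c_mem, g_channels=g_channels, e_channels=e_channels,
        c_my=c_my, g_my=g_my, r_ax=r_ax, r_p=r_p,
        node_index=node_index, node_lengths=node_lengths, n_wraps=wraps,
    )
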