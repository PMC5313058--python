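# Rat optic nerve myelinated axon preset.
# Conductance densities mS/cm², capacitances µF/cm², resistivities Ω·cm,
# potentials mV, lengths/diameters µm, periaxonal widths nm.
name: optic_nerve
g_Na: 3000.0
g_Ks: 80.0
g_Nap: 5.0
g_L_node: 80.0
g_L_internode: 0.1
g_my: 1.0
c_ax: 0.9
c_my: 0.9
rho_ax: 70.0
rho_p: 70.0
E_r: -82.0
E_Lk: -83.38
E_Na: 50.0
E_K: -84.0
d_node: 0.73
L_node: 1.02
L_paranode: 2.11
w_paranode: 0.0077
d_axon_internode: 0.82
w_internode: 15.0
g_ratio: 0.78
N_wraps: 7
L_internode: 139.26
spiral_area: 170.0
periodicity: 15.6
n_internodal_compartments: 66
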