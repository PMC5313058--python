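# Rat cortical grey-matter (layer V) myelinated axon preset.
# Conductance densities mS/cm², capacitances µF/cm², resistivities Ω·cm,
# potentials mV, lengths/diameters µm, periaxonal widths nm.
name: cortex
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
d_node: 0.64
L_node: 1.5
L_paranode: 1.9
w_paranode: 0.0123
d_axon_internode: 0.73
w_internode: 15.0
g_ratio: 0.81
N_wraps: 5
L_internode: 81.7
spiral_area: 170.0
periodicity: 15.6
n_internodal_compartments: 86
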