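# Methods

## Model structure

The axon is an unbranched chain of 51 nodes of Ranvier alternating with 50
internodal regions.  Each internodal region has fixed length `L_internode`
(139.26 µm optic nerve, 81.7 µm cortex) and is divided into equal
compartments (66 and 86 respectively); the runs of compartments at each end
represent the paranode (2.11 µm = 1 compartment for the optic nerve,
1.90 µm = 2 compartments for the cortex).  The node is a single compartment:
it is electrically compact (≤ 3.7 µm at the largest measured length).

Two potentials are integrated per compartment: intracellular `V_i` and
periaxonal `V_p` (the space between axolemma and innermost myelin
membrane).  The axolemma separates `V_i` from `V_p`; the myelin stack
separates `V_p` from grounded extracellular space.  At nodes there is no
myelin and no periaxonal space: the axolemma faces ground directly and the
periaxonal pathway of the adjacent paranode terminates at ground there.
Axial current flows intracellularly (resistivity ρ_ax = 70 Ω·cm through the
axoplasmic cross-section) and periaxonally (ρ_p = 70 Ω·cm through the
annulus π·d·w).  Under the internode w = 15 nm; under the paranode the
spiral pathway between the myelin attachment loops (cross-section
A = 170 nm², length π·d·N_wraps) is represented by its equivalent uniform
width `w = A·L/[(π·d)²·N_wraps]`: 0.0077 nm (optic nerve) and 0.0123 nm
(cortex).  Ends are sealed; the extracellular space is grounded
(no extracellular resistance parameters exist in the presets).

Voltage-gated K⁺ channels at the juxtaparanode are omitted: the myelin
stack divides the ~100 mV spike across its 11–15 membranes, leaving only a
few mV across the internodal axolemma (asserted by a test), so those
channels are barely activated.

### Myelin admittance convention

Each wrap contributes two membranes in electrical series.  The per-
compartment myelin capacitance and conductance are the series combination
of the 2·N_wraps membranes **at their true lamella radii**, spaced evenly
from (axon radius + periaxonal width) to the outer sheath radius implied by
the g-ratio.  This convention, rather than placing all membranes at the
axon diameter, reproduces the nodal share of total membrane capacitance per
repeating unit (7.9% optic nerve, 13.6% cortex) and the mean-wrap-radius
correction factors of the membrane-area ledger (18.2 and 13.0).

### Wrap counts and the membrane-area ledger

The sheath thickness available for wraps is `(d/g − d)/2` minus the 15 nm
periaxonal space; the wrap count is the ceiling of thickness/periodicity
(15.6 nm per wrap), i.e. the smallest whole number of wraps that fills the
space.  The shipped g-ratios (0.78, 0.81) then give exactly 7 and 5 wraps.

The ledger compares the axolemma area change of a node-length change,
π·d_node·|ΔL|, with the membrane area of one added lamella — two membranes
at the **outer** sheath circumference over one internode (a new wrap is
laid on the outside).  For the published matched-speed changes this gives
ratios of ~1015 (optic) and ~266 (cortex).  The correction factor for the
scenario in which the internode must lengthen to conserve axon length is
2·N_wraps·r̄/r_node with r̄ the arithmetic mean of the innermost and
outermost lamella radii.

## Nodal channel kinetics

The node carries fast Na⁺ (m³h), persistent Na⁺ (p³) and slow K⁺ (s)
conductances plus leak; these kinetics follow the standard mammalian-node
compartment-model family.  Two published variants of the fast Na⁺ rate
constants exist in that lineage: the original human-node voltage-clamp
measurements (α_m = 1.86·(V+18.4)/…, β_h = 2.3/…, reported at 20 °C) and a
later modified set.  This package uses the original set for m and h,
Q10-scaled (2.2 for m, 2.9 for h) to the 37 °C working temperature, and the
standard persistent-Na⁺ and slow-K⁺ rates referenced to 36 °C (Q10 2.2 and
3.0).  The choice is validated end-to-end: with it the model's baseline
conduction speeds are 2.97 m/s (optic nerve) and 2.63 m/s (cortex), within
1% of the published model outputs, whereas the modified set runs ~10% fast.

Two caveats are intrinsic to these published rate forms:

- the slow-K⁺ sigmoids are not monotone below ≈ −90 mV (outside their
  fitted range); simulated voltages never reach that regime;
- the leak reversal E_Lk = −83.38 mV does **not** exactly stationarise the
  nominal resting potential of −82 mV under these kinetics: the chain's
  true fixed point is ≈ −83.1 mV.  `resting_state` solves that fixed point
  (fixed-point iteration on the pure-conductance network with gates
  re-equilibrated) and reports the residual |dV/dt| instead of re-tuning
  E_Lk; the residual at the returned state is ≲ 1e-9 mV/ms.

## Numerics

Backward Euler on the linear cable terms: per step, one pentadiagonal
banded solve over the interleaved unknowns (V_i, V_p) — only the nodal
diagonal entries change between steps.  Gates advance with the exponential
(Rush–Larsen) update at the previous step's nodal voltages.  Default
dt = 0.25 µs; halving dt changes the measured conduction delay by ~0.3%
(Richardson-extrapolated delay stable to < 0.5%, asserted by a test);
doubling the spatial compartment count changes speed by ~0.5%.  The solver
is deterministic and bitwise reproducible; |V| > 500 mV raises a blow-up
error naming the compartment.

The default stimulus is a fixed 2 nA × 0.1 ms intracellular pulse at node 0
— comfortably suprathreshold for every configuration explored here.  A
bisection threshold finder (`find_threshold`) is provided for calibrated
stimulation, but the fixed pulse is the default because all reported
percent changes are stimulus-invariant (asserted by a test) and it keeps
each experiment to one simulation.  Sweeps stop integrating ~0.15 ms after
the spike passes node 35, five nodes beyond the measurement window.

Conduction speed: centre-to-centre distance between nodes 20 and 30
(10 × (L_internode + L_node) for uniform axons) divided by the difference
of spike times; spike time is the linearly interpolated upward crossing of
−20 mV.  A peak-time marker is also implemented and agrees within 1%.

When internode length is swept, the compartment count is re-derived to keep
the preset's compartment size, and the paranode is represented by
`round(L_paranode/dl)` compartments — exact integrality is unattainable for
arbitrary internode lengths, so the represented paranode length may flex by
up to half a compartment (< 0.5% effect on speed).

## Experiment conventions

- Percent changes are relative to the preset's mean-node-length baseline
  (at which the two channel-scaling modes coincide by construction).
- Spread statistics over a sweep are reported max-vs-min
  (`100·(v_max − v_min)/v_min`), the convention that matches the published
  spread figures; a max-vs-baseline convention is also available
  (`SweepResult.max_spread_percent("baseline")`).
- Default node-length grids span the measured ranges: 0.5–2.2 µm (optic
  nerve), 0.43–3.7 µm (cortex).
- In `constant_number` mode the nodal leak scales together with the gated
  channels, per the preset definition of the nodal densities.

## Synthetic data

`sample_population` draws a hierarchical node-length population: axon mean
lengths are lognormal (right-skewed, strictly positive) with the measured
between-axon moments; node lengths along an axon are normal around the axon
mean with within-axon s.d. 0.25 µm, truncated at 0.1 µm; internode lengths
are normal (mean 82.7 µm, s.d. 34.5 µm — the published s.e.m. 6.3 µm over
30 internodes) clipped to the observed 27–154 µm range; nodal marker
intensity is proportional to node length with 25% lognormal noise.  The
cortical between-axon s.d. is back-computed as sqrt(0.58² − 0.25²) =
0.523 µm, since only the pooled and within-axon spreads are published.
Nodes per axon are Poisson (mean 6.7) clipped to 2–13.

`render_profile` renders one node's line profile analytically: two paranode
boxcars flanking the node gap, convolved with a Gaussian PSF via the error
function, sampled at the pixel size (default 52.7 nm), plus background and
optional additive noise.  The generator emulates the *statistical*
structure of the measurements only; it does not model axon tilt relative to
the optical section (the published tilt-induced underestimate is ~1.7%),
non-uniform paranode brightness, chromatic offsets, or 2-D/3-D image
formation.  Passing tests therefore demonstrate correctness of the
measurement pipeline under the stated forward model, not robustness to
every confocal artefact.

## Morphometry

Background is estimated as the mean of the lowest decile of samples and
subtracted (clipped at zero).  Peak finding restricts attention to the span
between the outermost samples reaching half the robust (99.5th-percentile)
maximum, takes local maxima ≥ 30% of that maximum as candidates, places the
node valley at the deepest sample between the outermost candidates, and
takes the highest sample on each side as the paranode peaks — deterministic
and robust to isolated noise spikes.  Each half-maximum crossing uses half
of its own paranode's peak and is located by linear interpolation between
samples (pixel sizes are a large fraction of short nodes).  Profiles whose
paranode bands merge (gaps ≲ 2 PSF σ) are rejected as unmeasurable rather
than silently mismeasured.  Measurement operates on raw profiles by
default; a 3-point smoothing flag exists.

The along-vs-between analysis computes the pooled CoV over all nodes of all
axons and each axon's reduction `(1 − CoV_axon/CoV_pooled)·100`, reporting
mean ± s.e.m. and a one-sample t-test against zero.  On populations
calibrated to the measured variance components (18 axons × ~7 nodes) the
mean reduction falls in the 40–60% band around the published ~49%.  Note
the statistic is biased slightly positive even without between-axon
structure (sample-s.d. bias at small n, and E[1/mean] > 1/E[mean]); the
null-case test bounds this at < 15 percentage points.

## Known limitations

- The constant-density speed–node-length curve is flatter than the source
  model's: the predicted slowing for the shortest measured nodes is
  −11.1% (optic nerve, 0.5 µm) and −15.9% (cortex, 0.43 µm) against
  published values of −14.1% and −19.6%, and the 154-µm-internode spread is
  ~30% against 42%.  Equivalently, the model's speed is more elastic to the
  fast-Na⁺ density alone and less sensitive to total nodal channel number
  than the source implementation.  The discrepancy traces to rate-equation
  details of the nodal channels that are not recoverable from the available
  descriptions of the source model (its printed leak-reversal calibration
  implies ~5× more non-leak inward current at rest than the transcribed
  kinetics produce).  All constant-number predictions, baseline speeds and
  wrap-count effects agree to ≤ 0.2 percentage points.
- For the same reason the interior maximum of the constant-density curve
  sits at ≈ 1.4–1.6 µm rather than the published 1.7 µm; the curve is flat
  to < 0.5% between those points.
- Problem sizes: all reported numbers use 51 nodes, the preset compartment
  counts, dt = 0.25 µs, and 6–9-point sweep grids; these choices are
  converged to well under the tolerances quoted above.
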