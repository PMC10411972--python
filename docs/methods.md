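# Methods

## The model

`msnsim` simulates a single D1 medium spiny neuron (D1-MSN) as a branched
passive cable populated with voltage-gated conductances and conductance-based
synapses, driven either by somatic current steps (for calibration) or by
stochastic ensembles of excitatory and inhibitory synaptic inputs (for
input–output mapping).

**Geometry.** A morphology (SWC tree, µm units) is discretized into frustum
compartments no longer than `max_seg_length_um` (default 10–20 µm). The soma
is treated as a sphere of the mean soma-node radius, represented by its
area-equivalent cylinder (L = d = 2r). Membrane area equals the exact frustum
lateral areas, so discretization conserves area identically. When the
morphology has no axon and the channel specification places sodium in the
axon initial segment, a 50 µm × 0.5 µm initial segment is appended to the
soma (the experimental model geometry) and the action is logged.

**Channels.** Surface densities follow the published D1-MSN model: Na
2.4 S/cm² (axon initial segment only), CaV1.2 6.7e-6, CaV1.3 1.0e-4,
KAs 4.0e-5, KDR 5.0e-3, KIR 1.0e-4, KRP 2.0e-4 S/cm² (soma and dendrites),
passive leak everywhere. One channel set serves both genotypes. The *rate
equations* behind those densities are not published; this package therefore
uses a generic Hodgkin–Huxley gate library (Boltzmann steady states,
constant or bell-shaped time constants) whose parameters are data, not code.
The shipped defaults were calibrated once against MSN-like behaviour:
hyperpolarized rest (≈ −87 mV, dominated by the inward rectifier KIR),
delayed spike onset, rheobase near 50 pA, a monotone f–I curve reaching
~20 Hz over the 10–80 pA step range used experimentally (500 ms steps), and
no depolarization block across the tested synaptic-drive range. Reversal
potentials default to E_Na = +50, E_K = −90, E_Ca = +120 (fixed, no GHK),
E_AMPA/NMDA = 0, E_GABA_A = −60 mV; passive defaults Cm = 1 µF/cm²,
Ra = 150 Ω·cm, g_leak = 8e-6 S/cm², E_leak = −70 mV. All are plain dataclass
fields and can be overridden wholesale.

**Numerics.** The membrane equation is advanced by an implicit θ-method
(backward Euler by default; Crank–Nicolson available). Gates advance by
exponential (Rush–Larsen) updates evaluated through voltage lookup tables
(0.1 mV resolution, rebuilt per run) between voltage solves; ionic and
synaptic conductances are frozen over each step, making the voltage update a
symmetric tree-structured linear system solved exactly in O(n) by ordered
(Hines) elimination. Default dt = 0.025 ms for clamp/step protocols and
0.05 ms for the 2 s ensemble trials. Synaptic events snap to the next grid
time. The hot loop is numba-compiled. Integration is bitwise deterministic
for identical inputs.

**Synapses.** Dual-exponential conductances normalized so the peak equals
`gpeak`: AMPA (τr 0.5 ms), GABA_A (τr 0.8 ms), NMDA (τr 3 ms), with
published starting peaks 7.2e-4, 3.6e-4 and 6.8e-5 µS. The NMDA Mg²⁺ block
(standard sigmoidal voltage dependence) is off in calibration protocols —
the constraining recordings were Mg-free — and on (1 mM) in the in-vivo-like
ensemble drive, where an unblocked NMDA tail at 100 inputs would produce an
unphysical tonic depolarization.

**Spike criterion.** Spikes are upward crossings of −20 mV at the soma with
a 2 ms refractory period. With sodium confined to the thin initial segment,
the axonal spike (+50 mV locally) attenuates to ≈ −15 mV at the soma, so a
0 mV somatic criterion would miss real spikes; the experimental spike
criterion is not published.

## Calibration to miniature PSCs

`simulate_mpsc` mimics the experimental constraint procedure: the somatic
voltage is pinned by an ideal clamp (V_hold = −70 mV for AMPA, +40 mV for
GABA_A/NMDA), one synapse is placed at a random dendritic location (uniform
per unit length), a single release event is delivered, and the electrode
current is recorded; the mean over iterations (100 in the full procedure,
fewer in tests) is summarized by amplitude, 20–80% rise, t₅₀ and a
mono-exponential decay fit. Voltage-gated channels are removed during clamp
runs, emulating the Cs⁺/QX-314 internal solution of the recordings; leaving
them in destroys space clamp at +40 mV. Series resistance is not modelled.
The clamped cell is settled once (400 ms) and every iteration branches from
the stored state.

`match_psc` finds (gpeak, τ_decay) reproducing a target (amplitude, t₅₀) by
a damped fixed-point iteration — somatic amplitude is nearly proportional to
gpeak and somatic t₅₀ nearly proportional to τ_decay — using identical
placement seeds per iteration so the search surface is deterministic.
Convergence tolerance defaults to 2% on both observables; parameter-recovery
tests tighten it because observable error amplifies into parameter error
through the cable-filtering floor.

**Targets.** Experimental A₁/τ₁ values per genotype appear only as figure
panels, so targets are package inputs. Defaults: AMPA amplitude 15.0 pA (WT)
vs 19.3 pA (KO) at −70 mV (the printed means) with t₅₀ 4.5 ms for both
genotypes (kinetics are genotype-similar experimentally; dendritic filtering
on the large KO arbor imposes a ≈4.3 ms somatic floor, so a faster shared
target would be unreachable); GABA_A 25 pA/8 ms (WT) vs 19 pA/6 ms (KO),
encoding the measured direction — smaller, faster knockout mIPSCs — at
magnitudes typical of mIPSCs at +40 mV; NMDA amplitudes 5.8/6.3 pA from the
driving-force product (AMPA amplitude × NMDA/AMPA ratio × 40/70).

## Morphometry

Sholl profiles count transversal crossings of concentric spheres centred on
the soma-node centroid; the squared distance along a segment is convex, so
crossings are the real roots of a quadratic in (0, 1] — a segment crossing a
shell twice counts twice, tangency counts zero, a tip exactly on a shell
counts. 3D distances are the default, with an `xy` projection switch
(2D-projection tracing is common). The geometric centroid ⟨t⟩ is the
count-weighted mean radius; the maximum radius is the largest non-empty
shell. Neuropil coverage is the convex-hull area of the xy-projected
dendritic nodes — the published polar-plot "coverage area" has no printed
formula, and the hull is the simplest reproducible surrogate. Branches are
maximal unbranched dendritic paths delimited by the soma, branching points
(≥2 dendritic children) and tips; branch lengths sum exactly to the total
dendritic cable length. The axon is excluded from all dendritic metrics.

## Synthetic data

The morphology generator grows `n_primary` dendrites from a spherical soma;
branch lengths are Normal draws, direction wanders, and branches bifurcate
with probability `branching_prob` to `max_depth`, rejecting realizations
outside the target total length ± tolerance. Presets encode the genotype
contrast: WT 1500 µm target, 4 primaries, p = 0.65, depth 3; KO 3000 µm
(the reported ~twofold difference), 5 primaries, p = 0.72, depth 4 — giving
more branches, more branching points and a larger maximal Sholl radius, with
similar mean branch length. The event-trace generator (Poisson events,
lognormal amplitudes — mPSC distributions are right-skewed — linear
summation, Gaussian noise) and the per-cell genotype dataset generator ship
their generating parameters so every metric is validated as recovery.

What the generators do *not* emulate: spine geometry, series-resistance and
line-noise artifacts, correlated input statistics, dopamine neuromodulation,
and network feedback. Passing tests therefore demonstrate correctness of the
analysis chain on data with the stated statistical structure, not fidelity
of the generator to every feature of the recordings.

## Input–output mapping

Each ensemble gives the cell `n_exc` excitatory (AMPA+NMDA at the same
sites) and `n_inh` GABA_A inputs placed uniformly per unit dendritic length.
Per iteration, each input's activation frequency is an independent
truncated-Normal draw (sd = 20% of the nominal rate) and events follow a
Poisson process (jittered-regular available). Grid cells average
`n_iterations` independent ensembles; all seeds derive from
(base_seed, cell row, cell column, iteration), so the surface is
reproducible and cells are independently parallelizable. The wild-type cell
receives 100 E + 100 I inputs; the knockout excitatory count scales with its
total dendritic length (spine density is genotype-independent, so synapse
number follows cable length), while the inhibitory count stays at 100.

Iso-firing contours use marching squares with linear interpolation
(scikit-image) mapped into (f_exc, f_inh) coordinates; `excitation_threshold`
gives the per-inhibition-level excitation rate at which mean firing crosses
a level, the robust scalar used for the genotype contour-shift comparison.
Gain/offset are quantified by a threshold-linear fit
r = gain·max(0, f − offset) (coarse offset scan with closed-form gain, then
local least squares); a 4-parameter logistic is available, with gain = max
slope and offset = half-activation rate. `compare_io` classifies changes as
additive/subtractive (offset) and multiplicative/divisive (gain) against
stated tolerances.

**Problem sizes.** The shipped analyses use a 4×4 grid (excitation 0–21 Hz,
spanning the theta ~8 Hz and beta ~20 Hz bands; inhibition 0–100 Hz),
10 iterations per cell and 2 s trials, with full 100-iteration runs available
through the same API. Tests calibrate synapses with 5–10 placement
iterations; the full procedure uses 100.

## Known limitations

* Channel kinetics are behaviourally constrained stand-ins, not the original
  model's rate equations; quantitative firing rates should be read as
  model-relative, and the package's claims about genotype effects are
  orderings (contour shifts, monotonicity), not absolute rates.
* The somatic voltage-clamp is ideal (no series resistance) and the somatic
  spike is attenuated because sodium is axonal only.
* Calcium dynamics, GHK fluxes, tonic GABA currents (experimentally similar
  across genotypes) and stochastic channel gating are omitted.
* The GABA_A reversal used in current-clamp ensemble runs (−60 mV) is a
  defensible but unverified choice; the experimental value is not published.
* Uncertainty is not propagated through the GABA-source decomposition; the
  shares are point estimates, as reported.
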