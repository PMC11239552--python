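# Methods

`fibrosim` simulates re-entrant arrhythmias in a two-dimensional sheet of
human ventricular tissue in which fibrotic scar is represented as a smoothly
varying reduction of the diffusion coefficient, textured by a Gaussian random
field (GRF).  This note records the models, the numerical choices, and the
limits of what the test suite demonstrates.

## Tissue and cell electrophysiology

Voltage obeys the monodomain equation

    dV/dt = div( D(x,y) grad V ) − I_ion / C_m,

on a 10 × 10 cm sheet (default), isotropic, with no-flux edges.  Membrane
kinetics are the ten Tusscher–Panfilov 2006 (TNNP06) human ventricular
epicardial model, configured for steep action-potential-duration (APD)
restitution: G_Kr = 0.172, G_Ks = 0.441, G_pCa = 0.8666, G_pK = 0.00219
nS/pF, and tau_f doubled for V > 0 mV.  Currents are expressed in pA/pF, so
the voltage equation uses dV/dt = −(I_ion + I_stim) directly; the membrane
capacitance constant (0.185 µF/cm²) enters the ionic concentration balances.
A −52 pA/pF stimulus is depolarising.

The steep parameter set is cited rather than reprinted in most of the
literature, and two readings of its f-gate modification circulate (halving
versus doubling of tau_f at depolarised potentials).  The package adopts the
doubling: it gives a single-cell APD(−70 mV) of ≈ 268 ms at a 400 ms cycle
length, makes the steep restitution curve converge to the default
parameter set at long diastolic intervals, produces an S1S2 restitution
slope well above 1 at short diastolic intervals, and — decisive for this
package — reproduces the scale of the first dynamically triggered premature
coupling interval (~300 ms on the thin strip versus 323 ms at full scale).
The halving variant yields APD ≈ 193 ms and coupling intervals near 215 ms,
inconsistent with the tissue-level behaviour this package targets.

With this parameter set, 10 s of quiescent integration settles at
V ≈ −86.55 mV rather than the nominal −86.2 mV: the sevenfold-raised
sarcolemmal Ca pump lowers diastolic Ca²⁺, and the Na/Ca exchanger then
hyperpolarises the cell slightly.  The same code with the default (slope
1.1) conductances rests at −86.26 mV, which matches published TNNP06
behaviour and is the evidence that the port itself is sound.  −86.2 mV is
retained as the *initial condition* of tissue simulations (all simulations
start pacing immediately and never sit quiescent), and `initial_state()`
returns the 10 s relaxed state, which is a fixed point to < 0.01 mV/s.

## Numerics

Explicit operator splitting per 0.05 ms cycle: first the reaction term at
every excitable node, then one forward-Euler diffusion step.  The diffusion
term uses a conservative five-point flux-form stencil with arithmetic-mean
face diffusivities; faces touching an uncoupled node, and all boundary
faces, carry zero flux.  The stability bound dt ≤ dx²/(4 D_max) = 0.156 ms
holds with a wide margin at dt = 0.05 ms, dx = 0.25 mm.

The reaction term integrates gates with the Rush–Larsen exponential scheme
(unconditionally stable for gates: they cannot leave [0, 1]) and voltage
plus concentrations with forward Euler, using an adaptive substep: 0.001 ms
whenever |dV/dt| > 1 mV/ms (upstroke and steep repolarisation), otherwise
up to 0.1 ms, always subdividing the 0.05 ms cycle exactly.  The tissue
kernel tabulates all voltage-dependent rate quantities on a 0.01 mV grid
(linear interpolation) and freezes reversal potentials over each 0.05 ms
cycle; both shortcuts are validated against the direct-formula single-cell
integrator (agreement within 0.5 mV away from the upstroke, APD within
1 ms) and against a dt = 10⁻⁴ ms reference integration (within 1 mV).
Removable singularities in the rate formulas (the Goldman-type I_CaL factor
at V = 15 mV) are evaluated by series limit.

## Scar structure

A zero-mean, unit-variance GRF with squared-exponential covariance
k(r) = exp(−r²/(2ℓ²)) is sampled exactly by circulant embedding: the
covariance is embedded on a torus at least twice the grid plus five length
scales per axis (FFT-friendly size), its FFT eigenvalues are clamped at
−10⁻⁶ of the maximum (round-off negatives reach ~10⁻⁸ at ℓ = 10 mm), and
one sample is the real part of the FFT of complex white noise scaled by the
square-root eigenvalues.  Length scales 1.25–10 mm span diffuse to patchy
fibrosis texture.

The GRF maps to diffusion as D_GRF = D_max (GRF + 2)/4 with
D_max = 0.1 mm²/ms, then two scar lobes centred at one- and two-thirds of
the sheet diagonal are superposed through paired logistic radial weights
(infarct radius 12.5 mm, border radius 30 mm, slope 0.075/mm), and the
result is clipped once to [0, 0.1].  Six coupling models derive from this
smooth field: ThresholdD (binary 0/0.1 at the 0.025 threshold, zero regions
uncoupled), SmoothD (field kept above 0.025, zeroed and uncoupled below),
ContinuousD (field kept everywhere; below 0.025 the membrane current is
fixed to zero but diffusion is retained), and their `-random` variants with
percolation-style node removal: remove when a uniform draw exceeds 20 D,
i.e. with probability max(0, 1 − 20 D).  The removal probability is always
evaluated on the smooth pre-model field — evaluating it on the binarised
ThresholdD field would make it identically zero in excitable tissue,
contradicting the stated edge probability of 0.5 — and removal uses its own
RNG stream, independent of the GRF seed.

## Pacing and post-processing

Stimuli (−52 pA/pF, 2 ms) go to a 1.25 mm disc centred 18.5 mm from the
lower-left edges: 3 S1 beats at 0/400/800 ms, then up to 5 premature S2
stimuli each fired at the first 0.05 ms step at which the *maximum* voltage
over the disc has fallen below −84.5 mV (the whole site must recover — the
conservative reading of the recovery trigger).  A `fixed_s2` mode delivers
one premature beat at a set coupling interval instead (used for
activation-delay and APD-difference maps).

Recordings sample every node each 1 ms.  LAT and APD derive from linearly
interpolated crossings of −70 mV inside beat windows anchored at stimulus
events; activation delay subtracts a uniform-diffusion (D = 0.1, no scar)
baseline beat-for-beat relative to stimulus onset.  Dispersion statistics
(median, IQR, inter-decile range) use linear interpolation of order
statistics over defined nodes.  Active wavefronts at time t are
4-connected components of nodes below threshold at t − 20 ms with an upward
crossing inside the 20 ms window; sustained re-entry means ≥ 1 wavefront at
3.0 s, transient means wavefronts at 2.6 s but none at 3.0 s.

## Problem sizes in the test suite

The full experiment (20 samples × 4 length scales × 6 models, 3 s each on
the 400 × 400 sheet) is implemented and scriptable but takes cluster-scale
compute; the package's own test suite exercises the same physics at reduced
size, chosen as the smallest domains that still express each phenomenon:

* single-cell runs for rest state, restitution, refractoriness and the
  fine-step integration oracle;
* a 25 × 4 mm strip (the same geometry used to illustrate model-dependent
  block) for full-protocol propagation, dynamic S2 coupling intervals, and
  the ThresholdD/ContinuousD block ordering.  On this strip the first
  dynamic coupling interval measures ≈ 295 ms against 323 ms at full scale;
* 100 × 100 pure-diffusion sheets for the conservation oracle, and 10 × 10
  grids for the dense-matrix discretisation oracle.

The default strip profile descends from 0.1 to a 0.024 mm²/ms plateau; in
ContinuousD that plateau stays diffusively coupled, while ThresholdD and
SmoothD seal it off behind a no-flux boundary.

What the passing tests do *not* show: re-entry incidence statistics across
the 480-run grid (they need the full 3 s sheet simulations), anisotropy or
3D effects (out of scope), and any fidelity of the GRF texture to real
fibrosis imaging — the generator reproduces the prescribed covariance, not
histology.

## Known limitations

* **Coupled-inexcitable regions hold charge.**  With I_ion fixed to exactly
  zero, passive scar has no leak pathway: charge injected by each beat
  drains only diffusively (time constant L²/D — seconds for a
  centimetre-scale region).  After the S1 train the coupled scar is
  pre-charged and does not behave as the electrical sink one might expect;
  measured block thresholds for premature beats on the strip are identical
  across the three base models (block always occurs at the pacing source),
  and a charged passive tail can even help marginal beats penetrate
  slightly farther in ContinuousD than in ThresholdD.  The test asserting
  that a premature beat blocks in ContinuousD while conducting in
  ThresholdD is accordingly expected to fail under this model reading; a
  coupled scar with a retained resting conductance would behave
  differently, but that is a different model.
* The dynamic S2 trigger can release a stimulus into tissue whose sodium
  system has not yet recovered even though voltage has (the slow j gate,
  with a time constant near 80 ms at diastolic potentials, lags the voltage
  tail); such a beat fails to capture and the next trigger follows tens of
  ms later.  Captured-beat intervals therefore alternate more strongly on
  the strip (295 / 39 / 222 / 52 / 231 ms) than the printed full-scale
  sequence suggests.
* Coupled-but-inexcitable nodes carry no cell state (I_ion ≡ 0 exactly);
  if a pacing disc overlapped such nodes the stimulus current would still
  be applied there (it never does in the default geometry).
* The per-node adaptive substep rule is a two-level scheme; error control
  is by the fine-step oracle, not a local error estimate.
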