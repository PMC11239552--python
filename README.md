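# fibrosim

Re-entrant arrhythmias in 2D ventricular tissue with fibrotic scar modelled
as a Gaussian random field.

Fibrotic scar slows and blocks cardiac action-potential propagation and is a
major substrate for ventricular tachycardia, but there is no consensus on how
to represent the mixture of myocytes, fibroblasts and collagen in tissue-scale
models.  `fibrosim` is for computational cardiac electrophysiologists who want
to study how that modelling choice matters.  It builds structural scar models
with controllable texture, applies six different electrical couplings between
normal and fibrotic tissue, provokes re-entry with aggressive pacing, and
quantifies the outcome.

## The model

* **Structure.** A stationary Gaussian random field with squared-exponential
  covariance `k(r) = exp(-r²/2ℓ²)` (length scale ℓ = 1.25–10 mm, sampled
  exactly by FFT circulant embedding) is mapped to a diffusion field
  `D_GRF = D_max (GRF + 2)/4` and shaped into a two-lobe scar with a central
  isthmus by paired logistic radial weights (infarct radius 12.5 mm, border
  zone radius 30 mm), then clipped to [0, 0.1] mm²/ms.
* **Coupling models.** `ThresholdD`, `SmoothD`, `ContinuousD` and their
  `-random` percolation variants translate the smooth field into per-node
  diffusion plus a class: normal, inexcitable-uncoupled (no-flux island), or
  inexcitable-coupled (membrane current fixed to zero, diffusion retained).
* **Electrophysiology.** The monodomain equation
  `∂V/∂t = ∇·D∇V − I_ion/C_m` with the ten Tusscher–Panfilov 2006 epicardial
  cell model in its steep-restitution configuration; explicit finite
  differences (Δx = 0.25 mm, diffusion Δt = 0.05 ms), Rush–Larsen gating with
  an adaptive 0.001–0.1 ms reaction substep.
* **Protocol and metrics.** 3 S1 beats (400 ms cycle length) then up to 5
  premature stimuli, each fired as soon as the pacing disc recovers below
  −84.5 mV.  Post-processing yields local activation time and APD maps
  (−70 mV threshold), activation delay against a uniform-diffusion baseline,
  dispersion statistics, and a re-entry classification from 20 ms active
  wavefronts at 2.6 s / 3.0 s (none / transient / sustained).

## Worked example

Propagate the full pacing protocol down a 25 × 4 mm strip whose diffusion
descends from 0.1 mm²/ms into a sub-threshold fibrotic tail, under two
coupling models:

```python
from fibrosim.experiment import make_strip_fixture, default_strip_profile
from fibrosim.pacing import PacingProtocol
from fibrosim.solver import NumericsConfig, simulate

protocol = PacingProtocol(site_center=(2.0, 2.0))   # pace the left end
numerics = NumericsConfig(duration=1500.0)
for name in ("ThresholdD", "ContinuousD"):
    model = make_strip_fixture(default_strip_profile, name)
    rec = simulate(model, protocol, numerics)
    print(name, [(round(t, 1), lbl) for t, lbl in rec.stim_events])
```

```
ThresholdD [(0.0, 'S1'), (400.0, 'S1'), (800.0, 'S1'), (1095.3, 'S2'), (1134.7, 'S2'), (1356.3, 'S2'), (1408.4, 'S2')]
ContinuousD [(0.0, 'S1'), (400.0, 'S1'), (800.0, 'S1'), (1095.2, 'S2'), (1134.5, 'S2'), (1355.9, 'S2'), (1406.8, 'S2')]
```

The three S1 beats arrive on schedule; the first premature stimulus fires
295 ms after the last S1 — the local recovery time of the pacing site — and
later intervals shorten as APD restitution engages.  The coupling sequence is
essentially identical across models because recovery at the unmodified pacing
site controls it; what differs between models is the electrical environment
the beats then propagate into — `ThresholdD` seals the fibrotic tail behind a
no-flux boundary, while `ContinuousD` keeps it diffusively coupled, so charge
flows between active tissue and scar.  How much that distinction matters (and
in which direction) is exactly what this class of simulations probes; see
`docs/methods.md` for what this package finds at strip scale.

A 481-run experiment grid (20 GRF samples × 4 length scales × 6 models plus
a uniform baseline) is available through `fibrosim.experiment.run_experiment`
or the `fibrosim experiment` CLI; each 3 s full-sheet simulation takes on the
order of an hour of CPU, so the grid is meant for batch execution.

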