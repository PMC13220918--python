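# flimlite

Analysis toolbox for fluorescence lifetime imaging (FLIM/FLI) data:
phasor analysis with instrument-response calibration (including per-pixel
calibration for SPAD-camera data), automatic universal-circle reference
finding, two-component decomposition into amplitude-averaged lifetime
maps, and single/double-exponential decay fitting by iterative
reconvolution — with a ground-truthed synthetic-data generator so every
stage can be exercised without instrument data.

It is written for microscopists and image-analysis developers who need a
scriptable, reproducible counterpart to interactive FLIM GUIs: every
step is a plain function over documented containers, every result is a
CSV/JSON file, and a config-driven pipeline chains the standard
two-component workflow end to end.

## The model

A FLIM dataset is a photon-count cube `counts[time_bin, row, col]`
acquired under pulsed excitation with laser period *T* (frequency
*f* = 1/*T*). Two complementary analyses are provided.

**Phasor analysis.** Each decay is mapped to its normalized Fourier
coefficient at harmonic *n* of the repetition frequency (ω = 2π*n*/*T*):

    g = Σₖ cₖ cos(ω tₖ) / Σₖ cₖ ,   s = Σₖ cₖ sin(ω tₖ) / Σₖ cₖ .

Single-exponential decays of lifetime τ fall on the *universal circle*
g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²); mixtures fall inside it on the chord
between their components. Instrument effects are removed by complex
division by the phasor of a reference of known lifetime (an IRF is a
τ = 0 reference), pixel-wise if the IRF varies across the detector.
Reference finding intersects the principal axis of inertia of the
calibrated phasor cloud with the universal circle; decomposing a phasor
onto the chord between the two references gives intensity fractions
f₁ + f₂ = 1 and the amplitude-averaged lifetime
⟨τ⟩ₐ = 1 / (f₁/τ₁ + f₂/τ₂).

**Decay fitting.** The forward model is the steady-state periodic
response Σᵢ aᵢ e^(−t/τᵢ) / (1 − e^(−T/τᵢ)) circularly convolved with the
unit-normalized, shiftable IRF, plus a flat background. It is fitted per
decay or per pixel by unweighted least squares, Neyman-weighted least
squares (σ² = max(n, 1)), or Poisson maximum likelihood (deviance
minimization).

## Worked example

Simulate a field of 20 bi-exponential cells (components 1.0 / 3.5 ns,
78.02 MHz laser, Gaussian IRF, Poisson noise) and run the two-component
phasor workflow:

```python
from flimlite.workflow import run_workflow

out = run_workflow({
    "simulate": {"n_cells": 20, "counts_per_cell": 1e5},
    "seed": 1,
}, "example_out")
print((out / "references.json").read_text())
```

The references JSON produced by this exact call reads (abridged):

```json
{
  "tau1_ns": 0.9501704430693211,
  "tau2_ns": 3.375750001181867,
  "message": "all valid phasors"
}
```

i.e. the major axis of the 20 calibrated ROI phasors crosses the
universal circle near the true 1.0 and 3.5 ns components. The companion
`decomposition.csv` lists per-cell fractions and ⟨τ⟩ₐ (within 2.6% of
the generator's ground truth at this seed, `truth.csv`), and
`peak_fit.json` holds the Gaussian fit of the ⟨τ⟩ₐ histogram
(mean 1.530 ns vs population mean 1.554 ns here). The same pipeline runs
from the shell:

```bash
flimlite workflow --config config.json --out example_out
flimlite simulate --out scene --seed 1        # scene + mask + IRF + truth
flimlite fit scene/dataset.h5 --irf scene/irf.txt --out maps --method mle
```

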