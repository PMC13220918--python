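# Methods

## Data model

All analyses consume a `FLIDataset`: a non-negative count cube
`(time_bin, row, col)` with a `TimeAxis` holding the laser period *T*
(ns), the repetition frequency *f* = 1000/*T* (MHz) and the bin-center
times. Times are stored as **bin centers** throughout; no sub-bin
interpolation is used anywhere in the phasor path. This removes the
half-bin ambiguity from downstream formulas at the cost of a small,
quantified discretization residual (below).

## Phasor transform and calibration

The phasor of a decay at harmonic *n* is the count-normalized discrete
Fourier sum over bin centers with ω = 2π*n*/*T*. Calibration is complex
division by a measured reference phasor followed by multiplication by
the ideal universal-circle (UC) phasor of the reference's lifetime;
τ_ref = 0 (an IRF) makes the second factor unity. Per-pixel mode divides
pixel-wise, which is what SPAD-array data with spatially varying IRF
arrival times require; the synthetic generator can inject a smooth
per-pixel shift field to exercise exactly this.

**Discretization residual.** Midpoint sampling of a circular convolution
carries a residual half-bin phase: after IRF-phasor calibration a
noiseless mono-exponential sits ~e^(−iωΔt/2) away from its ideal UC
point. The displacement scales as 1/n_bins: ≈5·10⁻⁴ phasor units at
4096 bins, ≈2·10⁻³ at 1024 bins (ω ≈ 0.49 rad/ns). It is common to all
pixels and largely cancels in *differences* of lifetimes; calibrating
against a same-grid single-exponential reference of known lifetime
cancels it almost completely (residual ~10⁻⁷ at 4096 bins), which is the
configuration used for the phasor-vs-fit consistency check.

## Reference finding (principal axis ∩ universal circle)

Valid phasors — optionally restricted to phasor-plot selection regions
and optionally intensity-weighted — are summarized by their mean and the
2×2 second-moment matrix about the mean (the inertia tensor of the
scatter). The line through the mean along the major (or minor)
eigenvector is intersected with the circle of center (½, 0), radius ½ by
solving the quadratic; the two roots, ordered short-lifetime-first
(larger g), become the reference pair with lifetimes τ = s/(gω).
Weights default to *none* (each valid phasor counts equally); intensity
weighting is available but changes results only for heteroscedastic
clouds. Degeneracies raise typed errors: an isotropic cloud
(eigenvalue gap < 10⁻⁹ of the trace) has no preferred axis; a
discriminant below 10⁻¹² means the axis misses (or is tangent to) the
circle — tangency reports the single touch point in the error object.

Conditioning note: the axis direction is estimated to
~(σ_perp/σ_axis)/√N rad, so reference quality degrades when the phasor
cloud is short (a population with little lifetime heterogeneity) or
sparse. With 20 ROIs spread over ~8% of the chord the recovered
reference lifetimes are within ~5% of the true components, which biases
per-cell ⟨τ⟩ₐ by ≲2%.

## Two-component decomposition

A phasor is decomposed by orthogonal projection onto the chord between
the references; the projection coordinate is the **intensity** fraction
f₁. Projections outside [0, 1] are clamped and flagged, never
extrapolated; the perpendicular distance to the chord is kept as a
residual, and an optional residual band (a perpendicular-distance
threshold) marks decompositions invalid so maps and histograms can
exclude them. Intensity fractions convert to amplitude fractions by
aᵢ ∝ fᵢ/τᵢ, giving ⟨τ⟩ₐ = 1/(f₁/τ₁ + f₂/τ₂) ∈ [τ₁, τ₂].

## Decay fitting

The reconvolution model evaluates the wrapped multi-exponential at bin
centers — the amplitude factor 1/(1 − e^(−T/τ)) is the steady-state
periodic-excitation sum — and circularly convolves it (FFT) with the
unit-normalized IRF, shifted by a free time offset via periodic linear
interpolation. The IRF shift is fitted by default because color shift is
the dominant reconvolution nuisance. Objectives:

* unweighted SSE;
* Neyman-weighted χ² with σ² = max(n, 1) (standard TCSPC practice);
* Poisson deviance 2Σ[m − n + n ln(n/m)], expressed as signed
  square-root deviance residuals so one bounded trust-region
  least-squares solver (`scipy.optimize.least_squares`, trf) serves all
  three. Near-exact fits evaluate δ − log1p(δ) by series for |δ| < 10⁻³;
  without this the cancellation noise floors the fit around 10⁻⁵
  relative error instead of machine precision.

Bounds: τ ∈ [10⁻³, 10³] ns, a ≥ 0, B ≥ 0, |shift| ≤ T/2. Initialization
is deterministic: background from the minimum bin, lifetime from a
log-linear regression on the tail beyond the peak, two-component starts
split τ by ×/÷2. Components are reported in canonical order τ₁ < τ₂.
`chi2_reduced` is the Neyman χ² per degree of freedom for the NLSF
methods and deviance/dof for MLE; the covariance is (JᵀJ)⁻¹ at the
optimum (scaled by SSE/dof for the unweighted objective). At 10⁵ counts
the MLE lifetime shows the known small negative bias, ~0.5 of one
replicate standard deviation.

## Synthetic scenes

`simulate_scene` emulates a confocal-TCSPC acquisition of a field of
cell-shaped regions: non-overlapping random ellipses (semi-axes 3–6 px)
in a 64×64 frame, 1024 time bins over one period of a 78.02 MHz laser
(~12.5 ps bins, typical of TCSPC electronics), a Gaussian IRF (FWHM
0.3 ns, centered at 2 ns), 10⁵ expected photons per cell spread evenly
over its pixels, a faint flat background (0.05 counts/bin) outside the
cells, and independent per-bin Poisson draws. Each cell draws its decay
from a `Population`: two shared lifetime components (defaults 1.0 and
3.5 ns) mixed with a per-cell short-component intensity fraction
f₁ ~ N(0.5, 0.02) clipped to [0.02, 0.98] — the tight unimodal spread
(≈2% CV in ⟨τ⟩ₐ) of a clonal population in a steady state, which is the
regime in which a 20-sample lifetime histogram is meaningfully
summarized by a Gaussian mean and width. A uniform `f1_range` option
produces deliberately broad mixtures instead. Everything is a pure
function of the seed.

What the generator does **not** emulate: optical blur (cells have hard
edges), detector afterpulsing and crosstalk, read noise, count-rate
pile-up (available separately as a correction, not as a corruption), and
instrument drift. Passing tests therefore demonstrate correctness of the
analysis chain under ideal photon-counting statistics, not robustness to
every instrumental artifact of real hardware.

## Histograms and peak fitting

Parameter maps carry an explicit set/unset mask (CSV export writes empty
fields, since NaN conventions vary across CSV dialects). Histogram peak
fitting is least squares of a sum of area-parameterized Gaussians over
bin centers. Means are constrained to the histogram range and widths to
half its span: on sparse histograms an unconstrained fit can converge to
a "half-Gaussian" ramp centered outside the data, which is never an
acceptable population summary. Initialization is deterministic — the
tallest local maxima for multi-peak fits, the moment mean for a single
peak, with a moment-based common width. Even so, a single-Gaussian fit
to a histogram of only ~20 values estimates the population mean with an
intrinsic instability of up to ~0.5 of the sample standard deviation in
unlucky draws; with the default tight population this corresponds to
~1–2% of ⟨τ⟩ₐ.

## Pile-up and background

Pile-up correction inverts the one-photon-per-frame saturation map
n = N(1 − e^(−m/N)) for gated/SPAD-style acquisition over N frames:
m = −N ln(1 − n/N); counts at or above N are a hard error naming the
offending pixel and bin. Background subtraction (a constant, or the
per-pixel mean over a stated pre-pulse window) clamps at zero to keep
counts non-negative for weights and phasors; the clamp bias is
negligible at count levels where analysis is meaningful. Note that under
periodic excitation the previous pulse's tail never fully vanishes, so a
"pre-pulse" window only estimates pure background when the lifetime is
well below the period.

## Problem sizes

Default test and acceptance runs use 256–4096 time bins, 20-cell 64×64
scenes at 10⁵ photons/cell, 100-replicate noise studies and 500-point
phasor clouds — sizes at which every stated tolerance is resolvable and
the whole suite completes in well under a minute of CPU.
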