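# Methods

This note records the models implemented in `ecmfluor`, their assumptions,
the defaults of the synthetic-data generators, and the numerical choices
made where the design was genuinely open.  No empirical claim appears here
that the test suite or `scripts/acceptance.py` does not itself compute.

## Two-state dye photophysics

A fluorogenic glycan-binding dye is modeled as two states — unbound (free
in buffer) and bound (diol-engaged) — each carrying an absorbance spectrum
A(λ), an emission spectrum, a peak molar extinction ε and a quantum yield
Φ.  The signal of a pure state at an acquisition setting (one excitation
line λ_ex, one emission band) is

    S = Φ · (1 − 10^(−A(λ_ex))) · ∫_band emission(λ) dλ

The factor Φ(1 − 10^(−A)) is the wavelength-specific excitation
coefficient; it is a proportionality, and the constant is fixed to 1
because every quantity derived from it (renormalized spectra, ΔF/F,
excitation-scan responses) is a ratio in which the constant cancels.  A
mixed pixel or cuvette with bound fraction f gives the affine combination
S(f) = f·S_bound + (1−f)·S_unbound.

Assumptions: Beer–Lambert scaling of absorbance with concentration
(spectra are stored for a reference condition, 5 μM and 1 cm path);
linear interpolation between the stored wavelength samples; no
extrapolation outside the stored grid — queries beyond it raise rather
than invent photophysics.  Band integrals use the trapezoidal rule on the
stored grid clipped to the band; a longpass band integrates to the last
stored wavelength.  Two-photon cross-sections, solvatochromism and pH
effects on boronic-acid ionization are out of scope.

## Binding kinetics

Dye binding to an immobilized substrate under pseudo-first-order
conditions (dye in large excess, concentration C constant) approaches
equilibrium mono-exponentially:

    I(t) = Imax · (1 − e^(−kobs·(t − t0))) + b,    kobs = kon·C + koff

t0 absorbs the arbitrary moment of dye addition; the model is clamped to
the background b for t < t0.  KD = koff/kon.

Fitting: nonlinear least squares (`scipy.optimize.curve_fit`, trust-region
reflective, `x_scale='jac'`, tolerances 1e-14) with a deterministic
initialization — b₀ = min I, Imax₀ = max I − min I, kobs₀ from the
log-linearized tail slope of (Imax₀ + b₀ − I), t₀₀ = first time I exceeds
b₀ + 5% of Imax₀ — and a multi-start over {0.3, 1, 3}×kobs₀, keeping the
lowest-RMS fit.  Bounds: kobs ∈ (10⁻⁷, 1) s⁻¹ (physically plausible for
hour-scale binding), Imax > 0, t0 ∈ [0, t_max/2].  A flat trace (range
< 10⁻⁹ of its mean) raises a "not identifiable" error.  Parameter standard
errors come from the fit covariance; the 95% CI for kobs uses the t
distribution with n − 4 degrees of freedom.

The kobs-versus-concentration regression is ordinary least squares by
default; inverse-variance weighting by the per-fit kobs standard errors is
available but not default, since the choice of weighting is an experiment
design decision, not a property of the data.  With two points the line is
exact and the uncertainty columns degenerate to NaN.  A nonpositive fitted
intercept leaves KD undefined (flagged, with a warning) rather than
reporting a negative dissociation constant.

Affine invariance of kobs under intensity rescaling (I → aI + c) holds to
optimizer precision (~10⁻⁴ relative), not bit-exactly; Imax and b
transform accordingly.

Default simulated experiment: concentrations {2.5, 5, 10, 20} μM —
a 2×-spaced ladder bracketing the 5 μM working concentration typical for
such probes — 181 frames over 3 h (one per minute), Imax = 100 a.u.,
t0 = 60 s, b = 10 a.u., additive Gaussian noise of 2% of Imax, generating
rates kon = 12.8 M⁻¹s⁻¹ and koff = 6.77×10⁻⁴ s⁻¹ (KD ≈ 53 μM).  At 5 μM
these give kobs = 7.41×10⁻⁴ s⁻¹, a half-rise of ln2/kobs ≈ 935 s
(≈ 15.6 min) and a 90% rise of ln10/kobs ≈ 3107 s (≈ 52 min).

## Hyperspectral excitation scans

An excitation scan steps the laser from 500 to 566 nm in 2 nm increments
with detection at 575–630 nm, so each pixel carries an excitation
spectrum.  "Peak wavelength" is the argmax over the sampled grid — no
sub-grid interpolation, because the acquisition is grid-valued and
interpolation would claim precision the scan does not have.  Spatial
binning (default 2 px) is a block mean applied *before* the argmax, with
trailing partial blocks dropped.  Ties break to the lowest wavelength, a
deterministic rule under which flat noise-floor pixels read maximally
blue and are visually distinct.  An optional intensity floor (fraction of
the global maximum total intensity) can mask background pixels; the
default of 0 keeps the full field.

## FLIM phasors

Per-pixel decay histograms over one laser period T = 1/rep-rate (default
80 MHz, a standard mode-locked Ti:Sapphire rate) are transformed at the
first harmonic with bin midpoints:

    g = Σ nₖ cos(ω tₖ) / Σ nₖ,   s = Σ nₖ sin(ω tₖ) / Σ nₖ,   ω = 2π/T

No instrument-response deconvolution is applied.  A mono-exponential
lifetime τ has the closed form g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²) — on the
universal semicircle — and the transform is linear in counts, so mixtures
lie on the segment between component phasors at the photon-weighted
fraction.  An exponential restricted to one period and renormalized *is*
the wrapped-decay distribution, so the closed forms hold exactly for the
simulated histograms; midpoint binning adds O((ωΔt)²) error, below 10⁻³
for ≥ 256 bins.  Gates are circles in (g, s); free-form ROIs add nothing
for two well-separated populations and circles are fully specifiable.
Default simulated lifetimes: 2 ns (free dye) and 3.5 ns (bound), 5000
photons/pixel, multinomial (photon-counting) noise.

## Glycan-array quantification and statistics

Spot signal is the mean over a disk (default radius 4 px); local
background is the *median* over an annulus (default radii 5.5–7.5 px),
robust to bleed from neighbouring spots; corrected = mean − median, and
the annulus SD feeds detection.  Corrected values are normalized within
each array by division by the array-wide mean corrected signal over all
spots — a normalizer that cancels any multiplicative gain while leaving
relative glycan signals untouched.  On a blank array (mean corrected
signal ≤ 0) the normalizer is undefined and normalized values are NaN.

Detection: corrected mean strictly greater than 2× the background SD.

Significance: each glycan's replicate values are compared to the pooled
negative controls (two sets of 4 spots pooled to n = 8 — pooling is the
natural choice given both sets are printing buffer) with a Welch t
statistic (unequal variances).  Family-wise adjustment follows Dunnett's
many-to-one logic, but the unequal-variance case has no closed form, so
the null distribution of max|T| over the family is simulated by seeded
Monte Carlo (default 10⁵ draws; adjusted p = (1 + #{draws ≥ |t|})/(draws
+ 1), monotone in |t| and reproducible).  In the homoscedastic,
well-replicated limit this agrees with the classical parametric Dunnett
procedure (cross-checked against `scipy.stats.dunnett` in the tests).
A glycan is a "hit" when it is both detected and significantly *increased*
(t > 0) versus controls.

Default simulated array: 100 glycans × 4 replicate spots plus two sets of
4 negative controls on a 24-column grid (16 px pitch); background 100
a.u., Gaussian noise SD 2 a.u. (2%), binders at amplitude 10 a.u. (5× the
noise SD), 98 binders / 2 non-binders — a structural analogue of a
commercial 100-glycan array in which nearly all glycans bind a
broad-specificity probe.  This is *not* a reproduction of any particular
array's raw images, which are not publicly deposited.

## Photostability

For a reversibly bound dye with bound-state photobleaching rate k_b:
without exchange the trace is I₀·e^(−k_b·t); with exchange each frame
bleaches a fraction 1 − e^(−k_b·Δt) of the *bound* molecules, which
re-equilibrate into a free pool `free_pool_excess` times the bound pool,
so the unbleached fraction decays by factor (1 − q·w) per frame with
w = 1/(1 + excess).  The default excess of 1000 reflects a benchtop
configuration — microliters of substrate coating under milliliters of
micromolar dye solution — and yields < 0.1% loss over 9.6 h; an excess of
100 stays under 1%.  The default k_b = 10⁻⁵ s⁻¹ makes the no-exchange
control lose ≈ 29% over the same window, so the two regimes are clearly
separated.  The model has no spatial diffusion; it is the minimal
embodiment of the free-pool-replenishment mechanism.

The bleaching metric compares the mean of the first and last 5% of frames
(windows of ≥ 3 frames, fraction configurable) and also reports the
least-squares slope divided by the trace mean (per hour).  Window
averaging biases the relative change toward zero by about half a window
of decay (≈ 1.2% for a 29% total loss), which is why the closed-form
comparison in the tests carries a 2% tolerance.  "No loss" is
operationalized as relative change ≥ −1%.

## Synthetic dye defaults

The generator dye uses Gaussian spectral bands.  Unbound absorbance peaks
at 548 nm, bound at 561 nm (13 nm red shift); unbound emission at 573 nm,
bound at 587 nm (14 nm shift); band σ = 7 nm (absorbance) and 12 nm
(emission); ε = 4×10⁴ / 6×10⁴ M⁻¹cm⁻¹ and Φ = 0.25 / 0.50 for
unbound/bound (binding increases both, as observed for turn-on probes).
The absorbance bandwidth is chosen so the excitation-scan response is
well-resolved on the 2 nm scan grid — with σ = 7 nm the response drops
measurably between adjacent grid steps, and the per-pixel argmax is
stable at the generator's default noise; real rhodamine bands are broader
(σ ≈ 15–20 nm), which is a recognized idealization of this generator.
The bound emission amplitude is calibrated analytically (emission is in
arbitrary units) so that ΔF/F at 561 nm excitation / 575 nm longpass
equals the configured target, default 7.3, exactly; ε and Φ are left at
their stated values.  Because the unbound absorbance tail at 561 nm is
small but finite, the dye also reproduces the qualitative filter-choice
effect: contrast at 561/575LP far exceeds contrast at 488 nm excitation
with a 500–545 nm band, where the blue-shifted free dye dominates.

What the generators do *not* emulate: optical PSFs, scattering and depth
attenuation, detector offsets/afterpulsing, spot-morphology defects, or
real tissue structure.  Passing round-trips on these synthetics therefore
validates the *estimators* (their identities, invariances and noise
robustness at the stated levels), not performance on real microscope data.

## Problem sizes

Defaults were chosen to keep every analysis exact or statistically stable
while remaining interactive: 181-frame timelapses × 4 concentrations × 20
replicate experiments for rate recovery; 64×64 px excitation-scan scenes;
32×32 px FLIM scenes at 5000 photons/pixel with 256 bins (4096 bins for
quadrature checks); one 100-glycan array per analysis plus a vectorized
2000-experiment null for the family-wise error check; 577-frame
photostability traces.

## Known limitations

* The kinetics fitter assumes a single exponential; multi-site or
  diffusion-limited binding is out of scope.
* Dunnett adjustment assumes equal replicate counts across glycans (true
  for printed arrays).
* The FLIM transform ignores the instrument response function; absolute
  lifetime placement on the semicircle is only as good as that
  approximation.
* Spot geometry comes from a layout config; there is no automatic grid
  registration.
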