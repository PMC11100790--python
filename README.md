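# ecmfluor

Analysis toolkit for experiments with fluorogenic glycan-binding dyes —
turn-on probes (e.g. boronic-acid-functionalized rhodamines) that brighten
and red-shift upon reversible binding to the diols of glycans, enabling
wash-free imaging of the extracellular matrix.  The package implements the
quantitative pipeline such an experiment needs, end to end, together with a
synthetic-data generator that produces every input with known ground truth.

It is written for microscopists and chemical biologists who characterize
fluorogenic probes: the photophysics, kinetics and statistics are ordinary
benchtop quantities, and every stage is a plain function over NumPy arrays
and pandas DataFrames, with an optional CLI on top.

## What it computes

**Two-state photophysics** (`ecmfluor.photophysics`).  A dye is modeled as
an unbound and a bound state, each with absorbance/emission spectra, molar
extinction ε and quantum yield Φ.  Signal at an acquisition setting uses the
wavelength-specific excitation coefficient *E*(λ<sub>ex</sub>) =
Φ(1 − 10<sup>−A(λex)</sup>) times the emission integral over the detection
band; fluorogenic contrast is ΔF/F = (F<sub>bound</sub> −
F<sub>free</sub>)/F<sub>free</sub>.

**Binding kinetics** (`ecmfluor.kinetics`).  Timelapses of dye binding to a
substrate follow the pseudo-first-order saturation model

I(t) = I<sub>max</sub>(1 − e<sup>−k\_obs(t − t₀)</sup>) + b,  k\_obs = k\_on·C + k\_off.

Each trace is fit by deterministic multi-start nonlinear least squares;
regressing k<sub>obs</sub> against concentration gives k<sub>on</sub>
(slope), k<sub>off</sub> (intercept) and K<sub>D</sub> = k<sub>off</sub>/
k<sub>on</sub>, with standard errors and 95% CIs.

**Hyperspectral excitation scans** (`ecmfluor.hyperspectral`).  Per-pixel
excitation spectra (500–566 nm in 2 nm steps) are reduced to ROI mean
spectra and to "spectral contrast" maps — the grid wavelength of each
(binned) pixel's maximal response, which separates red-shifted bound dye
from free dye.

**FLIM phasors** (`ecmfluor.flim`).  The first-harmonic phasor transform
maps decay histograms to (g, s); mono-exponential decays lie on the
universal semicircle g² + s² = g.  Circular gates select lifetime
populations (e.g. 2 ns free vs 3.5 ns bound) and map them back to image
masks.

**Glycan arrays** (`ecmfluor.arrayquant`).  Spot disks are corrected by a
local-background annulus median, normalized within each array, called
detected when the corrected signal exceeds 2× the background SD, and tested
against pooled negative controls with Welch t statistics under a
Dunnett-style family-wise adjustment (seeded Monte Carlo, since the
unequal-variance case has no closed form).

**Photostability** (`ecmfluor.photostability`).  ROI traces from long
timelapses (e.g. 9.6 h at one frame per minute) are summarized by the
relative first-to-last-window change and a mean-normalized slope; reversible
binding with a large free-dye pool predicts essentially no signal loss.

**Synthetic data** (`ecmfluor.synthetic`).  Seeded generators for all of
the above, with ground truth returned alongside the data.  The default dye
is red-shifted 13 nm (absorbance) / 14 nm (emission) on binding and
calibrated to ΔF/F = 7.3 at 561 nm excitation / 575 nm longpass; the default
kinetics use k<sub>on</sub> = 12.8 M⁻¹s⁻¹ and k<sub>off</sub> = 6.77×10⁻⁴ s⁻¹
(K<sub>D</sub> ≈ 53 μM).

## Worked example

Simulate a four-concentration binding experiment and recover the rate
constants:

```sh
$ ecmfluor simulate timelapse --seed 7 --out sim
wrote 4 timelapse(s) to sim
$ ecmfluor kinetics --input sim/timelapse_2.5uM.csv --input sim/timelapse_5uM.csv \
    --input sim/timelapse_10uM.csv --input sim/timelapse_20uM.csv --out kinetics.json
kon = 12.68 M^-1 s^-1, koff = 0.0006788 s^-1, KD = 53.5 uM
$ ecmfluor contrast
dF/F = 7.3 at 561 nm ex / 575 nm em
```

The simulated experiment (2% intensity noise) returns k<sub>on</sub> within
1% and K<sub>D</sub> within 1 μM of the generating values above;
`kinetics.json` holds the per-concentration fits (I<sub>max</sub>,
k<sub>obs</sub>, t₀, b with standard errors) and the regression block with
confidence intervals.  The same library calls are available in Python:

```python
from ecmfluor import synthetic, kinetics

points = []
for c in (2.5e-6, 5e-6, 10e-6, 20e-6):        # molar
    tl, truth = synthetic.simulate_timelapse(concentration_M=c, seed=1)
    points.append((c, kinetics.fit_binding_timelapse(tl).kobs))
rc = kinetics.fit_rate_line(points)
print(rc.kon, rc.koff, rc.kd)                  # ~12.8, ~6.8e-4, ~5.3e-5
print(kinetics.time_to_fraction(rc, 5e-6, 0.5) / 60)   # ~15.6 min half-rise
```

Other subcommands: `simulate {hyperspectral,flim,array,photostability}`,
`spectral-map`, `flim phasor`, `array`, `photostability` — see `--help`.

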