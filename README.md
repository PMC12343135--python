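# myomorph

Automated morphometry of striated-muscle myofibrils from two-channel
fluorescence micrographs, with a matching image simulator and scaled
myofilament-lattice models.  It is aimed at muscle-development labs
measuring sarcomere growth — the reference system is the *Drosophila*
indirect flight muscle (IFM), whose isolated myofibrils are near-perfect
cylinders with exceptionally regular sarcomeres — but the measurement
core applies to any preparation with a Z-disc marker channel and an
F-actin (phalloidin) channel.

## What it measures and how

**Sarcomere length.** A myofibril is segmented from the phalloidin
channel, its axis is extracted as an arclength-parameterised smoothing
spline, and the Z-disc channel is sampled along that axis.  The profile
is fitted jointly with a multi-Gaussian model

    I(s) = B + Σᵢ Aᵢ · exp(−(s − µᵢ)² / 2σᵢ²),

one Gaussian per Z-disc; sarcomere lengths are the successive
peak-to-peak distances µᵢ₊₁ − µᵢ.  Peak centres are insensitive to
diffraction blur, so no PSF correction is needed for lengths.

**Myofibril diameter.** Transverse profiles are fitted with a
PSF-convolved disc model: the 2D projection of a uniformly labelled
cylinder of radius *R* is the chord C(u) = 2√(R² − u²), and the observed
profile is

    I(x) = B + A · (C ⊛ G_σ)(x) / 2R,

with G_σ a Gaussian PSF approximation.  The fit returns the true
diameter 2R.  A naive full-width-at-half-maximum systematically
underestimates it — the FWHM of the bare chord is already
√3·R ≈ 0.87·2R — which is the main bias of manual measurements.

**Simulator.**  Synthetic two-channel micrographs with exactly known
ground truth: chord-weighted cylinder projections with Z-disc overlap
bands (double intensity) and H-zone gaps (zero), Gaussian labelling
noise, Airy-disc diffraction blur ((2·J₁(v)/v)², NA 1.4, λ 525 nm by
default) and Poisson shot noise.  All measurement code is validated by
parameter recovery on these images.

**Lattice models.**  Thick filaments pack hexagonally with spacing *d*;
thin filaments sit at the midpoints of nearest-neighbour thick pairs,
which makes every interior thick filament border six half-shared thin
filaments — the familiar 1:3 thick:thin stoichiometry emerges from the
geometry.  Scaled 3D sarcomere models (filament spans anchored at
Z-lines and the M-line) are built from per-stage band widths and export
to OBJ/CSV.  Helper functions convert band widths to filament lengths
(L_thick = L_s − W_I-band, L_thin = (L_s − W_H-zone + W_Z-disc)/2) and
filament-count time series to incorporation rates.

## Worked example

Simulate two myofibrils (6 sarcomeres of 3.2 µm, diameter 1.5 µm, full
noise model), analyse them back, and inspect the mature-stage models:

```sh
$ myomorph simulate --n-fibrils 2 --seed 11 --out demo.ome.tif
wrote demo.ome.tif (2 fibril(s), canvas 240x464)

$ myomorph analyze demo.ome.tif --out-prefix demo
n (experiments/measurements): 1/4
sarcomere_length_um: mean 3.2023 sd 0.0000
diameter_um: mean 1.5116 sd 0.0000
wrote demo_measurements.csv and demo_diagnostics.csv

$ myomorph morph --stage 24h_AE
L_thick = 3.240 um (3240 nm)
L_thin  = 1.680 um (1680 nm)

$ myomorph lattice --stage 24h_AE
stage 24h_AE: 846 thick / 4872 thin filaments, spacing 48 nm, D_eq 1.47 um
```

The analyser recovered the simulated ground truth to 0.07 % (sarcomere
length) and 0.8 % (diameter).  `n 1/4` means one experiment and four
individual sarcomere measurements (terminal sarcomeres are excluded by
default); the `sd 0.0000` is the between-experiment spread, zero with a
single experiment.  The mature-stage table gives 3.24 µm thick and
1.68 µm thin filaments, and 846 thick filaments at 48 nm spacing pack
into an area-equivalent diameter of 1.47 µm.

The same pipeline is scriptable from Python:

```python
from myomorph import AnalysisConfig, analyze
table, diagnostics = analyze("demo.ome.tif", AnalysisConfig())
print(table.grand)
```

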