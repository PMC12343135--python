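# Methods

## Scope and model

myomorph measures two morphometric traits of isolated striated-muscle
myofibrils — sarcomere length and myofibril diameter — from two-channel
fluorescence images (channel 0: phalloidin/F-actin, channel 1: a Z-disc
marker), and complements the measurements with a synthetic-image
simulator and geometric myofilament-lattice models.  The design targets
fibrillar insect flight muscle: cylindrical myofibrils lying flat in the
focal plane, high signal-to-noise, sparse fields.  Densely packed
whole-muscle sections are supported only through manual polylines.

## Image formation model (simulator)

A myofibril is a uniformly labelled cylinder.  Its ideal 2D projection
at transverse offset *t* from the axis is the chord 2√(R² − t²); along
the axis the F-actin density is 1 in thin-filament regions, 2 inside the
Z-disc overlap band of width `zdisc_width` centred on each Z-line (thin
filaments of adjacent sarcomeres interdigitate there), and 0 inside the
H-zone gap of width `hzone_width` centred on each M-line.  The fibril
extends half a Z-band past its first and last Z-line, so all
`n_sarcomeres + 1` Z-discs are complete; total Z-channel intensity is
therefore proportional to the Z-disc count at fixed geometry.  The
ground truth is evaluated analytically at 4× linear supersampling and
box-binned to the pixel grid, which suppresses aliasing of the cylinder
boundary at the default 50 nm pixels.  Each channel is normalised to a
peak of 100 grey levels.

Image degradation is applied in a fixed order:

1. **Uneven labelling** — zero-mean Gaussian noise, default σ = 2 grey
   levels on the peak-100 scale, clipped at 0.  The σ is expressed on
   this normalised scale because absolute fluorescence units are
   arbitrary.
2. **Diffraction** — convolution (reflect padding) with an Airy kernel
   (2·J₁(v)/v)², v = 2πNA·r/λ, default NA 1.4 / λ 525 nm; kernel radius
   15 px, normalised to unit sum.  Only the in-plane widefield/confocal
   PSF is modelled; no 3D optics or detector read noise.
3. **Shot noise** — multiplication by `photon_scale` (default 1.0,
   i.e. ≈100 expected photons at the brightest pixel, a typical confocal
   operating point) followed by a per-pixel Poisson draw.

A single integer seed drives both noise stages; identical seeds give
bit-identical images.  Curved fibrils are rendered as constant-curvature
arcs — adequate for robustness tests since real isolated fibrils are
nearly straight.

**What the simulator does not emulate:** out-of-focus light and z-stack
optics, detector-specific noise (EMCCD gain, read noise), labelling
chemistry artefacts (linkage error, bleaching), background from
neighbouring tissue, and diameter changes induced by sample
preparation.  Passing parameter-recovery tests therefore demonstrates
correctness of the measurement mathematics under the stated noise
model, not robustness to every failure mode of real micrographs.

## Segmentation and centerline

The phalloidin channel (max-projected if a stack) is median-filtered
(3×3) and thresholded; Otsu's method is the parameter-free default and
suits high-contrast isolated-fibril fields ("li", "yen" or a numeric
threshold are accepted).  Connected components shorter than
`min_length_um` (default 4 µm ≈ one mature sarcomere plus margin) are
dropped; the rest carry three QC flags: `touches_border`,
`overlaps_neighbour` (another component within 2 px) and
`branched_skeleton`.  Branching is detected by removing the skeleton's
longest geodesic path (dilated by 2 px) and checking whether any
residual branch exceeds one fibril width — boundary-noise spurs and
staircase corners leave only small residues, whereas crossing or forking
fibrils leave whole arms.  Flagged fibrils are excluded from automatic
analysis but reported, with reason codes logged.

The centerline is extracted in three steps: (i) the filled mask is
skeletonized and the longest geodesic path through the skeleton graph
(double-sweep Dijkstra, 8-connectivity) is taken as the initial axis —
robust to the loops and spurs that threshold noise creates; (ii) a
smoothing spline through the path (residual RMS target ≈ 1 px) is
refined by shifting every arclength sample to the transverse intensity
centroid, which removes the skeleton's pixel-grid bias (the symmetric
fibril profile localises the axis to a small fraction of a pixel), and
re-fitted at RMS target ≈ 0.5 px; (iii) both ends are trimmed by one
fibril diameter measured from the mask cap positions — cap positions
are stable under image isometries, unlike skeleton endpoints — and the
spline is extended linearly first if the skeleton stopped short of the
trim mark.  Centerlines are resampled at uniform 0.05 µm arclength with
unit tangents and normals.  Physical coordinates follow the convention
that pixel *i* is centred at *i* × pixel size.

In manual mode a JSON sidecar of per-fibril polylines replaces
segmentation; the polyline is splined and used directly (no trimming).

## Profiles and model fits

Longitudinal profiles average the image over ±0.3 µm along the local
normal (bilinear interpolation, 25 nm sampling at default pixels);
transverse profiles sample ±2.5 µm along the normal, covering the
mature fibril radius plus PSF tails.  ROI widths are configurable since
the optimum depends on fibril diameter.

Z-disc peaks are initialised from prominence-filtered local maxima
(default prominence ≥ 20 % of the dynamic range) and fitted jointly —
baseline plus one Gaussian per peak — with every centre bounded within
half the median initial spacing of its start value, which prevents peak
swapping or merging; ties in initial maxima resolve toward the lower
index through the stable sort.  Sarcomere lengths are successive centre
differences; by default the first and last difference are dropped
(`exclude_terminal`), because the terminal sarcomeres of mechanically
isolated fibrils are often damaged.  Manual mode defaults to keeping
them.

The disc model is the projected chord convolved numerically with a
unit-area Gaussian on a grid of at most R/50 (and at most σ/5),
normalised so the fitted amplitude is the axial excess over baseline.
The five parameters (centre, R, σ_PSF, A, B) are fitted by bounded
least squares; R is initialised at half the 20 %-threshold width,
σ_PSF at 0.21·λ/NA ≈ 0.079 µm.  Fitting a Gaussian PSF against
Airy-blurred simulations is a deliberate approximation; the resulting
diameter error is bounded empirically at ≈3 % in the tests.  Per-fibril
diameter is the median of converged fits at `n_transverse` (default 10)
equally spaced arclengths with the terminal 10 % excluded; fewer than
half converging raises an error rather than returning a dubious value.

## Morphometric identities and aggregation

Filament lengths derive from band widths:
L_thick = L_sarcomere − W_I-band and
L_thin = (L_sarcomere − W_H-zone + W_Z-disc)/2.  "Z-disc width" here
always means the thin-filament overlap width at the Z-disc — one
symbol, one field.  Inputs are used unrounded.  Summaries follow the
superplot convention: measurements → per-myofibril means →
per-experiment means → grand mean and s.d. *across experiments*, so
unbalanced experiments cannot skew the estimate; sample size is
reported as "experiments/individual measurements".  Hypothesis testing
is intentionally out of scope.

## Lattice geometry

Thick filaments fill a triangular lattice in concentric hexagonal rings
from the centre; a partial outer ring is filled in angular order
(counter-clockwise from angle 0) — a convention chosen here, since only
edge irregularity is observable.  Thin sites are the midpoints of all
nearest-neighbour thick pairs (tolerance 10⁻⁶·d).  Interior sites are
those with six thick neighbours; each has exactly six adjacent thin
sites, each shared by two thick filaments, so the interior thin:thick
ratio is exactly 3 while the whole-lattice ratio approaches 3 from
below with a boundary deficit of order √n.  The area-equivalent
diameter assigns each thick filament its hexagonal unit cell
(√3/2)·d².

3D models place thick filaments symmetric about the M-line with length
L_thick, and two thin filaments per thin site — one per Z-line,
spanning [−W_Z/2, L_thin − W_Z/2] and its mirror image — assuming
mirror symmetry of thin filaments in the Z-disc.  Under the length
identities the pointed-end-to-M-line distance is W_H-zone/2 and the
thick-tip-to-Z-line gap is W_I-band/2 exactly, which the tests verify
as a round-trip.  Cross-bridges, bare-zone substructure and filament
twist are not modelled.  OBJ export (thick radius 8 nm, thin 4 nm) is
display-only; the CSV of spans is exact.

The packaged stage table carries published per-stage averages for IFM
development (thick-filament counts 23/32/134/846 from TEM; lattice
spacings 53 → 46–48 nm; dSTORM band widths).  Sarcomere length at the
three pupal stages is not printed alongside those averages and is
back-filled with values consistent with the reported growth curves
(2.35, 2.45, 3.00 µm); these rows are marked `L_s_estimated` in the
CSV.  The mature row (3.40, 0.16, 0.134, 0.094 µm) reproduces the
published filament lengths (3240 / 1680 nm) exactly.  Incorporation
rates are plain arithmetic, 60·Δt/Δn minutes per thick filament
(equivalently per six thin filaments), computed from the printed
integer counts.

## Numerical choices and limitations

* Bilinear interpolation throughout profile extraction: differentiable,
  standard, and adequate at the target precision (<10 nm parameter
  error after fitting).
* Convolutions use FFTs with explicit reflect padding; kernels are
  normalised to unit sum so blur conserves intensity away from borders.
* Test problem sizes: the recovery benchmark uses 20 simulated fibrils
  of 6 sarcomeres at a 140×470 px canvas, and Monte-Carlo checks use
  ~10²–10³ draws on reduced canvases — sizes at which the targeted
  tolerances are already resolved by a comfortable margin.
* Degenerate inputs fail loudly (typed exceptions per stage) rather
  than returning NaNs; the pipeline logs every rejection with a reason
  code so batch runs are auditable.
* Known limitations: no 3D segmentation; automatic mode assumes sparse
  fields; diameter accuracy degrades for fibrils near the diffraction
  limit (sub-resolution early-stage fibrils need super-resolution
  data); the Gaussian-PSF disc fit inherits a small systematic error
  under non-Gaussian blur; native microscope formats (.czi) are not
  read — convert to OME-TIFF upstream.
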