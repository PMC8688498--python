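# Methods

This note documents the models and procedures implemented in
`retinagel`, the assumptions baked into the synthetic-data generators,
and the numerical choices made where the underlying procedures left the
design open.

## Passive microrheology and the gel point

**Model.** A tracer bead of radius *a* (default 7.5 µm, the midpoint of
10–20 µm PLGA microbeads) in a medium at temperature *T* (default
310.15 K) explores the medium by Brownian motion.  In a gelling medium
the mean square displacement follows a local power law
MSD(τ) ≈ A·τ^α(t) whose exponent α falls from a liquid-like value
(α near 1) to a gel-like one (α near 0).  The Mason approximation of the
generalized Stokes–Einstein relation converts one MSD window into
moduli at ω = 1/τ:

|G\*| = k_B·T / (π·a·MSD₃D(τ)·Γ(1+α)),  G′ = |G\*|·cos(πα/2),
G″ = |G\*|·sin(πα/2).

Video tracking measures the in-plane (2D) MSD; isotropy gives
MSD₃D = (3/2)·MSD₂D.  Because cos = sin at π/4, G′ = G″ exactly when
α = 0.5: the gel point does not depend on the GSER prefactor, the bead
radius or the temperature.  These parameters only scale the modulus
magnitudes.

**Estimation.** `compute_msd` averages |r(t+τ) − r(t)|² over all ordered
frame pairs of all beads, optionally inside sliding windows (default
10 s wide, centered every 2 s — matching a 2 s modulus sampling
cadence).  Per window, ln MSD vs ln τ is fitted with a second-order
polynomial; α is its derivative at the geometric-mean lag, clamped to
[0, 1] (estimates outside [−0.1, 1.1] are flagged unreliable before
clamping).  The window's maximum lag defaults to a tenth of the window
so the local fit stays local.  `detect_gel_point` locates the earliest
sign change of G′ − G″ by linear interpolation between samples; with
multiple crossings the earliest is returned and the count reported.
A lag supported by a single displacement pair is kept (with a warning)
rather than dropped, so short tracks remain analyzable; lags with no
pairs are dropped.

**Double-exponential fit.** The decay of the MSD amplitude during
gelation is summarized by y(t) = a₁e^(−t/τ₁) + a₂e^(−t/τ₂) + c with
non-negative parameters, fitted by least squares from a log-spaced grid
of (τ₁, τ₂) starts over the sampled time range; ties are broken by RSS
then by the smaller τ₁, and the returned fit is canonically ordered
τ₁ ≤ τ₂.  The fit is descriptive; the modulus pathway runs on the raw
windowed MSD.

**Synthetic tracks.** The generator produces displacement increments as
fractional Gaussian noise with a locally constant Hurst exponent
H = α(t)/2, sampled in independent 4 s blocks (Cholesky factor of the
exact fGn correlation within each block), with per-dimension step
variance (A/2)·Δt^α so the 2D windowed MSD scales as A·τ^α(t).
α(t) = α_gel + (α_liquid − α_gel)·logistic((t_gel − t)/w); the presets
use the symmetric pair (0.9, 0.1) so α crosses 0.5 exactly at t_gel,
with transition width w = 8 s, A = 0.1 µm²/s^α (the diffusivity of a
~15 µm bead in a water-like prege1), 15 beads at 10 Hz for 4–5 min.
Block independence slightly inflates MSD at lags comparable to the
block length, which biases the recovered gel point upward by about
2–3%; this is well inside the 10% recovery tolerance and is the cost of
an exactly specified local exponent.  A `localization_sd` parameter
(default 0 µm) adds tracking noise when wanted.  With amplitude 0 the
beads are frozen and the MSD is identically zero.

**Plateau, compression, GPC.**  `time_to_plateau` defines the plateau
as the mean of the final 10% of G′ and returns the earliest time the
trace stays within ±2% (relative) of it for at least 20 s.
`young_modulus` is the OLS slope of true stress vs strain restricted to
the 0–7% linear regime.  `gpc_molecular_weight` evaluates the printed
column calibration log₁₀(Mn) = 10.2086 − 0.7604·Vp.

## Selective enzymatic degradation

Released-mass curves are fitted with the saturating exponential
m(t) = f∞·(1 − e^(−kt)), f∞ ∈ [0, 1], k > 0 — the only monotone bounded
model consistent with the observed plateaus.  Collagenase digests only
the gelatin network and hyaluronidase only the hyaluronan network, so
the two plateaus estimate the IPN composition directly
(`infer_composition`), with a residual-bootstrap standard error
(200 resamples, default seed 1234).  A flat near-zero series returns
f∞ = 0 with the rate flagged unidentifiable, as is a fit whose first
sample already sits deep in the plateau.  `compare_curves` interpolates
the denser (in vitro) remaining-mass curve onto the sparser (in vivo)
time grid over the overlapping range and reports R² (squared Pearson
correlation, matching the remaining-mass scale on which such curves are
plotted) along with r; the interpolation direction makes the comparison
mildly asymmetric, which is documented rather than hidden.  The
generator's in vitro presets sample every 5 min for 1 h (12 points,
noise SD 0.02, rates 0.08/min collagenase and 0.06/min hyaluronidase —
saturation well inside the assay window); the in vivo-like preset runs
daily for 9 days with both enzymes.  The vitreal enzyme concentrations
(0.5 U/ml collagenase, 0.3 U/ml hyaluronidase) are recorded as
metadata only; no concentration-to-rate model is attempted.

## Live/dead viability pipeline

`segment_channel` applies, in order: 1–99 percentile contrast stretch,
3×3 Wiener adaptive smoothing, global Otsu threshold, removal of
border-touching components (1 px frame), hole filling, morphological
opening, and removal of connected components under 10 px (strict: a
10 px component survives).  Components are 8-connected.  The opening
disc radius is 1 px: a 2 px disc would remove every structure under
13 px and make the 10 px rule vacuous; radius 1 removes isolated
specks while letting the printed size rule do its work.
`watershed_split` finds interior maxima of the Euclidean distance
transform (minimum separation 5 µm, a typical nuclear radius) and runs
a marker-controlled watershed; components without a second maximum pass
through unchanged and the label count never decreases.

Per-cell area is the pixel count times pixel_size²; the perimeter is a
multi-direction Cauchy–Crofton estimate (mean object/background
transition count along unit-spaced scan lines over 16 directions,
single-pixel staircase notches closed first).  This estimator is within
a few percent for discs, squares, bars and ellipses down to a few
pixels across, where the common 4-direction approximations misjudge
axis-aligned shapes enough to distort the shape factor C = 4πA/P².
Objects under 5 px are measured but flagged unreliable.  Viability is
100·live/(live+dead) per field, pooled, and as mean ± SEM across fields
(fields with no cells are excluded with a warning).  `z_profile`
averages intensity in 150 µm z-slabs and normalizes the peak slab to 1,
distinguishing uniform 3D cell distributions (flat profile) from
monolayers (single peak).

## Engraftment mapping

`fusion_segment` normalizes intensities to [0, 1] (min–max), blurs with
σ = 1 px, thresholds at 0.10 (recall mask), closes then opens with a
2 px disc, labels 8-connected components, keeps only components
containing at least one pixel above 0.30 (precision filter), then
deletes all pixels within 5 px of the border and drops emptied labels.
Both thresholds and all radii are configuration fields.

Orientation uses moments-equivalent ellipses for both the cell and its
annotated layer (a unique, rotation-stable choice; an inscribed or
enclosing ellipse would need an arbitrary tie-break on discrete pixel
sets).  θ is the axial difference of the two major-axis angles wrapped
to [−90°, 90°].  Cell extent r is the maximum Feret diameter (total
reach, appropriate for process extension); the ellipse major axis is
also reported.  Size classes: r ≤ 30 µm round, 30 < r ≤ 150 µm medium,
r > 150 µm long — boundary values go to the lower class so the
classification is deterministic.  Layers are assigned by maximum pixel
overlap, ties broken by the centroid's layer, zero overlap falling back
to the vitreous.

`summarize_engraftment` reports per-layer percentages over assigned
cells and extrapolates the engrafted share of the injected dose
(5×10⁴ cells) as mean per-field count × `fields_per_retina_scale` /
injected_total.  The scale constant says how many cells the analyzed
injection region holds per cell seen in one field; the generator
constructs fields under the same convention, so recovery is well posed
and the constant is explicit rather than implicit.

**Synthetic sections.** Fields are 320×384 px at 1.5 µm/px with
horizontal layer bands (vitreous, GCL, IPL, INL, ONL).  Each cell draws
a layer from the preset occupancies, a size class from the preset mix,
an orientation ~ N(0, 10°) clamped so the cell stays inside its band,
and an amplitude in [0.6, 1.0]; cells are placed with a 5 px guard ring
so neighbours cannot merge under closing + blur (a crowded draw may
still occasionally overlap, costing the detector ~2–4% of cells —
visible as a small downward bias in the engrafted-share recovery).
A `coloc_level` fraction of each cell's pixels appears in both the
human-marker and reporter channels; the remainder is split between the
two.  Two dim (0.15 amplitude) artifacts per field exercise the
high-threshold rejection.  Per-field cell counts are fixed at the
preset value; the IPN50 preset (18 cells/field, GCL occupancy 0.40,
engrafted fraction 0.56) and the saline preset (12 cells/field, GCL
occupancy 0.30, engrafted fraction 0.38, no long cells) are chosen so
the expected GCL cell-count ratio is exactly 2.  The reported ~40% GCL
share and the 2-fold GCL ratio cannot both hold exactly at engrafted
fractions of 56% vs 38%; the control's GCL occupancy is set to honor
the fold ratio, the quantity the comparison targets.

## Co-localization and coverage

Pearson r is computed over all pixels; M1 and M2 are
intensity-weighted Manders coefficients over supra-threshold supports;
the co-localized fraction is |both above threshold| / |either above
threshold| — the statistic used for the "co-localized cell" criterion
(≥ 0.70).  Thresholds are per-channel Otsu by default or fixed; an
intensity tolerance of 1e-4 (0.01% of the normalized scale) is applied
at every threshold comparison.  The p-value permutes 16 px blocks of
one channel (500 permutations by default, seeded) to respect spatial
autocorrelation, with the +1 small-sample correction; identical
channels therefore give p = 1/(n_perm+1) provided the image holds more
than a handful of blocks.  Surface coverage is the percentage of pixels
above threshold − tolerance.

## Interface attachment and OCT gel mass

The retina's vitreal boundary is extracted as the topmost retina pixel
per column, ordered into a polyline, and resampled at 1 µm arc-length
steps.  A step is attached when a gel pixel lies within the gap
tolerance (2 px default) of the boundary point, evaluated on the
Euclidean distance transform of the gel mask.  Percentages are reported
per consecutive non-overlapping 200 µm segment (the final partial
segment is reported separately and excluded from the per-segment
aggregate) and overall; maximal unattached runs are listed as holes
with start and length.  Across slides, the heat map at each position is
the arithmetic mean of the per-slide attachment flags.  Hole edges that
fall inside the gap tolerance add a small (~1–3 point) positive bias to
the measured percentage on hole-rich interfaces.

The interface generator draws attachment as an alternating renewal
process: hole lengths exponential with a 30 µm scale, attached-run
lengths scaled so the marginal attachment probability equals the preset
(0.79 / 0.59 / 0.50 for the IPN50 / IPN75 / gelatin presets, 10 slides
of 600 µm each); gel pixels touch the (gently sinusoidal) boundary
exactly where the flags are true, and detached gel blobs float well
outside the tolerance inside some holes.

OCT stacks are registered to their first frame by integer-pixel phase
correlation (frames needing shifts above 25% of the frame are dropped)
and averaged.  Gel mass is the surplus of Otsu-foreground pixels over a
no-injection baseline (mean over control scans), clamped at zero, and
normalized to the first post-injection scan to give the in vivo
degradation series consumed by `compare_curves`.  The OCT generator
paints a fixed bright curved retina band plus gel islands totalling
gel_px_day0·e^(−rate·day) pixels, with multiplicative speckle and
random ±4 px frame translations; the control preset shares the retina
geometry at equal seeds so baselines match.

## Reproducibility and problem sizes

Every generator is deterministic given (preset, seed); the default
global seed is 20211220 and every operation takes an explicit seed.
Recovery tests run at the preset study sizes (15 beads, 12 assay
points, 10 slides, 60 fields); replicate counts in the test-suite and
acceptance runs (5–20 seeds per quantity) are chosen to pin the Monte
Carlo error of each recovered mean or median well below its assertion
tolerance.  What passing recovery shows is that each pipeline measures
what the generator encodes under realistic noise; the generators do not
emulate optics (PSF, depth attenuation), staining variability,
autofluorescence, or annotation error, so performance on real
micrographs still depends on acquisition quality.

## Known limitations

- The locally-fGn gelation model has independent blocks; lags spanning
  block boundaries mildly inflate the MSD (small positive gel-point
  bias, documented above).
- `fusion_segment` has no cell-splitting step, so touching cells in
  crowded fields merge (the watershed splitter belongs to the viability
  pipeline, mirroring the procedures being reproduced).
- The in vitro/in vivo R² depends on the interpolation direction;
  always pass the denser curve first.
- OCT registration is integer-pixel only; subpixel drift blurs the
  z-projection slightly but does not move Otsu counts materially.
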