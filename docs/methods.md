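# Methods

`shgdir` recovers the intrinsic forward/backward ratio of second-harmonic
generation (SHG), F_SHG/B_SHG, locally within image stacks of collagenous
tissue, and quantifies how the spatial heterogeneity of that ratio and its
correlation with SHG intensity differ between tissue classes.  This note
records the models, parameter choices, and numerical decisions.

## Photon transport model (`shgdir.mc`)

SHG photons are created at a known depth `z` inside a single homogeneous
slab (thickness `T`, default 150 µm).  Depth is measured from the
objective-side face, where the backward (epi) signal is collected; the
forward signal exits the opposite (condenser-side) face.

**Launch.** A photon leaves the creation point along +z with probability
`r/(1+r)` and along −z with probability `1/(1+r)`, where `r` is the
creation ratio.  Directions are uniform in solid angle within a cone about
±z.  The default cone half-angle is the excitation focal cone refracted
into the tissue, `asin(NA_exc / n_tissue)` with NA_exc = 0.8 (the
objective NA): this choice follows Snell's law at the interface and has
the property that `n_tissue · sin θ ≤ 0.8`, i.e. every ballistic photon
falls inside both detection cones, making the non-scattering limit exact
(measured F/B = r).  The half-angle is configurable.

**Propagation.** Step lengths are exponential with `µ_t = µ_s + µ_a`,
`µ_s = µ_s′/(1−g)`.  Scattering is Henyey–Greenstein with anisotropy `g`
(default 0.9, typical of collagenous tissue; the underlying data constrain
only µ_s′).  Absorption is applied as per-interaction weight decay;
photons below weight 1e−6 are terminated with their residue booked as
absorbed, so the energy ledger `launched = F + B + escaped + absorbed`
closes to 1e−9 relative **exactly** (no roulette amplification).  µ_a is
negligible at 494 nm in this tissue and defaults to 0.

**Collection.** At a face, the Snell invariant `n_tissue · sin θ` decides
everything: total internal reflection if it exceeds the immersion index
(1.33; the photon re-enters), collection if it is at most the face's NA
(0.9 forward, 0.8 backward), escape otherwise.  Partial Fresnel
reflection below the TIR angle is neglected.

**Default optics.** µ_s′ = 2.0 mm⁻¹, g = 0.9, n = 1.4, T = 150 µm for all
synthetic tissue classes.  Per-class measured values exist only in prior
instrument-specific work, so a single representative set is used; it is a
parameter of `OpticalProperties`, not a constant.

## Lookup tables and inversion

`build_lookup_table` simulates the grid of creation ratios 1.0–19.9 in
steps of 0.3 (64 values) × emission depths, storing measured F/B, its MC
standard error, and the absolute collected fractions.  Per-condition RNG
streams are spawned from the root seed keyed by (ratio index, depth
index), so tables are bit-reproducible in any evaluation order.

*Stratified launch.*  Table construction launches exactly half the
photons in each direction and carries the direction probabilities as
weights.  The estimator is unbiased with the same photon count but a much
smaller backward-channel variance at high ratios, where Bernoulli
launching starves the backward detector.  Standard errors use effective
(Kish) counts.  `simulate_emission` keeps the plain Bernoulli launch.

*Monotonicity check.*  Measured F/B must be nondecreasing in creation
ratio at fixed depth.  The per-comparison threshold is 3 SE,
Bonferroni-adjusted for the ~1200 joint comparisons of a full grid
(otherwise the check would false-alarm on almost every table at standard
photon budgets).

*Inversion.*  `invert_measured_fb` selects the nearest depth row (the
1 µm section spacing makes depth interpolation unnecessary) and inverts
the monotone response by piecewise-linear interpolation, clamping to the
grid with `clamped_low` / `clamped_high` flags.  Because transport is
independent of the creation ratio given the launch direction, the exact
form of the response at fixed depth is rational-linear,
`fb(r) = (p_Ff r + p_Fb)/(p_Bf r + p_Bb)`, with direction-conditional
collection probabilities `p`.  These are estimated by linear least
squares across the whole ratio axis (the products `c(r)·(1+r)` are linear
in the parameters), which averages per-node MC noise; if the fitted curve
fails positivity, monotonicity, or a residual z-test, the inversion falls
back to weighted isotonic regression of the raw column.  The synthetic
renderer uses the same fitted fractions as its instrument response.

## Patch extraction (`shgdir.stacks`)

Stacks are preprocessed by dropping the first and last 10 optical
sections (boundary effects; configurable), marking pixels at or above the
saturation level in either channel as invalid in both, and optional 3×3
median denoising applied identically to both channels.  Calibration
divides the forward channel by the measured forward/backward
collection-efficiency ratio so an isotropic emitter reads F/B = 1.

Each section is tiled into non-overlapping patches (default 30×30 px ≈
10×10 µm, sized to contain whole fiber structures; trailing margins are
discarded to keep patch statistics uniform).  The patch ratio is
mean(F)/mean(B) over valid pixels — the photon-count estimator, robust to
zero pixels.  A patch is valid when at least half its pixels are valid,
both channel means are positive, and the mean total intensity reaches a
configurable floor (default in the pipeline: 20 % of the nominal
count level) that excludes collagen-free regions containing only dark
counts; without it, background patches invert to ratio ≈ 1 and bias class
means.  `patch_size_sweep` reproduces the patch-size diagnostic: at one
pixel the fit-failure fraction rises steeply (shot noise), while very
large patches converge to the frame average.

## Phase matching (`shgdir.phase_matching`)

The harmonic field over an interaction length `L` with phase mismatch
`Δk` is `E_2ω = κ E_ω² sinc(ΔkL/2)`; intensity is its square, symmetric
in Δk, with the removable singularity at 0 handled exactly.  κ and E_ω
are arbitrary-unit constants; only ratios and correlations are used.

The mapping from |Δk| to creation ratio is not fixed by first principles;
the package uses the simplest monotone form,
`ratio(|Δk|) = 1 + (r_max − 1)·exp(−|Δk|/d)` with `r_max = 19.9` (the
grid maximum).  The decay constant `d = 0.65 rad/µm` is chosen so that,
after calibrating class centers to the target mean ratios, the typical
`ΔkL/2` of every class stays inside the monotone sinc lobe (< π) for
`L ≈ 2.2 µm` fiber widths — the regime in which brighter emission and
more forward-directed emission co-vary, which is the physical picture the
analysis probes.  The map is pluggable.

## Synthetic tissue generator (`shgdir.synthetic`)

The generator defines the study conditions for all end-to-end tests.

**Class presets.**  Target creation-ratio moments (mean, within-volume SD)
per class: normal (4.0, 2.0), benign (8.8, 3.9), endometrioid (3.0, 1.7),
LGS (5.1, 3.5), HGS (2.7, 1.7) — the measured tissue-class values used as
generator configuration.  Morphology parameters (density, mean width ±
SD µm, length µm, orientation concentration κ, waviness µm):

| class        | density | width (µm)  | length | κ   | waviness |
|--------------|---------|-------------|--------|-----|----------|
| normal       | 0.15    | 2.13 ± 0.25 | 30     | 0.5 | 2.0      |
| benign       | 0.20    | 2.19 ± 0.30 | 25     | 1.0 | 2.0      |
| endometrioid | 0.15    | 2.13 ± 0.25 | 25     | 1.0 | 2.0      |
| LGS          | 0.30    | 2.14 ± 0.90 | 15     | 2.0 | 1.0      |
| HGS          | 0.35    | 2.20 ± 0.20 | 35     | 5.0 | 4.0      |

Mean widths follow the reported fiber/bundle widths; the width SDs encode
the reported contrast in width heterogeneity (LGS strongly heterogeneous,
HGS uniform).  Densities and lengths are scaled to the synthetic
85×85 µm field so each axial block contains tens of fibers — enough that
class statistics are not dominated by fiber-sampling noise — while
preserving the qualitative relations (normal loose and dispersed, LGS a
tightly packed matrix of the shortest fibers, HGS densest and aligned).

**Fiber fields.**  Wavy line segments with truncated-normal widths and
von Mises orientations are rasterized (distance-to-centerline threshold
with a dithered radius; the −0.05 px offset is the empirical residual of
the width estimator on isolated rasterized fibers) until the target area
density; later fibers overwrite earlier ones.

**Δk assignment.**  Per fiber, `|Δk| = |c + σ z|`, `z ~ N(0,1)`.  σ is
solved by Gauss–Hermite quadrature + least squares so the induced ratio
distribution has the class's (mean, SD); the center `c` is then re-solved
on the realized draws so the *pixel-weighted* realized mean (what the
patch statistics downstream estimate) equals the class mean within 0.1 at
any fiber count.

**Rendering.**  Created intensity per fiber pixel is
`(1−f)·sinc²(Δk·L/2) + f` with `L` the local fiber width and `f = 0.1` an
incoherent sub-domain fraction: a fiber is not a single coherent domain,
so the sinc zero is never fully realized.  The intensity is split into
expected F and B counts using the lookup table's fitted detection
fractions at the section depth, scaled so the mean detected count on
fiber pixels at the middle section equals `mean_counts` (default 50),
offset by dark counts (1 % of `mean_counts`), and Poisson-sampled per
channel.  Fiber geometry persists through an axial block of 8 sections
(≈ the scale over which a fiber stays in the imaged plane) with ±1 px
jitter per section, then turns over to a fresh realization; full 3-D
fiber growth is out of scope.

**What the generator does not emulate.**  Coherent speckle, polarization,
depth-dependent aberrations and attenuation of the *excitation*, real
fiber branching/curvature statistics, per-class optical properties, and
instrument drift.  Passing the end-to-end tests therefore demonstrates
that the inversion and statistics recover the truth of this generative
model at realistic counts — not that the pipeline is validated on real
tissue, whose images are not publicly deposited.

**Known attenuation.**  Patch averaging over multiple fibers shrinks the
within-volume SD of patch ratios relative to the configured fiber-level
SD (e.g. HGS ≈ 1.05 observed vs 1.7 configured at the default field
scale).  The class *contrast* in heterogeneity survives and is what the
cohort checks assert; matching the absolute SD would require
single-fiber patches.

## Statistics (`shgdir.analysis`)

Per volume: mean and SD of valid (ok or clamped) patch ratios; groups are
summarized as mean ± SE over volumes.  Per section, the Pearson
correlation between the heat map and the patch-averaged forward-channel
intensity is computed over valid patches after per-section min–max
self-normalization (Pearson is affine-invariant, so normalization is kept
for exported-map comparability, not because it changes r); sections with
fewer than 3 valid patches or zero variance return NaN and are dropped
from the stack average.  Group comparisons use two-sided Welch t-tests
(pooled-variance available).  GLCM features quantize the image to 16
equal-width levels, accumulate a symmetric normalized co-occurrence
matrix averaged over offsets (0,1),(1,0),(1,1),(1,−1), and report
energy ΣP², entropy −ΣP log₂P, homogeneity ΣP/(1+|i−j|); a constant
image gives energy 1, entropy 0, homogeneity 1.

## Fiber widths (`shgdir.fibers`)

Segmentation is Otsu (or fixed) thresholding plus small-object removal.
Widths are measured per skeleton segment between branch points:
`width = (2·mean EDT − 0.5) · pixel size`, where EDT is the Euclidean
distance transform on the mask.  The −0.5 px term centers the estimator
between the lattice-aligned (−1) and oblique (0) sampling cases; on
straight bars of width 3–15 px at 0–90° the bias stays within one pixel
of the rasterized width (area per unit length).  Segments shorter than
10 px are discarded as skeleton spurs.  Where fibers overlap the
estimator reports the merged bundle, so dense classes read slightly wide
— the same fiber-versus-bundle semantics as curvelet-based fiber tracers.

## Problem sizes

The test suite and the acceptance script run at desk scale: lookup tables
with the full 64-ratio axis, 20 depth rows and 10⁴ photons per condition
(10⁵ for single-condition checks); round trips on 240×240 fields over 6
sections; cohorts of 5 classes × 3 volumes × 64 sections at 256×256 px
and 50 detected counts per fiber pixel.  The full suite completes in
about a minute on one CPU; the acceptance script in about 40 s.
Cross-seed checks during development showed the cohort ordering criterion
stable and the HGS−LGS correlation gap positive at +0.08 ± 0.03 across
16 seeds; as a ~2.5 σ stochastic effect it can in principle flip at an
unlucky seed.

## Limitations

Single homogeneous slab (no layered media, no glass interfaces beyond
exit refraction); no polarization or coherence in transport; the
Δk→ratio map is a heuristic monotone stand-in, not derived from fibril
ultrastructure; CT-FIRE-style curvelet fiber extraction is deliberately
replaced by the transparent skeleton estimator; correlations use
patch-reduced intensity (nearest-neighbor upsampling of the heat map is a
documented alternative reading).
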