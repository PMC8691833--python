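# Methods

This note documents the models behind `iridisim`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate, and
the numerical conventions that affect results.

## Interference conditions and optical constants

A one-dimensional photonic crystal of alternating melanin and keratin layers
produces its first-order reflectance peak where the optical thickness of one
repeat equals half a wavelength, `t_mel·n_mel + t_ker·n_ker = λ/2`, with
maximal reflectance when both layers are quarter-wave
(`t_mel·n_mel = t_ker·n_ker = λ/4`). Bounding the reinforced wavelength to the
bird-visible window (300–700 nm) gives the expected melanin-layer range
37.5–206 nm and, treating air pockets as the low-index layer (n = 1), an air
range of 75–350 nm.

Optical constants: melanin n = 2.0 at 300 nm and 1.7 at 700 nm with constant
extinction k = 0.1; keratin n = 1.56, lossless; air n = 1. Melanin dispersion
between the two anchors is **linear** — the simplest monotone model consistent
with indices falling toward long wavelengths; outside 300–700 nm the anchor
values are held (used only by the fixed-point peak solver). The inverse
problem (`first_order_peak`) is solved by damped fixed-point iteration
(damping 0.5, tolerance 1e-6 nm, max 100 iterations); the map is a strong
contraction because the dispersion slope is small.

Melanin layers are classified "thin" below 190 nm, the antimode of the
bimodal solid-rod diameter distribution. For hollow melanosomes one wall is
one optical layer by default; a `doubled_wall` option applies the cut to
twice the wall thickness for structures with no keratin between layers.

## Structure geometry and the simulation grids

A structure is a melanosome (type, shortest-axis diameter `d_melsom`,
air-core diameter `d_air`, width `l_melsom`), a packing (laminar or
hexagonal), a center-to-center lattice spacing `a`, a keratin cortex `c` and a
layer count (fixed at 4 in the grids, the database median). Derived metrics:
melanin layer thickness `mt` (= `d_melsom` for solid forms,
`(d_melsom − d_air)/2` for hollow), hollowness `d_air/d_melsom`, flatness
`l_melsom/d_melsom`.

The per-kind simulation grids are Cartesian products of inclusive, evenly
spaced sequences (endpoint handling is a package choice; e.g. cortex
5–1000 nm in 3 steps → {5, 502.5, 1000}): diameter 190–300 (30) /
65–180 (30) / 135–440 (10) / 45–140 (30) / 135–280 (10) nm for thick rods,
thin rods, hollow rods, solid platelets and hollow platelets respectively;
hollowness 0.26–0.69 (3) for hollow kinds; relative lattice spacing
`r_melsom/a` 0.15–0.5 (5); flatness fixed at 2.4 for platelets. Rod kinds are
crossed with both packings (900 structures); platelets are laminar-only and
enumerate to the literal product of 450 — a `duplicate_laminar` switch lists
each platelet structure twice for per-kind count parity but is off by
default. Square packing is deliberately excluded (a single-genus
curiosity).

Geometric conventions: melanosomes are laterally contiguous within a layer
(lateral period = diameter for rods, width for platelets); the lattice
spacing is the between-layer center distance, so the laminar vertical period
is `a` and the keratin spacing `ks = a − d_melsom` is the thinnest keratin
gap. Hexagonal packing offsets successive rows by half a lateral period with
vertical row spacing `a·√3/2`. Rod cross-sections are circles (annuli when
hollow); platelets are ellipses whose hollow core inherits the shell's
flatness. For hexagonal structures with relative spacing above ~0.433 the row
period is smaller than the diameter and the outermost rows are slightly
truncated by the `c + n·period` depth bookkeeping; laminar structures are
never affected.

## Reflectance simulation

The 2-D unit cell is reduced to homogeneous slabs by slicing it in depth
(default 80 slices per period; 160+ recommended for hollow geometries, where
the annulus edge converges more slowly) and averaging the **permittivity**
(not the index) of melanin, air and keratin over each slice — exact for
fields parallel to the interfaces at normal incidence, which is the field
orientation in a laminar stack. Reflectance follows from the standard
characteristic-matrix product between an air incident medium and a
semi-infinite keratin substrate (the barbule interior; the boundary media are
a package choice). Normal incidence only: the angle-resolved measurement
protocol is a property of spectrophotometry, not of the simulated structure.
The transfer matrix is validated against the closed-form Airy single-film
formula (1e-8) and exact lossless energy conservation (1e-9).

Spectra are computed wavelength-by-wavelength on a 300–700 nm grid (step must
divide the 400 nm span). Peak reflectance ties break toward the shortest
wavelength.

## Avian color space

Cone sensitivities are built from the standard A1 visual-pigment template
(alpha plus beta band), peak-normalised. The full peak-wavelength sets are
VS = {416, 478, 542, 607} nm and UVS = {372, 456, 544, 609} nm — conventional
"average" avian sets anchored at the two SWS1 peaks — with a 571 nm template
standing in for the chicken double cone. These are documented substitutions
for packaged sensitivity data; no ocular-media or receptor-noise corrections
are applied. The illuminant defaults to equal energy and is exposed as a
parameter. Quantum catches are von Kries–normalised (divided by the catch of
a perfect reflector), so a flat spectrum maps to the achromatic origin.

The tetrahedron uses the conventional vertex coordinates u = (0, 0, 0.75),
s = (−0.61237, −0.35355, −0.25), m = (0.61237, −0.35355, −0.25),
l = (0, 0.70711, −0.25) (circumradius 0.75, achromatic center at the origin;
because the printed coordinates are rounded, "zero" is ~1e-6). Saturation is
`r = ‖xyz‖`; color span is the mean pairwise distance.

Voxel occupancy uses an axis-aligned cubic grid (side = resolution, default
0.1) anchored at the tetrahedron's bounding-box minimum. Two membership rules
are implemented for the total: the default counts cells whose cube intersects
the tetrahedron volume (exact, via linear-programming feasibility; 376 cells
at resolution 0.1) and the fallback counts cells whose center lies inside
(211 cells). The tetrahedron volume (≈0.2165) corresponds to ≈216 cells, so
the two rules bracket the volume-equivalent count; intermediate totals
reported elsewhere in the literature depend on grid anchoring choices that
are not recoverable from published descriptions. Both rules are exposed; the
acceptance script reports the center rule.

## Spectral pre-processing

LOESS smoothing is local linear regression with tricube weights over a
window covering a `span` fraction of points (default 0.2), no robustness
iterations, delegated to `statsmodels.lowess` and cross-checked against an
independent implementation in the tests. Negative reflectance values are
removed by shifting the spectrum so its minimum is zero and clipping at 100%
(values above 100% only arise from measurement artefacts); a linear
min–max stretch to [0, 100] is available behind `mode="stretch"` but is not
the default, since shifting preserves spectral shape. Per patch the spectrum
with maximal area under the curve is kept (ties to the first column);
replicate individuals more than 0.1 apart in color space (strict inequality)
are flagged for review, mirroring standard replicate QC.

## Phylogenetic statistics

The Brownian covariance of two tips is the rate times their shared root-path
length; `tree_vcv` builds this matrix from any rooted Newick tree
(ultrametry not required). Simulation-based phylogenetic ANOVA computes the
ordinary one-way F and refers it to F statistics from Brownian simulations on
the tree with the maximum-likelihood rate (GLS mean profiled out); p-values
carry the add-one continuity correction `(1 + #{F* ≥ F}) / (n_sim + 1)`.
Because F is scale-invariant, the procedure is exact under the Brownian null.
Pairwise t-tests reuse the same simulated nulls with pooled-variance t
statistics and Holm correction (the multiplicity rule is a package choice).
Pagel's λ multiplies the off-diagonal covariance; the ML estimate is found by
bounded scalar optimisation on [0, 1] with endpoint checks, and the test
against λ = 0 is a 1-df likelihood ratio. On a star tree λ is unidentifiable
and the result is flagged rather than raised.

The multimodality test uses the excess-mass statistic
`D = max_λ [E_{m+1}(λ) − E_m(λ)]`, computed exactly over the candidate
intervals by a prefix-maximum recurrence and maximised over a 64-point
logarithmic λ grid spanning the empirical density scale. Calibration is a
smoothed bootstrap from the Gaussian KDE at the critical bandwidth (the
smallest bandwidth, on a log grid, whose KDE has at most the null number of
modes), with the smoothing variance inflation corrected. Power and level are
verified in the tests on two-component diameter mixtures and Gaussian
samples.

Effect models on simulation output are ordinary least squares with binary
predictors thin / hollow / platelet and the hollow×platelet interaction
(brightness responses log-transformed). The plumage analogue is a Gaussian
mixed model with a phylogenetic random effect (covariance proportional to the
shared-path matrix, scaled to unit mean depth) and a patch random intercept,
fitted by REML over the two variance ratios (Nelder–Mead on the log scale,
three starts); fixed effects are GLS at the optimum with Wald intervals.
This is a deterministic analogue of Bayesian MCMC mixed models with the same
estimand; intervals are Wald rather than profile-likelihood because the
fixed-effect sampling distributions are well approximated as normal at the
sample sizes involved, and determinism is worth more here than second-order
interval accuracy. Variance components can be fixed (e.g. at zero, reducing
the fit to OLS) via `var_components`. Duplicate database rows per species are
averaged before any comparative test.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, from
one seed: a pure-birth (Yule) tree grown to the requested tip count
(ultrametric; tips extended to the next unobserved event); melanosome types
assigned by ranking a latent Brownian trait and cutting at the cumulative
type frequencies, which clusters types phylogenetically without an explicit
Markov transition model (simpler, and sufficient to give λ > 0 signal);
solid-rod diameters from a two-component truncated normal mixture — thin
N(110, 20²) on [40, 189], thick N(250, 30²) on [190, 350] — straddling the
190 nm cut and matching the ~100/~200 nm varieties; hollow-kind air pockets
within the observed 50–251 nm span (walls are automatically thin,
< 190 nm, for the table's diameter ranges); platelet flatness fixed at 2.4;
lattice spacing, cortex and layer counts drawn uniformly from the database
ranges. Replicate spectra are the transfer-matrix spectrum of each species'
structure with a per-replicate multiplicative gain (sd 0.05) and additive
Gaussian noise (default 1%); a configurable fraction (default 5%) of patches
has one replicate chromatically distorted by a strong far-side spectral bump
so the replicate QC has true positives to find.

What the generator does **not** emulate: taxonomic sampling bias, real clade
compositions, angle-resolved measurement geometry, instrument calibration
error, within-species structural variation beyond the replicate noise, and
melanosome types missing from the five-type scheme (e.g. porous-interior
rods). Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes, not that real plumage data satisfy those assumptions.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible.
The test suite uses desk-scale sizes chosen to keep the full run in a few
minutes while leaving comfortable statistical margins: reduced simulation
grids of 5 diameters × 3 spacings (× 3 hollowness × 3 cortex values where
applicable) at a 2 nm wavelength step; ANOVA calibration with 500 replicates
of 200 null simulations on a 64-tip tree; λ recovery with 100 replicates on
128 tips; multimodality power/level with 60 replicates of 500 bootstraps at
n = 150; and a 16-species end-to-end fixture run.

## Known limitations

* Effective-index slicing collapses lateral structure; it captures the
  spectral position and strength of first-order peaks but not polarisation
  splitting, oblique incidence or disorder, and hexagonal lattices are
  treated as vertically stratified rows.
* Melanin extinction is held constant (k = 0.1) across wavelength, and the
  dispersion model is a two-anchor line.
* The voxel total depends on an unrecoverable rasterisation convention; both
  implemented rules are documented above.
* The mixed model assumes Gaussian responses and a single tree; tree
  uncertainty (consensus over tree distributions) is out of scope.
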