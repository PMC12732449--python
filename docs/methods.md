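# Methods

This note documents the models, estimators and numerical choices behind
`hhgm_quant`, and what its synthetic validation does and does not establish.

## The measurement problem

Label-free higher-harmonic-generation microscopy of 3D dermal fibroblast
cultures yields two-channel z-stacks: second-harmonic generation (SHG) from
fibrillar collagen and third-harmonic generation (THG) from cell and nucleus
interfaces. The package turns such stacks into per-stack quantities — cell
counts and density, cell area and width-to-length ratio, collagen amount
(thresholded SHG pixel counts) and collagen per cell, collagen fiber
diameter, per-voxel 3D orientation with depth-resolved angular heatmaps, a
scalar orientation index, the cell–fiber orientation correlation and a
depth-rotation rate — and then into group-level statistics.

Because real patient-derived stacks are not redistributable, every estimator
is validated by parameter recovery on synthetic stacks whose ground truth is
known exactly.

## Synthetic stacks (`synthstack`)

Fibers are straight chords with a Gaussian radial intensity profile:
intensity at distance *d* from the centerline is `peak · exp(−d²/2σ²)` with
`σ = FWHM / (2√(2 ln 2))`. The FWHM **is** the fiber's nominal diameter,
making generator truth commensurate with the Gaussian-FWHM diametry
operator. Rendering evaluates the exact point-segment distance in physical
µm, so the radial law holds to machine precision and superposition is exact.
Default diameters are drawn from a clipped normal (mean 0.9 µm, SD 0.2 µm),
bracketing the sub-micron range reported for cultured dermal matrices.

Cells are hollow ellipsoidal shells — a Gaussian intensity band around the
normalized ellipsoid radius m = 1 plus an inner nucleus rim at m ≈ 0.35,
with dark interiors — reflecting the interface sensitivity of THG; any cell
segmentation must therefore cope with hollow objects. Semi-axes default to
a ∈ [8, 13], b ∈ [2.5, 4.5], c ∈ [1.8, 2.2] µm — elongated spindles
(width-to-length ≈ 0.2–0.4) sized so that the densest validation condition
(100 non-overlapping cells) remains geometrically feasible in the default
102 µm crop; real fibroblasts are longer, but at the field's cell density a
full-size cell population cannot fit a crop this small at all, so cell size
and count are scaled together. Cell z-centers sit on the centers of the
pairwise-projection slabs (cultured fibroblasts form discrete contiguous
layers), with z-extent smaller than a slab, so each truth cell appears in
exactly one projected layer-pair and per-layer count sums are directly
comparable to the number of cells generated. Placement is rejection-sampled
with a capsule overlap test along the long axis. Only full layer-pairs host
cells: a trailing odd layer's slab center coincides with the layer itself,
which would bleed the cell's z-shell into the neighboring slab.

Depth rotation: the nominal in-plane angle at depth z is
`θ(z) = θ₀ + r·z (mod 180°)` with r in °/µm, positive = counterclockwise in
the conventional image plane (x right, y up, viewed from +z). The default
r = 0.25 °/µm produces a gradual whorl (≈7.5° over a 30 µm culture).
Cell–fiber coupling: each cell's long axis is
`θ_fiber(z) + (1 − κ)·U(−90°, 90°)`; κ = 1 locks cells to the local fiber
angle, κ = 0 is uniform. Default κ = 0.9 (tight coupling).

Noise is Poisson on (signal + background) plus Gaussian read noise
(SD 1 count). Defaults — background 5 counts, fiber peaks 30–60, cell rims
40–70 — give peak SNR ≈ 6–9, a shot-noise-limited regime typical of
photon-counting detection. No optical PSF is simulated: rendered structures
are as sharp as their geometric profiles, so recovery results bound what the
estimators do on well-resolved structures, not on diffraction-limited or
aberrated data. Other unmodeled features of real data: depth-dependent
attenuation, mosaic illumination structure, non-fibrillar SHG, touching
cells in dense sheets.

Default geometry is 512×512×15 voxels at 0.2 µm/pixel and 2 µm z-step — a
102.4 µm² crop of a 1×1 mm² field at the same sampling; all operators take
physical voxel sizes and run at full field size when given one.

## Enhancement and thresholds (`stackio`)

Histogram truncation clips intensities above a per-image percentile
(default 99.5) — removing hot-pixel outliers while remaining monotone and
idempotent. CLAHE is scikit-image's `equalize_adapthist` (clip limit 0.01,
64×64 tiles), output normalized to [0, 1].

The background threshold of a channel is the mean of the mean intensities of
several local background regions. Region choice is automated: the candidate
regions are the lowest-mean square patches (32 px, 5 regions) on a stratified
grid over all layers; a manual mode accepts explicit coordinates. Where a
*dark* validity threshold is needed (pixel counting, orientation validity),
the pipeline adds a 3·√(background) shot-noise margin, since a Poisson
background of mean λ fluctuates with SD √λ and the bare mean would admit
roughly half of all background voxels.

Collagen pixel counts use raw (un-enhanced) intensities; enhancement is
reserved for detection tasks. A config switch (`collagen.count_on_enhanced`)
exposes the alternative.

## Cell segmentation (`cellseg`)

The chain, per projected layer-pair: histogram truncation → edge-aware TV
denoising → prior-weighted two-phase active contour → distance-transform
watershed.

*TV denoising* minimizes `½‖u − f‖² + w·Σ√(∇uᵀD∇u + ε²)` by gradient descent
with backtracking (energy strictly non-increasing). D is built from the
input's structure tensor: the penalty along the dominant gradient direction
is shrunk by the squared coherence, so smoothing acts along interfaces, not
across them; in flat regions D is the identity and the penalty is ordinary
isotropic TV. Defaults: weight 0.08 on [0, 1]-normalized layers, ε = 10⁻³,
80 iterations max, relative-change tolerance 3·10⁻⁴.

*Active contour*: a Chan–Vese-type region evolution in which the two phase
means are estimated with per-pixel weights from a local-extrema prior — the
local max-min contrast in a 31-px window, floored at 0.2 — so flat
background windows do not drag the phase means; pixels are reassigned to the
nearer phase mean and the interface is regularized morphologically each
iteration. Initialization is mean + 0.5 SD global thresholding. Layers with
no usable contrast return an empty mask with a warning rather than noise.

*Watershed split*: the mask is closed (radius 4 px; hollow shells are often
open at high-curvature cell tips, and closing lets hole-filling recover a
solid footprint), filled, and the Euclidean distance transform is smoothed
(Gaussian, σ = 3 px) to remove boundary-ripple maxima on the ridge. Markers
are per-component h-maxima with depth 0.3× the component's maximum: a convex
cell keeps one marker, a pinched union of two cells keeps two. Fragments
below 15 µm² are discarded as noise or detached nucleus rims.

Counting follows the per-layer-sum convention ("cells per z-stack"): labels
are counted independently per projected layer and summed, with no linking
across depth — a volume count that double-counts any cell visible in several
slabs, reproduced deliberately as the field's convention (the generator's
slab-centered cells make it exact on synthetic data).

Morphology: area = pixel count × voxel², length/width = major/minor axis of
the second-moment ellipse. Border-touching labels are dropped (incomplete
cells), the first 2 projected layers are excluded by default (cells flatten
against the stiff glass substrate), and a 3-px morphological opening
suppresses thin filopodia before moment computation. A
`max_cells_per_layer` option subsamples for parity with small-sample manual
protocols.

## Collagen quantification (`collagenq`)

Amount: strict count of SHG voxels above the threshold, per layer and per
stack, in raw voxels (the field's "pixels per z-stack" unit); a µm³
conversion is provided as a labeled extension. Collagen per cell divides the
stack count by the cell count; zero-cell slabs yield NaN (flagged), never 0.

Diametry automates perpendicular-profile FWHM measurement. Sites are sampled
on the skeleton of the thresholded fiber mask, at least one expected FWHM
from branch points (crossings), with a minimum pairwise separation (5 µm)
and seeded order; the local tangent comes from PCA of the skeleton
neighborhood. The intensity profile perpendicular to the tangent is sampled
at half-pixel spacing with cubic-spline interpolation — linear interpolation
measurably widens profiles whose σ is near one pixel (a ~3–5% FWHM bias at
0.6 µm diameters), cubic interpolation does not — and fitted with
`A·exp(−(s−s₀)²/2σ²) + b` by least squares. FWHM = 2√(2 ln 2)·σ. Fits are
rejected when r² < 0.8, the center falls off the inner half of the profile,
or the width is unresolved in the window. Site detection runs on a
CLAHE-enhanced copy (better skeleton continuity); the fit always uses raw
intensities, whose radial shape carries the diameter — enhancement is
nonlinear and would distort the profile being measured.

Two cleanup passes mirror manual practice: duplicate sightings of one fiber
on adjacent layers (within one FWHM laterally) are chained and only the
brightest (then widest) member kept; and per-stack width outliers beyond
3.5 robust SDs (MAD × 1.4826) of the median are rejected — a lone Gaussian
fitted across two merged parallel fibers converges, with acceptable
residuals, to their envelope width, and such contaminated sites appear as
gross outliers rather than subtle bias.

## 3D orientation (`orient3d`)

Gradients of the Gaussian-smoothed volume (gradient scale 0.5 µm) are taken
in physical units — finite differences divided by the per-axis voxel size —
so anisotropic sampling (e.g. 2 µm z-steps vs 0.2 µm pixels) is handled
correctly; a regression test verifies that pretending voxels are isotropic
misestimates a 45° climbing fiber by far more than the 5° tolerance within
which the physical-unit estimator recovers it. The structure tensor is the
outer product of gradients averaged at the integration scale (1.0 µm), and
the local axis is the eigenvector of the smallest eigenvalue. Voxels are
valid where intensity exceeds the dark threshold and the two smallest
eigenvalues are separated by > 0.5% of the largest (with 2 µm z-steps the
z-gradient energy of a thin fiber is a small fraction of the in-plane
energy, so the separation between "along fiber" and "z" eigenvalues is
genuinely small even for clean fibers; the tolerance must sit below it).
Stacks with fewer than 3 layers fall back to a per-layer 2D tensor with
φ fixed at 90°, flagged on the output.

θ is axial ([0°, 180°), counterclockwise from +x, y up); φ is measured from
+z. All θ statistics use the doubled-angle circle. The (θ, φ) pair restricted
to [0,180)×[0,90] folds azimuthal half-spaces together — harmless for
in-plane histograms, but biasing for second-moment statistics of
out-of-plane fields — so the field also retains the raw unit eigenvectors,
and the orientation index is computed from them.

Heatmaps: per-layer θ histograms over valid voxels (1° bins by default),
normalized to percent; empty layers are flagged and excluded downstream.
Heatmap correlation is the Pearson correlation over all shared finite
(layer, bin) cells of the raw percentage matrices (no smoothing by default).

Orientation index: the nematic order parameter S = (3λ_max − 1)/2 of the
mean dyadic tensor ⟨n nᵀ⟩ — 1 for parallel fields, 0 in expectation for
isotropic 3D directions, matching the stated limits of alignment indices
used for fiber imagery. The two-population case (half 0°, half 90°,
in-plane) gives exactly 0.25, a useful analytic anchor.

Rotation rate: per-layer circular mean angles (doubled-angle, weighted by
the heatmap row), layers with circular variance > 0.95 excluded, unwrapped
across depth with period 180°, then a resultant-length-weighted linear fit
of angle against depth in µm. Diagnostics carry per-layer circular variance
and the weighted residual. Fewer than 3 usable layers → NaN.

## Group statistics (`groupstats`)

Summaries are mean ± sample SD (n−1). Comparisons are gated on normality:
each group is screened with Shapiro–Wilk, Kolmogorov–Smirnov (on
standardized values), Lilliefors and Anderson–Darling, and called normal if
a majority of applicable tests do not reject at α = 0.05 (the combination
rule is a declared choice; no single convention exists). All groups normal →
one-way ANOVA with Tukey's HSD; otherwise Kruskal–Wallis (tie-corrected)
with Dunn's post hoc test. Dunn's z uses the standard rank variance
`N(N+1)/12 − Σ(t³−t)/(12(N−1))` with Bonferroni adjustment by default (Holm
available). Dunn's test is implemented here directly and checked against a
rank-sum oracle in the tests. The gated procedure's type-I error is verified
by null simulation (4 groups × n=10, 1000 replicates) to sit in the binomial
band around 0.05. Stacks are treated as independent observations — no
mixed-effects modeling of repeated stacks per donor — which understates
between-donor correlation; reproduced as the field's convention and noted
as a caveat.

## Pipeline and demo (`pipeline`)

`run_all` executes threshold estimation, segmentation, collagen metrics,
diametry and orientation per stack, isolates per-stack failures, and runs
group statistics for each metric with ≥2 groups of n ≥ 3. All randomness
derives from the manifest seed; reruns reproduce byte-identical CSVs (the
log carries wall-clock timings and is excluded from that guarantee).

The demo fabricates a four-group study (3 stacks/group, 256×256×12 at
0.2 µm/px) in which fiber count, fiber diameter and cell count differ by
construction such that collagen-per-cell ranks control > eds_like > dn_like
> hi_like — a structural recovery target (ranking), not a numeric
reproduction of any real cohort. The eds_like group gets the thinnest fibers
(0.78 µm vs 1.0 control), dn_like and hi_like progressively fewer fibers,
and hi_like the most cells.

## Problem sizes used in validation

Recovery tests run at desk scale by choice: 256–512 px fields, 6–20 layers,
18–120 fibers, 14–100 cells, 3–4 seeds per condition, 600–1000 Monte-Carlo
replicates for test calibration. These sizes give recovery estimates whose
sampling error is comfortably inside the asserted tolerances while keeping
the whole suite re-runnable on a single CPU.

## Known limitations

* No PSF, attenuation or scattering model; recovery bounds assume resolved
  structures.
* Fiber curvature is not exercised (straight chords); the diametry tangent
  estimate tolerates mild curvature but is untested on tight whorls.
* The per-layer-sum cell count convention overestimates true cell numbers on
  real data where cells span slabs; on synthetic data the generator makes it
  exact, so count-recovery results do not measure that overestimate.
* Heatmap correlation is computed on raw percentages; strongly different
  valid-voxel counts between channels make it noisier at small fields.
* The normality battery's majority vote, Dunn's Bonferroni adjustment and
  the 3·√background dark margin are declared conventions, configurable but
  not inferred from data.
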