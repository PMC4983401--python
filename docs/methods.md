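# Methods

`vasctomo` implements, end to end, the analysis chain of a synchrotron
inline (propagation-based) phase-contrast CT experiment on air-filled
brain vasculature: simulated acquisition of a vessel-tree phantom,
flat/dark-field correction, optional single-distance phase retrieval,
parallel-beam filtered back projection, Hessian-ridge vessel
segmentation, and branching radius-ratio (K) morphometry. This note
records the models, their assumptions, the defaults, and the design
choices made where the design was genuinely open.

## Phantom and acquisition model

**Vessel trees.** Trees are recursive bifurcations. At each junction a
radius ratio is drawn from Normal(`radius_ratio_mean`,
`radius_ratio_sd`), clipped to (0.3, 0.95) and additionally capped so
that `ratio·(1+asymmetry) < 1` (both daughters strictly thinner than the
parent). The daughters receive `ratio·(1±asymmetry)` of the parent
radius, so their arithmetic mean is exactly `ratio × parent` — the
ground-truth K of that junction. Segment length is
`length_per_radius × radius` (default 6, a typical vessel-segment
aspect); daughters deviate from the parent axis by `branch_angle_deg`
(default 35°) on opposite sides of a uniformly random azimuth.
Recursion stops at `min_radius` or `max_depth`.

**Voxelization.** Voxels carry a fractional lumen occupancy with a
one-voxel linear ramp across the tube surface (the partial-volume
behavior of a real pixel); the binary ground-truth mask is occupancy
≥ 0.5. Sub-voxel branches always mark the voxels their axis passes
through, so one-voxel-wide vessels stay connected. Attenuation and
refractive decrement are `(1 − occupancy)` times the tissue values;
defaults at 16 keV are µ = 1.0·10⁻⁴ /µm and δ = 1.0·10⁻⁶ for soft
tissue and 0 for air. The tissue support is the cylinder inscribed in
the grid's (y, x) footprint — a sample in a tube — which keeps
parallel-beam sinograms consistent with a detector as wide as the grid.

**Projection.** Parallel rays rotate about the z axis; line integrals
are computed by resampling the volume on a rotated grid (trilinear,
unit-voxel ray spacing) and summing. The rotation sign and the
center-at-`n//2` convention are chosen to match `skimage.transform.radon`
exactly, so sinograms feed `iradon` without re-registration.

**Propagation.** Free-space propagation over distance z uses the
transport-of-intensity (weak-defocus) model

    I_z = I_0 + z · ∇²⊥( I_0 · ∫δ ds ),

which is the exact inverse of the Paganin filter for a homogeneous
object. The Laplacian is evaluated as a Laplacian-of-Gaussian whose
width combines in quadrature a fixed detector response of 0.8 voxels
(pixel/scintillator blur; sub-pixel fringes are not resolvable) and
0.5·√(λz), the scale of the first Fresnel zone below which the
weak-defocus expansion over-amplifies edges that full Fresnel
propagation would render as bounded fringes. With this band limit the
edge contrast grows roughly linearly at short distances and saturates at
long ones — which is both the physically expected behavior and what
produces a visibility plateau at 600–800 mm, the working range the
imaging system was optimized to. The regularization applies to the
fringe term only, so at z = 0 the model reduces exactly to Beer–Lambert
transmission; this limit is verified against an independent brute-force
ray-marching oracle at 10⁻⁶ relative accuracy. Validity: weak defocus
(fringe width √(λz) small against the field of view — enforced with an
error at half the detector width) and a single weakly absorbing
material.

**Detector.** The flat field is `photons_per_pixel` with an optional
parabolic vignette; projections are Poisson counts of the
fringe-modulated signal plus a Gaussian dark level (`dark_offset`,
`dark_sd`). Defaults — 10⁴ photons/pixel, 100 ± 2 counts dark, 10 %
vignette — give the percent-level shot noise typical of a
well-exposed beamline CCD frame. One `SeedSequence` per acquisition is
split into per-frame substreams by angle index, so runs are bit
reproducible and frames are independent.

## Correction, visibility and phase retrieval

Flat/dark correction is `I_p = (I − I_d)/(I_f − I_d)` elementwise.
Pixels with `flat − dark ≤ 0` are repaired with the median of their
valid 8-neighbors (warning) up to 1 % of the frame, beyond which the
correction errors out. Visibility over a region is
`V = (I_max − I_min)/(I_max + I_min)` from raw extrema; a percentile
variant (0.5 %/99.5 %) exists for noisy data and is off by default. The
distance sweep simulates one projection per distance with a fixed seed,
averages V over the supplied regions, and reports the plateau onset:
the smallest distance with `V ≥ 0.95 × max V`.

Paganin retrieval divides the corrected frame's spectrum by
`1 + πλz(δ/β)|f|²` (frequencies in cycles/µm from the physical pixel
size, DC at index 0) and takes `−ln/µ` with `µ = 4πβ/λ`. The default
`δ/β = 1000` is the order of magnitude for soft tissue at 16 keV; the
retrieval is a side branch — tomographic reconstruction deliberately
consumes the *corrected*, edge-enhanced projections, where vessel
contrast is highest, not the retrieved ones.

## Reconstruction

Corrected frames are rearranged losslessly into per-row sinograms,
converted to line integrals by `p = −ln(max(I_p, 10⁻⁶))` and
reconstructed by standard parallel-beam FBP (frequency-domain ramp
filter with selectable ram-lak / shepp-logan / hann apodization, linear
backprojection) via `skimage.transform.iradon`, rescaled to attenuation
per µm. The rotation center is fixed at the detector column center
(the simulator guarantees it); angles are sorted internally, making the
result order-invariant. Edge-enhanced projections pass through the same
path, so lumina reconstruct dark with bright fringe rims — the contrast
the segmentation exploits.

## Segmentation

The volume is intensity-canonicalized (median-centered, range-scaled —
making the mask exactly invariant to intensity shift and positive
scaling) and negated so air lumina become bright. Ridge strength is a
Sato-style line measure from scale-normalized (γ = 2) Hessian
eigenvalues |λ₁| ≤ |λ₂| ≤ |λ₃|:

    s = max(0, |λ₂| − penalty(λ₁)),   λ₂ < 0, λ₃ < 0,

with full penalty |λ₁| for λ₁ ≤ 0 and quarter weight for λ₁ > 0; the
measure is maximized over detection scales (default 1, 2, 3, 5 voxels,
spanning the sub-20 µm analysis band at a 3.7 µm pixel). A Frangi-type
vesselness was evaluated first but its sharper radial fall-off
truncated tube cross-sections on tree phantoms; both are standard
Hessian tubularity measures and the choice is recorded here.

Ridge points are voxels above a strength quantile (default 0.95 of
positive strengths) that are maxima among their 26-neighbors transverse
to the local ridge direction (the small-|λ| Hessian eigenvector of the
strength field). At up to 400 deterministically subsampled points, the
strength profile along each of the two transverse directions is fitted
with an asymmetric Gaussian `b + A·exp(−(x−c)²/2σ²)`, σ = σ_L left of
the center and σ_R right of it; the fitted parameters form the ridge
descriptor. Fits are bounded (A ≤ 1.5 × profile range) and never raise;
quality is flagged through the fit RMSE.

Descriptor amplitudes are clustered with a Gaussian mixture on
log-amplitude, with 2 or 3 components chosen by BIC: on reconstructed
data the spurious ridges (FBP streaks) are often themselves a
multi-scale population that a forced 2-component fit would split
instead of isolating the vessels. The vessel class is the top-mean
component; the segmentation threshold is the equal-posterior point
between the bottom (spurious floor) and the vessel components — a
middle component, when present, consists of streak ridges whose peak
amplitudes overlap the vessel flanks, so the decision boundary is taken
against the floor and the streaks are rejected by connectivity instead.
The mask is grown by hysteresis:
voxels above the threshold that connect to a voxel at the vessel
component's mean level (seeded from the ridge points themselves if
fitted amplitudes overshoot the grid). When all amplitudes are
identical the mixture is degenerate and each ridge is grown to its
positive-strength basin, whose rim — the transverse inflection of the
smoothed profile — sits at the structure boundary. The mask is then
regularized by morphological closing and hole filling (propagation
fringes leave lobes that would tangle the medial skeleton) and
26-connected components below `min_component_voxels` (default 27) are
removed.

## Morphometry

The mask is thinned with 3D medial-axis skeletonization; per-voxel
radii come from the Euclidean distance transform times the voxel size.
Skeleton voxels with ≥ 3 neighbors are junction voxels; 26-adjacent
ones merge into a node at their centroid. Two cleanups keep the graph
at the anatomical scale: junction nodes joined by branches shorter than
1.5 × the local radius are consolidated (a bifurcation whose medial
axis splits early otherwise reads as two junctions), and leaf branches
shorter than 2 × the junction radius are pruned as skeleton spurs, with
degree-2 junctions dissolved. A branch radius is the median of its
per-voxel radii excluding voxels within 2 × the junction radius of
either end (junction bulges bias radii upward).

At each junction the parent (pre-branching) branch is the incident
branch of largest radius — flow direction is not observable in a static
volume, and the largest vessel is the physiologically standard parent;
exact ties are broken deterministically and flagged. The post-branching
radius is the arithmetic mean of the daughter radii, and
`K = post / pre`. Analysis keeps junctions with pre-branching radius
< 20 µm, binned as [0, 7.4) and [7.4, 20) µm — 7.4 µm being the
smallest resolvable vessel diameter (two 3.7 µm pixels). Groups are
compared per bin with an equal-variance two-sample Student's t-test on
per-animal mean K: animals, not branch points, are the statistical
unit, avoiding pseudo-replication from animals with many junctions.
Animals with an empty bin are excluded from that bin with a warning;
zero-variance degenerate comparisons return t = 0, p = 1 when the means
agree.

## What the synthetic data does and does not emulate

The generator reproduces the features the pipeline is sensitive to:
air-lumen contrast in tissue, parallel-beam geometry over 180°,
distance-dependent edge enhancement, flat-field vignetting, dark offset
and photon noise, and ground-truth branching with a controlled K.
It does not model partial coherence, polychromaticity, detector PSF
beyond the pixel-scale term in the propagation kernel, ring artifacts,
rotation-center drift, sample motion, or real vascular geometry
(tortuosity, anastomoses, diameter taper within segments). Passing
tests therefore demonstrate the correctness and internal consistency of
the analysis chain under its own forward model — not robustness to
every artifact of real beamline data.

## Problem sizes, numerical choices, known limitations

Tests and the acceptance script run at desk scale: 128³ voxels and
120–160 angles per phantom, against the experiment's 2048² × 1500. At
these scales FBP streaks from angular undersampling are the dominant
artifact; the BIC mixture absorbs them into a separate amplitude
population.

When a phantom is sampled finer than the experiment's 3.7 µm pixel, the
propagation distance is scaled to hold the Fresnel number
pixel²/(λz) fixed: the cohort phantoms at a 1 µm voxel are imaged at
52 mm rather than 700 mm. At the unscaled distance the fringe width
√(λz) ≈ 7.4 µm exceeds the radii of the smallest vessels, and radii
measured through the fringes lose the group difference; at the matched
distance fringes stay at the pixel scale — the same operating point the
real system's distance optimization selects — and the radius-ratio bias
becomes common-mode between cohorts. Detection scales are likewise
chosen to span the phantom's radius band in physical units, which is
what the voxel-unit defaults already do at the experiment's own pixel
size.

Radius quantization is the main accuracy limit: distance-transform
radii carry ±0.5 voxel discretization, so K measured on branches of
2–3 voxel radius is compressed toward 1. Single-phantom K recovery at
radii ≥ 2.2 voxels is accurate to ~0.01 (measured 0.786 at a true
0.794); cohort comparisons at small radii retain the group ordering and
significance but with an upward common-mode bias. Numerical floors:
`−ln` clipping at 10⁻⁶, non-positive frames clipped at 10⁻⁸ before
retrieval, a 10⁻⁶ relative epsilon between the float64 threshold and
the float32 strength grid, and fixed random states for the mixture fit
(results are deterministic given the seeds).
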