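# Methods

This note documents the models, parameter choices and numerical decisions
behind petquant, and what the synthetic phantoms do and do not establish
about behavior on real scans.

## Pipeline model and assumptions

The pipeline assumes a 3D SUV image (body-weight normalized, decay
corrected to scan start when converted from activity via
`intensity_to_suv`) with non-negative finite voxels and known spacing.
Lesions are assumed to be connected regions of elevated uptake over a
lower-uptake neighborhood; nothing anatomical (organ maps, CT) is used.

### Detection

The encoder keeps voxels with SUV in [lower, upper]. The default lower
bound is 40 % of the global SUV_max, the conventional clinical uptake
threshold; an absolute-SUV mode exists for protocols with calibrated
cutoffs. Component labeling uses 8-connectivity within slices plus face
adjacency across slices — the 2D labeling convention lifted to 3D; pure
6- or 26-connectivity are available. The `EncoderConfig` size floor is 2
voxels; the *pipeline* raises it to 8 voxels (0.5 mL at 4 mm voxels)
because sub-resolution components are reconstruction noise, not lesions,
and on low-contrast scans the 40 % threshold otherwise yields thousands of
2–3-voxel speckle regions.

### Seeding

Foreground seeds: the part of the region's SUV distribution trusted as
definite lesion. `place_seeds` defaults to the voxels at the region
SUV_max (relative tolerance 1e-6); on noisy images that is a single voxel,
which starves the walker of foreground evidence against a full ring of
background seeds (the harmonic field then collapses around the lone
source). The pipeline therefore seeds the *upper half* of the region's SUV
distribution (`fg_quantile = 0.5`), so the walker adjudicates exactly the
ambiguous band between the ≥50th-percentile core and the 40 %-of-max
background criterion. Background seeds: breadth-first rings expand outward
from the region; the first ring containing voxels with SUV ≤ SUV_max/N
(N = 2.5) supplies all its qualifying voxels, and expansion never exceeds
15 rings so distant structures are not marked.

### Random-walker delineation

Edge weights w_ij = exp(−β(ĝ_i−ĝ_j)²) + 1e-6 with ĝ min-max rescaled over
the crop; β = 90 on the [0,1] scale is common random-walker practice and
makes β contrast-invariant across lesions. The ε = 1e-6 floor keeps the
Laplacian irreducible. The crop is the region bounding box plus a 6-voxel
margin (expanded to include all seeds), bounding the linear system.

Priors: the SUV samples of each seed class feed the diffusion KDE; the
two densities are evaluated at each voxel's SUV and normalized per voxel
to λ_fg + λ_bg ≤ 1. They enter the energy as a unary term of strength
γ = 0.05, giving the augmented SPD system
(L_U + γ·diag(λ_fg+λ_bg)) x_U = −Bᵀm + γλ_fg. γ = 0 recovers the classic
seeded walker; as γ → ∞ every unlabeled voxel approaches its prior ratio
λ_fg/(λ_fg+λ_bg) (this monotone pull is property-tested). A seed class
with a single distinct SUV (e.g. one maximal voxel) degenerates to a
narrow Gaussian bump at that value.

Solver: sparse LU for systems up to 40 000 unknowns, diagonally
preconditioned conjugate gradients (rtol 1e-10) above that, with a sparse
direct fallback if CG stalls. A dense fallback was rejected: a dense
10 000² system alone costs ~0.8 GB. Solutions are clamped to [0,1] after
solving; the decision threshold on the foreground probability is 0.5.

The final mask keeps only the connected component(s) containing
foreground seeds. Under heavy noise the 0.5-level set can grow thin
tendrils or detached islands through chance fluctuations; the restriction
removes islands while preserving every foreground seed (the postcondition
that foreground seeds are inside and background seeds outside the mask is
unaffected).

Noise robustness: the pipeline computes *detection* on the original
volume (so the fraction-of-max criterion sees the true SUV_max) but
*delineation* — seeding SUVs, edge weights, priors — on a Gaussian-smoothed
copy with σ = 1 voxel, matching the PET point-spread scale. Estimating
edge weights from a denoised field is standard practice in graph-based
segmentation; without it, single-voxel noise steps create spurious weight
barriers and the Hausdorff distance is dominated by noise tendrils.
Setting `delineation_smoothing_vox = 0` disables it.

### Texture features

Gray levels: G = 64 equal-width bins over the lesion min–max (G = 16 for
window-size selection, where joint histograms over small windows need
coarser bins). Adding a constant to all SUVs leaves every GLCM/RLM feature
unchanged by construction.

GLCM: four in-plane distance-1 offsets (0°, 45°, 90°, 135°), symmetrized,
accumulated into a single matrix before feature computation. Masked pixels
never pair. Entropies use log base 2 (bits). SUM.AVG, SUM.VAR and
DIFFENTROPY use the standard sum/difference distributions p_{x+y}, p_{x−y};
SUM.SQR is the variance about the marginal mean.

Run lengths: maximal equal-level runs per direction, masked pixels
terminate runs; the 11 Galloway/Chu/Dasarathy statistics are computed per
direction and averaged over the four in-plane directions.

Descriptive statistics: mean, sample SD, median, median absolute
deviation (MADint) and the maximum absolute deviation as a separately
named variant (MAXDEVint), since both readings of "MAD" occur in the
radiomics literature. The interquartile range comes from the diffusion-KDE
CDF — stable for the small samples local windows produce — and skewness /
excess kurtosis from sample moments (normal = 0). Fewer than 4 values
flags the higher-order entries NaN.

GMRF: the conditional autoregression I_xy ≈ Σ_z θ_z S_xy;z + ε, where
S_xy;z sums the two symmetric neighbors of pair z; the default n = 6
neighborhood is the horizontal, vertical and main-diagonal pairs.
Estimation is ordinary least squares over pixels whose whole neighborhood
is valid; σ is the residual SD. The 180°-rotation invariance of θ is
structural and tested. A Gibbs sampler for the same conditional model
(checkerboard updates, periodic boundaries, validity condition
2Σ|θ| < 1) provides parameter-recovery validation.

### Local-window analysis

Windows are non-overlapping block_size² tiles anchored at the lesion
bounding-box corner, per slice; tiles with ≥ 50 % lesion coverage are
kept, and if none qualifies anywhere the lesion falls back to one
whole-lesion window per slice. The MMI selector quantizes lesion SUVs at
G = 16 and sums, over all in-slice grid-adjacent window pairs, the mutual
information between raster-paired pixel levels; the size with the largest
sum wins, ties to the smaller size. "Adjacent-window paired-pixel MI" is
one concrete reading of window-to-window information sharing; comparing
each window to the whole lesion is a plausible alternative and the
adjacent-pair form was chosen as the more local of the two. The run-length
selector instead maximizes the mean Pearson correlation between adjacent
windows' run-length distributions (run matrices summed over directions
and levels, zero-padded to a common length).

Global values pool the lesion pseudo-3D: descriptive statistics over all
lesion voxels, GLCM counts and run matrices accumulated across slices
before feature computation, the GMRF design stacked across slices. Local
SDs are sample (n−1) standard deviations of per-window values; windows
where a feature fails (e.g. a degenerate GMRF fit) are skipped.

### Shape

Volume is voxel counting times voxel volume. Surface area is the area of
the marching-cubes isosurface at level 0.5 after smoothing the binary
indicator with σ = 0.5 voxels: raw marching cubes on a binary field
overestimates curved surfaces by ~8 % (staircase bevels) while heavier
smoothing rounds away real edges; σ = 0.5 keeps both a digitized ball and
a large slab within a few percent of their analytic areas (and voxel-face
counting, ~1.5× high on spheres, would bias sphericity down by a third).
Sphericity is ψ = π^⅓(6V)^⅔/A, the single 3D circularity measure.
Box-counting fractal dimension fits log N(s) vs log(1/s) over dyadic box
sizes up to half the smallest extent, dropping the two coarsest scales
when five or more exist (they carry the largest finite-size bias).

### Evaluation

Dice 2|A∩B|/(|A|+|B|); Hausdorff between boundary voxel centers (boundary
= mask voxel with a face neighbor outside) in physical mm, 100th
percentile by default with an HD95 option. In cohort evaluation a missed
lesion scores Dice 0 and the grid diagonal as worst-case HD rather than
being dropped.

### Statistics

Pearson CIs by Fisher z; Spearman is Pearson on mid-ranks with a
rank-corrected z CI. Clustering standardizes feature columns and uses
complete linkage with Euclidean distance (so clusters reflect correlation
structure, not scale). The morphology predictor rank-scales the response
to (0,1) via r/(n+1) (min–max scaling available), applies the logit, fits
a linear model by maximum likelihood (Gaussian errors on the logit scale
= least squares, ridge 1e-6 for conditioning), and evaluates by LOOCV;
predictions are back-transformed and summarized by Spearman correlation
with the observed response. LOOCV is conservative: under a permutation
null the Spearman of held-out predictions sits slightly *below* zero
(≈ −0.1 to −0.2 at n ≈ 40–100), the familiar pessimistic bias of
cross-validated predictions; a positive observed correlation therefore
understates, not overstates, predictive signal. Raw p-values are
reported; a Benjamini–Hochberg column can be added where tables are
assembled.

## The phantom generator

Phantoms emulate whole-body FDG-PET SUV maps at clinical sampling: 4 mm
isotropic voxels on a 96×96×44 grid (the in-plane matrix is reduced from
the full 150×150 clinical field of view to the region of interest around
the lesions), background SUV 0.8, spherical / ellipsoidal / lobulated
lesions with peak SUV 1–14, smooth interior texture (Gaussian random
field at 15 % relative amplitude by default), Gaussian partial-volume
blur with σ = 1 voxel applied before additive Gaussian noise (SD 0.5
default). Ground truth is each lesion's pre-noise blurred contribution
thresholded at 50 % of its peak contrast — the standard half-maximum
definition of the functional boundary — and is by construction independent
of the noise stream.

The longitudinal cohort draws 1–3 lesions per patient; companion lesions
take peaks within 60–100 % of the scan's hottest lesion, emulating
tracked target lesions of comparable avidity (a fraction-of-global-max
detector can only see lesions above 40 % of the hottest; tracking
protocols select measurable target lesions in the same spirit).
Follow-up scans rescale each lesion radius by a drawn volume factor
(lognormal σ = 0.3, clipped to [0.45, 2.2]) and perturb ellipsoid axis
ratios by ±15 %, with the drawn factors recorded as ground truth for
prediction tests.

What the phantoms do **not** emulate: spatially correlated reconstruction
noise, respiratory motion, physiologic uptake (brain, bladder, heart)
that real pipelines must exclude, scanner-specific PSF anisotropy, and
partial-volume bias beyond the isotropic Gaussian. Passing phantom tests
therefore validates the algorithmic chain (detection geometry, solver
correctness, feature formulas, statistical calibration), not clinical
accuracy on patient scans.

## Problem sizes and runtime

Default validation sizes: 30-scan cohort (≈ 60 lesions) for segmentation
accuracy, 20 replicates of 64×64 Gibbs textures for GMRF recovery, 1000
replicates for test-size calibration, n = 10 000 for KDE integrated
squared error. A full cohort evaluation runs in a few minutes on one CPU;
single-lesion segmentation is sub-second (crops of ~10⁴ unknowns).

## Known limitations

- The encoder's fraction-of-max threshold degrades gracefully but
  meaninglessly when 0.4·SUV_max approaches the background level
  (very-low-contrast scans): detection then returns many speckle regions
  and the size floor does the filtering.
- Window-size selection is near-optimal only; for lesions spanning few
  slices the MMI sum rests on a handful of window pairs.
- The GMRF least-squares estimator is consistent for the interior of
  homogeneous textures but biased near strong gradients; lesion-boundary
  windows are excluded only by the mask, not by a gradient test.
- Sphericity of digitized masks carries a ±2 % mesh tolerance; values
  marginally above 1 are possible for near-perfect spheres.
- Multi-label delineation (> 2 classes), dynamic (4D) PET, and DICOM
  series handling are out of scope; NIfTI is the interchange format.
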