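# Methods

`hdlatent` re-implements, as a tested pipeline on synthetic data, a
quantitative-CT workflow for characterizing lungs of subjects exposed to
aerosolized humidifier disinfectants (HD) whose CT and pulmonary
function tests look normal: unsupervised tissue-pattern discovery on
paired inspiratory/expiratory CT, latent-trait extraction, subject
phenotyping, and a 1D aerosol-deposition surrogate for the airway
physiology stage.

## Two-channel image model

Each subject is represented on the inspiratory (TLC) grid by two
co-located channels:

- **density** — CT attenuation linearly rescaled from [−1024, 200] HU to
  [0, 1]. The window spans air to soft tissue; the normalized densities
  of interest (≈0.09–0.27) fall comfortably inside it.
- **Jacobian J** — det(I + ∇u) of the displacement u mapping IN to EX
  coordinates (mm), computed by central differences (one-sided at
  boundaries) and floored at 10⁻³. J is the EX/IN local volume ratio:
  J < 1 is normal regional deflation from TLC to RV, J > 1 marks
  hypo-inflation (a region larger at RV than at TLC); 1/J is the local
  expansion. Central differences are exact for affine displacements and
  second-order accurate otherwise.

Outside the lung both channels take the neutral fill (0, 1) so border
patches carry no extrapulmonary signal.

## Synthetic cohort

No public imaging data exist for this population, so the package
generates its own study condition with known ground truth:

- **Phantom**: two ellipsoidal lungs on a 64³ grid at 1 mm isotropic
  spacing, split into five lobes (LUL/LLL; RUL/RML/RLL) by fixed
  fractional planes. Anatomy fidelity is irrelevant to what the tests
  measure; lobe labels are needed for lobe-resolved metrics.
- **Tissue patterns**: each subject carries a mixture over pattern
  classes, each with a mean/SD attenuation and a mean/SD Jacobian. The
  four defaults — normal parenchyma (−870 HU, J 0.55), a hyperlucent
  high-expansion pattern (−916 HU, J 0.77), a deflation-limited pattern
  (−833 HU, J 0.44) and a dense hypo-inflated pattern (−697 HU, J 1.40)
  — are loosely calibrated to the normalized densities and Jacobians
  that separate the published latent traits. Blobs are obtained by
  quantile-partitioning one smoothed Gaussian random field inside the
  lung: spatially coherent, disjoint, with realized proportions exact up
  to voxel discretization. Blob coherence defaults to the secondary
  pulmonary lobule scale (20 mm).
- **Displacement**: purely axial (apex–base, diaphragm-like)
  compression u = (0, 0, g) with g(x,y,z) = ∫₀ᶻ (j_target − 1) dz′. For
  a field of this form det(I + ∇u) = 1 + ∂g/∂z = j_target *exactly*,
  independent of lateral variation, and the map is invertible whenever
  j_target > 0. A radial-scaling cosine-series construction was
  prototyped first and abandoned: at the required deformation magnitude
  (J 0.44–1.4) the x·∇c cross term produced 20–50% per-blob errors and
  its fixed-point correction diverged. A 3-iteration per-blob amplitude
  correction absorbs the central-difference smearing at blob faces;
  per-blob mean J lands within 0.1% of the planted value (the test
  bound is 5%).
- **EX image**: generated directly on the IN grid in registered-EX
  convention via mass conservation, HU_EX = (HU_IN + 1000)/J − 1000.
  The CT-measured RV volume is the Jacobian integral over the lung.
- **Airway trees**: rooted binary trees with per-generation diameter
  reduction (default 0.78, Weibel-like), circular lumens, length = 3
  diameters, optional sibling asymmetry, and anatomical lobar labels
  (left main → LUL/LLL; right main → RUL + intermediate → RML/RLL).

What the generator does **not** emulate: scanner noise and
reconstruction kernels, airway lumens inside the image volumes,
realistic lobe shapes, registration error in the displacement field
(displacements are exact by construction), or correlated clinical
covariates. Passing tests therefore demonstrate that the pipeline
recovers planted structure through all of its stages — not that it
would recover pathology from real CT, where registration artifacts and
scanner variability add noise sources this phantom does not contain.

## Patch sampling

Patches are 20 mm cubes (the scale of a secondary pulmonary lobule), at
least 50% inside the lung by default. Training patches are drawn by
seeded rejection sampling, uniform over valid positions; quantification
uses a deterministic sliding-window raster (sampler default stride
10 mm; the pipeline's study configuration uses 5 mm, which quadruples
the windows per subject and visibly smooths the 20-subject histograms).
Anisotropic inputs must be resampled to isotropic spacing first so a
physical cube is a voxel cube.

## CAE-FC: autoencoder with feature constructor

The encoder is three stride-2 3D convolutions (channels 2→16→32→C) with
ReLU; for 20³ patches the embedding is C×3³. The feature constructor
scores each embedding channel by the sum of its positive activations,
keeps the top channel (ties → lowest index) and zeroes the rest; the
transposed-convolution decoder reconstructs the patch from that single
channel. The surviving channel index is the patch's pattern cluster.
The cluster count C is chosen by training one model per candidate under
an identical budget and keeping the lowest final loss.

**Training schedule.** Naive winner-take-all training collapses onto one
channel: only the winner receives reconstruction gradient, so the
largest-norm channel wins everywhere (verified empirically; purity at
chance). Training therefore runs in two phases:

1. *Alignment* (default: the whole budget): patches are self-labelled
   once by k-means on their standardized in-lung channel means (average
   density, average J — the same two-channel summary used to describe a
   pattern), and reconstruction is gated by those labels. Two auxiliary
   terms act on the embedding: a softmax cross-entropy (weight 0.1)
   pulling each patch's channel-score vector toward its label, applied
   to the **pre-ReLU** activations so silenced channels can recover, and
   a suppression penalty (weight 0.1) on the losing channels' positive
   activations — the feature constructor's "suppress the small
   activations" made explicit in the loss.
2. *Free* (optional, `align_fraction < 1`): the fixed labels are
   replaced by the model's own dominant-channel rule. Left on for long
   it can re-merge clusters, which is why the default keeps alignment on
   throughout; assignment at inference is always the model's own
   dominant-channel rule, and on the four-pattern fixture it agrees with
   the planted classes at purity ≥ 0.99 across seeds (bound tested:
   0.8).

Optimization is Adam (lr 3·10⁻³), batch 32, fixed epoch budget, all
randomness (weights, self-labelling, shuffling) from one seed; training
is bit-reproducible. Everything runs in numpy on one CPU; the layer
stack is small enough that im2col convolutions are fast at these sizes.

A consequence of the gated decoder worth noting: per-patch capacity is
one channel regardless of C, so reconstruction loss is not globally
monotone in C (a C=1 model, which gates nothing, trains to a lower loss
than any gated model). Within gated models on the four-pattern fixture,
loss at the planted C=4 is reliably below C=2, which is what the
lowest-loss selection rule needs.

## Histograms, EFA, subject clusters

Sliding-window assignments become per-subject pattern-cluster frequency
histograms (counts/total, whole lung, no lobe weighting). The
subjects×C matrix is standardized per column (zero-variance columns
dropped) and factored by iterated principal-axis factoring (SMC start,
tolerance 10⁻⁴, 200 iterations) with varimax rotation (orthogonal —
keeps the k-means geometry downstream interpretable; promax available).
The factor count is fixed when given, else Horn-style parallel analysis
(seeded, 95th percentile). Subject scores are Thomson regression
scores, computed with a pseudo-inverse because compositional histogram
columns can make the correlation matrix exactly singular. Factors with
salient loadings (|λ| ≥ 0.4, the conventional cutoff) of both signs are
flagged bi-polar; their positive/negative cluster sets describe
opposite tissue configurations of one trait. Factor–variable
correlations use Pearson (continuous) or point-biserial (binary), and
the reported table masks entries with p ≥ 0.05 while the full table is
always written.

Subjects are clustered by k-means on the factor scores (raw regression
scores, 10 seeded restarts), the count chosen by the Calinski–Harabasz
variance ratio over 2–10 unless fixed; clusters are relabeled by
descending size and clusters under 5 members are flagged minor.
Representatives are the subjects nearest their cluster centroid. The
classifier is a depth-3 Gini CART on clinical + imaging variables with
stratified 3-fold cross-validated accuracy.

## QCT metrics

LAA% is the fraction of mask voxels under a threshold (−950 HU at TLC,
−856 HU at RV — field-standard values; configurable). Tissue% linearly
interpolates HU between air (−1000) and soft tissue (+55). fSAD% uses
the joint parametric-response-map rule (non-emphysematous at TLC, gas
trapping at registered RV); the 4-class PRM decomposition (normal,
fSAD, emphysema-like, high-attenuation at −810 HU) partitions the mask
exactly. RV/TLC uses mask volume at TLC and the Jacobian integral as RV
volume; AWV% uses branch-cylinder airway volume when no airway mask is
given. All metrics are reported total and per lobe.

## 1D airway surrogate

The 3D CFD stage is replaced by a quasi-steady 1D description — this
package's deliberate scope, since whole-tree deposition fractions are a
1D-model quantity anyway. The inspiratory waveform is a half-sine with
tidal volume 7 mL/kg body weight and peak at 1.2 s; "period 4.8 s" is
read as the full breath cycle, so the inspiratory phase is 2.4 s (the
alternative reading, 4.8 s of inspiration, is a config switch). Branch
flows split symmetrically (or area-weighted) at bifurcations; pressure
drops are laminar Poiseuille, ΔP = 128 μ L Q / (π Dh⁴), with hydraulic
diameter Dh = 4A/P and μ = 1.81×10⁻⁵ Pa·s. Deposition efficiencies per
branch at peak flow: Chan–Lippmann Stokes-number fit for impaction
(η = 1.606·Stk + 0.0023, non-root branches), Pich's laminar inclined-
tube formula for gravitational sedimentation (default branch angle 45°,
verified against a Monte-Carlo particle-tracking oracle to <2%), and
Ingham's expression for Brownian diffusion; mechanisms combine as
independent, η = 1 − Π(1 − ηᵢ). The entering fraction propagates root →
leaves with flow-split weights; bookkeeping is exact (ΣDF + escape = 1).
For 0.5 µm unit-density particles (slip correction ≈ 1.34) all three
efficiencies are small, total conducting DF is a few percent, and
uniform narrowing raises it — the affected-cluster direction.

## Statistics

Welch's t and Welch's heteroscedastic ANOVA are implemented from
summary statistics (n, mean, SD) so published tables can be re-analyzed
without raw data; raw-sample forms reduce to them exactly.
Games–Howell uses per-pair Welch df and the studentized-range
distribution with k groups. Chi-square applies Yates continuity
correction for 2×2 tables by default — with the published
gender-by-exposure counts this reproduces the printed p = 0.013, which
the uncorrected statistic does not — and never for larger tables. Tests
are two-sided at α = 0.05. The exposure-by-cluster association is
p < 0.001 whether or not the two minor clusters are included.

## Problem sizes and numerical choices

Default desk-scale sizes: 64³ grids, 2×10 subjects, 24 training patches
per subject, C = 8 pattern clusters, 2 factors, sliding-window stride
5 mm, 20 epochs; a full pipeline run takes about a minute on one CPU
(the network runs in float32), and the paper-scale settings (80
clusters, 98k patches, 6 factors) remain reachable by config. Degenerate inputs are
rejected with messages (empty masks, non-normalized mixtures, zero
margins, classes too small to stratify). Ties break deterministically
(lowest channel index; lexicographic subject id). All stage seeds fan
out from one global seed by fixed offsets, and the pipeline manifest
records per-file checksums; a rerun with the same config is
byte-identical.

## Known limitations

- **Subject-cluster recovery at desk scale is imperfect.** On the
  default two-group condition (10 subjects per group), the planted
  groups are recovered exactly (ARI 1.0) in about 6 of 10 seeds; most
  other seeds misassign one or two subjects. Two effects dominate.
  First, with 20 subjects a single misassignment already drops the
  adjusted Rand index to 0.7996, so any "ARI >= 0.8" reading of
  recovery effectively demands perfection. Second, each lung hosts only
  a handful of independent lobule-scale pattern blobs, so a subject's
  realized window-composition distribution carries irreducible sampling
  variance that can make an individual subject borderline, and with
  only 20 subjects the factor analysis sometimes hands k-means a
  nuisance axis. Larger cohorts, stronger planted contrast, or
  finer-grained blobs all resolve this — at the cost of departing from
  the desk-scale defaults documented here.
- The CAE-FC's cluster semantics are anchored by the k-means
  self-labelling on channel means; patterns that differ only in spatial
  texture at equal means would need a richer seeding statistic.
- Histogram quantification assigns each window its dominant pattern;
  heavily mixed windows dilute frequencies toward uniform.
- The 1D deposition surrogate has no secondary flows, turbulence or
  expiratory phase, and branch gravity angles default to a single
  value.
- Welch/Games–Howell from summaries assume within-group normality; no
  multiple-testing correction is applied beyond Games–Howell, matching
  the analysis it reproduces.
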