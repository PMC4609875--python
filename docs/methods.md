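# Methods

## Scope and data model

`tumortex` classifies binary-labeled volumes of interest (VOIs) — masked
regions of 3D scalar images — by volumetric texture. The in-memory currency
is the `QuantizedVOI`: a full-grid integer array of gray levels 1..G inside
the mask and 0 outside, together with G, the voxel spacing, and the longest
bounding-box edge L (which bounds the useful co-occurrence distance range at
L/2). Labels are encoded +1 (malignant, the "positive" class for
sensitivity bookkeeping) and −1 (benign).

## Preprocessing

**LoG filter.** The anisotropic 3D Laplacian-of-Gaussian kernel is

C·[(x²/σx⁴ − 1/σx²) + (y²/σy⁴ − 1/σy²) + (z²/σz⁴ − 1/σz²)]·exp(−x²/2σx² − y²/2σy² − z²/2σz²),

sampled on the integer grid [−r, r]³ with r = ⌈4·max σ⌉ by default (at least
3σ is enforced so the truncated tails are negligible). The continuous LoG
integrates to zero; truncation breaks this, so the discrete kernel is
mean-subtracted, making the filter exactly DC-free (constant volumes map to
zero). Convolution uses reflective boundaries. Defaults: σ = 1 voxel
isotropic, C = 1. Whether downstream features are computed on filtered or
raw intensities is a pipeline flag (`use_log_filter`, default on); the two
choices give different but equally valid texture representations, and the
phantom experiments pass under both.

**Quantization.** Min–max linear binning of *in-mask* intensities into
levels 1..G, G = 16 by default (a conventional radiomics choice balancing
matrix sparsity against level resolution; configurable). The maximum maps
to G; a constant region maps to level 1; binning is monotone by
construction. Coordinates are 0-based voxel indices and all direction
offsets act in (x, y, z) index space.

## The 77-feature descriptor

**Directions.** A voxel's 26-neighbourhood contains 13 antipodal offset
pairs; the canonical table keeps one offset per pair with its (θ, φ) angle
label. Co-occurrence matrices are symmetrised (each pair counted in both
orders), which makes the 13 half-neighbourhood directions equivalent to the
full 26-neighbourhood and gives the correlation statistic a single
well-defined marginal.

**GLCM block (5).** Entropy −Σ P log₂ P, homogeneity Σ P/(1+|i−j|),
contrast Σ (i−j)² P, energy Σ P², and correlation
Σ (i−μ)(j−μ) P / σ² with μ, σ² from the symmetric marginal (defined as 0
when σ² = 0). Entropy is the standard positive (base-2) form. Features are
averaged over the 13 directions and the distance set, default {1, 2}
(configurable up to L/2): d = 1 captures fine local texture, d = 2 adds a
coarser scale at modest cost. Directions with no valid voxel pair are
skipped from the average.

**Run-length block (11).** Runs are maximal sequences of equal gray level
along lattice lines parallel to an offset, restricted to in-mask voxels; a
mask gap breaks a run. The 11 statistics are the classical
Galloway/Chu set: SRE, LRE, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE,
GLNU = (1/nr)Σᵢ(Σⱼ p)², RLNU = (1/nr)Σⱼ(Σᵢ p)², and run percentage
RPC = nr / Σ j·p(i,j) (runs per covered voxel). Averaged over the 13
directions.

**Centroid-line block (61, SCLGM).** The centroid is the rounded mean
in-mask coordinate (exact .5 fractions round toward the lower index). For
each of the 13 offsets a digital line steps in integer multiples of
±offset across the bounding box; its profile is the ordered gray levels of
the in-mask voxels crossed. Twelve distributional statistics — mean,
variance, mean absolute deviation, standard deviation, skewness, kurtosis,
median, min, max, range, histogram energy and histogram entropy — are
computed (a) on the pooled profile of all 13 lines (12 features) and
(b) per line, aggregated across lines by mean/min/max/range (48 features),
plus the mean line length (1 feature): 61 in total. This layout is a
reconstruction that uses only the method's stated ingredients (13 lines, 12
statistics, total 61); the original source fixes the counts but not the
enumeration. Moments use population (n) normalisation; skewness/kurtosis of
zero-variance profiles are defined as 0; kurtosis is excess. Statistics are
computed on quantized levels, consistent with the line definition. A line
that misses the mask entirely (possible for thin or concave masks) falls
back to the level of the in-mask voxel nearest the centroid.

The full vector is deterministic, invariant to VOI translation, and its
blocks concatenate in the fixed order SCLGM(61) ‖ GLCM(5) ‖ RLM(11).

## Gravitational search

Agents are positions in [0,1]ⁿ. Per iteration: raw masses
mᵢ = (fitᵢ − worst)/(best − worst) (minimization; uniform 1/N when all
fitnesses tie), normalized Mᵢ = mᵢ/Σm; gravitational coefficient
G(t) = G₀e^(−αt/T); forces from the K best agents only,
Fᵢ = Σⱼ rᵢⱼ·G·Mᵢ·Mⱼ/(Rᵢⱼ+ξ)·(xⱼ−xᵢ) with Euclidean Rᵢⱼ and softening
ξ = 10⁻⁹; acceleration a = F/M (zero-mass agents get zero acceleration);
velocity v ← rand·v + a; position clipped to the unit cube. K decreases
linearly from N to 1 over the run. Elitist bookkeeping returns the best
position ever evaluated; the history trace is monotone.

Defaults follow the published configuration: N = 100 agents, T = 500
iterations, G₀ = 100, objective minimized. α = 20 (the standard decay
setting; the source gives none) and Bernoulli p = 0.8 (defined but
unvalued there) are configurable.

*Velocity limit.* With G₀ = 100 on the unit cube, early accelerations
exceed the domain width roughly tenfold and an unchecked swarm pins at the
walls and never searches. Each velocity component is therefore clamped to
±vmax, vmax = 0.1 (10% of the domain width, the standard swarm-search
remedy); this is the one numerical guard added to the published dynamics.

**Refined variant.** Force weights rᵢⱼ are Bernoulli(p) draws — a force
either exists or does not — instead of Uniform[0,1]; the velocity memory
coefficient is ln(1/u)/4 with probability 0.6 (u uniform) and 0.4 + 0.1·g
otherwise (g standard normal), clamped to [0,1] since the logarithmic
branch is unbounded and the coefficient scales retained velocity. The
printed form of the logarithmic branch is ambiguous ("ln(1/rand_d4)") and
is read as ln(1/rand_d)/4, whose pre-clamp mean E[−ln U]/4 = 0.25 matches
the Uniform[0,1] mean expectation of the classical coefficient reasonably.

**Geometric benchmark.** A standalone VOI-localisation objective — the sum
of squared distances from a decoded point to all VOI voxels, minimized at
the centroid, with an additive penalty for points whose nearest voxel lies
outside the mask — is provided for optimizer demonstrations; it plays no
role in feature selection.

## Wrapper feature selection

An agent position of length d+2 decodes to a feature mask (coordinate
> 0.5 ⇒ feature on; an all-off mask is repaired by enabling the highest
coordinate) and, log-uniformly from the last two coordinates, the SVM
regularization C ∈ [0.1, 100] and RBF width σ ∈ [0.1, 10]. The fitness

fitness = θ·accuracy + (1−θ)/featuresel, θ = 0.7,

is maximized (negated for the minimizing engine); accuracy is stratified
5-fold cross-validated accuracy of the decoded SVM on the masked features —
LOO inside the search loop would multiply cost by n/5 for no ranking
benefit; final reported metrics always use LOO. Identical decodes are
cached within a run.

Note a structural property of this objective: the parsimony term is steep
at small subset sizes (1/1 − 1/2 = 0.5 of its range), so once a small
feature set reaches high cross-validated accuracy, the optimum favours
*very* few features; with strongly informative features the global optimum
can be a single feature. The selected-set composition among equally
accurate, equally sized masks is not identified by the fitness — a
limitation inherited from the objective, visible in the feature-recovery
experiments.

## Classification and evaluation

The SVM is scikit-learn's soft-margin RBF machine with gamma = 1/(2σ²);
predictions are the sign of the decision score; +1 (malignant) is the
positive class. Features are z-scored with each training fold's statistics
before classification — the 77 features span several orders of magnitude
(histogram energies near 0.1, gray-level non-uniformities in the
thousands) and the RBF kernel needs commensurate scales for σ to mean
anything. When no tuned (C, σ) is supplied, the kernel width defaults to
scikit-learn's data-driven `gamma="scale"`.

Leave-one-out evaluation performs n single-holdout fits; a fold whose
training split is single-class predicts the training majority (documented
fallback). Reported metrics: confusion counts, sensitivity TP/(TP+FN),
specificity TN/(TN+FP) (NaN, not 0, on empty denominators), accuracy,
RMSE/MAE on 0/1-encoded predicted classes, the ROC sweep with trapezoidal
AUC and the max(TP−FP) operating point. Classifier pairs are compared with
the two-sided Wilcoxon signed-rank test on paired per-subject losses
(p = 1 when all differences vanish). The kNN baseline (default k = 5, odd
so binary votes cannot tie) uses the same LOO protocol.

## Phantom generator

Phantoms emulate the *statistical* structure that the texture features
measure, not MRI physics. A lesion is an ellipsoid (default semi-axes
10×8×6 voxels in a 32³ grid) whose interior is Gaussian white noise
convolved with an isotropic Gaussian of the class correlation length,
standardised and rescaled to the class mean and noise std; the background
is independent noise. Defaults: benign (−1) mean 100, correlation length
1.0 voxel; malignant (+1) mean 110, correlation length 2.5 voxels; both
noise std 20 over background 60 ± 15 — a modest mean offset (0.5 noise-std)
plus a coarseness difference, chosen once as a plausible two-texture
contrast since the clinical source gives no quantitative texture
description of its classes. Larger correlation length yields higher
neighbour co-occurrence similarity (lower GLCM contrast, higher
homogeneity) and longer runs, so the two classes differ exactly where the
descriptor looks. Per-subject seeds are counter offsets from the master
seed, making cohorts of any size reproducible.

What the phantoms do *not* model: Rician noise, bias fields, partial-volume
effects, anatomy, multi-sequence acquisition, or inter-subject anatomical
variability. Passing phantom tests therefore demonstrates that the
pipeline recovers known statistical structure — not clinical performance.

The tabular generator emits n labeled d-dimensional unit Gaussians with k
informative columns shifted by `effect` noise-stds in the +1 class — the
controlled test bed for the wrapper: the informative set, and hence recall
and precision of any selected subset, is known exactly.

## Problem sizes in the shipped experiments

The test suite exercises the optimizer at N = 20 agents with T = 50
iterations (tabular selection, 60 samples × 30 features), T = 100 (sphere
benchmark, 10 dims) and T = 30 (10-subject phantom cohorts) — scaled-down
versions of the published N = 100 / T = 500 configuration, which remains
the library default. Oracle-equivalence checks run on 100 random 5×5×5
masked volumes (exact integer counts) and ROC pair-counting on ≤ 20-sample
instances.

## Known limitations

* The SCLGM layout is one defensible reconstruction of an underspecified
  enumeration; only the block total (61) and its ingredients are fixed by
  the source method.
* The wrapper objective cannot distinguish equally sized, equally accurate
  subsets (see above), so "which" features are selected is partly
  arbitrary on easy problems.
* Internal 5-fold CV on very small cohorts (folds of two at n = 10) makes
  the co-tuned (C, σ) noisy; the selected *subset* is more stable than the
  selected hyperparameters.
* Run-length and centroid-line extraction walk lattice lines in Python;
  comfortably fast for lesion-sized VOIs (~10⁴ voxels), not tuned for
  whole-brain masks.
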