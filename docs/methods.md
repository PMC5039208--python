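# Methods

`triplenet` implements a complete triple-network resting-state analysis —
within-network functional connectivity by group ICA and voxelwise tests,
between-network effective connectivity by linear-Gaussian Bayesian
networks, and group comparison of directed edge weights by a group-label
permutation test — together with a synthetic cohort generator that plants
a known spatial and causal truth so that every stage can be validated by
recovery.

## Synthetic cohorts

Each subject's 4D volume is

    y(v, t) = sum_k  s_g(k) * M_k(v) * x_k(t)  +  b * t  +  eps(v, t)

where `M_k` are three non-overlapping spherical templates (CEN, DMN, SN),
`x_k(t)` are node time courses drawn from a linear-Gaussian structural
equation model, `s_g(k)` is a per-group loading scale, `b` a linear drift
per volume, and `eps ~ N(0, sigma^2)` white scanner noise.

Node dynamics follow `x_j(t) = sum_p w_{p->j} x_p(t) + e_j(t)` over an
acyclic graph; the implied covariance is `(I - W')^-1 D (I - W')^-T`. Time
points are white by default because the downstream network model treats
samples as exchangeable; an AR(1) knob exists (`ar_coeff`) but defaults to
0 so the generator and the model make the same assumption. Spatial ICA's
independence assumption is over voxels, and sparse blobs are already
super-Gaussian there, so no extra source transformation is needed for
identifiability.

Defaults describe the emulated study design: 17 "HR" and 12 "LR" subjects,
120 time points at TR 2.5 s, a 24x24x18 grid at 4 mm isotropic (RAS affine,
origin at the volume center), noise sd 0.5 (peak SNR 2 against unit-variance
node series), drift 0.02 per volume, hub model SN->CEN 0.6 and SN->DMN 0.5
with unit noise, and an HR>LR loading of 1.5 on the DMN. No published
effect sizes exist for the within-network group difference, so the 1.5
loading is a generator choice producing a clearly detectable but not
trivial effect at n = 29. Template blobs have radius 4 voxels (16 mm):
planted features must be comfortably larger than the 8 mm FWHM smoothing
kernel, else the smoothing halo alone dominates any overlap score against
the hard truth sphere — a standard phantom-design constraint.

What the generator does *not* emulate: hemodynamic convolution, head
motion, physiological noise, anatomical structure, registration error.
Passing recovery tests therefore demonstrates correctness of the
algorithms under the model's own assumptions, not robustness to real
scanner data.

## Preprocessing

Fixed order: discard the first 5 volumes, remove each voxel's linear
temporal trend, smooth each frame with a Gaussian kernel of 8 mm FWHM
(sigma = FWHM / (voxel size * sqrt(8 ln 2)) per axis, nearest-edge
padding). Detrending preserves the temporal mean (the conventional
resting-state "remove linear trend"); ICA is mean-invariant either way.
Real studies smooth before detrending; for stationary synthetic data the
two orders are equivalent in expectation, and the order here keeps the
per-subject operations separable. Realignment and spatial normalization
are out of scope — cohorts are generated on a common grid. Before ICA only
per-voxel mean removal is applied (no variance normalization), matching
common group-ICA practice.

## Group ICA

Temporal-concatenation group ICA: per-subject temporal PCA to the model
order, concatenation, second PCA to the model order with whitening, then
Extended Infomax. Back-reconstruction uses the pseudo-inverse (GICA)
formulation: with `B = W @ whiten` partitioned into per-subject blocks
`B_i`, subject maps are `M * B_i @ R_i` and subject time courses
`F_i @ pinv(B_i)`.

The model order is estimated per subject by the Wax–Kailath MDL criterion
on temporal-covariance eigenvalues and aggregated by the median (robust on
synthetic cohorts; an integer override is available). Two numerical
details matter: eigenvalues are floored at 1e-12 of the maximum, and
directions removed exactly by earlier linear operations (detrending, mean
removal) are dropped from the spectrum before evaluating the criterion —
otherwise their null eigenvalues dominate the tail and the argmin
degenerates to p-1. Spatial smoothing correlates voxels and violates the
criterion's i.i.d.-sample assumption, so the estimated order on smoothed
data overshoots the number of planted networks (typically ~20-30 here);
the decomposition is robust to this overestimation because template
matching selects the three network components afterwards.

Extended Infomax uses full-batch natural-gradient updates
`dW = lr (I - K tanh(u) u'/N - u u'/N) W`, with the diagonal sign matrix K
per component from a moving-average kurtosis estimate (+1 super-Gaussian,
-1 sub-Gaussian, momentum 0.9). Defaults: learning rate 0.1 (full-batch
natural gradient is stable at large steps; stochastic variants of this
algorithm traditionally use ~0.01/ln(k), which under-converges without
sample noise to help), at most 2000 iterations, convergence when the
maximum absolute weight change falls below 1e-6, learning-rate annealing
by 0.9 on blow-up. Initialization is a seeded random orthonormal matrix,
so results are reproducible given the seed. Sign/permutation indeterminacy
is resolved deterministically: components are ordered by explained
variance in the concatenated reduced data and each map is flipped so its
maximum-|z| voxel is positive.

Component maps are z-scored over in-mask voxels (the usual display
convention), which makes template-matching correlations and the
`min_corr` threshold scale-free. Matching is greedy without replacement in
descending absolute spatial correlation, flipping signs so matched
correlations are positive; a best correlation below `min_corr` (default
0.2) raises an error naming the unmatched network. A single joint
decomposition is run for both groups (group-wise inference happens
downstream); per-group decompositions are intentionally not implemented.

## Voxelwise statistics

One-sample t-maps (per group, per matched component) define the network
ROIs: t = mean/(sd/sqrt(n)), dof n-1, two-sided p, Bonferroni control over
in-mask voxels at alpha 0.001, mask restricted to t > 0. Bonferroni stands
in for "FWE" because random-field corrections need smoothness estimation
that is out of scope. Two-sample maps use the pooled-variance t (dof
n_a+n_b-2), two-sided p, Benjamini–Hochberg FDR at q = 0.05, with positive
(HR>LR) and negative (LR>HR) suprathreshold masks reported separately; by
default the test is restricted to the union of the two groups'
one-sample masks for that network. Zero-variance voxels get t = 0 and are
excluded from the multiplicity count. Clusters are 26-connected components
of a suprathreshold mask, dropped below 10 voxels (configurable), reported
with peak |t| voxel mapped to millimetres through the affine and sorted by
peak |t|. Anatomical labelling is out of scope.

## Gaussian Bayesian networks

Per subject, network time series are mask-averages of the (preprocessed)
signal over each group's own one-sample ROI, standardized per subject;
group models are learned on the concatenation of subject series (the
minimal reading of per-subject extraction followed by one model per
group; per-subject fitting with weight averaging is available as an
option). Temporal autocorrelation is ignored — samples are exchangeable
under both the generator's default and the model.

Each node is linear-Gaussian in its parents; the decomposable maximized
BIC is `sum_j loglik_j(MLE) - (d/2) ln N` with d counting edges plus one
variance and one intercept per node (intercepts are ~0 after
standardization but are kept in d so the score stays correct for
non-standardized input). Local scores are computed from the sample mean
and covariance — algebraically identical to per-node OLS — which makes a
full exhaustive search cost only n*2^(n-1) small solves and lets the
permutation test relearn structures thousands of times in seconds.
Residual variances are floored at 1e-12.

The exhaustive search enumerates all labelled DAGs (guarded to <= 5
nodes; 25 DAGs for the three-network case), returns the BIC argmax with
ties within 1e-9 broken by canonical enumeration order, and reports the
full tie set plus the winner's CPDAG (v-structures oriented, closed under
Meek rules R1–R3; R4 is only needed with background knowledge). BIC is
score-equivalent, so a hub like SN->{CEN,DMN} is returned as its 3-member
Markov equivalence class with an undirected CPDAG skeleton — the class is
surfaced rather than silently orienting, because no Gaussian BIC search
can distinguish members of one class.

The L1-regularization-paths search prunes each node's candidate parents
by where they enter the node's lasso path over a penalty grid (default 50
log-spaced values from the null-inducing penalty down to 1e-3 of it),
scores all acyclic combinations of per-node parent subsets (falling back
to path prefixes above a combination cap), and refits the best by MLE.

## Permutation test

The statistic is, for every directed pair present in either group's
learned structure, the difference of connection weights, with an absent
edge contributing 0. Each of the (default 1000) iterations reassigns
subjects to groups of the original sizes uniformly at random (identity
arrangement allowed), relearns both networks — structure and weights —
and records signed differences for all directed pairs. Empirical
two-sided p-values use the add-one correction
`p = (1 + #{|null| >= |obs|}) / (P + 1)`, so p is never exactly 0 and
never below 1/(P+1). No multiple-testing correction is applied across the
<= 6 directed pairs by default (an optional BH flag exists downstream of
the result object). A fixed-structure refit mode exists but is off by
default: relearning inside every iteration is the honest null for a
statistic whose structure is itself data-dependent.

## Pipeline

`run_pipeline` executes simulate → preprocess → gica → stats → bn →
permtest from a single config; stage seeds are derived from the global
seed by SHA-256 hashing of stage names, every artifact is checksummed
into a manifest, and gzip streams carry no timestamp, so a rerun with the
same config is byte-identical. The report lists the matched components,
suprathreshold extents, cluster table, per-group edge weights with the
equivalence-class caveat, and permutation p-values.

## Validation scale

Recovery tests run at the study's design scale where that is cheap
(structure recovery, calibration and power of the permutation test: 17+12
subjects x 135 standardized samples; calibration uses 200 replicate
cohorts of 100 permutations) and at a reduced scale where full volumes
are involved (unit-test fixtures use a 16x16x10 grid with 11 subjects;
the end-to-end check uses the full default 24x24x18, 29-subject cohort).
Scaled-down fixtures plant proportionally stronger effects to keep
detection power comparable.

## Known limitations

- No hemodynamics, motion, or physiological noise: recovery results bound
  algorithmic correctness, not real-data performance.
- Bonferroni is conservative relative to random-field FWE on smooth maps.
- The MDL order estimate inherits the i.i.d. assumption over voxels and
  overestimates on smoothed data (a well-known effect); template matching
  absorbs this.
- Directed orientation inside a Markov equivalence class is not
  identifiable from Gaussian BIC; the package reports classes, and any
  uniquely directed published figure must have used extra conventions.
- The permutation test assumes exchangeable subjects under the null;
  per-subject standardization removes gross scale differences but not
  all conceivable confounds of real cohorts.
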