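# Methods

This note records the model, the defaults and why they are what they are,
the numerical choices, and what the synthetic validation does and does not
establish.

## Morphological connectivity model

An edge between regions *i* and *j* of one subject is the similarity of
their gray-matter (GM) value distributions. Each region's voxel-value
sample is turned into a discretized probability distribution (a pmf on an
*n*-point uniform grid), and the edge weight is KLS = exp(−D), where D is
the symmetrized Kullback–Leibler divergence (natural logs). The model
assumes nothing about the shape of the distributions — unlike
correlation-based morphological networks it needs no normality across
subjects or voxels — but it does assume each region has enough voxels for
a meaningful density estimate (regions under 10 usable voxels are
rejected, threshold configurable).

**Masses, not cumulatives.** KL divergence is defined for normalized
distributions. We therefore compute it on the discretized, renormalized
probability *masses* at the grid points, not on cumulative curves:
cumulative distribution values do not sum to one and do not form a valid
argument for the KL sum. This is the main place where an external
implementation could differ; the KLS = 1 identity, symmetry, and range
(0, 1] are all asserted in the tests on exactly this convention.

**Grid sharing.** The divergence requires both pmfs on one grid. Default
policy (`pairwise`): for each region pair, both densities are evaluated on
a fresh uniform grid spanning the union of the two value ranges extended
by 3 bandwidths; each region keeps its own bandwidth. Alternative
(`global`): one grid spanning all regions, cheaper (each density evaluated
once) but with wasted resolution for narrow regions. Both are exposed;
pairwise is the default because it adapts resolution to each pair.

**Zero floor.** Grid points where one pmf underflows to 0 would make
log-ratios undefined, so both pmfs are floored at 1e-12 and renormalized
before the divergence. This bounds D at roughly 55 on a 128-point grid and
keeps KLS strictly positive. The floor is configurable; results are
insensitive to it for any overlapping pair of distributions.

## Density estimation

- **Bandwidth**: the diffusion-estimator (improved Sheather–Jones)
  fixed point, implemented in its discrete-cosine-transform form: data are
  binned on a fine mesh over the 10%-padded range, and the squared scaled
  time t\* solving t = ξγ^[7](t) is found by scanning a log grid of 120
  points in [1e-10, 1] for a sign change and polishing with Brent's
  method. The estimate is translation-invariant and scale-equivariant
  (asserted in tests) and lands within a few percent of the AMISE-optimal
  1.06·σ·n^(−1/5) on Gaussian samples. If no root is bracketed — common
  below ~30 samples — Silverman's rule (0.9·min(σ, IQR/1.34)·n^(−1/5)) is
  used and a warning is logged.
- **Evaluation**: exact Gaussian-kernel sums on the grid (no FFT
  approximation; grids are ≤ 1024 points and regions ≤ a few thousand
  voxels, so the exact sum is cheap and deterministic).
- **Grid size**: n must be a power of two in 2⁴…2¹⁰; the default is
  2⁷ = 128. The package ships the machinery used to justify such a choice:
  for every region, density curves at adjacent grid sizes are compared by
  the discrete Fréchet distance (dynamic-programming coupling recurrence,
  Euclidean ground metric, tolerant of different curve lengths), subject
  means are tabulated region × adjacent-pair, and adjacent columns are
  compared with a two-sided paired sign-flip permutation test (default
  10,000 iterations, seeded). Curves are (grid abscissa, pmf ordinate)
  pairs in native units. Once the column differences stop being
  significant, refining the grid further no longer changes the estimated
  curves; 2⁷ sits conservatively past that point on smooth data.

## Thresholding and graph metrics

- **Edge count**: round-half-away-from-zero of S·N(N−1)/2, asserted exact
  for every S in the default grid. Ties at the cut are broken by raster
  index order (deterministic across runs and subjects) and logged.
- **Sparsity grid**: 0.05…0.39 step 0.02 — sparse enough to be nontrivial,
  dense enough for small-world estimability; AUC by the trapezoid rule
  (exact for linear metric curves, asserted).
- **Conventions** (Rubinov–Sporns): binary clustering = triangle fraction;
  weighted clustering = Onnela geometric-mean form with weights normalized
  by the graph maximum; weighted path lengths use 1/w edge lengths; nodal
  betweenness is the unnormalized shortest-path count (each unordered pair
  once). Characteristic path length is averaged over *connected* pairs
  with a logged flag when the network is disconnected (the sparsest
  thresholds can isolate nodes); global efficiency, which handles
  disconnection gracefully, is the robust companion. Every metric is
  checked against hand-written brute-force oracles (Floyd–Warshall,
  triangle enumeration, shortest-path counting) to 1e-9 on random ≤12-node
  graphs, binary and weighted.
- **Nulls**: Maslov–Sneppen double-edge swaps (10 attempts per edge,
  seeded), preserving the degree sequence exactly; weighted nulls reassign
  the original weight multiset uniformly over the rewired topology. The
  choice to preserve the weight *multiset* (rather than weights-per-edge)
  keeps the weighted strength distribution comparable while fully
  randomizing weight placement.
- **Modularity**: seeded Louvain, best of 100 restarts (10 per null). The
  z score of Q against the null ensemble is reported alongside the
  normalized Q.
- **Hub rule**: per centrality map, the ⌊0.10·N⌋ top nodes are flagged
  (floor reproduces the 9-of-90 and 11-of-112 counts); the hub score sums
  flags over 3 metrics × 2 network types, and "consistent" means score
  > 3. Ties at the selection boundary go to lower node indices,
  deterministically, with a log message.

## Reliability

One-way random-effects ANOVA per measured quantity: ICC = (MS_b − MS_w) /
(MS_b + (k−1)·MS_w), k = sessions. Between-subject df requires only ≥ 2
subjects; zero-variance tables raise an explicit error rather than
returning NaN. Negative estimates are *reported as computed* and labeled
"nonpositive" (the categories start at 0); boundary values fall into the
upper category (0.25 → "low"). Balanced-table agreement with the standard
ICC(1,1) formulation is asserted against an independent implementation to
1e-10, and affine invariance is asserted as a property.

## Synthetic cohort: what it emulates

The generator plants every structure the pipeline is supposed to recover.

- **Parcels**: cubes of `parcel_edge`³ voxels (≥ 27) on a lattice in the
  left half-volume; each homotopic partner is the mirror image across the
  mid-sagittal voxel plane (odd widths reflect about the center column).
- **Families**: regions share a family base distribution — a two-component
  Gaussian mixture, a reasonable stand-in for skewed regional GM
  histograms. Default family parameters share a broad component at 0.45
  (mass common to all of gray matter, sd 0.10) plus a family-specific
  component whose location (0.25 + 0.05·((3f) mod F)) and weight vary
  non-monotonically with the family label, so cross-family similarity is
  not a single 1-D gradient. These defaults were chosen so that the
  group-mean network at S = 0.2 reproduces the weakly modular,
  small-world regime reported for real cortical morphology (normalized
  Cp, Eloc, Q > 1 with normalized Lp, Eglob within ~0.2 of 1); the
  well-separated alternative (`separated_family_params`, 0.09 spacing, no
  shared component) plants unambiguous modules for partition-recovery
  tests.
- **Random effects**: a subject draws one location shift per *family*
  (sd `subject_sd`, default 0.05) and each session adds another per-family
  shift (sd `session_sd`, default 0.01). Drawing effects at family rather
  than region granularity makes same-family regions of one subject
  *identically* distributed, lets cross-family similarities vary between
  subjects (the substrate of elementwise ICC), and gives homotopic
  partners — which share a family — elevated similarity. Each region also
  carries a fixed idiosyncratic offset (sd `region_jitter_sd`, default
  0.03, shared by homotopic partners) representing stable region-specific
  shape; it supplies the cross-family "shortcut" edges that make the
  planted network small-world rather than a chain of cliques.
- **Sessions**: the base voxel sample is drawn once per (subject, region)
  and reused across sessions, so with `session_sd = 0` the two sessions
  are voxelwise identical and the only within-subject variability comes
  from the session shifts — which is what makes the planted ICC regime
  interpretable: high subject_sd/session_sd ratios give elementwise ICC
  medians above 0.7, `subject_sd = 0` with session noise dominating
  sampling noise gives medians below 0.2.
- **ICC ground truth**: `generate_icc_table` emits y_st = b_s + w_st
  directly, whose population ICC is σ_b²/(σ_b²+σ_w²); the estimator
  recovers it within ±0.05 at 57 subjects × 2 sessions over 100
  replicates (asserted at ratios 0.2, 0.5, 0.8).

**What passing tests do not show.** The generator has no cortical folding,
no registration error, no partial-volume gradients, no spatial
autocorrelation beyond the parcel structure, and its "smoothing effect" is
simply the Gaussian filter applied to block parcels. Results on real data
additionally depend on segmentation quality and atlas fit, which nothing
here exercises; dataset-dependent magnitudes (mean elementwise ICC of a
given cohort, a cohort's modularity value) are not claims this package
makes.

## Study driver

`run_study` executes the full {smoothing on/off} × {atlas} × {binary,
weighted} factorial: similarity matrices (cached to TSV keyed by the
config hash; reloaded with `resume=True`), metric curves and AUCs, nodal
maps, hub scores from group-mean session-1 centrality maps, intersession
matrix correlations, elementwise and metric ICC, and reliability hub
scores. One master seed is fanned out per stage through a SHA-256
derivation of (seed, stage tags), so any stage can be reproduced in
isolation; every output table carries the config hash and seed in a header
comment. A failing subject is logged, skipped, and excluded from
group-level stages; the run continues and reports the failures.

Default problem sizes in the tests (cohorts of ~6–15 subjects, 8–28
regions of 125–216 voxels) were chosen as the smallest sizes at which the
planted effects are comfortably detectable; all generators scale to
arbitrary cohort sizes.

## Known limitations

- The continuous Fréchet distance is not implemented (the discrete variant
  is what the stability analysis needs); densities are fixed-bandwidth,
  not adaptive.
- Sparsity thresholding assumes a fully positive similarity matrix, which
  KLS guarantees; it is not suitable for signed matrices.
- Weighted betweenness with tied path lengths depends on floating-point
  comparisons inside the shortest-path routine; with continuous similarity
  values ties are measure-zero, but exactly tied weights (hand-crafted
  matrices) may resolve differently than an oracle that enumerates paths
  with a tolerance.
- ICC variants beyond one-way ICC(1,1) (two-way consistency/agreement) are
  out of scope, as are repeated-measures ANOVA factor comparisons across
  smoothing/atlas/type — the tidy output tables are designed to feed any
  external stats package.
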