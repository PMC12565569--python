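# Methods

This note records what `fractolung` computes, the assumptions and defaults
behind each stage, what the synthetic data does and does not emulate, and the
numerical choices that affect results.

## Scientific model

The package implements a morphometric-complexity pipeline for radiation
pneumonitis (RP) risk assessment in lung-cancer radiotherapy:

1. **Normal attenuation area (NAA) masking.** All texture metrics are
   computed on the binary set of lung voxels whose attenuation lies in the
   window `(-950, -700]` HU — parenchyma that is neither emphysematous or
   air-like (≤ −950 HU) nor consolidated or vascular (> −700 HU). The lower
   bound is exclusive, the upper inclusive. Lung segmentation is an upstream
   input, never produced here.
2. **Three biomarkers per scan** (details below): box-counting fractal
   dimension (BoxFD), gliding-box lacunarity, and MST fractal dimension
   (MSTFD). Δ features are post-treatment minus pre-treatment values.
3. **Dosimetry.** Mean lung dose (MLD, cGy) and V5/V10/V20 (percent of lung
   volume receiving ≥ 5/10/20 Gy, inclusive thresholds) from a dose grid in
   Gy co-registered with the lung mask, or ingested from a planning-system
   CSV export.
4. **Cohort statistics.** Baseline summaries (counts/percentages, median and
   range) and paired pre/post comparison of each biomarker by the Wilcoxon
   signed-rank test.
5. **Risk modeling.** Random-forest Gini-importance ranking (averaged over
   stratified CV folds) selects the top-k predictors; a Gini decision tree on
   those predictors is cost-complexity pruned (one-standard-error rule); the
   pruned tree is evaluated by pooled cross-validated predictions (accuracy,
   F1, AUROC from leaf probabilities, confusion matrix at 0.5, and a
   one-sided exact binomial test of accuracy against the no-information
   rate). The endpoint is grade ≥ 2 RP as a binary label.

## Estimators

### Box-counting fractal dimension

The occupied set is cropped to its bounding box and covered with grid-aligned
cubic boxes of edge `s`; `N(s)` counts boxes containing at least one occupied
voxel. BoxFD is the least-squares slope of `log N(s)` vs `log(1/s)`. The grid
is anchored at the bounding-box corner (single origin, no multi-offset
averaging), which makes counts translation invariant and reproducible.
Default scales are powers of 2 from 1 up to a quarter of the smallest
bounding-box dimension; a `fit_range` can restrict the regression (at least
three scales must remain). A level-`L` Menger sponge yields exactly
`20^L, 20^(L-1), …` boxes at scales `1, 3, 9, …` and slope
`log 20 / log 3 ≈ 2.7268`, which the tests check to 1e−12.

### Gliding-box lacunarity

For box edge `r`, every fully-interior `r`-cube window (stride 1, integral
volume implementation) contributes its occupied-voxel mass `M`;
`λ(r) = Var(M) / Mean(M)²` with population variance — the squared
coefficient of variation, so a translation-invariant pattern scores 0. The
scalar lacunarity is the arithmetic mean of `λ(r)` over the requested box
sizes (default `2, 4, 8, 16`). This convention (not the `E[M²]/E[M]²` form,
which equals λ+1) is chosen because published parenchymal values below 1
are only consistent with the variance-ratio form. Closed-form checks: a
single voxel in an 8³ grid at `r = 2` gives exactly `343/8 − 1 = 41.875`;
a 3D checkerboard at `r = 2` gives exactly 0.

### MST fractal dimension

For subsets of `n` occupied-voxel coordinates, the total Euclidean edge
length of a minimum spanning tree scales as `L(n) ∝ n^((D−1)/D)` for a
`D`-dimensional support. The slope `m` of `log L` vs `log n` over a schedule
of subsample sizes (default 256…4096, 10 repetitions each, seeded sampling
without replacement) gives `D = 1/(1 − m)`. Full-volume MSTs over 10⁶+
voxels are infeasible, hence subsampling. MST total length is computed by an
`O(n²)`-time, `O(n)`-memory vectorized Prim algorithm (validated against
`scipy.sparse.csgraph` to 1e−13 and ~13× faster at n = 4096 because no dense
distance matrix is materialized). A slope ≥ 1 has no finite dimension and
raises a dedicated error carrying the raw slope.

### Anisotropy

BoxFD and lacunarity assume cubic cells, so masks are nearest-neighbour
resampled to isotropic voxels (default 1 mm) first; occupied physical volume
is preserved to within a few percent on smooth shapes. The MST needs only
pairwise distances and uses the physical mm coordinates of the original
(possibly anisotropic) voxels.

### Pre/post profiles

`compute_profile(pre, post, settings)` computes both profiles with the same
settings, including the same MST subsampling seed, and returns exact
post-minus-pre deltas. Identical masks therefore give exactly zero deltas.

## Statistics

The Wilcoxon signed-rank test drops zero differences (Wilcoxon's original
convention), assigns mid-ranks to ties, and computes the two-sided p-value
exactly from the full signed-rank distribution (dynamic programming over the
doubled mid-ranks) when the number of non-zero differences is ≤ 25;
otherwise a normal approximation with tie-corrected variance and continuity
correction is used. All-zero differences produce a degenerate result with
p = 1. P-values are reported per biomarker without multiple-testing
correction, matching the descriptive presentation of a three-biomarker
panel.

Percent rendering supports `half_up` (default), `half_down`, and `truncate`
because published tables are not consistent about the rounding of ties
(e.g. 19/85 = 22.35…% printed as 22.3%).

## Modeling

- Feature ranking trains one `RandomForestClassifier` (500 trees,
  `max_features="sqrt"`) per stratified CV training fold and averages
  per-feature Gini importances over folds, retaining fold-to-fold dispersion.
- The decision tree is grown by Gini gain on the top-k (default 3) features
  and pruned with the cost-complexity path; candidate alphas are
  cross-validated and the **largest** alpha within one standard error of the
  best mean accuracy is chosen, trading a little accuracy for a simpler tree.
- Evaluation defaults to `cv_pooled`: a tree with identical hyper-parameters
  is refit on each training fold and out-of-fold leaf event-probabilities are
  pooled, so each patient is scored exactly once out-of-sample. A `holdout`
  scheme (single stratified split) is also provided, since published reports
  are often ambiguous between the two.
- The no-information rate (NIR) is the majority-class frequency; accuracy is
  tested against it with a one-sided exact binomial tail.
- Δ biomarkers require the follow-up scan, so models using them stratify
  early post-treatment risk rather than make purely pre-treatment
  predictions; this caveat is the caller's to own.

## Synthetic data

Patient CT cohorts in this problem domain are typically not deposited, so the
package ships generators that stand in for them:

- **Phantoms with known answers**: filled cube (BoxFD 3), plane (BoxFD 2),
  Menger sponge (`log 20/log 3`), random dust, smoothed-and-thresholded
  Gaussian fields (texture resembling an NAA mask: at 64³, occupancy 0.15,
  correlation length 0.75 the three biomarkers land in realistic parenchymal
  ranges), and point clouds of dimension 1/2/3 for the MST estimator.
  Stochastic field phantoms use *exact-count* thresholding: the top
  `round(occupancy·N)` scores are occupied, so the voxel count is identical
  across realizations.
- **Paired pre/post volumes with a planted lacunarity effect**
  (`generate_paired_volumes`): both members are independent realizations of
  the base texture at exactly the same occupied count; the post member's
  score field (pre, for a negative shift) additionally carries a weak
  large-scale occupancy modulation `a·g`, where `g` is standardized
  Gaussian-filtered noise (σ = 10 voxels, periodic). The modulation makes
  the mass distribution clumpier — raising gliding-box lacunarity — without
  changing the occupied count or, at dense occupancies, the box counts at
  any scale (ΔBoxFD is exactly 0), and it leaves the MST subsample scaling
  approximately unbiased. Candidates are re-drawn with escalating amplitude
  (bounded, seeded retries) until the measured shift has the requested sign
  and magnitude and |ΔBoxFD| is within tolerance, as measured by this
  package's own estimators. This emulates the radiation-induced texture
  coarsening reported after radiotherapy *as a direction-of-effect
  mechanism*; it does not claim to model lung physiology.
- **Cohorts with planted decision-tree structure** (`generate_cohort`):
  uniform clinical/dosimetric/biomarker marginals over ranges bracketing
  published NSCLC cohorts, labels produced by a planted decision list of
  threshold rules (optionally with label noise), CTCAE-like grades consistent
  with the binary endpoint. With zero noise and rule probabilities in
  {0, 1}, the label column equals the planted tree's output row by row,
  giving exact ground truth for ranking and threshold-recovery tests.

What the synthetic data does **not** emulate: real parenchymal textures'
long-range correlations, registration or segmentation error, dose-texture
interactions, correlated dosimetric features, or realistic feature joint
distributions (marginals are independent uniforms). Patient-level published
values are therefore a plausibility target, not an acceptance surface.

## Determinism

Every stochastic stage takes an explicit seed; internal streams are spawned
from `numpy.random.SeedSequence` so sub-streams never collide. Repeated runs
with the same configuration are byte-identical (phantoms, paired volumes,
cohort CSVs, profiles, pipeline JSON), which the acceptance suite checks.

## Known limitations

- The exact lacunarity scale set and MST subsampling schedule behind
  published parenchymal tables are generally unreported; absolute values are
  therefore configuration dependent, and only directions/magnitude classes
  transfer.
- The MSTFD subsample estimator retains its honest ~5% type-I rate under the
  null in paired comparisons; planted-effect acceptance accounts for this.
- `read_dvh_table` rejects physically impossible Vx values (> 100%) rather
  than attempting repair; published tables occasionally contain such typos.
- Percentage Vx uses voxel counts, assuming uniform spacing within a grid.
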