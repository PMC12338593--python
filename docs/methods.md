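# Methods

## The model

The package implements Pareto task inference for per-subject resting-state
network (RSN) variance compositions.  The premise: if a population faces
trade-offs between a small number of functional "tasks", individual trait
vectors are confined to a low-dimensional polytope in trait space whose
vertices — the archetypes — are the phenotypes fully specialized for one
task, and performance at a task decays with distance from its archetype.
Here a subject's trait vector is the share of BOLD variance carried by each
of D resting-state networks (a composition: non-negative, summing to one),
and the fitted polytope is a k-vertex simplex.

The analysis has four stages:

1. **Adjusted compositions.** Raw per-network variances are normalized to
   row proportions, then each component column is residualized on an
   intercept plus confounds (age, a 0/1 gender dummy, mean framewise
   displacement, mean DVARS, percent outlier volumes) by ordinary least
   squares; the column mean is added back so values stay on the proportion
   scale.  Rows are *not* re-normalized after adjustment (the adjusted table
   is no longer exactly compositional); a boolean switch re-enables
   normalization for users who want it.  Missing behavioral features are
   median-imputed per feature.

2. **Polytope fit.** Centered PCA without standardization projects the
   adjusted matrix onto the first k−1 principal components.  A minimum-volume
   k-vertex simplex approximately enclosing the scores is found by a
   SISAL-type solver (see below).  Significance is assessed by the t-ratio
   test: t = (convex-hull volume of the scores) / (simplex volume), compared
   against t values from datasets in which every column of the adjusted
   matrix is independently permuted and the whole fit (PCA + simplex)
   re-run.  The empirical p is (1 + #{t_null ≥ t_obs}) / (1 + n_shuffles).
   Vertex uncertainty comes from bootstrap resampling of subjects; each
   resample is projected onto the reference PC basis, re-fit, and its
   vertices matched to the reference solution by the permutation minimizing
   total Euclidean distance (optimal assignment), yielding per-vertex
   covariance ellipses.

3. **Enrichment.** For each archetype, subjects are sorted by Euclidean
   distance to that archetype (in the original D-dimensional space by
   default; PC space optional) and divided into B equal bins (B = 10
   default, 4 supported), remainders assigned to the closest bins.  The
   closest bin is tested against all other subjects: Mann-Whitney U
   (tie-corrected normal z, no continuity correction) for continuous
   features, hypergeometric tail tests for Boolean features.  Effect size is
   the rank-biserial correlation r = 1 − 2U/(n1 n2), oriented so r > 0 means
   the closest bin is larger.  Benjamini-Hochberg FDR (threshold 0.1) is
   applied within each archetype × direction family, and a feature is called
   maximally (minimally) enriched only if, additionally, the closest bin
   carries the largest (smallest) bin statistic — the "closest-bin-extremum"
   filter that screens out mid-gradient features.  Confound columns are
   carried through the enrichment as control features.  A leave-one-out
   loop drops each component (or each labeled system of components) in
   turn, re-fits, re-matches archetype labels via subject distance-profile
   correlations, and marks a result robust only if significant in every
   feasible iteration.

4. **Maps and groups.** An archetype's spatial map is the voxelwise weighted
   average of the component maps with signed rank-biserial weights,
   normalized by Σ|w| so that rescaling all weights leaves the map
   unchanged.  Display thresholding keeps suprathreshold voxels only in
   face-connected (6-connectivity) clusters above a minimum size; positive
   and negative excursions are clustered separately.  Map-to-map similarity
   is Spearman's rho with a two-sided empirical p from
   autocorrelation-preserving surrogates of the archetype map (see below).
   Held-out groups are adjusted for their own confounds, projected onto the
   reference PC basis (centered at the reference mean), and compared per
   archetype by Kruskal-Wallis on the distances with tie correction,
   followed — when significant at 0.05 — by all pairwise Mann-Whitney tests
   with BH-FDR at 0.05 within the archetype's pairwise family.

## The simplex solver

With scores y lifted to ỹ = [y; 1] and M the (k × k) lifted vertex matrix,
barycentric coordinates are A = M⁻¹ Ỹ and the simplex volume is
|det M|/(k−1)!.  Writing Q = M⁻¹, the solver minimizes

    −log|det Q| + λ · Σᵢⱼ hinge(−(Q Ỹ)ᵢⱼ)

over Q, with the affine constraint (barycentric coordinates sum to one)
eliminated analytically by expressing the last row of Q in terms of the
others.  The hinge charges λ per unit of barycentric depth per point
outside the simplex, so λ controls how softly outliers are tolerated.  The
hinge is Huber-smoothed with width δ; optimization is L-BFGS from a
furthest-point initial simplex inflated by 10% about its centroid, solved
first at δ = 10⁻³ and then polished at the target width (10⁻⁷ by default)
so that degenerate inputs (data exactly at the vertices) reproduce t = 1 to
high accuracy.  Failures trigger seeded, jittered restarts.  Scores are
scale-normalized internally for conditioning; vertices are rescaled on exit.

**Choice of λ.**  Two regimes are deliberately exposed:

- *Position estimation and bootstrap* default to λ = 0.1.  Under ambient
  measurement noise the convex hull of the data extends well beyond the true
  simplex (with ~2% of the simplex diameter of isotropic noise the hull area
  is ~20% too large), so a hard-enclosure fit inflates vertex positions by
  ~10%.  A soft penalty that leaves roughly the expected noise tail (a few
  percent of points) outside removes this bias; λ = 0.1 makes vertex
  recovery empirically unbiased at the package's standard noise level.
- *The t-ratio test* defaults to λ = 5.0.  The hull/simplex volume ratio is
  only interpretable on (0, 1] when the simplex (nearly) encloses the
  scores; the permutation test remains exact for any fixed λ because
  observed and null datasets are fit identically.

Both are configuration parameters.

## The synthetic-data generator

The generator emulates the post-ICA stage of a resting-state study: k
archetypes in D ≈ 19 dimensions, n subjects as Dirichlet-weighted convex
combinations of the archetypes plus isotropic Gaussian noise applied in the
ambient space after mixing.  Defaults are k = 3, D = 19, n = 900, symmetric
Dirichlet concentration α = 1 (uniform over the simplex), and noise standard
deviation 2% of the simplex diameter.  Confound contamination is linear
(compositions + confounds·betas, clipped at zero and re-normalized), leaving
a recoverable linear signal.  Planted continuous features follow
±effect·(1 − normalized distance to a chosen archetype) + Gaussian noise;
planted Boolean features are Bernoulli with a logistic link in the same
distance.  In planted-recovery checks "strong effect" means an
effect-to-noise ratio of about 6 (effect 2.0, feature noise 0.3), the regime
where the bin-median profile is reliably monotone near the archetype.
Clinical subgroups use an asymmetric Dirichlet whose target-archetype
expected weight is moved from 1/k toward 1 by a shift fraction (0.5 in the
standard condition), preserving simplex support.

What the generator does **not** emulate: BOLD time series, ICA mixing and
back-reconstruction, head motion, site effects, non-Dirichlet weight laws,
or heavy-tailed measurement noise.  Passing recovery tests therefore shows
the estimator chain is correct and calibrated under the stated generative
model, not that real adjusted variance proportions follow it — in particular
the Dirichlet+noise family is an assumption, and the empirical distribution
of real adjusted proportions is unknown.

## Surrogate maps

Map-to-map correlation nulls must preserve spatial autocorrelation.  The
surrogate generator permutes the source map's values, smooths the
permutation with Gaussian distance kernels over a bandwidth grid (2%–35% of
the maximal pairwise distance), selects the bandwidth whose empirical
semivariogram best matches the source variogram under an affine
(scale + nugget) least-squares fit, and rank-remaps the winner onto the
sorted source values.  Every surrogate therefore has exactly the source's
value multiset and approximately its variogram (median relative deviation
under 15% on smooth lattice maps).  Surrogates are built from the archetype
map (not the reference map), and the reported p is two-sided — both choices
the package makes explicit because either convention is defensible.

## Numerical choices and degenerate inputs

- PCA sign convention: each loading's largest-magnitude entry is made
  positive, so runs are comparable across machines.
- Normalization is exactly idempotent: a row already summing to 1 within a
  few ulp is left bit-identical rather than re-divided.
- Binning ties are broken by stable input order; bin-size remainders go to
  the bins closest to the archetype.
- A constant feature tests as null (z = 0, p = 1 in both directions);
  all-true or all-false Boolean features likewise.
- Degenerate hulls/simplices (affinely dependent points) raise errors rather
  than returning zero volumes.
- Null re-fits that fail inside the t-ratio test are retried with a fresh
  permutation; more than 1% failures aborts.  Bootstrap resamples that
  collapse are skipped; more than 5% skips aborts.
- All randomness flows from one root seed through named SHA-256 substreams
  (stage-level reproducibility without cross-stage coupling); every output
  artifact embeds the seed and a configuration hash.

## Problem sizes in the test suite

The statistical tests run at the package's standard study scale — n = 900
(Gaussian-null calibration at n = 500 over 200 replicates with 199 shuffles
each, surrogate calibration on 6×6×6 lattices with 499 surrogates,
bootstrap coverage with 1,000 resamples over 20 replicates).  The
acceptance script reports the same quantities at the same scale with
replicate counts of 10–50.  Full-scale Monte-Carlo sizes (10,000
shuffles, bootstraps and surrogates) remain available through configuration.

## Known limitations

- The solver finds a locally minimal volume; pathological point clouds could
  require more restarts than the default three.
- The leave-one-out robustness summary counts only feasible iterations; an
  iteration whose reduced-dimension fit fails is recorded but does not veto
  robustness.
- With k = 2 the score space is one-dimensional and the "hull" is a segment
  length; k well above 5 has not been profiled.
- Surrogate quality degrades on very small maps (< ~100 voxels) where the
  variogram is noisy.
- Group comparison assumes independent subjects; no site or family structure
  is modeled.
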