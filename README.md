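# neuroparti

Pareto task inference (archetypal analysis) for resting-state network
variance compositions.

## The problem

Resting-state fMRI decomposes into a small set of networks (RSNs); for each
subject, the share of BOLD variance carried by each network is a
composition — a point on a simplex in D ≈ 19 dimensions.  If brain
organization reflects trade-offs between a few functional "tasks", these
points should be confined to a low-dimensional polytope whose vertices
(**archetypes**) are the configurations fully specialized for one task, and
a subject's behavioral profile should vary systematically with distance
from each archetype.  This package provides the full inference chain for
that hypothesis, for researchers working with per-subject network variance
tables (or any non-negative compositional trait data):

- **compositions** — proportion-of-variance normalization, confound
  residualization (age, gender, motion summaries) via OLS with
  scale-preserving residuals, median imputation of behavioral features;
- **polytope_fit** — centered PCA (no standardization), minimum-volume
  simplex identification by a SISAL-type hinge-penalized solver, the
  **t-ratio** significance test (convex-hull volume / simplex volume,
  against column-permuted nulls with full re-fitting), and bootstrap vertex
  uncertainty with optimal-assignment label alignment;
- **enrichment** — distance-binned feature enrichment per archetype
  (Mann-Whitney U with rank-biserial effect sizes r = 1 − 2U/(n₁n₂) for
  continuous features, hypergeometric tests for Boolean ones,
  Benjamini-Hochberg FDR at 0.1, closest-bin-extremum filter,
  leave-one-component-out robustness);
- **archetype_maps** — archetype brain maps as effect-size-weighted averages
  of component spatial maps, cluster-extent thresholding, and Spearman
  map comparisons against variogram-matching, autocorrelation-preserving
  surrogate nulls;
- **group_compare** — projection of held-out (e.g. clinical) samples onto
  the reference archetype space and Kruskal-Wallis + post-hoc Mann-Whitney
  comparisons of archetype distances (FDR 0.05);
- **synthetic_data** — a fully seeded generator of simplex-structured
  populations (Dirichlet mixture weights, ambient Gaussian noise, linear
  confound contamination, planted distance-graded features, shifted
  clinical subgroups, smooth lattice component maps) with complete ground
  truth, so every stage is testable without access-restricted imaging data.

## Worked example

Simulate a synthetic study (n = 400 subjects, D = 19 networks, 3 planted
archetypes), fit and test the polytope, run the enrichment, and compare a
shifted "clinical" subgroup:

```bash
neuroparti simulate --n 400 --d 19 --seed 7 --out demo
neuroparti fit demo/compositions.tsv --k 3 --n-shuffles 199 --n-boot 200 \
    --seed 7 --out demo/solution.json
neuroparti enrich demo/compositions.tsv demo/features.tsv demo/solution.json \
    --out demo/enrichment.tsv
neuroparti compare demo/solution.json demo/compositions.tsv \
    demo/clinical_compositions.tsv --labels reference,clinical \
    --out demo/groups.tsv
```

which prints:

```
synthetic study written to demo
t-ratio 0.9446, p = 0.005 -> demo/solution.json
10 significant rows -> demo/enrichment.tsv
 archetype          H  df            p
         0 108.311217   1 2.297208e-25
         1 124.844962   1 5.503057e-29
         2 102.803152   1 3.701601e-24
```

Reading the output: the fitted 3-vertex simplex fills 94% of the data's
convex hull (t-ratio 0.9446 — simplex-like data have t near 1) and none of
199 column-shuffled null datasets reached that value (p = 0.005, the
smallest value the permutation estimator can report).  Ten
feature × archetype × direction results pass FDR 0.1 with the
closest-bin-extremum filter, recovering the planted effects.  The
Kruskal-Wallis table shows the clinical subgroup's distances to all three
archetypes differ strongly from the reference population; the post-hoc
table in `demo/groups.tsv` shows it is significantly *closer* to the
archetype toward which it was shifted.  The same pipeline runs end-to-end
from a YAML config with `neuroparti run` (see `docs/example_config.yaml`),
and `docs/methods.md` documents the model, solver, and all numerical
choices.

With real data, replace the simulated tables: a subject × component TSV of
variance proportions, a subject × confound TSV, a subject × feature TSV
(missing entries empty or `NA`), and optionally NIfTI component maps.

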