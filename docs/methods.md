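# Methods

`hemisnet` implements an individual-level analysis of left–right
asymmetry in cortical structural covariance networks, together with a
synthetic-cohort generator that makes every stage of the analysis
testable end to end.

## The networks

Each subject contributes two networks, one per hemisphere, whose 34
nodes are the Desikan–Killiany cortical regions. Regional mean
thickness values (mm) are first standardized against a *control
reference*: within each dataset, the mean and sample SD (ddof = 1) of
each region over that dataset's control subjects. Standardizing within
dataset absorbs scanner and protocol differences; standardizing against
controls keeps case pathology out of the norm. The edge weight between
regions *i* and *j* of one subject is a similarity of their
standardized values,

    w_ij = exp(−(z_i − z_j)² / 2),

a Gaussian kernel on the z-difference, as used in the intra-individual
covariance literature. The weighted network is binarized by rank: at
sparsity *S*, the `floor(S × 561)` strongest of the 561 node pairs are
kept (224 at the default S = 0.4), so every subject and hemisphere has
exactly the same edge count and topological metrics are comparable
across subjects. Ties are broken deterministically (stable sort by
weight, then lexicographic pair order); for continuous data they have
measure zero.

Because binarization only consults the *ranks* of the weights, the
binary topology — and with it every topological result downstream — is
invariant to replacing the kernel with any strictly decreasing function
of |z_i − z_j|. This is asserted bit-exactly in the test suite. Only the
unthresholded edge-level analysis depends on the kernel's functional
form, and there only the raw magnitudes: signs, ranks and the
calibration of its inference are kernel-robust.

## Topological metrics

Node level (binary, undirected): degree centrality (row sum);
clustering coefficient (2·triangles / k(k−1), 0 when k < 2); nodal
global efficiency (mean inverse shortest-path length to all other
nodes, unreachable pairs contributing 0); nodal local efficiency
(global efficiency of the subgraph induced by the node's neighbours, 0
when k < 2). Hemisphere level: mean clustering C̄ and characteristic
path length L (mean over reachable ordered pairs), normalized by the
means of degree-preserving null networks: γ = C̄/C̄_rand, λ = L/L_rand,
σ = γ/λ. Null networks use Maslov–Sneppen double edge swaps with a
budget of 10 × (edge count) successful swaps, 100 nulls by default
(both configurable); graphs admitting no legal swap (e.g. complete
graphs) are returned unchanged with a flag. Distances are unweighted
shortest paths (BFS/Dijkstra via `scipy.sparse.csgraph`). All metrics
are checked against naive Floyd–Warshall / triangle-enumeration
implementations on a seeded family of small graphs.

Disconnected networks are flagged rather than rejected: L averages over
reachable pairs and efficiencies treat unreachable pairs as zero. At
S = 0.4 (mean degree ≈ 13 of 33 possible) disconnection is rare.

The per-subject null-model seeds are shared between hemispheres, so
relabeling L↔R swaps γ, λ, σ exactly — the asymmetry statistics are
exactly antisymmetric under hemisphere relabeling, which the tests
assert for every reported quantity.

## Asymmetry and inference

For every metric the subject-level asymmetry is the hemispheric
difference HD = Left − Right (positive = leftward). The asymmetry index
(L−R)/(L+R) is deliberately not used: several metrics can be zero in
one hemisphere. Case–control differences are tested with a
random-intercept linear mixed model,

    HD ~ diagnosis + age + sex + (1 | dataset),

estimated by REML. The implementation profiles the REML criterion down
to a one-dimensional search over the variance ratio τ²/σ² using only
per-dataset sums (Woodbury identity for the block-of-ones random-effect
covariance). This makes a fit cheap enough to repeat for every
permutation, and a batched path refits thousands of permuted diagnosis
columns simultaneously (coarse λ grid, then a vectorized golden-section
refinement). The solver is cross-checked against statsmodels `MixedLM`
in the test suite.

The diagnosis t is converted to Cohen's d with the two-group conversion
d = t(n₁+n₂)/(√(n₁n₂)·√df), df being the residual degrees of freedom of
the fixed-effects design. Empirical two-tailed p-values come from
label-swap permutations (10,000 by default) with add-one smoothing,
p = (1 + #{|t_perm| ≥ |t_obs|}) / (1 + n_perm); the observed t is
computed by the same batched estimator as the permuted ones. Labels are
swapped *within* dataset by default, preserving each dataset's
case/control counts — the exchangeability that the random-intercept
model implies; global swapping is available behind a flag.

Multiplicity is corrected per analysis tier: Bonferroni over the 3
hemisphere-level metrics (significance at p < 0.05/3);
Benjamini–Hochberg over the 34 nodes of each node-level metric with
threshold 0.05/4 (four node metrics are tested); BH at 0.05 over the 33
edges of each seed region; no correction for the post hoc unilateral
(left-only / right-only) and within-case clinical follow-ups, which are
descriptive.

Within-case models relate the significant HDs to clinical variables
among cases only (HD ~ variable + age + sex + (1 | dataset), the
variable's own term dropped when it is age or sex); variables with
fewer than 20 non-missing cases are skipped with a logged reason.

## Sensitivity analyses

The sparsity sweep re-thresholds each subject's cached weighted
networks at S = 0.25 … 0.50 in steps of 0.01 (26 thresholds; edge sets
are nested along the sweep because thresholding is by rank), integrates
each metric over the range by the trapezoidal rule, and reruns the
case–control models on the HD of the AUC. HD is linear in the two
hemispheres, so HD-of-AUC equals AUC-of-HD; the equivalence is
unit-tested. Model variants rerun the main models with a quadratic
centred-age term, or with the subject's mean thickness over all 68
regions as an extra fixed effect.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

- regional baselines μ_r drawn once per cohort, uniform on 1.8–3.2 mm,
  shared by hemispheres and datasets (homotopic regions are
  exchangeable unless an effect is injected);
- per-dataset scanner offsets (SD 0.10 mm) and heterogeneous dataset
  sizes;
- bilateral age (−0.01 mm/year around a reference age of 15 years,
  roughly the mean age of multi-site ASD cohorts) and sex (0.03 mm)
  effects — bilateral, hence irrelevant to asymmetry;
- a shared within-subject factor (SD 0.12 mm) that makes any two
  regions positively correlated across subjects, the premise of
  structural covariance;
- regional noise (SD 0.15 mm).

Group differences are injected as a convex coupling of chosen
(region, hemisphere, group) cells toward the subject's hemispheric mean
*profile*: with deviation d_r = t_r − μ_r, the coupled value is
μ_r + (1−α)·d_r + α·mean_s(d_s). The pull acts on deviations from the
regional baselines, not on raw thickness — baselines differ by up to
~1 mm, and pulling raw values toward the raw hemisphere mean would
mostly relocate the region (lowering its similarity to everything)
rather than couple it. Coupling a region shrinks its standardized
distance |z_i − z_j| to every other region, which raises the similarity
rank of its edges and hence its degree once networks are thresholded —
so an injected effect must survive the entire pipeline
(standardization → similarity → sparsity → metrics) to be detected,
which is the point: recovery tests are end-to-end. Coupling the right
hemisphere in cases produces a *negative* shift of the region's
degree-centrality HD (reduced leftward asymmetry), and the injected
effect grows monotonically with α.

What the generator does *not* emulate: spatially structured covariance
(one global factor instead of networks of correlated factors),
non-Gaussian thickness distributions, age × diagnosis interactions,
site differences in age/sex composition, and segmentation artifacts.
Passing recovery and calibration tests therefore show that the pipeline
detects coupling-type effects embedded in realistic nuisance structure —
not that real ASD effects have this form or size.

## Numerical choices

- Edge count at threshold: `floor(S × 561)`, reproducing 224 at S = 0.4.
- REML λ search: grid {0} ∪ 41 log-spaced points on [10⁻⁶, 10⁴], then
  40 golden-section iterations; residual df = n − p.
- Degenerate fits: constant outcomes and singular designs raise; in the
  permutation batch, isolated failed fits are tolerated up to 1% and
  excluded, beyond that the test errors.
- The add-one permutation estimator never returns p = 0; its minimum is
  1/(n_perm + 1). Node-tier BH significance at threshold 0.05/4 over 34
  nodes therefore needs n_perm ≥ 2721 for the smallest attainable
  adjusted p to clear the threshold; analyses meant to feed the node
  tier should use at least ~3000 permutations.
- Problem sizes in the tests and the acceptance script are desk-scale
  by design: 5 synthetic datasets rather than 43, 60–400 subjects,
  500–3000 permutations, and degree-centrality-only panels where the
  slower shortest-path metrics are not under test.

## Known limitations

- **Reference-estimation noise and permutation calibration.** The
  label-swap permutation refits the *model* under each permuted
  labeling but keeps the networks — and hence the control reference —
  fixed, mirroring standard practice. The test is therefore exact for
  any outcome that is exchangeable within datasets (verified by
  simulation), but only approximately exact end to end, because the
  control reference is estimated from the very controls whose labels
  are being swapped. With tiny control samples this is measurable: at 6
  controls per dataset the empirical type-I rate of the degree-HD test
  is ~0.10–0.13 at nominal 0.05, decaying roughly as 1/n_controls
  (nominal by ~24 controls per dataset, and nominal at any size when
  the reference comes from an external control sample). Cohorts in
  which some datasets contribute fewer than ~15–20 controls should
  interpret borderline node-tier p-values cautiously.

- Inter-hemispheric edges are out of scope: each network is purely
  intra-hemispheric, so the analysis cannot see altered callosal-type
  connectivity.

- Weighted-graph metric variants, betweenness, modularity and rich-club
  statistics are deliberately not implemented.

- The hemisphere-level γ/λ/σ depend on the null-model sample (100
  rewired graphs by default); their Monte-Carlo error is not propagated
  into the mixed models, matching common practice.
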