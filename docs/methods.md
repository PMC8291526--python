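# Methods

## Distance layer

**Genetic distances.** Populations are summarised by haplogroup (or
paragroup) frequency compositions; the distance between two populations
is the Euclidean distance between their frequency vectors. Rows must sum
to 1; loaders renormalise deviations up to 1e-6 and reject anything
larger as a malformed composition.

**Linguistic distances.** Languages are binary trait vectors (lexical
cognate sets, phoneme inventory segments) with an explicit missingness
mask. The Hamming distance counts disagreements over jointly observed
traits. Two missing-data policies are provided: `pairwise_complete`
(default) drops, per pair, only the traits unobserved in either language;
`complete_case` drops every column containing any missing value. By
default the count is normalised by the number of jointly observed traits
so pairs with different missingness are comparable; the raw count is
retained as an option. A pair with no jointly observed trait is an error
rather than a silent zero.

**Geographic distances.** Great-circle distances use the haversine
formulation on a sphere of mean radius 6371.0 km — haversine rather than
the spherical law of cosines because the latter loses ~1e-4 km of
precision at small separations. Distances are log10-transformed by
default (gene flow and contact decay roughly with log distance);
off-diagonal distances below `floor_km` (default 1 km) are floored first
so co-located populations stay finite. The diagonal is kept at exactly 0
after the transform — a pure representation convention, since every
statistic downstream uses off-diagonal entries only.

## Matrix association tests

The Mantel statistic is the Pearson correlation of the two off-diagonal
(upper-triangle, row-major) vectors. The permutation null relabels rows
and columns of one matrix simultaneously, drawing permutations uniformly
(identity included); the p-value uses the add-one estimator
`p = (1 + #{r* ≥ r_obs}) / (1 + B)`, so p is never exactly 0 and ties
count against the hypothesis (conservative). The default alternative is
one-sided (`greater`), since the substantive hypotheses here concern
positive association; a two-sided option is available.

Three procedures control for a third matrix:

* **partial Mantel** — the first-order partial correlation of the three
  condensed vectors; the null permutes the *first* matrix and recomputes
  the partial statistic each round. Which matrix to permute is a
  convention (the procedure is symmetric under swapping the two focal
  matrices); it is stated here and fixed.
* **partial Pearson** — same statistic, parametric p from
  `t = r sqrt((m−3)/(1−r²))` with `m = n(n−1)/2`. Distance pairs sharing
  a population are not independent, so this p is anti-conservative; the
  result object carries that caveat and is flagged `parametric`.
* **residual Mantel** (Smouse–Long–Sokal) — ordinary least-squares
  residuals (with intercept) of each focal matrix's condensed vector on
  the control's, reassembled into symmetric zero-diagonal matrices, then
  plain-Mantel-tested. Its observed statistic equals the partial
  correlation exactly (residual-correlation identity); only the
  permutation scheme differs.

All randomised operations accept an integer seed or a numpy Generator,
and every result records the seed, permutation count and method.

## Ordination and Procrustes

PCA centres columns (no scaling — frequency columns share units, and
binary traits are left in their natural 0/1 scale) and projects onto the
top right-singular directions, with a deterministic sign convention
(largest-magnitude loading positive). The Procrustes comparison centres
both 2-D configurations, scales each to unit total sum of squares, and
minimises the residual sum of squares over rotation, reflection and
isotropic scale; `D` is the minimum and `t₀ = sqrt(1 − D)` the similarity
score. Reflections are deliberately permitted because PC orientation is
sign-arbitrary. The geographic configuration is (longitude, latitude) in
degrees treated as planar; no map projection is applied, and because
reflections are allowed the axis order is immaterial. The permutation
test permutes the row order of the geographic configuration; for 2-D
configurations the permuted score has the closed form
`t₀ = sqrt(‖A‖_F² + 2|det A|)` with `A` the 2×2 cross-product matrix,
which makes 100 000 permutations a vectorised pass.

## Jackknife schemes

Scheme I keeps all populations of a focal group (size g) and adds a
uniform random g-subset of the complement (subset size 2g); scheme II
draws a uniform random subset of a requested size from the whole panel.
Per replicate, all five matrices are restricted to the subset and the
four gene–language partial Mantel tests are re-run. Summaries per test:
median/min/max and the 2.5–97.5 percentile interval of r (a percentile
interval is used because no distributional form is assumed), p-value
quartiles, and the counts of p < 0.05 and p < 0.01. Replicate seeds
derive from the master seed through a spawn-key counter, so any single
replicate is reproducible in isolation. The long-format audit table is
emitted alongside and the summaries recompute from it exactly.

## Synthetic data generator

The generator emulates the *statistical signature* of sex-biased
gene–language coevolution, not its demography. For an n-population panel
with great-circle distance matrix `D_geo` (km):

* **Coordinates** — two groups (defaults 11 + 23, mimicking an
  Indo-Iranian-like focal group and a European-like complement) drawn
  uniformly from per-group bounding boxes that partially overlap.
* **Haplogroup compositions** — per haplogroup k an independent latent
  field `z_k ~ MVN(0, exp(−D_geo/λ) + σ²_w I)` plus a per-haplogroup
  baseline (s.d. 1) and a per-group offset (s.d. 0.12 paternal, 0.08
  maternal — the paternal side is differentiated slightly more, as with
  sex-biased migration); frequencies are the row-wise softmax over
  haplogroups (softmax-of-fields rather than a Dirichlet because it
  preserves the spatial autocorrelation in the frequencies).
* **Binary traits** — an effective distance
  `D* = w_geo D̃_geo + w_pat D̃_pat + w_mat D̃_mat`, with each driver
  rescaled to unit mean off-diagonal so the weights are comparable, and
  `D̃_pat`, `D̃_mat` the *realised* Euclidean distances of the generated
  frequency tables. Traits are latent-Gaussian-threshold draws:
  `z ~ MVN(0, exp(−D*) + nugget I)`, present where z exceeds the
  empirical quantile giving the target presence frequency (default
  0.35, a typical polymorphic-trait frequency). Missingness is applied
  completely at random (default 5% in the lexical table, none in the
  phoneme table, mirroring patchy cognate coding versus essentially
  complete phoneme inventories).

Default weights plant the asymmetric structure: lexicon ← geography +
paternal (1, 1, 0), phonemes ← geography + maternal (1, 0, 1).

### Kernel parameters and calibration

Mantel-type permutation tests assume the permuted matrix's residuals are
exchangeable. Distance matrices that are smooth functions of a shared
geography violate this: a linear partial on log-distance leaves
correlated curvature, and realised smooth-field fluctuations are
spatially structured, both of which inflate the tests' type-I error —
with strong smooth fields and large group offsets the four null
gene–language partial tests rejected at 15–30% instead of 5%. The
default kernel parameters are therefore chosen so that geographic
structure is present (plain Mantel gene–language tests reject at ~3×
nominal through the confound) while the partial test stays calibrated:

| parameter | default | role |
| --- | --- | --- |
| `lengthscale_km` λ | 1200 | range of spatial autocorrelation |
| `freq_nugget` σ²_w | 6.0 | white variance in gene fields; drift noise dominates the smooth cline |
| `nugget` | 0.3 | white variance in trait fields |
| `group_offset_paternal/maternal` | 0.12 / 0.08 | between-group differentiation |
| `n_haplogroups_y/mt` | 30 / 30 | columns averaged into the genetic distances |
| `trait_presence_target` | 0.35 | per-trait presence frequency |

With these values, measured at design time over hundreds of simulated
panels: null partial-test rejection 0.04–0.06 at α = 0.05, plain-Mantel
confounded rejection 0.14–0.17, power of the two planted tests ≈ 0.86 at
n = 34 with 500 traits per system, crossed-pair false-hit rate ≈ 0.05.
These are the conditions the acceptance checks re-measure; they were
fixed once and are not tuned per run.

### What the generator does not emulate

No phylogeny (cognates do not evolve on a tree, so there is no
tree-like signal or borrowing structure), no admixture events, no
realistic haplogroup frequency spectra (softmax fields produce smoother
compositions than real drift), and missingness is MCAR whereas real
lexical missingness is not. Passing tests therefore show that the
statistical machinery behaves correctly under the planted covariance
structure — not that real panels satisfy the exchangeability and
linearity assumptions; on real data the partial Mantel p-values should
be read with the same caution the literature attaches to them.

## Numerical choices

* Distance-matrix symmetry is enforced to 1e-12 and the diagonal to 0;
  inputs are symmetrised by averaging after validation.
* Covariance factors for MVN sampling use an eigendecomposition with
  negative eigenvalues clipped at 0 (the nugget keeps the matrices
  comfortably positive definite; clipping only guards round-off).
* Permutation engines draw all relabellings up front and evaluate the
  statistics as vectorised fancy-indexing passes; permutation p-values
  with non-finite partial statistics (degenerate denominators under
  relabelling, essentially impossible with continuous data) are dropped
  from both numerator and denominator.
* OLS residuals use `numpy.linalg.lstsq`; the partial-correlation
  denominator rejects |r| ≥ 1 with an explicit error rather than
  returning infinities.
* Ties in permutation counts use `≥` with a 1e-12 tolerance in the
  Procrustes test only, where the observed statistic comes from an SVD
  and the permuted ones from the closed form.

## Problem sizes

The test suite runs the statistical checks at the scales the analyses
are designed for: 500 null panels for calibration, 300 for confound
removal, 200 for planted-effect recovery (999 permutations each), 500
jackknife replicates at 999 permutations, and full enumeration (n! ≤
720) for the exact-null equivalence checks. The acceptance script uses
10 000 permutations for the headline grid and 100 000 for Procrustes,
matching the defaults recorded in the result objects.
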