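# genelang

Tools for testing **gene–language coevolution** in structured population
panels: do a population's linguistic distances track its paternal
(Y-chromosomal) or maternal (mtDNA) genetic distances once shared
geography is accounted for?

The package is aimed at population geneticists and quantitative
linguists working with panels of populations for which four data types
are available — Y-chromosomal and mtDNA haplogroup compositions, lexical
cognate-set presence/absence, and phoneme-inventory presence/absence —
plus coordinates. The motivating hypotheses are the *father-tongue* /
*mother-tongue* conjectures: lexicon tracking paternal lineages and
phonology tracking maternal lineages.

## What it computes

Five labelled distance matrices are built from the inputs:

* genetic: Euclidean distance between haplogroup frequency vectors,
  `d(i,j) = sqrt(Σ_k (f_ik − f_jk)²)`, separately for the paternal and
  maternal side;
* linguistic: Hamming distance between binary trait vectors, by default
  normalised by the number of jointly observed traits per pair
  (missing cells are ignored pairwise);
* geographic: great-circle distance on a sphere (R = 6371 km), by
  default log10-transformed.

Associations between matrices are tested with:

* the **Mantel test** — Pearson correlation `r` of the off-diagonal
  vectors, permutation null from simultaneous row/column relabelling,
  `p = (1 + #{r* ≥ r}) / (1 + B)`;
* three partial procedures controlling geography `C`: the **partial
  Mantel test** on the first-order partial correlation
  `r_AB·C = (r_AB − r_AC r_BC) / sqrt((1−r_AC²)(1−r_BC²))`, the
  parametric **partial Pearson** test, and the **residual-matrix
  (Smouse–Long–Sokal) test** which Mantel-tests the residuals of `A|C`
  and `B|C`;
* **PCA + Procrustes**: the first two principal components of any table
  are superimposed on the geographic map; similarity is
  `t₀ = sqrt(1 − D)` with `D` the minimised normalised sum of squared
  deviations, tested by permuting locations;
* two **jackknife** subsampling schemes (balanced focal-group +
  equal-sized complement; unconstrained random subsets) that re-run the
  four gene–language partial tests on hundreds of subsampled panels.

A synthetic-data generator produces full five-table panels with
controllable geographic autocorrelation and separately tunable
paternal→lexicon and maternal→phoneme effects, so the entire pipeline is
testable without any external data. See `docs/methods.md` for the
generative model and design choices.

## Worked example

```python
import genelang as gl

model = gl.CoevolutionAnalysis.from_synthetic(gl.SyntheticConfig(), seed=1)
results = model.fit(n_perm=999, seed=7)
print(results.summary())
```

```
Gene-language coevolution test grid
populations: 34
==============================================================================
test                                           r           p     perms
mantel:Y~mtDNA                           -0.0392       0.627       999
mantel:Y~lexicon                          0.2738       0.001       999
mantel:Y~phoneme                          0.0387       0.214       999
mantel:mtDNA~lexicon                     -0.0409       0.805       999
mantel:mtDNA~phoneme                      0.2397       0.001       999
mantel:lexicon~phoneme                    0.2797       0.001       999
mantel:Y~geography                        0.1435       0.022       999
mantel:mtDNA~geography                    0.0027       0.473       999
mantel:lexicon~geography                  0.4681       0.001       999
mantel:phoneme~geography                  0.5345       0.001       999
partial_mantel:Y~mtDNA|geography         -0.0400       0.631       999
partial_mantel:Y~lexicon|geography        0.2363       0.001       999
partial_mantel:Y~phoneme|geography       -0.0454       0.759       999
partial_mantel:mtDNA~lexicon|geography   -0.0478       0.756       999
partial_mantel:mtDNA~phoneme|geography    0.2819       0.001       999
partial_mantel:lexicon~phoneme|geography    0.0396       0.172       999
==============================================================================
```

This synthetic panel was generated with the default planted structure —
lexicon driven by geography plus the paternal distances, phonemes by
geography plus the maternal distances. The grid recovers exactly that
asymmetry: after controlling geography, Y~lexicon (r = 0.236) and
mtDNA~phoneme (r = 0.282) remain significant at the minimum attainable
p = 1/(B+1) = 0.001, while the two crossed pairs and Y~mtDNA drop to
noise. Both linguistic systems correlate strongly with geography
(r ≈ 0.47–0.53), which is why the plain and partial grids differ.

The same analysis is available from the shell:

```sh
genelang simulate --out data/ --seed 1
genelang pipeline --config config.yaml --out results/
genelang distances --panel data/panel.tsv --freq-y data/freq_y.tsv \
    --out dist/ --nexus          # NEXUS export for SplitsTree networks
genelang jackknife --data-dir data/ --scheme 1 --replicates 500 \
    --out jk/ --seed 1
```

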