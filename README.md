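# dietrep

Replication effects in DNA-metabarcoding diet analysis.

`dietrep` analyses hierarchical presence/absence diet data — individuals,
samples (faecal pellets) per individual, and PCR replicates per sample —
and quantifies how biological and technical replication shape the usual
diet descriptors:

- **Accumulation curves**: per-individual sample-based rarefaction
  (analytic hypergeometric form) and Chao2 richness curves, averaged
  across individuals, plus the smallest number of pellets needed to
  reach a given fraction of the full-sample richness.
- **Frequency-of-occurrence (FO) error**: a Monte-Carlo procedure that
  resamples n pellets per individual (with replacement) and builds the
  empirical distribution of FO estimates at each n, with absolute or
  relative error summaries; a matching pooled-sample error comparison
  and paired t-tests of pool vs separate-pellet richness.
- **Nested PERMANOVA**: three-level decomposition (individual / pellet
  within individual / PCR within pellet) of squared-Euclidean sums of
  squares on the PCR-level 0/1 profiles, with randomized-residual
  permutation (RRPP) p-values, plus a two-group pooled-vs-separate
  composition test.
- **Regression**: maximum-likelihood beta regression of FO error rates
  on the number of pellets, FOtot, FOpel and all interactions (logit
  mean link, log-linked precision), and a logistic fit of pool
  detection against within-individual frequency.
- **Synthetic data**: a seeded hierarchical generator (consumption
  probabilities → within-individual pellet frequencies → pellet
  presence → PCR detection → pool detection) with ground truth, so the
  whole pipeline is testable without any external data.

## Data format

Long-format CSV/TSV with header columns `individual, unit, unit_kind
(pellet|pool), pcr, taxon` and either `detected` (0/1) or `reads`
(non-negative integers; a per-PCR relative-abundance filter with a 1%
default threshold can be applied before detection is derived). Column
names are remappable via a schema mapping. Ragged designs (unequal
pellets or PCRs per individual) are supported through an explicit
presence mask.

## CLI

```sh
dietrep simulate   --seed 1 --config params.yaml --out cube.csv --truth truth.json
dietrep accumulate --cube cube.csv --collapse single_random --seed 1 --reps 200 --out curve.csv
dietrep fo-error   --cube cube.csv --reps 10000 --seed 1 --error relative --out errors.csv --fo-out fo.csv
dietrep permanova  --cube cube.csv --perms 10000 --seed 1 --out anova.csv
dietrep betareg    --errors errors.csv --fo fo.csv --out fit.json
dietrep run        --config config.yaml --seed 1 --out outdir
```

`dietrep run` executes the full pipeline (simulate/ingest → collapse →
accumulation → FO errors → PERMANOVA → regressions) and writes
`curve.csv`, `fo.csv`, `errors.csv`, `anova.csv`, `fit.json` and
`report.md` into the output directory. All stages are seeded from one
base seed; identical configs give byte-identical outputs.

## Library use

```python
import dietrep as dr

cube, pools, truth = dr.generate_dataset(dr.SynthParams(seed=1))
mode = dr.CollapseMode("single_random", seed=2)
mats = dr.collapse_pcrs(cube, mode)

curve = dr.mean_curve(mats, reps=200, seed=3)
fo = dr.fo_table(mats, dr.collapse_pool(pools, mode))
errors = dr.error_curve(mats, reps=10_000, seed=4)

from dietrep.permanova import cube_to_units
Y, ind, pel, pcr = cube_to_units(cube)
anova = dr.rrpp_test(Y, (ind, pel, pcr), B=999, seed=5)

X, y = dr.beta_design(errors, fo)
fit = dr.fit_betareg(X, y)
```
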