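# regulaburden

Function-informed directional rare-variant collapsing analysis for
regulatory regions, built around an extreme-phenotype sequencing design.

A classical collapsing (CAST-style) burden test compares the number of
distinct rare-variant carriers between two phenotypic-extreme cohorts.
This package adds the function-informed refinements: variants are first
classified by a dual-luciferase reporter assay into expression-decreasing,
neutral, or expression-increasing, then collapsed separately by direction,
optionally restricted to variants whose carriers occur in only one cohort
(the exclusivity filter).  Supporting stages — reporter-plate
normalization and direction calling, EM-based pairwise LD estimation from
unphased genotypes, quantitative-trait residualization and additive
regression, and a synthetic-study generator for power/type-I studies —
make every stage testable offline.

## Layout

| module                  | purpose                                                        |
|-------------------------|----------------------------------------------------------------|
| `regulaburden.catalog`  | variant catalog/cohort model, TSV I/O, MAF classes, carriers   |
| `regulaburden.assay`    | firefly/Renilla normalization, t-test direction calls          |
| `regulaburden.burden`   | exact Fisher 2×2 test; undirected/directional/exclusive collapsing; weighted-sum and C-alpha comparators |
| `regulaburden.ld`       | two-locus EM haplotype frequencies; D, D′, r²                  |
| `regulaburden.assoc`    | stratified residualization; additive genotype regression       |
| `regulaburden.synth`    | synthetic cohorts, assay plates, LD pairs; power engine        |
| `regulaburden.pipeline` | orchestration, fixture digests, bundled reproduction           |
| `regulaburden.data`     | bundled variant/carrier/call fixtures (TSV + checksums)        |

## CLI

```sh
regulaburden reproduce --out report/          # bundled-fixture burden analysis
regulaburden burden --variants variants.tsv --carriers carriers.tsv \
    --cohorts cohorts.tsv --calls functional_calls.tsv \
    --direction decrease --exclusive --sided 2
regulaburden assay --wells assay.tsv --out functional_calls.tsv
regulaburden ld --genotypes genotypes.tsv --pair locusA,locusB
regulaburden assoc --phenotypes phenotypes.tsv --genotypes genotypes.tsv \
    --variant rs123 --trait el --transform log
regulaburden simulate --config sim.yaml --out simdir/
regulaburden power --tests cast,directional --n-sims 200 --seed 1
```

`regulaburden reproduce` prints the five collapsing results from the
bundled catalog: the undirected test, both directional tests, and both
exclusivity-filtered directional tests, with de-duplicated carrier counts
and exact two-sided p-values.

## File formats

All inputs are plain TSV: `variants.tsv` (variant_id, position, ref, alt,
cohort, n_het, n_hom_minor — one row per variant×cohort), `carriers.tsv`
(individual_id, cohort, variant_id), `cohorts.tsv`, `assay.tsv`
(plate_id, construct, firefly, renilla), `genotypes.tsv` (individual_id,
variant_id, genotype∈{0,1,2}), `phenotypes.tsv`.  Positions are signed
TSS-relative base pairs (negative upstream, no position 0).
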