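# outwelling

Estuaries export organic matter to the coastal ocean (the "outwelling"
hypothesis). Whether that export actually subsidises coastal food webs — and
restructures the benthic communities that receive it — is a quantitative
question this package answers from two kinds of data: dual stable-isotope
measurements (δ¹³C, δ¹⁵N) of primary-producer endmembers and consumer
tissues along an estuary-to-coast gradient, and site × taxon count matrices
with environmental covariates from the same gradient.

It is written for benthic and food-web ecologists who have endmember and
consumer isotope tables, replicate-core community data, and a gradient
design, and want the full analysis chain as tested, scriptable Python.

## What it computes

**Feasible-solution mixing model** (`outwelling.mixing`). A consumer is a
mixture of k sources: δ_j = Σᵢ pᵢ·δ_j(sourceᵢ) with Σpᵢ = 1. With five
sources and two isotopes there is no unique solution, so the model
enumerates every proportion vector on the simplex at a fixed increment
(4,598,126 vectors for k = 5 at 1%) and keeps those reproducing the
consumer signature within a mass-balance tolerance on each axis, reporting
per-source percentile ranges and flagging indeterminable sites. Sources are
first corrected for one trophic level of fractionation (TEF: +0.4 ‰ δ¹³C,
+2.3 ‰ δ¹⁵N) and optionally pooled or degradation-averaged
(`outwelling.isotopes`).

**Community structure** (`outwelling.community`). Bias-corrected Chao2
richness S_obs + ((m−1)/m)·Q1(Q1−1)/(2(Q2+1)) with incidence-based standard
errors and seeded sample-based accumulation curves; Bray–Curtis
dissimilarity; abundance-weighted biological-traits expansion over a
32-trait fuzzy-coded table.

**Distance-based linear models** (`outwelling.inference`). Gower-centred
dbRDA of Bray–Curtis matrices on environmental covariates: pseudo-F with
exact or Monte-Carlo permutation p-values, adjusted R², distance-based AIC,
backwards model selection, principal-coordinate ordination, plus one-way
ANOVA, Tukey HSD and linear/exponential-decay gradient regressions.

**Synthetic scenarios** (`outwelling.simulate`). A seeded generator for the
whole study design (2 locations × 9-site gradients, 15 cores/site, five
endmembers per estuary, decaying true mixing proportions, gradient-
structured communities) with ground-truth sidecars, used by the test suite
and usable for power analysis.

## Worked example

```python
from outwelling.isotopes import (IsotopeSignature, SourceEndmember, SourceSet,
                                 DEFAULT_TEF, correct_sources)
from outwelling.mixing import MixingConfig, feasible_solutions

sources = SourceSet("Tairua", (
    SourceEndmember("estuary-SPOM", IsotopeSignature(-22.4, 7.7), (0.3, 0.3), 5),
    SourceEndmember("marine-SPOM", IsotopeSignature(-19.6, 4.3), (0.3, 0.3), 5),
    SourceEndmember("seagrass-detritus", IsotopeSignature(-10.0, 7.0), (0.3, 0.3), 5),
    SourceEndmember("microphytobenthos", IsotopeSignature(-13.0, 5.8), (0.3, 0.3), 5),
    SourceEndmember("fringing-vegetation", IsotopeSignature(-27.0, 4.0), (0.3, 0.3), 5),
))
corrected = correct_sources(sources, DEFAULT_TEF)       # shift by one trophic level
consumer = IsotopeSignature(-19.9, 8.9)                 # site-1 bivalve foot muscle
result = feasible_solutions(consumer, corrected, MixingConfig())
print(f"{result.n_solutions} feasible solutions at tolerance {result.tolerance_used} per mil")
print(result.summary.round(2))
```

prints

```
5187 feasible solutions at tolerance 0.1 per mil
                      p05   p25   p50   p75   p95   min   max
source
estuary-SPOM         0.50  0.53  0.56  0.58  0.61  0.46  0.63
marine-SPOM          0.01  0.05  0.11  0.18  0.26  0.00  0.33
seagrass-detritus    0.01  0.05  0.10  0.15  0.21  0.00  0.27
microphytobenthos    0.01  0.05  0.10  0.17  0.24  0.00  0.31
fringing-vegetation  0.01  0.06  0.11  0.16  0.21  0.00  0.27
```

Read this as: of the ~4.6 million candidate diets, 5,187 reproduce this
consumer's signature within 0.1 ‰ on both isotopes. Estuarine SPOM must
contribute 46–63% of the diet (median 56%) — a tightly constrained, dominant
estuarine subsidy — while the remaining four sources are individually
unresolved (each 0–~30%), which is the honest answer an underdetermined
dual-isotope system can give.

The same analysis runs from the shell:

```sh
outwelling synth --seed 1 --out data/                 # synthetic study bundle
outwelling mix --sources data/sources.csv --consumers data/consumers.csv \
    --estuary Tairua --out feasible.csv
outwelling run --seed 1 --out results/                # full pipeline + manifest
```

`run` writes `feasible.csv` (per-site contribution percentiles),
`richness.csv` / `accumulation.csv` (Chao2), `trait_abundance.csv`,
`dblm.csv` / `ordination.csv` (model selection and axes) and a
`manifest.json` that makes the run bit-reproducible.

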