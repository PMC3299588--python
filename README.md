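# gsrelate

**How much of genomic prediction accuracy comes from relatives?**

`gsrelate` is a simulation and evaluation toolkit for livestock genomic
selection.  It quantifies how the relationship between selection
candidates ("test" animals) and the phenotyped, genotyped reference
population drives the accuracy of estimated breeding values, comparing:

* **gBLUP** — BLUP with a VanRaden genomic relationship matrix (GRM),
* **BLUP-D** — pedigree BLUP with a deep (ten-generation) numerator
  relationship matrix,
* **BLUP-S** — pedigree BLUP with a shallow (single-generation) pedigree.

It is aimed at quantitative geneticists and breeding-program designers who
want a tested, reproducible pipeline for reference-population design
questions: when do unrelated animals still obtain useful genomic breeding
values, and what baseline accuracy does population LD alone support?

## The model

Phenotypes follow the single-trait animal model

    y = 1 μ + Z g + e,   var(g) = K σg²,   var(e) = I σe²,

where K is either the GRM, `G = WW′ / (2 Σ pᵢ(1−pᵢ))` with `W = M − 2P`,
or the pedigree NRM **A**.  Variance components are estimated by REML
(exact restricted likelihood, spectral profiling) and the mixed-model
equations are solved densely, so each animal's prediction error variance
`PEV_i = σe² C_ii` is exact.  Accuracy is measured two ways:

* empirically, `r_cor = cor(EBV, TBV)` in the test set;
* per animal, `r_PEV = sqrt(1 − σe² C_ii / (σa² K_ii))`.

Deterministic expectations for an unphenotyped candidate are also
implemented: the Goddard formula (via the effective number of chromosome
segments `Me = 2 Ne L`) and the Daetwyler formula
`r = sqrt(N h² / (N h² + Me))`.

The synthetic data generator reproduces a classical sheep-scale design:
coalescent base haplotypes (30 × 100 cM, Ne = 100, μ = 2.5e-8), 60k
random markers + 10k gamma-distributed QTL, ten discrete generations of
80 sires × 25 dams × 2 offspring, h² = 0.3, and three reference/test
scenarios (close = 20 half sibs in the reference; distant = no shared
parents; unrelated = generation-1 females vs generation-10 candidates).

## Worked example

```python
from gsrelate import ExperimentConfig, run_replicate, goddard_accuracy

# deterministic expectation for an unrelated candidate
p = goddard_accuracy(n_reference=1750, ne=100, h2=0.3,
                     genome_length_morgans=30)
print(f"k={p.k:.3f} lambda={p.lambda_:.1f} a={p.a:.2f} r={p.r:.2f}")

# one simulated replicate, genomic vs deep-pedigree prediction
cfg = ExperimentConfig.preset("paper")
rep = run_replicate(cfg, replicate_seed=7,
                    jobs=[("close", "gBLUP"), ("close", "BLUP-D"),
                          ("unrelated", "gBLUP"), ("unrelated", "BLUP-D")])
for (design, method), fit in sorted(rep.fits.items()):
    print(f"{design:9s} {method:6s} r_cor={fit.r_cor:.3f} "
          f"mean r_PEV={fit.mean_r_pev:.3f}")
```

Output:

```
k=0.189 lambda=3774.8 a=5.31 r=0.36
close     BLUP-D r_cor=0.394 mean r_PEV=0.455
close     gBLUP  r_cor=0.555 mean r_PEV=0.563
unrelated BLUP-D r_cor=0.043 mean r_PEV=0.044
unrelated gBLUP  r_cor=0.547 mean r_PEV=0.394
```

The deterministic line says a 1,750-animal reference at Ne = 100 supports
a baseline accuracy of 0.36 for a candidate with no phenotype and no close
relatives; the simulated replicate shows gBLUP achieving accuracy of that
order even for unrelated candidates, while deep-pedigree BLUP collapses to
near zero without pedigree links (single replicates scatter around the
replicated means).

A command-line interface wraps the same functionality:

```bash
gsrelate predict-accuracy -N 1750 --ne 100 --h2 0.3 -L 30
gsrelate reproduce-table1 --preset desk --seed 1 --out results/
gsrelate simulate --preset desk --seed 1 --out simdata/
gsrelate fit --phenotypes phen.csv --pedigree ped.txt --out ebv.csv
```

`reproduce-table1` writes `accuracy_table.csv` (mean ± SE per design ×
method), `per_animal.csv` (per-test-animal reliability and relationship
summaries) and a JSON run manifest.

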