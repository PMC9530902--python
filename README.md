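# mutgrowth

Quantitative linkage of bacterial **mutation rate** and **growth rate**
across genetic and nutritional variation, as a tested end-to-end pipeline.

*Escherichia coli* strains that are genome-reduced, mismatch-repair (MMR)
deficient ("mutators"), or both, grown in media of decreasing richness
(LB, MAA = minimal + 20 amino acids, M63 = minimal), trade mutability
against fitness along a common per-medium law:

```
log10(M_i) = log10(M_inf) + alpha * mu_i
```

where `M_i` is a strain's mutation rate (bp⁻¹ division⁻¹) and `mu_i` its
growth rate (h⁻¹) in a given medium. `M_inf` — the maximal mutation rate as
growth approaches zero — and the slope `alpha < 0` are **medium** properties,
not genotype properties: fitted values are alpha = −9.5, −12.6, −12.8 and
M_inf = 1e-3, 4e-4, 7e-6 bp⁻¹ division⁻¹ for LB, MAA, M63.

The package implements every stage needed to measure and model that law:

| module | what it does |
| --- | --- |
| `mutgrowth.synthetic` | seeded generators: strain panels (MDS / KHK / MG collections), ground-truth rates on the trade-off law, Luria–Delbrück fluctuation assays by stochastic clone-size simulation, Poisson CFU plates, logistic OD curves |
| `mutgrowth.fluctuation` | exact Lea–Coulson pmf via the Ma–Sandri–Sarkar recursion, MSS maximum-likelihood and P0 estimators of the expected mutations per culture `m`, profile-likelihood CIs, CFU sizing with the 10–500-colony reliability filter, conversion to bp⁻¹ division⁻¹ |
| `mutgrowth.growth` | plate-reader OD595 series → growth rates by windowed log-linear fitting with quality gates and zero-density extrapolation |
| `mutgrowth.tradeoff` | per-medium trade-off fits (alpha, M_inf), Pearson statistics, paired media-shift tests, cross-media correlations, fold changes vs parent strains, mutations-per-genome arithmetic |
| `mutgrowth.models` | multiple linear regression of either rate on (other rate, medium code 1/0/−1, genotype coded interactively `gr·md` or additively `gr+md`); linear / RBF SVM classification of medium and genotype from (mu, log10 M) under a repeated stratified 60/40 protocol with nested 5-fold hyperparameter search |
| `mutgrowth.pipeline` + `mutgrowth` CLI | one-command orchestration: simulate → estimate → fit → predict → report |

## Worked example

```sh
mutgrowth run --seed 7 --outdir out/
```

simulates the default panel (34 strains: 14 MDS, 10 KHK, 10 MG, each
collection with its parent) in all three media, runs ~300 fluctuation
assays (30 parallel cultures × 3 replicates per condition) and ~600 growth
curves through the estimators, refits the trade-off law, and prints:

```
== mutation/growth trade-off pipeline ==
strains: 34  conditions: 102

Trade-off law per medium (true -> recovered):
    LB: alpha -9.50 -> -9.69 (2.0% err), log10 M_inf -3.00 -> -2.89, r = -0.968
   MAA: alpha -12.60 -> -12.24 (2.9% err), log10 M_inf -3.40 -> -3.61, r = -0.976
   M63: alpha -12.80 -> -12.95 (1.2% err), log10 M_inf -5.15 -> -5.08, r = -0.975

Mutations per genome per division at M_inf (4 Mb genome):
    LB: 5,103.2
   MAA: 979.6
   M63: 33.1

Multiple linear regression (adjusted R^2):
  mutation ~ (interactive): adj R2 = 0.908, n = 102
    growth ~ (interactive): adj R2 = 0.981, n = 102
  mutation ~ (additive): adj R2 = 0.908, n = 102
    growth ~ (additive): adj R2 = 0.982, n = 102

SVM classification (mean test accuracy over repeats):
    medium / linear: mean 0.995 [1.00, 1.00, 1.00, 0.98, 1.00]
    medium / rbf   : mean 0.985 [1.00, 0.98, 1.00, 0.98, 0.98]
  genotype / linear: mean 0.580 [0.51, 0.56, 0.54, 0.66, 0.63]
  genotype / rbf   : mean 0.537 [0.51, 0.54, 0.54, 0.61, 0.49]
```

Reading it: the estimators recover each medium's slope within a few
percent of the generative truth with strongly negative within-medium
correlations (growth costs mutability); at zero growth the rich medium
would permit thousands of mutations per genome per division while the poor
medium permits a few dozen; either rate is predictable from the other plus
medium and genotype (adjusted R² ≈ 0.9); and the growth medium is read
almost perfectly off the (mu, log10 M) plane while the four genotype
classes overlap more (accuracy ≈ 0.5–0.6 vs a 0.25 chance floor).

Each stage is also a standalone subcommand (`simulate`,
`estimate-mutation`, `estimate-growth`, `fit-tradeoff`, `regress`,
`classify`, `report`) operating on the documented CSV schemas, so measured
data can be substituted for any synthetic stage.

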