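# heritvc

Additive and dominance heritability decomposition in simulated isolate and
outbred populations.

Estimates of the dominance (non-additive) fraction of trait variance
disagree sharply between studies of population isolates and studies of
unrelated individuals. `heritvc` is a simulation-and-estimation toolkit for
investigating why: it simulates genotypes with controlled population
structure — outbred cohorts as recombinant mosaics of a reference haplotype
panel, and isolates by dropping founder haplotypes through a deep closed
pedigree with exact identity-by-descent tracking — then simulates traits
with additive, dominance and sibling shared-environment components and
decomposes their variance with a linear mixed model.

The core model, for a trait vector *Y* with fixed effects *X*, is

> *Y* ~ MVN(*Xb*, τ_A **K** + τ_D **D** + σ²_S **S** + σ²_E **I**)

where **K** is an additive relationship matrix (2φ, twice the kinship),
**D** a dominance relationship matrix (the probability of sharing both
alleles IBD, or its genotypic analogue), and **S** a sibling indicator for
shared environment. Heritabilities follow as h²_A = τ_A/T, h²_D = τ_D/T,
H² = (τ_A + τ_D)/T with T the total variance. Fitting is by
average-information REML; **K** and **D** can be built four ways — from
genotypes (method-of-moments GRMs with the HWE-orthogonal dominance
coding), from the pedigree (tabular kinship; Jacquard's nine condensed
identity coefficients via Karigl's recursions, with φ = Δ1 + ½(Δ3+Δ5+Δ7) +
¼Δ8 and D = Δ1 + Δ7), or from the exact IBD sharing recorded during the
simulation.

## Worked example

Simulate a small isolate, build genotype-based relationship matrices, draw
a trait with h²_A = h²_D = 0.4 from mostly-rare causal variants, and fit
the two-component model:

```python
import numpy as np
from heritvc.experiments import (PanelRecipe, PopulationRecipe,
                                 build_population, make_panel,
                                 relatedness_matrices)
from heritvc.phenosim import PhenotypeSpec, simulate_phenotype
from heritvc.vc import VarianceComponentsModel

panel = make_panel(PanelRecipe(n_haplotypes=200, n_sites=6000), seed=7)
pop = build_population(
    PopulationRecipe(kind="isolate", n_genotyped=300, n_founders=300,
                     n_generations=6, pool_subset_size=120),
    panel, seed=8)
mats = relatedness_matrices(pop, "grm")
_, sibs = pop.sibship()
pheno = simulate_phenotype(pop.cohort,
                           PhenotypeSpec(M=500, scenario="A",
                                         h2A=0.4, h2D=0.4),
                           sibship_labels=sibs, seed=9)
fit = VarianceComponentsModel(pheno.Y, {"K": mats.K, "D": mats.D}).fit()
print(fit.summary())
```

prints

```
Variance components model KD (N=300, p=1)
REML log-likelihood -100.7477   converged=True in 6 iterations
component          tau        h2    se(h2)
K              0.48664    0.4260    0.0843
D              0.33305    0.2916    0.0786
residual       0.32253    0.2824
H2 = 0.7176
```

The trait was simulated with 40% additive and 40% dominance variance; this
one replicate estimates h²_A = 0.43 ± 0.08 and h²_D = 0.29 ± 0.08 — the
additive fraction is recovered tightly while the dominance fraction is
noisier, the generic pattern for this decomposition. Replicated batteries
(`heritvc.experiments.run_battery`) average hundreds of such fits;
`fit.model.likelihood_surface()` evaluates the whole (h²_A, h²_D)
likelihood surface with likelihood-ratio confidence regions, and
`heritvc.experiments.confounding_study` quantifies how a sibling
shared-environment component masquerades as dominance unless a sibship
component is included in the model.

A command-line interface mirrors the library
(`heritvc simulate-pool | simulate-pedigree | simulate-cohort | genedrop |
pedkin | grm | phenosim | fit | surface | battery | confounding`), reading
and writing PLINK bed/bim/fam, GCTA binary GRM triples and TSV tables.

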