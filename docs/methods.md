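# Methods

`heritvc` simulates genetic data with controlled population structure and
decomposes quantitative-trait variance into additive, dominance and shared
-environment components by restricted maximum likelihood. This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic data does and does not emulate.

## The variance-decomposition model

For N phenotyped individuals the trait is modelled as

    Y ~ MVN(Xb,  tau_A K + tau_D D + sigma_S^2 S + sigma_E^2 I_N)

where `K` is an additive relationship matrix (twice the kinship), `D` a
dominance relationship matrix (probability of sharing both alleles identical
by descent, or its genotypic analogue), and `S` a binary sibship indicator
used as a shared-environment covariance. Model names list the included
components (K, KD, KS, KDS). Heritability fractions are

    h2_A = tau_A / T,  h2_D = tau_D / T,  h2_S = sigma_S^2 / T,
    H2 = (tau_A + tau_D) / T,     T = tau_A + tau_D + sigma_S^2 + sigma_E^2.

Both `phi` (kinship) and `D` are expressible in Jacquard's nine condensed
identity coefficients: `phi = D1 + (D3 + D5 + D7)/2 + D8/4` and
`D_ij = D1 + D7`. Under random mating the implied phenotypic covariances
between relatives are `tau_A / 2` for parent-offspring pairs and
`tau_A / 2 + tau_D / 4 + sigma_S^2` for full siblings; both are verified by
simulation in the test suite.

### AI-REML

`VarianceComponentsModel.fit()` maximizes the restricted likelihood
`-1/2 [log|V| + log|X'V^-1 X| + y'Py]` by average-information (AI) updates.
Numerical policy:

* start at an equal split of the phenotypic variance across components;
* per iteration, try the full AI step first; if a variance component would
  leave the feasible region, pin it at the boundary and re-solve the AI
  system for the remaining parameters; then step-halving; then an EM update
  (which can never decrease the likelihood) as the final fallback;
* variances are constrained non-negative by projection with a floor of
  1e-8 of the phenotypic variance; a component finishing at the floor is
  reported as exactly 0 (`pinned`);
* convergence when the log-likelihood changes by less than 1e-6 (default),
  with at most 200 iterations; non-convergence sets `converged=False` on
  the results rather than raising;
* standard errors come from the inverse AI matrix at the optimum (delta
  method for the heritability fractions) and are approximate near the zero
  boundary.

### Likelihood surface and confidence regions

For the two-component KD model the restricted likelihood is evaluated on a
grid over the simplex `{h2_A >= 0, h2_D >= 0, h2_A + h2_D <= 1}` with the
overall variance scale and the fixed effects profiled out analytically, so
each node costs one Cholesky factorization. Confidence regions use the
likelihood-ratio rule: a node is inside the 95% region when
`2 (ll_max - ll) <= 5.991` (the chi-square quantile with 2 degrees of
freedom); the grid argmax agrees with the AI-REML optimum to within one
grid step. Simplex corners where the covariance degenerates evaluate to
`-inf` and are never part of a region.

## Genotype simulation

### Reference pool

`generate_reference_pool` draws per-site alternate-allele counts from a
truncated power law `P(c) ~ c^-alpha` on `1 <= c <= H-1` (H haplotypes; no
monomorphic sites). The exponent defaults to a per-pool-size calibration
targeting 55% of sites below 1% minor allele frequency — the headline
property of a sequencing imputation panel — because a fixed exponent cannot
reproduce that fraction at more than one pool size (at H=200 only
singletons are below 1%; at H=7,500 the first ~75 count classes are).
Linkage disequilibrium is induced by tiling each pool haplotype with a
mosaic of 60 seed-ancestry labels with ~0.5 cM blocks (Poisson switches at
2.0 per cM) and placing each variant's carriers preferentially on
haplotypes sharing the local ancestry; LD therefore decays on the ~0.5 cM
scale, roughly where panel LD does.

### Mosaic copying and gene-dropping

New haplotypes are recombinant mosaics of the pool: a uniform initial
source, switch points as a Poisson process on the genetic map (default
intensity 0.04 per cM, i.e. ~25 cM segments) and a uniform redraw of the
source at each switch; alleles are copied without error and every segment's
source is recorded. Outbred cohorts take two independent mosaics per
individual per chromosome from the full pool. Isolates restrict the
copyable pool to a random subset of 200 haplotypes per chromosome for the
founder gametes, then drop them through the pedigree: each meiosis
transmits a recombinant with crossovers as a Poisson process of 1 per
100 cM (no interference), and origin labels compose transitively down to
founder gametes. Those labels give exact pairwise IBD1/IBD2 genome
fractions ("true IBD" matrices `K_true = ibd2 + ibd1/2`, `D_true = ibd2`,
physical-length weighting by default).

### Isolate pedigree

`generate_isolate_pedigree` grows a closed population (no migrants after
founding): founders in generation 0, random monogamous couples avoiding
first-degree matings, children assigned multinomially with mean sibship 3,
and a generation-size trajectory that contracts to ~1/6 of the founding
size at mid-history before re-expanding. The default (1,000 founders, 8
generations, genotyped stratum = final generation) yields mean inbreeding
f ~ 0.011 and a drift-flattened cohort spectrum (~19% of polymorphic sites
below 1% MAF) — the consanguinity and founding structure of a Southern
European village isolate. A flat-size closure gives f ~ 0.004 and leaves
the cohort spectrum so rare-heavy that dominance variance placed on rare
sites cannot be expressed in a cohort of 1,000 (see Limitations).

Desk-scale genome default: 2 chromosomes of 100 Mb at a uniform 1 cM/Mb
(22 chromosomes would be more faithful but, at 20,000 sites total, dilutes
per-pair relatedness below what a ~4,500-variant GRM can resolve).

## Phenotype simulation

`simulate_phenotype` draws M causal additive and M causal dominance sites
(independent uniform draws, possibly overlapping) from sites polymorphic
in the cohort — Causal Variant Scenario A — or from sites with cohort
MAF > 0.01 (Scenario B). Codings are standardized by their theoretical
Hardy-Weinberg moments at the cohort allele frequency:
`z_A = (g - 2p)/sqrt(2p(1-p))` and `z_D = (d - 2p^2)/(2p(1-p))` with
`d(g) = {0, 2p, 4p-2}` — the unique coding orthogonal to the additive one
under HWE. Effect sizes are i.i.d. standard normal rescaled so
`sum(beta_A^2) = h2_A` and `sum(beta_D^2) = h2_D` exactly; the residual is
`sigma_E^2 = 1 - h2_A - h2_D - h2_S` i.i.d. noise plus, when `h2_S > 0`,
one shared normal deviate per sibship with variance `sigma_S^2 = h2_S`
(equivalently: residual covariance with `sigma_E^2 + sigma_S^2` on the
diagonal and `sigma_S^2` on sibling off-diagonals). Total phenotypic
variance is 1 in expectation.

Standardizing by HWE moments rather than the realised column variance is a
deliberate choice: empirical restandardization makes the dominance coding
of a site with no minor-allele homozygotes exactly collinear with its
additive coding, silently relabelling dominance variance as additive.
Under HWE-moment scaling the per-site expectation `E[z_Di z_Dj] = D_ij` is
preserved; the price is that variance assigned to sites whose homozygotes
never realise simply fails to appear in the trait (it deflates `Var(Y)`
slightly instead of contaminating `h2_A`).

## Relatedness estimators

* **GRM** — method-of-moments `K` and `D` as average outer products of the
  standardized codings over QC-passing variants (sample MAF > 0.05 and
  exact Hardy-Weinberg p > 1e-5; the exact test is the standard conditional
  enumeration, no mid-p).
* **Pedigree** — `K = 2 phi` by the tabular kinship recurrence; `D` by the
  parental-kinship product `phi(fi,fj) phi(mi,mj) + phi(fi,mj) phi(mi,fj)`
  for all-pairs matrices (exact when parents are not inbred-and-cross-
  related, the standard pedigree-BLUP dominance matrix), with an exact
  Jacquard route (`method="jacquard"`, Karigl's recursions in rational
  arithmetic) for small member sets and for `jacquard_coefficients` itself.
* **True IBD** — the origin-label matrices described above.

All three are exposed through one `RelatednessSet` interface and can be
dropped into any model.

## Experiment batteries

`run_battery` wires population construction, matrix estimation, phenotype
replication and model fitting into a table of per-replicate estimates
(deterministic given the config seed; per-row failures are recorded and do
not stop the battery). `confounding_study` runs the shared-environment
grid (`h2_S in {0, 0.02, 0.05, 0.10, 0.20, 0.40}` with `h2_A = 0.4`,
`h2_D = 0.4 - h2_S`) under models KD and KDS for GRM and pedigree
matrices. MLE clouds are summarized by empirical means and standard
errors and by a minimal 95% ellipse: drop the 5% of points with the
largest Mahalanobis distance from the mean, then the minimum-area
enclosing ellipse of the survivors by Khachiyan's algorithm (tolerance
1e-7, exact containment enforced by a final rescale); collinear survivor
sets degenerate to a flagged segment. The causal-count sweep defaults to a
12-point log-uniform grid on [1, 10^6].

## Problem sizes

The acceptance script (`scripts/acceptance.py`) runs the batteries at a
desk scale chosen to finish on one CPU in well under half an hour: panels
of 600 haplotypes x 20,000 sites on 2 chromosomes; isolates of 1,000
genotyped members gene-dropped through a 1,000-founder, 8-generation
pedigree (founder pool restricted to 200 haplotypes per chromosome);
outbred cohorts of 1,000; M = 1,000 causal variants per component; 100
phenotype replicates per battery. The isolate-recovery battery spreads its
100 replicates over 5 independent gene-drop cohorts: with a 2-chromosome
genome a single cohort's realised relatedness carries noticeable sampling
wobble, and averaging over cohort draws is the faithful desk-scale
analogue of a 22-chromosome genome averaging within one cohort. The test
suite runs further-reduced versions of the same batteries.

## Limitations

* Dominance recovery is attenuated at desk scale, for two stacking
  reasons. First, ~19% of cohort-polymorphic sites never show a
  minor-allele homozygote in N = 1,000, so the dominance variance assigned
  to them cannot be expressed (the realised HWE-coding variance averages
  ~0.9 instead of 1). Second, with ~20,000 simulated sites only ~4,500
  pass the common-variant QC, and the resulting per-entry GRM sampling
  noise (~1/sqrt(m) ~ 0.015) is comparable to the dominance matrix's own
  structural spread, which shrinks the fitted dominance fraction the way
  errors-in-variables regression does. Together they put the mean
  recovered dominance fraction near 0.30 when 0.40 is simulated, while the
  additive fraction overshoots slightly (~0.42) because the unexpressed
  dominance variance deflates the total. Deeper variant panels (hundreds
  of thousands of QC-passing sites, as in a real study) remove the second
  effect and most of the first; the gap is a property of the scale, not of
  the estimator.
* The covariance model ignores inbreeding-specific dominance terms (the
  full Jacquard covariance has additional components under consanguinity);
  at f ~ 0.01 the distortion is small but real.
* The synthetic panel has power-law site frequencies and single-scale
  block LD; real panels have demography-shaped spectra, variable
  recombination and mutation/genotyping error (not modelled — copying is
  error-free).
* The pedigree generator produces random-mating closure with a smooth
  bottleneck; real genealogies have migration pulses, assortative mating
  and cohort effects.
* Shared environment is modelled only as an exchangeable sibship effect;
  household, maternal or spatial structure is out of scope, as are
  epistatic components and HMM-based IBD inference from genotypes.
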