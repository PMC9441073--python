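# Methods

This note documents the models implemented in `amaci`, the synthetic data
generator that stands in for confidential multi-country records, the
numerical choices, and the known limitations. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The evaluation models

**Pedigree model (AMACI).** Each of the c countries is one trait, twice: a
direct and a maternal genetic effect per animal and country, giving a
2c-trait animal model. Per-country fixed effects are the country mean, sex
(first observed level dropped as the reference, which resolves the rank
deficiency between a sex factor and the country mean deterministically),
and — in single-step runs — the J covariates. Random terms are a herd
(environmental) effect and a maternal permanent-environment effect per dam,
both iid within country with their national variances, and a per-country
residual. The genetic covariance is `G ⊗ A` with `G = S Φ S`; the trait
ordering is fixed everywhere as (direct for countries 1..c, then maternal
1..c), so `G` partitions as `[[G_dd, G_dm], [G_md, G_mm]]` and the Kronecker
products follow the same convention. Records whose dam is unknown keep
their direct effect; the maternal and permanent-environment terms are
omitted for that record (the count is reported on the results object).

**Single-step model.** The genetic covariance becomes `G ⊗ H` with

    H⁻¹ = A⁻¹ + [[0, 0], [0, G_w⁻¹ − A₂₂⁻¹]],
    G_w = (1 − w) G* + w A₂₂,

where `G* = ZZ′ / (2 Σ_j p_j(1−p_j))`, `Z` the dosage matrix centred by the
observed allele frequencies of the genotyped set in use, and `w` the
residual polygenic fraction (default 0.05). The blend keeps `G_w` positive
definite even when `G*` is rank-deficient (few SNPs, clones). Whole and
partial evaluations of one scenario share one precomputed genomic structure,
which also guarantees they use identical observed allele frequencies.

**J covariates.** Genotyped animals get J = −1; their non-genotyped
ancestors get `J_anc = A_anc,g (A_g,g)⁻¹ J_g`; every other animal receives
the average of its parents' J in topological order (an unknown parent
contributes 0). The two resulting record-level covariates — the animal's
own J for the direct effect, its dam's J for the maternal effect — are
fitted as fixed effects, one shared coefficient each across countries (a
per-country variant exists but is off by default). An animal's genomic EBV
adds its own J times the estimated coefficient, for the direct and for the
maternal effect: an animal's maternal value is expressed when it acts as a
dam, where its own J is the covariate attached to it. The regression can be
switched off (`ModelSpec.fit_j = False`) for the case where genomic and
pedigree bases are known to be compatible; in that configuration, and with
`G* = A₂₂`, the single-step system reduces exactly to the pedigree system.
With the regression on, the reduction is only approximate: the two extra
unpenalised columns absorb part of the genotyped group's mean, which is
their purpose.

## Solving the mixed model equations

The coefficient matrix is kept in operator form: a sparse data part
`W′R⁻¹W`, a sparse prior part (herd and PE precisions plus
`G⁻¹ ⊗ A⁻¹` from Henderson's rules with inbreeding), and the dense
single-step correction `G⁻¹ ⊗ (G_w⁻¹ − A₂₂⁻¹)` applied per matvec as two
small dense products on the genotyped columns — it is never expanded, which
is what keeps full-population genomic systems tractable. Inbreeding is
computed with the Meuwissen–Luo algorithm; dense A blocks (A₂₂, the
ancestor block for J) come from solving `A⁻¹X = E` with a sparse LU
factorisation.

The solver is preconditioned conjugate gradients with a block-Jacobi
preconditioner: one 2c × 2c block per animal for the genetic effects
(capturing the strong across-trait coupling of `G⁻¹`), scalar Jacobi
elsewhere. Convergence is declared when the square root of the relative
difference between consecutive solutions,
`sqrt(Σ(x_k − x_{k−1})² / Σx_k²)`, falls below 10⁻⁵ (configurable); the
relative residual of the normal equations is recorded alongside. Small
systems can be solved directly (`fit(method="direct")`), which is what the
oracle-equivalence tests use so that solver tolerance and assembly
correctness are tested separately.

After solving, EBV are rescaled to a per-country base: the national animals
born in the base year (default 2002) with a phenotype; their mean EBV is
subtracted per country-trait and effect. Rescaling is a pure shift, so LR
slopes and correlations are unaffected (asserted in the tests).

## The synthetic data generator

The generator emulates the data structure a multi-country weaning-weight
evaluation consumes; its defaults are the package's study conditions.

* **Populations and mating.** Five country populations, 180 founders each,
  five discrete offspring generations on a four-year interval (birth years
  2002–2018, founders 1998). Within-country random mating; each dam
  produces two offspring; a fraction 0.08 of matings use a sire from
  another country, which creates the common bulls and common maternal
  grand-sires that connect countries. Dams are mated within country only.
  Sex is 1:1; one phenotype per animal, recorded in its own country.
* **Genotypes.** Per-SNP founder allele frequencies drawn uniformly on
  (0.05, 0.5]; 800 unlinked SNPs gene-dropped through the pedigree (one
  allele per parent, uniform at random, no linkage).
* **True values.** SNP effects are drawn once per SNP from a zero-mean
  2c-variate normal with covariance `(1−w) G / (2 Σ_j p_j(1−p_j))`, so the
  genomic part of the founder genetic variance is `(1−w) G`; a residual
  polygenic part (fraction w = 0.05, matching the evaluation model exactly)
  is propagated through the pedigree with Mendelian-sampling covariance
  `0.5 w G (1 − (F_s + F_d)/2)`. The single-step generative assumption
  therefore holds by construction.
* **Phenotypes.** `y = μ_i + sex + herd + u_direct + m_maternal(dam) +
  pe(dam) + e` with defaults μ = 250 kg, sex effect +12 kg for males, herd
  variance 200 kg², PE variance 100 kg², residual 800 kg², genetic SDs
  20 kg (direct) and 12 kg (maternal), across-country correlations 0.8
  (direct–direct), 0.7 (maternal–maternal) and mildly negative
  direct–maternal correlations — weaning-weight-like magnitudes with a
  phenotypic SD near 40 kg.
* **Genotyping.** By default 65 % of the animals born from 2006 onwards,
  chosen at random; a selective mode genotypes the top animals ranked by
  true direct value within country. Genotyping deliberately spans cohorts
  (not only the validation cohorts): real genotyped sets include proven
  animals, and the maternal J regression is only stably identified when
  genotyped dams keep recorded offspring in the partial evaluation — if
  genotyping is confined to the cohorts whose phenotypes the LR design
  masks, the coefficient is re-identified from disjoint data between whole
  and partial runs and the focal group's maternal level moves with it.
* **Determinism.** One master seed; independent sub-streams (pedigree
  structure, haplotypes/gene dropping, SNP effects, polygenics,
  environmental noise, genotyping assignment) are spawned from it, so runs
  are byte-identical given a configuration.

**What the generator does not emulate:** linkage and LD structure (SNPs are
independent, so imputation is trivial and genomic accuracy per SNP count is
optimistic relative to real chips), missing or wrong pedigree links, breed
admixture (breed fraction is 1), heterogeneous national recording models
(only sex and herd are simulated as environmental structure), unknown-parent
groups, and selection other than the optional selective genotyping (no
genetic trend). Passing tests therefore demonstrate internal correctness
and the qualitative behaviour of the estimators under known conditions, not
performance on real data.

## The validation pipeline

For each scenario the pipeline runs a whole evaluation and a partial one in
which phenotypes of animals born from the cutoff year (default 2014) onward
are masked; pedigree and genotypes are untouched. The focal group per
country is the phenotyped and genotyped animals born from the cutoff
onwards. Within-scenario LR estimators use the n−1 covariance denominator;
dispersion outside [0.85, 1.15] is flagged as considerable over-/
under-dispersion. `acĉ_p` uses the focal group's mean pedigree inbreeding
and the national genetic SD as inputs (σ_u is not re-estimated). Negative
`cov(û_w, û_p)` flags the accuracy as undefined rather than propagating a
NaN silently.

**Pooled estimators.** Besides per-country tables, the pipeline reports a
pooled row ("ALL"): per-country EBV are standardised by the national genetic
SD and combined. Level bias pools directly (it equals the size-weighted mean
of per-country level biases). The covariance-based estimators (b, acc, ρ)
are computed on deviations from each country's focal mean, because
between-country level differences are a property of the national bases and
would otherwise masquerade as individual predictive covariance. Bootstrap
resampling (10,000 samples by default) is within country; note that
resampling focal animals conditions on the fitted evaluations, so the
bootstrap SE understates across-replicate variability of estimators that
are sensitive to re-estimated fixed effects (the maternal J coefficient in
particular) — across-seed averages are the better summary for simulation
studies, and the acceptance checks average over seeds accordingly.

Between scenarios, the increase in population accuracy toward the
international single-step scenario is computed from the whole-evaluation
EBV of both scenarios on the shared focal group, `inc_acc = (1/ρ − 1)·100 %`
(ρ = 0.80 gives 25 %).

National ("pseudo-national") scenarios restrict phenotypes and genotypes to
one submitting country, prune the pedigree to national animals with data
plus all ancestors (no generation limit), and reuse the within-country
variance components. A country with no nationally submitted genotypes skips
the national single-step scenario with a logged reason.

## QC cascade

Order matters and is fixed: panel merge on the selected SNP set (duplicate
positions dropped, duplicate animals rejected), Mendelian SNP filter
(opposing homozygotes in parent–offspring pairs; removed when conflicts
strictly exceed 1 % of pairs with both calls), pedigree-link severing (a
pair conflicting at strictly more than 1 % of shared called SNPs has the
offspring's parent set to missing), per-SNP filters in the order call rate
(≥ 0.95, inclusive) → Hardy–Weinberg (1-df chi-square on observed counts,
p > 10⁻¹⁵ strict, monomorphic SNPs scored p = 1) → minor allele frequency
(> 0.01 strict), then per-animal filters (call rate ≥ 0.90, breed fraction
≥ 0.875, and removal of animals with no phenotype, no progeny and no known
parent). Remaining missing calls are filled with their expected dosage
2p_j — a deliberate stand-in for phased imputation, which would add nothing
for unlinked synthetic SNPs. "Conflict" means opposing homozygotes only;
heterozygote–homozygote pairs are consistent. Re-running the cascade on its
own output removes nothing.

## Numerical choices

* **Bending.** Eigenvalues of an assembled correlation matrix below 10⁻⁴
  are replaced by a strictly descending sequence bounded below by the
  floor, the matrix is reconstructed and rescaled to unit diagonal, and the
  procedure iterates (rescaling can reintroduce tiny negative eigenvalues;
  100 iterations maximum). An input already positive definite with minimum
  eigenvalue at or above the floor is returned unchanged, which makes the
  operation idempotent.
* **GRM.** VanRaden method 1 (`ZZ′/(2Σp(1−p))`, positive semidefinite by
  construction) and method 2 (per-SNP standardisation, requiring
  polymorphic SNPs) are both available; allele frequencies are always the
  observed ones of the genotyped set in use. PCA of a GRM uses a dense
  symmetric eigendecomposition with a deterministic sign convention
  (largest-magnitude loading positive); explained-variance fractions floor
  negative eigenvalues at zero in the denominator.
* **Degenerate inputs.** Zero-variance phenotype groups pass the outlier
  filter untouched; groups with fewer than two records are skipped; an
  empty genotype set makes the single-step model collapse to pedigree BLUP
  exactly; PCG detects an exactly solved system (zero residual) and stops.
* **Problem sizes.** The default study conditions (≈ 5,500 animals, ≈ 2,400
  genotyped, pooled focal group ≈ 1,100 across five countries) were chosen
  so a full four-scenario study with whole and partial runs completes in
  well under a minute on one CPU, which makes replicated simulation studies
  (tens of seeds) practical on a laptop; the dense genotyped-block algebra
  scales as the cube of the number of genotyped animals and is the binding
  cost at larger sizes.

## Known limitations

* Reliabilities (prediction error variances) are not computed; validation
  is entirely LR-based.
* Unknown-parent groups and metafounders are not fitted, matching the
  evaluation design the package implements.
* The per-country fixed-effect structure is minimal (mean + sex); real
  national models fit richer contemporary groups, which the `ModelSpec`
  accommodates in structure but the generator does not simulate.
* The J regression is fitted with flat (unpenalised) coefficients; its
  estimate is noisy when the maternal contrast between genotyped and
  ungenotyped dams is thin, and that noise propagates to maternal
  genomic-EBV levels — visible as across-replicate spread of the maternal
  level-bias estimator in simulation studies.
* With a single country the model is the standard univariate
  maternal-effects animal model; no hybrid multi-trait/single-trait
  shortcuts are implemented.
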