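# Methods

`imputeval` evaluates reference-based genotype imputation from low-density
SNP panels up to sequence density, and models what makes a SNP easy or hard
to impute. Because real sequenced cattle cohorts are access-restricted, the
package generates its own study population with a forward simulator whose
LD structure is controllable, then runs the full cross-validated evaluation
on it.

## Simulated population

A discrete Wright–Fisher population of `Ne` diploids (default 100,
matching the small effective size of intensively selected livestock
breeds) evolves for `n_generations` (default 400 ≈ 4·Ne, long enough to
approach mutation–drift–recombination equilibrium from monomorphic
founders) on a single chromosome (default 10 Mb at the 1 Mb = 1 cM map
convention, so 0.1 Morgan). Each generation every child draws two parents
uniformly at random and receives one recombinant gamete from each
(crossovers Poisson with mean equal to the map length, breakpoints uniform
on the genetic map), followed by symmetric 0↔1 mutation.

Variants live on a fixed lattice of candidate sites. The lattice must be
fine enough that the per-site mutation probability
(`mutation_rate × bp-per-site`) stays small: a coarse lattice concentrates
the chromosome's mutation supply onto few sites, and the resulting
recurrent mutation visibly erodes short-range LD. The default of 20 000
sites keeps per-site θ ≈ 0.03, close to infinite-sites behaviour, and the
default `mutation_rate` of 1.4e-7 per bp per generation yields 2000–2700
segregating sites in the full population — a sequence-like marker density
at desk scale. The defaults are chosen once as the package's study
conditions; the simulator is seeded and bit-reproducible.

What the generator emulates: Sved-type LD decay governed by `Ne`
(`E[r²] ≈ 1/(4·Ne·c + 1)` at genetic distance `c` Morgan), a
frequency spectrum dominated by rare variants (well over 40 % of
segregating sites have MAF < 0.1), and array-style panels nested inside
the sequence set. What it does not emulate: pedigree structure and close
relatives (all individuals are exchangeable), genotyping or sequencing
error (genotypes are true sums of haplotype alleles), INDELs, multiple
chromosomes, and non-equilibrium demography. Passing tests therefore
demonstrate the behaviour of the evaluation machinery and of the
reliability model under clean LD structure, not performance on any real
cohort — in particular, real data with close relatives should impute
*better* than this exchangeable population.

A known property worth stating explicitly: at very short distances
(4·Ne·c ≲ 1) the simulated mean r² plateaus near the neutral-equilibrium
expectation σ²_d(ρ→0) ≈ 10/22 rather than rising to 1 as the Sved
approximation does. The test suite's LD check compares binned mean r²
(sites with MAF ≥ 0.1, ten equal bins over 0–0.03 Morgan) against
`1/(4·Ne·c+1)` and agrees within ±0.1 in every bin except the shortest,
where the closed form itself is not valid; no neutral equilibrium
simulator can match it there.

## Panels and masking

Array ascertainment is emulated by a windowed greedy pick: the chromosome
is cut into `target_count` windows and the highest-MAF marker with
MAF ≥ `maf_min` (default 0.05) is taken per window, backfilling the
largest gaps when windows are empty. This reproduces the two properties
of commercial arrays that matter here — high MAF and roughly even
spacing. Panels are nested (lo ⊆ hd ⊆ sequence) by restricting the lo
search to hd markers. Defaults put hd at ~10 % and lo at ~1 % of
sequence markers, mirroring the density ratios of a high-density array
and a 50K-class array relative to sequence variants on one chromosome.
Masking a validation individual to a panel sets all off-panel genotypes
to missing and never alters retained ones.

## Cross-validation scenarios

Individuals are randomly partitioned into five near-equal groups; each
group is the validation set once. Reference sets per fold: S80 = the
other four groups, S60 = the three cyclically following groups, S40 = the
two following groups, wrapping group 5 → 1. The two-step scheme gives the
two following groups to step 1 (imputation up to the hd panel) and the
two preceding groups to step 2 (hd to sequence); the two reference sets
are disjoint. One random partition per seed is reused across scenarios so
comparisons are paired.

## Imputation engine

A diploid Li–Stephens haplotype-copying HMM: the hidden state is an
ordered pair of reference haplotypes; each chromosome switches template
across a gap of `d` Morgan with probability `1 − exp(−ρ·d)`
(`recombination_scale` ρ, default 100 — the simulated population's
effective size), landing uniformly; typed markers emit the unphased
genotype through a per-allele error (default 1e-3), untyped markers are
uninformative. Forward–backward yields per-marker posterior
P(AA), P(AB), P(BB) and the B-allele dosage
`0·P(AA) + 1·P(AB) + 2·P(BB)`. Typed markers are reported back as the
observed genotype. The factorised transition kernel needs only row/column
sums of the H×H message, so the sweep is O(L·H²); stored forward
messages are capped at ~200 MB by batching target individuals.

This engine is a transparent, exactly testable reference-based imputer:
its posteriors are verified against explicit path enumeration on small
instances to 1e-8. It is *not* a haplotype-cluster model; consequences of
that substitution are discussed under limitations. Between the two steps
of stepwise imputation the most likely genotypes (hard calls, ties broken
het-then-AA) are passed on, and dosages are not propagated.

## Accuracy metrics

Imputation accuracy `r` is the Pearson correlation between observed
genotypes (0/1/2) and imputed dosages. Markers whose observed genotypes
or dosages are constant within *any* validation group are removed first
(a correlation needs variation in both vectors). Per-SNP accuracy pools
the validation individuals of all five folds, so each SNP gets one value
per scenario; per-individual accuracy correlates over that individual's
evaluated markers and can additionally be centered by the per-marker mean
observed genotype (computed over the fold's validation individuals) or
standardized by the per-marker SD — centering removes the
allele-frequency component that inflates raw per-individual values.
Accuracy is evaluated at masked (off-panel) markers only; panel markers
are returned as observed and would contribute r = 1 artificially. For
stepwise imputation, step 1 is scored at hd-not-lo markers, step 2 at
sequence-not-hd, overall at sequence-not-lo.

## Reliability model

Per-SNP reliability (r²) is predicted as the product of three terms:

* `r2_dist = 1/(4·Ne·c + 1)` — LD decay with genetic distance to a panel
  SNP. The prediction default is Ne = 1000 even though the simulation
  uses Ne = 100: reliability at the short distances involved reflects
  deeper (historical) coalescent structure, and the larger value tracks
  the observed decay better. Both are supported.
* `r2_dmaf` — the upper limit of LD between two loci whose MAFs differ by
  `dMAF`. Two typeset variants of this bound circulate; the default
  `ratio_linear`, `(1 − 2·dMAF)/(1 + 2·dMAF)`, reaches 0 at dMAF = 0.5,
  while `ratio_squared`, `1 − 4·dMAF²/(dMAF + 1)`, does not. Reports
  always state the variant used.
* `r2_maf = Vmax·MAF/(Km + MAF)` — an empirical Michaelis–Menten curve in
  the imputed SNP's own MAF, fitted per scenario by nonlinear least
  squares on binned means (bins of 1000 SNPs sorted by MAF; smaller runs
  scale the bin size down). `Vmax` is the reliability ceiling; `Km`, the
  MAF at half the ceiling, shrinks as the reference group grows — the
  fitted Km ordering S40 > S60 > S80 reproduces on every simulated run.

For each SNP the `r2_dist·r2_dmaf` product is evaluated for its five
nearest panel SNPs and the best neighbour is kept (the nearest SNP is not
necessarily the one in highest LD); near chromosome ends fewer than five
exist and all are used. Components are clipped to [0, 1] (a fitted Vmax
slightly above 1 can push the MAF term past the ceiling). The package
also provides the exact maximal r² between two binary loci with given
margins (maximising D over coupling and repulsion phase), a hard bound
the `r2_dmaf` approximation can be checked against; simulated locus pairs
never exceed it.

## Numerical choices

Ties are fixed and deterministic throughout: nearest panel SNP → lower
position; hard call → heterozygote, then AA; best neighbour → smaller
distance, then nearest-first order; covariate binning → stable sort with
position as tie-break. The MM fit starts from Vmax₀ = max observed
reliability and Km₀ = the MAF where reliability first reaches half of
that, with parameter tolerance 1e-10; flat data and under-determined fits
raise instead of returning garbage. Posterior normalisation is enforced
to 1e-9 and the dosage/probability identity to 1e-12. A master seed
derives per-stage seeds via `SeedSequence` spawn keys, so every artifact
is a pure function of the configuration.

## Problem sizes

The shipped test-suite study sizes are: directional accuracy checks at 50
individuals, ~1300 segregating markers, hd = 130 / lo = 13, three seeds;
the stepwise-vs-direct comparison at 60 individuals, ~2000 markers,
hd = 200 / lo = 20, three seeds; LD validation on five full populations of
200 haplotypes × 20 000 candidate sites. These sizes give stable means
(seed-to-seed SD of mean per-SNP r ≈ 0.01–0.03) while keeping a full run
in minutes on one CPU.

## Limitations

* The exact-inference engine changes one qualitative conclusion: stepwise
  imputation (lo → hd → sequence with disjoint references) does **not**
  beat direct lo → sequence imputation here, falling short by ~0.01–0.05
  mean r. Under exact Li–Stephens inference the direct route is the
  optimal use of the low-density genotypes plus the sequence reference,
  while the two-step route processes same-sized references per stage and
  discards uncertainty by hard-calling in between. The advantage reported
  for cluster-based imputation software in this design is plausibly a
  property of its approximate haplotype search (which an intermediate
  scaffold stabilises), not of the information content of the design; an
  exact-posterior engine cannot reproduce it, and the corresponding
  directional test documents this as an expected failure.
* Reliability prediction uses single best-neighbour LD; haplotype-based
  (multi-SNP) prediction would be stronger and is out of scope.
* The Beagle-style allelic R² diagnostic, pedigree-aware imputation,
  phasing output, and non-equilibrium demography are out of scope.
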