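# Methods

This note documents the models and estimators implemented in
`ylineage`, the assumptions behind them, the choices made where the
design was genuinely open, and what the synthetic data do and do not
emulate.

## Haplotypes and families

A haplotype is the combination of the two IMM band-presence profiles
(UMN2405, UMN2303) and the six microsatellite alleles of one male.
Identical profiles collapse onto one haplotype; ids (`H1`, `H2`, …) are
assigned by descending multiplicity and then lexicographic profile, so
they are deterministic and permutation-invariant but are *labels*, not
identities shared with any external dataset — comparisons across
datasets must use the canonical profile, never the id.

Family classification applies the diagnostic band rules in fixed order:
any of UMN2303 bands 126/127/128 → Y3_B; otherwise UMN0307 ≠ 149
together with UMN2303 band 124 → Y3_C; otherwise Y3_A. Because such
band rules summarise a phylogeny rather than define it, an override
mapping (haplotype id → family) can replace individual rule-based calls;
the assignment records which entries were overridden. Rows with any
missing call are retained on input but flagged and excluded from
haplotype building and diversity (exclusions are logged); no imputation
is attempted.

## Diversity statistics

Unbiased haplotype diversity and its variance are

    h = n (1 − Σ p̂ᵢ²) / (n − 1)
    V(h) = 2/(n(n−1)) · { 2(n−2)[Σp̂ᵢ³ − (Σp̂ᵢ²)²] + Σp̂ᵢ² − (Σp̂ᵢ²)² }

with SE(h) = √V(h). Gene diversity applies the same estimator per locus
and averages over loci. Two conventions are exposed for the IMM
markers: each polymorphic band as a biallelic presence/absence locus
(default; polymorphism is judged on the whole table so every population
shares one locus registry), or each IMM as a single multi-allelic locus
whose allele is the whole band profile (used when comparing with
simulated data, where an IMM locus is one marker). "Overall" diversity
is exposed both as the across-population mean and as the pooled-sample
value; populations with n < 2 are dropped with a warning.

The between-population identity is the locus-average of Σᵢ xᵢⱼyᵢⱼ. Its
complement is summarised by classical PCoA: double-centring
B = −½ J D J of D = 1 − identity (no squaring — D is already a
bounded dissimilarity), eigendecomposition, scores = eigvec·√eigval,
percent variance over positive eigenvalues only (negative eigenvalues
of a non-Euclidean D are reported as 0 %).

## ρ dating

Distances count one step per IMM band present in exactly one of the two
haplotypes and |Δallele|/unit steps per microsatellite, all
polymorphisms weighted equally. The repeat unit per locus comes from
the panel (2 bp for all six loci of the default panel) or is inferred
as the GCD of observed allele differences; a non-integer step count
raises an error rather than silently rounding. ρ is the
multiplicity-weighted mean distance from the derived haplotypes to the
designated ancestral haplotype, SE = √(ρ/n) with n the number of
sampled chromosomes, and years = ρ·g/μ with defaults μ = 0.0008
mutations/generation (an intermediate rate for this mixed slow-IMM +
fast-microsatellite panel) and g = 4.84 years/generation. For
between-family dates the ancestral haplotype defaults to the other
family's most frequent ("central") haplotype. ρ is insensitive to
demography but assumes a star-like genealogy below the ancestral node;
with deep internal structure it underestimates dispersion, which the
√(ρ/n) error does not capture.

## Coalescent engine

Genealogies are sampled with msprime at ploidy 1, so a haploid
population of size N has pairwise coalescence rate 1/N per generation
(E[T₂] = N); times convert as generations = years / 4.84, rounded.
The three scenarios:

1. **Single domestication.** One domestic deme bottlenecked at 9,000
   B.P., splitting at 3,500 B.P. into three descendants, two of which
   merge at 2,000 B.P.
2. **Three ancestral lineages.** Three demes separated for 250,000
   years, each receiving its own founder-size bottleneck at 9,000 B.P.;
   two descendants merge at 2,000 B.P.
3. **Domestication with wild introgression.** One domesticated lineage
   (bottleneck at 9,000 B.P.) splits at 3,500 B.P.; at 3,000 B.P. both
   domestic subpopulations receive an admixture pulse of proportion
   0.79 from a wild population separated 250,000 years (no bottleneck
   on the wild side); the subpopulations merge at 2,000 B.P.

Design choices where the event grammar was open: size changes are
instantaneous (no growth curves); the founder size (prior U(1, 200))
applies for 20 generations (~100 years, a herd-establishment phase)
behind the domestication event, after which the deme reverts to a wild
ancestral size; every deme's size is an independent draw from
U(10³, 10⁵); backward merge proportions are 0.5/0.5; and the pooled
sample of 180 present-day lineages is allocated to the surviving demes
with equal probabilities (the "admixture at time 0" device that mirrors
analysing one combined sample). Priors: current/wild Ne ~ U(10³, 10⁵)
haploid, founder size ~ U(1, 200), IMM rate ~ U(2×10⁻⁵, 2×10⁻⁴) per
locus, microsatellite rate fixed at 0.008/generation.

Mutations are dropped on a single shared genealogy for all 8 loci
(fully linked, as on a non-recombining Y); a flag switches to
independent per-locus genealogies for comparison with simulators whose
default is unlinked loci. Microsatellites: Poisson(branch·0.008)
mutations, each ±1 repeat with equal probability (only the net
displacement is tracked). IMMs: any mutation replaces the band profile
with a novel state (infinite alleles), a deliberate surrogate for band
pattern change; simulated IMM "alleles" therefore correspond to whole
observed band profiles, which is how observed tables are summarised for
the ABC.

## ABC model choice

Summary statistics over the 8 loci of the pooled sample: SD of allele
counts (K_sd), mean and SD of unbiased per-locus gene diversity
(H̄, H_sd), and mean total heterozygosity (H̄t) computed on the pooled
sample. With a single pooled sample H̄t equals H̄ exactly; it is kept as
a fourth statistic (faithful to summarising a one-deme sample with the
standard four) — in the rejection distance this double-weights H̄, and
the GLM projects onto a full-rank subset of statistics before fitting.

Rejection retains ⌈fraction·N⌉ simulations (default 0.5 %) closest in
Euclidean distance on statistics standardised by the simulated pool's
SDs; zero-variance statistics are dropped from the distance with a
warning; ties break by simulation index. The marginal density under
each scenario follows the ABC-GLM construction: an OLS fit of
statistics on parameters over the retained simulations with a
multivariate-normal residual covariance, the density at the observed
statistics being the average fitted-normal density over retained
parameter draws; a singular fit falls back to a Gaussian KDE of the
retained statistics (logged). Posterior probabilities normalise the
densities under equal model priors; Bayes factors are density ratios.
A rejection-count estimator (each model's share of a globally retained
set) is reported alongside; when the observed statistics lie far
outside the simulated support the GLM extrapolates and the two
estimators can disagree — treat that disagreement as a misfit
diagnostic, not as evidence for either winner.

PODS validation draws pseudo-observed datasets from each scenario's own
reference table (leave-one-out), reruns the model choice, and reports
the confusion matrix, the winning-posterior distributions split by
correctness, and the per-pair maximum false-positive posterior — the
replayable form of the "observed PP never reached by false positives"
argument.

## Synthetic data: what it emulates, and what it does not

The generator plants: founder haplotypes honouring the family band
rules; shared within-family variants with exact multiplicities; a
per-population composition plan; singletons drawn as founder + (1 +
Poisson(λ)) stepwise steps at non-diagnostic loci (λ = 0.4 by default),
reflected at allele-domain boundaries so the planted 19-allele registry
is closed; and optional band-flip noise (off by default) to stress the
classifier. Diagnostic loci are frozen within each family so planted
family labels stay exactly recoverable unless noise is switched on.
A star-phylogeny mode removes domain reflection and records each row's
mutational distance to the founder, making the planted ρ known.

The paper-like preset reproduces, by construction, the structure of the
real intercontinental survey: 22 populations, 248 males, 47 haplotypes
(29 singletons), family census 186/24/38 samples and 26/12/9
haplotypes, a modal haplotype with 55 carriers, a Y3_C central
haplotype with 23 carriers, Y3_B confined to West Africa, 19
microsatellite alleles, a near-monomorphic Brazilian Nelore population
(h ≈ 0.090), across-population mean gene diversity ≈ 0.15 and a
leading PCoA axis carrying ≈ 66 % of the variability. It does **not**
emulate: linkage between the planted variant structure and any real
allele sizes; the real survey's within-population haplotype-diversity
profile (the preset's across-population mean is ≈ 0.46 — with 47
haplotypes, 29 of them singletons, spread over 22 populations of these
sizes, a substantially lower mean is not attainable by any composition,
so published overall haplotype-diversity figures should not be compared
against this preset); missing data; or genotyping error beyond the
optional band flips. Passing tests on the preset therefore demonstrate
correctness of the estimators and the pipeline plumbing on data of
realistic shape, not inference accuracy on the real cattle data.

## Numerical choices and problem sizes

Frequency vectors must sum to 1 within 1e-9; identity matrices are
symmetrised exactly by construction; PCoA treats eigenvalues below
1e-12 as zero. The GLM requires ≥ 30 retained simulations and returns a
floor of the smallest positive float rather than exactly zero density.
Test and example runs use desk-scale budgets chosen for a single CPU:
10⁴ coalescent replicates per scenario with 50 PODS per model for the
validation (the analysis-scale default in the literature is 10⁶
replicates), 10⁴ replicates for the pairwise-coalescence control, and
400 replicates of 40 samples for the stepwise-mutation equilibrium
check against H = 1 − 1/√(1+4Nμ). All randomness flows through
explicit integer seeds; identical seeds replay bit-identically.

## Known limitations

* The coalescent uses Kingman (binary-merger) dynamics; for founder
  sizes near 1 with 180 lineages, many-lineage bottleneck generations
  are approximated by fast sequences of binary mergers.
* The bottleneck duration (20 generations) and the per-deme independent
  Ne draws are package conventions; scenario comparisons are
  conditional on them.
* The ABC prior ranges produce simulated diversities well above those
  of strongly bottlenecked observed-style data, so absolute model fit
  is poor even where relative model choice is well-behaved; PODS
  results quantify the latter only.
* ρ standard errors use √(ρ/n), which ignores genealogical correlation
  among sampled chromosomes and is therefore optimistic for
  star-violating genealogies.
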