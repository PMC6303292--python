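# ylineage

Male-lineage population genetics of zebu cattle (*Bos indicus*) Y
chromosomes: haplotype assembly from Y-specific markers, Nei diversity
statistics, ρ-statistic divergence dating, haploid coalescent simulation
of competing domestication scenarios, and approximate Bayesian
computation (ABC) model choice with cross-validation.

## The problem

All zebu Y chromosomes fall in haplogroup Y3, which splits into three
haplotypic families: **Y3_A** (cosmopolitan and predominant), **Y3_B**
(observed only in West Africa) and **Y3_C** (centred on South India and
Yemen). Haplotypes are built from two kinds of Y-specific markers — two
Interspersed Multilocus Microsatellites (IMMs: UMN2405, UMN2303), typed
as band presence/absence profiles, and six Y-chromosome microsatellite
loci (INRA189, two UMN0103 loci, UMN0307, BM861, BYM1) typed as integer
alleles. The package is for population geneticists who want to rerun
this style of male-lineage analysis end-to-end, or to test each step
against data with planted ground truth.

## The methods at its core

* **Diversity.** Unbiased haplotype diversity h = n(1−Σp̂ᵢ²)/(n−1) with
  its sampling variance V(h); per-locus gene diversity and its mean;
  the between-population genetic identity Σᵢ xᵢⱼyᵢⱼ averaged over loci;
  classical PCoA of the complement 1 − identity.
* **ρ dating.** ρ = mean number of mutational steps from a family's
  haplotypes to a designated ancestral (central) haplotype, with
  SE = √(ρ/n); years = ρ · g/μ with μ = 0.0008 mutations/generation and
  g = 4.84 years/generation (so 1 mutation ≈ 6,050 years).
* **Coalescent engine.** Haploid (ploidy-1) genealogies via msprime for
  three demographic scenarios — single domestication (bottleneck at
  9,000 B.P., split 3,500 B.P., two descendants merged 2,000 B.P.);
  three lineages separated 250,000 years and independently
  domesticated; and domestication plus a 0.79 wild-introgression pulse
  at 3,000 B.P. All 8 loci are dropped on one shared genealogy
  (the Y does not recombine): microsatellites under a strict stepwise
  model at 0.008/generation, IMM profiles as slow infinite-alleles
  markers with rate drawn from U(2×10⁻⁵, 2×10⁻⁴).
* **ABC model choice.** Four summary statistics (K_sd, H̄, H_sd, H̄t),
  0.5 % rejection on SD-standardised Euclidean distance, GLM marginal
  densities (regression of statistics on parameters over the retained
  simulations, density = average fitted-normal density at the observed
  statistics), posterior probabilities and Bayes factors under equal
  model priors, and pseudo-observed-dataset (PODS) cross-validation
  with confusion matrices and false-positive posterior ceilings.
* **Synthetic data.** A generator that plants family structure, shared
  haplotypes with exact multiplicities, singletons, and star
  phylogenies, together with a ground-truth ledger, so every estimator
  can be validated without any external data.

## Worked example

```bash
python examples/survey_pipeline.py
```

prints, for the paper-like synthetic survey (248 males, 22 populations):

```
47 distinct haplotypes, 29 singletons, modal haplotype carried by 55 males

Family census (haplotypes / samples):
      n_haplotypes  n_samples  frac_haplotypes  frac_samples
Y3_A            26        186            0.553         0.750
Y3_B            12         24            0.255         0.097
Y3_C             9         38            0.191         0.153

Across-population means: gene diversity 0.152, haplotype diversity 0.462

PCA of (1 - genetic identity): PC1-PC3 explain 67.4 / 19.4 / 3.8 % of the variability
```

47 haplotypes of which 29 are one-off; three-quarters of the males
carry the cosmopolitan Y3_A family; the leading PCoA axis separates the
Y3_C-carrying populations (South India/Yemen) from the Y3_A mass while
the second axis pulls out the West-African Y3_B populations. The other
examples date family divergences with ρ (`examples/rho_dating.py`:
ρ = 1.15 → 6,957 ± 3,993 years B.P.), simulate the three demographic
scenarios (`examples/coalescent_models.py`) and run the ABC model
choice with a mini PODS validation (`examples/abc_model_choice.py`).

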