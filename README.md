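# diplotyper

Haplotype-cluster and diplotype-based association analysis for unphased SNP
genotypes.

Single-locus association tests ignore the joint structure of nearby variants,
and single-haplotype tests ignore that several haplotypes can carry the same
functional effect. `diplotyper` tests *haplotype clusters*: every nonempty
subset of an LD block's common haplotypes is treated as one pseudo-allele,
every pair of an individual's haplotypes becomes a *diplotype* at that
pseudo-locus, and each cluster hypothesis is scored by an additive trend
regression — exactly like a SNP coded 0/1/2, but for a set of haplotypes.
The package is aimed at candidate-gene association studies (the motivating
use case is hepatic-lipase variation and HDL-cholesterol levels) where a
cluster of haplotypes sharing a causal background gives a sharper signal
than any single SNP or single haplotype.

## Method

Given unphased biallelic genotypes for one region:

1. **QC** — drop SNPs with call rate < 95%, MAF < 0.05, or an exact
   Hardy-Weinberg test p < 1e-6.
2. **LD blocks** — partition SNPs by one of three standard rules: Gabriel
   et al. D′-confidence-interval blocks, the four-gamete test, or the solid
   spine of LD.
3. **EM phasing** — estimate block haplotype frequencies by
   expectation-maximization under random mating and assign each sample its
   most-likely haplotype pair with a posterior probability.
4. **Clusters** — with H = {H₁, …, Hₙ} the haplotypes above the frequency
   threshold (default 1%), enumerate all 2ⁿ − 1 nonempty subsets of H.
5. **Diplotype patterns** — for each cluster C, test C against the star
   `C/*` (every other haplotype, rare ones included), and test every
   unordered pair of disjoint clusters `C₁/C₂`; for n = 4 this gives
   15 + 25 = 40 patterns.
6. **Recoding** — each sample's assigned pair becomes a minor-cluster dose
   in {0, 1, 2} (the AA/AB/BB pseudo-genotype). For `C₁/C₂` patterns,
   samples carrying a haplotype outside C₁ ∪ C₂ are set missing.
7. **Regression** — OLS (quantitative trait, optionally log-transformed with
   effects reported on the raw scale) or logistic regression (binary trait)
   of the trait on dose plus covariates, with Wald inference and Bonferroni
   correction across all single-SNP and diplotype tests.

A synthetic-cohort generator (`diplotyper.synthetic_data`) draws haplotype
pairs per block under HWE random mating, adds covariates and an additive
cluster effect on the trait, and writes standard PED/MAP + phenotype TSV
files, so the whole pipeline is testable without any external data.

## Worked example

Simulate a cohort of 7,536 samples with one 3-SNP block, common haplotypes
AAC/AAT/AGC/GAC (frequencies 0.437/0.219/0.269/0.065, 1% rare mass) and a
+0.04 mmol/l HDL effect per {AAT, GAC} haplotype, then run the pipeline:

```bash
diplotyper simulate --seed 7 --n-samples 7536 --out demo
diplotyper run --ped demo/cohort.ped --map demo/cohort.map \
    --pheno demo/cohort.pheno.tsv --trait HDL --covar area,age,sex,bmi \
    --blocks four_gamete --log-transform --out demo/out
```

which prints the stage counts

```
samples: 7536
snps_kept: 3
blocks: 1
snp_tests: 3
clusters: 15
patterns: 40
diplotype_tests: 40
total_tests: 43
bonferroni_threshold: 1.163E-03
```

and writes `blocks.tsv`, `haplotypes.tsv`, `clusters.tsv`, `single_snp.tsv`
and `diplotypes.tsv`. The top diplotype rows (sorted by p):

```
test_id             minor_major          counts          effect   stderr    p_value
b1_H10/b1_OH10(*)   b1_H10; b1_OH10(*)   604/3040/3892   0.04068  0.004509  4.76E-19
b1_H5/b1_H10        b1_H10; b1_H5        604/3013/3826   0.04046  0.004535  1.05E-18
b1_H5/b1_OH5(*)     b1_OH5(*); b1_H5     631/3079/3826   0.03945  0.004481  1.95E-18
```

Here `b1_H10` is the cluster {AAT, GAC} and `b1_OH10(*)` everything else;
the counts triplet is (minor-homozygote / heterozygote / major-homozygote).
The cluster recovers the simulated effect (0.041 ± 0.005 per haplotype) at
p ≈ 5×10⁻¹⁹, while the best single SNP in `single_snp.tsv` only reaches
p ≈ 1.4×10⁻¹¹ — the cluster test concentrates the signal that the additive
single-locus tests split.

The same stages are available as library functions (`filter_snps`,
`find_blocks`, `em_frequencies`, `phase_samples`, `common_haplotypes`,
`enumerate_clusters`, `enumerate_patterns`, `diplotype_assoc`,
`bonferroni`, …) for use from Python.

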