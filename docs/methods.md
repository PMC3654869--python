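# Methods

## Model and procedure

`diplotyper` tests the association between a quantitative or binary trait
and *haplotype clusters* within an LD block. A cluster C is any nonempty
subset of the block's common haplotype set H (those with EM-estimated
frequency above a threshold, default 1%). Each individual's two assigned
haplotypes define a diplotype at the pseudo-locus induced by a *pattern*:

- `C/*` — C against the star, i.e. every haplotype not in C, explicitly
  including haplotypes below the frequency threshold. Every phased sample
  receives a dose (the count of its haplotypes in C, 0/1/2).
- `C₁/C₂` with C₁ ∩ C₂ = ∅ — only samples whose two haplotypes both lie in
  C₁ ∪ C₂ are scored; carriers of any outside haplotype are set missing.
  This is why cluster-versus-cluster sample sizes are smaller than the
  phased-cohort size whenever rare haplotypes segregate.

Because the star absorbs rare haplotypes, the star tests of a cluster and of
its complement within H are different hypotheses: they use identical dose
vectors only when no rare haplotype is present in the cohort (then the doses
are reflections, d ↦ 2 − d, and |effect|, SE and p coincide exactly — a
property the test suite asserts). With rare carriers the two tests diverge
slightly, which is the expected behaviour, not an artifact.

For |H| = n there are 2ⁿ − 1 clusters and
(2ⁿ − 1) + (3ⁿ − 2ⁿ⁺¹ + 1)/2 patterns; both counts are verified against
independent bitmask enumerations for n ≤ 8. Enumeration order is canonical
— ascending subset size, then lexicographic member tuples — and labels
`b{block}_H{k}` follow that order. Labels are therefore reproducible across
runs of this package but are a convention: a different ordering of H yields
a different numbering of the same clusters.

## Statistical model

Each pattern (and each SNP) is tested under the additive model: trait ~
intercept + dose + covariates, where dose counts the minor side (the cluster
or allele with the smaller total haplotype count among scored samples; ties
keep the declared first cluster and are logged). Inference is Wald-type, as
in standard GWAS toolchains. When the trait is right-skewed (the HDL-C use
case) the test p-value is computed on the log-transformed trait while the
reported effect and SE come from a companion fit on the raw scale, so
effects remain in measurement units (mmol/l per haplotype). A `dual=False`
switch reports a single transformed fit instead. Binary traits use
maximum-likelihood logistic regression; complete separation raises an error
rather than returning an unusable estimate. Multiplicity is controlled by
Bonferroni across all single-SNP plus all diplotype tests of the run — with
224 tests at α = 0.05 the per-test threshold is 2.23 × 10⁻⁴.

Samples missing the dose, trait or any covariate are dropped listwise per
test, and the per-row n is reported because it varies across
cluster-versus-cluster patterns.

## LD and phasing machinery

Two-locus haplotype frequencies come from an EM over the 3×3 genotype
table (only the double heterozygote is phase-ambiguous). D′ = |D|/D_max and
r² are computed from the fitted gamete frequencies. The D′ confidence
interval profiles the genotype likelihood over a fixed 101-point D′ grid
(allele frequencies at their MLEs, sign of D fixed), normalises to unit
mass, and takes the 5th and 95th cumulative percentiles — deterministic and
reproducible, with the grid step (0.01) as its resolution.

Block rules and their defaults:

- **Gabriel**: strong LD when CI ∈ [0.70, 1] with upper bound ≥ 0.98;
  strong recombination when the upper bound < 0.90; a candidate span needs
  ≥ 95% of its informative pairs in strong LD; maximal non-overlapping
  candidates are chosen longest-first, ties leftmost. Thresholds follow the
  published defaults and are configurable.
- **Four-gamete**: a block extends while every internal pair shows fewer
  than four gametes at estimated frequency ≥ 0.01.
- **Solid spine**: a span qualifies when D′ from its first SNP to every
  later SNP, and from its last SNP to every earlier one, is ≥ 0.80.

No distance cap is applied by default (the intended use is a single gene
region); `--max-block-kb` adds one for Gabriel blocks.

Multilocus block EM initialises uniformly over the product of observed
allele sets (deterministic, no seed), marginalises missing genotypes in the
E-step rather than imputing, and asserts a non-decreasing log-likelihood
every iteration. Convergence: max |Δf| < 1e-8, cap 1000 iterations (a
warning, not an error, on hitting the cap). Samples are grouped by
multilocus genotype pattern, so cost scales with the number of distinct
patterns (≤ 3^width), not cohort size. Hard assignment (most-likely pair,
ties to the lexicographically smallest index pair) feeds the recoding;
posterior-weighted dosages are intentionally out of scope, mirroring the
AA/AB/BB recoding the method is defined by. All-missing samples are omitted
from phasing and from all pattern tests.

## Synthetic cohorts

The generator emulates a two-site population cohort: haplotype pairs drawn
independently per block (HWE random mating, no LD between blocks),
covariates area ~ Bern(0.456), age ~ N(51.2, 8.7), sex ~ Bern(0.517),
BMI ~ N(24.4, 3.1) drawn independently of genotype, and trait = 1.2 +
effect × cluster dose + centred covariate effects + N(0, sd). Rare
haplotypes are distinct strings over the block's own biallelic site
alphabets (they never introduce a third allele), sharing the configured
rare mass equally.

The built-in worked-example cohort uses one 3-SNP block with common
haplotypes AAC/AAT/AGC/GAC at frequencies 0.437/0.219/0.269/0.065, 1% rare
mass, n = 7536, a +0.04 effect per {AAT, GAC} haplotype and residual sd
0.25 — sized so the cluster test yields p ~ 10⁻¹⁹ while the best single SNP
sits around 10⁻¹². One pseudo-random stream keyed by the seed makes outputs
byte-identical across runs.

What the generator does **not** emulate: recombination gradients and
inter-block LD, population structure and relatedness, genotyping error,
confounded covariates (an optional knob exists for effects, but covariates
are independent of genotype by default), and realistic rare-haplotype
spectra. On that last point: spreading 1% rare mass over the four
recombinant strings of a 3-SNP block makes each rare gamete (~0.25%) large
relative to D_max at these allele frequencies, so point D′ falls to
0.6–0.9 and the Gabriel CI rule — correctly, given its definition —
declines to call the block, while the four-gamete rule (gamete threshold
1%) recovers it. End-to-end examples on this cohort therefore use the
four-gamete method; Gabriel logic is exercised on rare-free constructions
where its CI classification is the property under test. Passing tests on
these cohorts validate the algorithmic chain and its calibration, not
robustness to the real-data complications listed above.

## Numerical and design choices

- HWE QC uses the exact conditional test (summing configurations no more
  likely than the observed heterozygote count), implemented directly since
  the 10⁻⁶ alpha sits where the chi-square approximation fails; it is
  checked against a factorial enumeration in the tests. MAF uses
  non-missing calls only; half-calls are treated as fully missing.
- PED/MAP is the PLINK text dialect ("0" = missing allele; family fields
  parsed but ignored); each pattern can be exported as a pseudo-SNP PED/MAP
  (minor → A, major → B, missing → "0 0") for external cross-validation.
  VCF input (via pysam) accepts both `/` and `|` separators and ignores
  phase.
- Cluster enumeration refuses |H| > 20 (2ⁿ guard). The full-set star
  pattern `H/*` is generated like any other; with no rare carriers its dose
  is constant and the test is skipped with a logged note.
- Simulation sizes used by the test suite follow the study conditions the
  checks are defined at: EM recovery at n = 2000; regression calibration
  with 1000 null cohorts of n = 1000 (linear and logistic) and 300
  effect-recovery replicates at n = 5000; power ordering and null control
  over 100 seeds of the n = 7536 worked-example cohort.

## Known limitations

- Phasing is within-block only; no partition-ligation for very wide blocks
  and no cross-block haplotypes.
- Hard assignment ignores phase uncertainty downstream; posteriors are
  recorded but not propagated into the regression.
- Bonferroni is the only multiplicity control (by design); tests are
  correlated, so it is conservative.
- No relatedness or population-structure correction; the regression assumes
  exchangeable individuals.
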