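"""Synthetic cohorts with known haplotype structure and trait effects.

Each sample draws two haplotypes per block independently from the block's
haplotype frequency vector (HWE random mating); genotypes are the phase-
collapsed allele pairs.  A quantitative trait is intercept + additive causal
cluster dose x effect + centred covariate effects + Gaussian noise; a binary
trait goes through a logistic link anchored at a baseline prevalence.  The
truth record keeps the generating haplotype pairs, frequencies and effects
so every downstream stage can be scored against them.

The default covariate model mirrors a two-site Korean population cohort of
middle-aged adults (area ~ Bernoulli(0.46), age ~ N(51.2, 8.7), sex ~
Bernoulli(0.52), BMI ~ N(24.4, 3.1)) with an HDL-like trait centred at
1.2 mmol/l.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .genotype_io import GenotypeMatrix, PhenotypeTable, SnpRecord

import pandas as pd


@dataclass(frozen=True)
class BlockSpec:
    """Common haplotypes and frequencies for one simulated LD block."""

    haplotypes: tuple[str, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self):
        if len(self.haplotypes) != len(self.frequencies):
            raise ConfigurationError("haplotypes/frequencies length mismatch")
        if len({len(h) for h in self.haplotypes}) != 1:
            raise ConfigurationError("haplotype strings must share one length")
        if any(f <= 0 for f in self.frequencies):
            raise ConfigurationError("frequencies must be positive")

    @property
    def width(self) -> int:
        return len(self.haplotypes[0])


@dataclass(frozen=True)
class CausalSpec:
    """An additive trait effect attached to a haplotype cluster."""

    block_index: int
    cluster_haplotypes: frozenset[str]
    effect: float  # trait units (or log-odds) per cluster haplotype
    trait_sd: float = 0.25


def _default_covariates() -> dict:
    return {
        "area": ("bernoulli", 0.456),
        "age": ("normal", 51.2, 8.7),
        "sex": ("bernoulli", 0.517),
        "bmi": ("normal", 24.4, 3.1),
    }


def _default_covariate_effects() -> dict:
    return {"area": 0.02, "age": -0.001, "sex": 0.15, "bmi": -0.02}


@dataclass
class SimConfig:
    seed: int = 0
    n_samples: int = 1000
    blocks: list[BlockSpec] = field(default_factory=list)
    rare_freq: float = 0.0  # per-block frequency mass on sub-threshold haplotypes
    n_rare: int = 4  # rare mass is split over up to this many haplotypes
    causal: CausalSpec | None = None
    covariate_model: dict = field(default_factory=_default_covariates)
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    trait_kind: str = "quantitative"  # or "binary"
    trait_mean: float = 1.2  # quantitative baseline (mmol/l-like)
    prevalence: float = 0.3  # binary baseline
    trait_name: str = "HDL"

    def __post_init__(self):
        if not self.blocks:
            raise ConfigurationError("at least one block is required")
        for b in self.blocks:
            total = sum(b.frequencies) + self.rare_freq
            if abs(total - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"block frequencies + rare_freq sum to {total}, not 1"
                )
        if self.trait_kind not in ("quantitative", "binary"):
            raise ConfigurationError(f"unknown trait kind {self.trait_kind!r}")


def _rare_strings(spec: BlockSpec, k: int, rng: np.random.Generator) -> list[str]:
    """Distinct sub-threshold haplotypes drawn from the block's own biallelic
    site alphabets, never colliding with the common set."""
    per_site = [sorted({h[s] for h in spec.haplotypes}) for s in range(spec.width)]
    pool = [
        "".join(t)
        for t in itertools.product(*per_site)
        if "".join(t) not in spec.haplotypes
    ]
    if not pool:
        raise ConfigurationError("no room for rare haplotypes in this block")
    k = min(k, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeTable, dict]:
    """Draw one cohort; fully reproducible from ``cfg.seed``.

    Returns the genotype matrix, the phenotype table and a truth record with
    keys ``haplotypes`` (full per-block lists, common first), ``frequencies``,
    ``hap_pairs`` (per-block (n, 2) index arrays), ``dose`` (causal cluster
    dose per sample) and ``config``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i + 1:05d}" for i in range(n)]

    snps: list[SnpRecord] = []
    call_cols: list[np.ndarray] = []
    truth_haps: list[list[str]] = []
    truth_freqs: list[np.ndarray] = []
    truth_pairs: list[np.ndarray] = []

    for bi, spec in enumerate(cfg.blocks):
        haps = list(spec.haplotypes)
        freqs = list(spec.frequencies)
        if cfg.rare_freq > 0:
            rare = _rare_strings(spec, cfg.n_rare, rng)
            haps += rare
            freqs += [cfg.rare_freq / len(rare)] * len(rare)
        freqs_arr = np.asarray(freqs)
        pairs = rng.choice(len(haps), size=(n, 2), p=freqs_arr)
        truth_haps.append(haps)
        truth_freqs.append(freqs_arr)
        truth_pairs.append(pairs)

        base_pos = 1_000_000 + bi * 500_000
        hap_mat = np.array([list(h) for h in haps])  # (n_hap, width) chars
        for s in range(spec.width):
            site_alleles = sorted(set(hap_mat[:, s]))
            allele_a = site_alleles[0]
            allele_b = site_alleles[1] if len(site_alleles) > 1 else None
            snps.append(
                SnpRecord(
                    f"snp_b{bi + 1}_{s + 1}",
                    "15",
                    base_pos + s * 1000,
                    allele_a,
                    allele_b,
                )
            )
            codes = np.array([0 if c == allele_a else 1 for c in hap_mat[:, s]], dtype=np.int8)
            col = codes[pairs]  # (n, 2)
            call_cols.append(col)

    calls = np.stack(call_cols, axis=1)
    g = GenotypeMatrix(samples, snps, calls)

    # covariates, in declared order
    cov_data: dict[str, np.ndarray] = {}
    cov_means: dict[str, float] = {}
    for name, model in cfg.covariate_model.items():
        if model[0] == "normal":
            _, mu, sd = model
            cov_data[name] = rng.normal(mu, sd, size=n)
            cov_means[name] = mu
        elif model[0] == "bernoulli":
            _, p = model
            cov_data[name] = rng.binomial(1, p, size=n).astype(float)
            cov_means[name] = p
        else:
            raise ConfigurationError(f"unknown covariate model {model[0]!r}")

    # causal dose
    dose = np.zeros(n)
    effect = 0.0
    sd = 0.25
    if cfg.causal is not None:
        ca = cfg.causal
        haps = truth_haps[ca.block_index]
        members = {k for k, h in enumerate(haps) if h in ca.cluster_haplotypes}
        if not members:
            raise ConfigurationError("causal cluster matches no simulated haplotype")
        pairs = truth_pairs[ca.block_index]
        dose = np.isin(pairs, list(members)).sum(axis=1).astype(float)
        effect = ca.effect
        sd = ca.trait_sd

    lin = effect * dose
    for name, beta in cfg.covariate_effects.items():
        if name in cov_data:
            lin = lin + beta * (cov_data[name] - cov_means[name])

    if cfg.trait_kind == "quantitative":
        trait = cfg.trait_mean + lin + rng.normal(0.0, sd, size=n)
    else:
        logit0 = np.log(cfg.prevalence / (1 - cfg.prevalence))
        p = 1.0 / (1.0 + np.exp(-(logit0 + lin)))
        trait = rng.binomial(1, p, size=n).astype(float)

    data = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    data["trait"] = trait
    for name in cfg.covariate_model:
        data[name] = cov_data[name]
    pheno = PhenotypeTable(data, cfg.trait_name, list(cfg.covariate_model))

    truth = {
        "haplotypes": truth_haps,
        "frequencies": truth_freqs,
        "hap_pairs": truth_pairs,
        "dose": dose,
        "effect": effect,
        "config": cfg,
    }
    return g, pheno, truth


# ---------------------------------------------------------------------------
# A cohort shaped like the worked example: one 3-SNP block, four common
# haplotypes AAC / AAT / AGC / GAC, 1% rare mass, and a positive HDL-like
# effect carried by the {AAT, GAC} cluster.

PAPER_LIKE_HAPLOTYPES = ("AAC", "AAT", "AGC", "GAC")
PAPER_LIKE_FREQUENCIES = (0.437, 0.219, 0.269, 0.065)
PAPER_LIKE_CLUSTER = frozenset({"AAT", "GAC"})


def paper_like_config(
    seed: int = 0,
    n_samples: int = 7536,
    effect: float = 0.04,
    rare_freq: float = 0.01,
    trait_sd: float = 0.25,
) -> SimConfig:
    freqs = PAPER_LIKE_FREQUENCIES
    if rare_freq != 0.01:
        # keep relative common frequencies, rescale to leave room for rare mass
        scale = (1.0 - rare_freq) / sum(PAPER_LIKE_FREQUENCIES)
        freqs = tuple(f * scale for f in PAPER_LIKE_FREQUENCIES)
    return SimConfig(
        seed=seed,
        n_samples=n_samples,
        blocks=[BlockSpec(PAPER_LIKE_HAPLOTYPES, freqs)],
        rare_freq=rare_freq,
        causal=CausalSpec(0, PAPER_LIKE_CLUSTER, effect, trait_sd),
    )


def paper_like_fixture(
    seed: int = 0, n_samples: int = 7536, effect: float = 0.04
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """One 3-SNP-block cohort with the AAC/AAT/AGC/GAC haplotype structure."""
    g, pheno, _ = simulate_cohort(paper_like_config(seed, n_samples, effect))
    return g, pheno
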