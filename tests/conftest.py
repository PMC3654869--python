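import numpy as np
import pytest

from diplotyper.genotype_io import GenotypeMatrix, SnpRecord


def matrix_from_pairs(pairs, chromosome="1", start=1000, spacing=1000, ids=None):
    """Build a GenotypeMatrix from per-sample haplotype string pairs.

    ``pairs`` is a list of (hap1, hap2) equal-length allele strings; site
    alleles are inferred per column (max 2).  Missing alleles are written
    as ``.`` in the strings.
    """
    n = len(pairs)
    width = len(pairs[0][0])
    snps = []
    calls = np.full((n, width, 2), -1, dtype=np.int8)
    for s in range(width):
        observed = sorted(
            {h[s] for p in pairs for h in p if h[s] != "."}
        )
        assert len(observed) <= 2, f"site {s}: >2 alleles in test construction"
        allele_a = observed[0] if observed else "A"
        allele_b = observed[1] if len(observed) == 2 else None
        snps.append(
            SnpRecord(f"snp{s + 1}", chromosome, start + s * spacing, allele_a, allele_b)
        )
        code = {allele_a: 0}
        if allele_b:
            code[allele_b] = 1
        for i, (h1, h2) in enumerate(pairs):
            if h1[s] != "." and h2[s] != ".":
                calls[i, s, 0] = code[h1[s]]
                calls[i, s, 1] = code[h2[s]]
    sample_ids = ids or [f"S{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, snps, calls)


def draw_pairs(haplotypes, freqs, n, rng):
    """HWE-random-mating haplotype string pairs."""
    idx = rng.choice(len(haplotypes), size=(n, 2), p=np.asarray(freqs))
    return [(haplotypes[a], haplotypes[b]) for a, b in idx]


@pytest.fixture
def rng():
    return np.random.default_rng(20131)
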