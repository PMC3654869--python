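"""Pairwise linkage disequilibrium and LD-block partitioning.

Two-locus haplotype frequencies are estimated by EM over the 3x3 genotype
table (only the double heterozygote is phase-ambiguous).  From them come
D' = |D|/Dmax and r^2, and a likelihood-based confidence interval on D'
computed on a 101-point grid — the construction behind the Gabriel et al.
"strong LD / strong recombination" classification.  Three block definitions
are provided: Gabriel confidence-interval blocks, the four-gamete test, and
the solid-spine-of-LD rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedLDError
from .genotype_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class PairwiseLD:
    d_prime: float
    r2: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class LDBlock:
    """A contiguous SNP index range, 0-based half-open."""

    snp_start: int
    snp_end: int
    method: str

    def __post_init__(self):
        if self.snp_end - self.snp_start < 2:
            raise ValueError("a block spans at least 2 SNPs")

    def indices(self) -> range:
        return range(self.snp_start, self.snp_end)

    @property
    def width(self) -> int:
        return self.snp_end - self.snp_start


def _pair_genotype_table(g: GenotypeMatrix, i: int, j: int) -> np.ndarray:
    """3x3 counts of (dose_i, dose_j) over doubly non-missing samples."""
    d = g.dosage()
    di, dj = d[:, i], d[:, j]
    ok = (di != MISSING) & (dj != MISSING)
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (di[ok], dj[ok]), 1)
    return table


def two_locus_frequencies(table: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """EM haplotype frequencies (2x2: f[x, y], x/y = allele code at locus i/j).

    All cells of the genotype table except the double heterozygote resolve
    into gametes directly; the double heterozygote's mass is split between
    the coupling (00/11) and repulsion (01/10) phases each E-step.
    """
    n2 = 2 * table.sum()
    if n2 == 0:
        raise UndefinedLDError("no doubly non-missing samples")
    # fixed gamete counts from unambiguous genotypes
    base = np.zeros((2, 2))
    for gi in range(3):
        for gj in range(3):
            c = table[gi, gj]
            if c == 0 or (gi == 1 and gj == 1):
                continue
            # each sample contributes 2 gametes with known phase
            ai = [0, 1] if gi == 1 else [gi // 2] * 2
            aj = [0, 1] if gj == 1 else [gj // 2] * 2
            for x, y in zip(ai, aj):
                base[x, y] += c
    dh = table[1, 1]
    f = np.full((2, 2), 0.25)
    for _ in range(max_iter):
        coup = f[0, 0] * f[1, 1]
        rep = f[0, 1] * f[1, 0]
        tot = coup + rep
        w = 0.5 if tot == 0 else coup / tot
        new = base.copy()
        new[0, 0] += dh * w
        new[1, 1] += dh * w
        new[0, 1] += dh * (1 - w)
        new[1, 0] += dh * (1 - w)
        new /= n2
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    return f


def _genotype_probs(f: np.ndarray) -> np.ndarray:
    """3x3 genotype probabilities under random union of gametes."""
    p = np.zeros((3, 3))
    for gi in range(3):
        for gj in range(3):
            if gi == 1 and gj == 1:
                p[gi, gj] = 2 * (f[0, 0] * f[1, 1] + f[0, 1] * f[1, 0])
                continue
            ai = [(0, 1)] if gi == 1 else [(gi // 2, gi // 2)]
            aj = [(0, 1)] if gj == 1 else [(gj // 2, gj // 2)]
            (x1, x2), (y1, y2) = ai[0], aj[0]
            mult = 2 ** ((gi == 1) + (gj == 1))
            p[gi, gj] = mult * f[x1, y1] * f[x2, y2]
    return p


def pairwise_ld(g: GenotypeMatrix, i: int, j: int, grid_points: int = 101) -> PairwiseLD:
    """D', r^2 and the Gabriel-style likelihood CI on D' for one SNP pair.

    The CI profiles the genotype likelihood over ``grid_points`` equally
    spaced D' values in [0, 1] (allele frequencies held at their MLEs, sign
    of D fixed), normalises it to unit mass and reports the 5th and 95th
    cumulative percentiles as one-sided bounds.
    """
    table = _pair_genotype_table(g, i, j)
    f = two_locus_frequencies(table)
    pA = f[0, :].sum()  # allele code 0 at locus i
    pB = f[:, 0].sum()
    if min(pA, 1 - pA) <= 0 or min(pB, 1 - pB) <= 0:
        raise UndefinedLDError(f"monomorphic SNP in pair ({i}, {j})")
    D = f[0, 0] - pA * pB
    if D >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if d_max == 0 else abs(D) / d_max
    d_prime = min(1.0, d_prime)
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    r2 = min(1.0, r2)

    sign = 1.0 if D >= 0 else -1.0
    grid = np.linspace(0.0, 1.0, grid_points)
    loglik = np.empty(grid_points)
    for k, dp in enumerate(grid):
        Dk = sign * dp * d_max
        fk = np.array(
            [
                [pA * pB + Dk, pA * (1 - pB) - Dk],
                [(1 - pA) * pB - Dk, (1 - pA) * (1 - pB) + Dk],
            ]
        )
        fk = np.clip(fk, 0.0, 1.0)
        probs = _genotype_probs(fk)
        obs = table > 0
        if (probs[obs] <= 0).any():
            loglik[k] = -np.inf
        else:
            loglik[k] = float((table[obs] * np.log(probs[obs])).sum())
    loglik -= loglik.max()
    mass = np.exp(loglik)
    mass /= mass.sum()
    cum = np.cumsum(mass)
    ci_low = float(grid[int(np.searchsorted(cum, 0.05))])
    ci_high = float(grid[min(int(np.searchsorted(cum, 0.95)), grid_points - 1)])
    return PairwiseLD(float(d_prime), float(r2), ci_low, ci_high)


def _ld_matrix(g: GenotypeMatrix) -> dict[tuple[int, int], PairwiseLD]:
    out: dict[tuple[int, int], PairwiseLD] = {}
    for i in range(g.n_snps):
        for j in range(i + 1, g.n_snps):
            out[(i, j)] = pairwise_ld(g, i, j)
    return out


def _select_greedy(candidates: list[tuple[int, int]], method: str) -> list[LDBlock]:
    """Longest-first, leftmost-tie-break, non-overlapping selection."""
    chosen: list[tuple[int, int]] = []
    for start, end in sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0])):
        if all(end <= s or start >= e for s, e in chosen):
            chosen.append((start, end))
    return [LDBlock(s, e, method) for s, e in sorted(chosen)]


def gabriel_blocks(
    g: GenotypeMatrix,
    ci_strong_low: float = 0.70,
    ci_strong_high: float = 0.98,
    ci_recomb_high: float = 0.90,
    informative_fraction: float = 0.95,
    max_block_kb: float | None = None,
) -> list[LDBlock]:
    """Confidence-interval blocks after Gabriel et al.

    A pair is *strong LD* when its D' CI satisfies ``ci_high >=
    ci_strong_high`` and ``ci_low >= ci_strong_low``; *strong recombination*
    when ``ci_high < ci_recomb_high``.  A span of >=2 SNPs is a candidate
    block when at least ``informative_fraction`` of its informative pairs
    (strong LD or strong recombination) are strong LD; maximal
    non-overlapping candidates are kept greedily, longest first.
    """
    ld = _ld_matrix(g)
    m = g.n_snps
    strong = {
        k: (v.ci_high >= ci_strong_high and v.ci_low >= ci_strong_low)
        for k, v in ld.items()
    }
    recomb = {k: v.ci_high < ci_recomb_high for k, v in ld.items()}
    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if max_block_kb is not None:
                span_kb = (g.snps[j].position - g.snps[i].position) / 1000.0
                if span_kb > max_block_kb:
                    continue
            pairs = [(a, b) for a in range(i, j + 1) for b in range(a + 1, j + 1)]
            n_strong = sum(strong[p] for p in pairs)
            n_inform = n_strong + sum(recomb[p] and not strong[p] for p in pairs)
            if n_inform == 0:
                continue
            if n_strong / n_inform >= informative_fraction:
                candidates.append((i, j + 1))
    return _select_greedy(candidates, "gabriel")


def four_gamete_blocks(
    g: GenotypeMatrix, min_gamete_freq: float = 0.01
) -> list[LDBlock]:
    """Four-gamete-test blocks.

    A block extends while every SNP pair inside it shows fewer than four
    two-locus gametes at estimated frequency >= ``min_gamete_freq``; it
    breaks where a fourth gamete appears.
    """

    def passes(i: int, j: int) -> bool:
        f = two_locus_frequencies(_pair_genotype_table(g, i, j))
        return int((f >= min_gamete_freq).sum()) < 4

    blocks: list[LDBlock] = []
    m = g.n_snps
    i = 0
    while i < m - 1:
        j = i + 1
        while j < m and all(passes(k, j) for k in range(i, j)):
            j += 1
        if j - i >= 2:
            blocks.append(LDBlock(i, j, "four_gamete"))
            i = j
        else:
            i += 1
    return blocks


def solid_spine_blocks(g: GenotypeMatrix, min_dprime: float = 0.80) -> list[LDBlock]:
    """Solid-spine-of-LD blocks.

    A span qualifies when D' between its first SNP and every later SNP, and
    between its last SNP and every earlier SNP, is >= ``min_dprime``; maximal
    non-overlapping qualifying spans are kept, longest first.
    """
    m = g.n_snps
    dp = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dp[i, j] = dp[j, i] = pairwise_ld(g, i, j).d_prime
    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if all(dp[i, k] >= min_dprime for k in range(i + 1, j + 1)) and all(
                dp[k, j] >= min_dprime for k in range(i, j)
            ):
                candidates.append((i, j + 1))
    return _select_greedy(candidates, "solid_spine")


BLOCK_METHODS = {
    "gabriel": gabriel_blocks,
    "four_gamete": four_gamete_blocks,
    "solid_spine": solid_spine_blocks,
}


def find_blocks(g: GenotypeMatrix, method: str = "gabriel", **kwargs) -> list[LDBlock]:
    try:
        fn = BLOCK_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown block method {method!r}") from None
    return fn(g, **kwargs)


def write_blocks_tsv(g: GenotypeMatrix, blocks: list[LDBlock], path) -> None:
    """Block table: 1-based inclusive bp span plus member SNP ids."""
    with open(path, "w") as fh:
        fh.write("block\tchrom\tstart_bp\tend_bp\tn_snps\tsnp_ids\n")
        for b_id, b in enumerate(blocks, 1):
            snps = [g.snps[j] for j in b.indices()]
            fh.write(
                f"b{b_id}\t{snps[0].chromosome}\t{snps[0].position}\t"
                f"{snps[-1].position}\t{b.width}\t"
                + ",".join(s.id for s in snps)
                + "\n"
            )
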