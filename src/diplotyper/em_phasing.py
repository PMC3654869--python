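"""Multilocus EM haplotype-frequency estimation and per-sample phasing.

Within one LD block, haplotype frequencies are the MLE under random mating
(Hardy-Weinberg pairing of gametes): each sample's likelihood mass is spread
over all haplotype pairs consistent with its unphased (possibly partially
missing) genotypes, proportional to ``2 f_a f_b`` for heterozygous pairs and
``f_a^2`` for homozygous ones.  Samples are grouped by their multilocus
genotype pattern so cohorts of any size cost the same as the number of
distinct patterns.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .genotype_io import MISSING, GenotypeMatrix
from .ld_blocks import LDBlock

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Haplotype:
    alleles: str
    frequency: float


@dataclass(frozen=True)
class SampleDiplotype:
    """Most-likely haplotype pair for one sample (indices into a hap list)."""

    sample_id: str
    hap1: int
    hap2: int
    posterior: float

    def __post_init__(self):
        if self.hap1 > self.hap2:
            raise ValueError("hap1 must be <= hap2")


def _block_codes(g: GenotypeMatrix, block) -> tuple[np.ndarray, list]:
    """Per-sample genotype dose codes over the block SNPs, plus SNP records.

    ``block`` is an :class:`LDBlock` or a plain ``(start, end)`` half-open
    index span — the latter allows single-SNP regions, which LDBlock itself
    excludes.
    """
    if isinstance(block, LDBlock):
        idx = list(block.indices())
    else:
        start, end = block
        idx = list(range(start, end))
    if not idx:
        raise ValueError("empty SNP span")
    d = g.dosage()[:, idx]
    return d, [g.snps[j] for j in idx]


def _haplotype_space(codes: np.ndarray) -> list[tuple[int, ...]]:
    """All allele-code strings in the product of observed allele sets."""
    per_site: list[list[int]] = []
    for s in range(codes.shape[1]):
        col = codes[:, s]
        col = col[col != MISSING]
        alleles = set()
        if (col == 0).any() or (col == 1).any():
            alleles.add(0)
        if (col == 2).any() or (col == 1).any():
            alleles.add(1)
        per_site.append(sorted(alleles) or [0])
    return [tuple(h) for h in itertools.product(*per_site)]


def _consistent_pairs(
    pattern: tuple[int, ...], space: list[tuple[int, ...]]
) -> list[tuple[int, int]]:
    """Unordered haplotype-index pairs consistent with one genotype pattern."""
    pairs = []
    for a in range(len(space)):
        for b in range(a, len(space)):
            ok = True
            for s, gcode in enumerate(pattern):
                if gcode == MISSING:
                    continue
                if space[a][s] + space[b][s] != gcode:
                    ok = False
                    break
            if ok:
                pairs.append((a, b))
    return pairs


def _group_patterns(codes: np.ndarray) -> dict[tuple[int, ...], list[int]]:
    groups: dict[tuple[int, ...], list[int]] = {}
    for i, row in enumerate(codes):
        groups.setdefault(tuple(int(x) for x in row), []).append(i)
    return groups


def em_frequencies(
    g: GenotypeMatrix,
    block: LDBlock,
    tol: float = 1e-8,
    max_iter: int = 1000,
    return_trace: bool = False,
):
    """EM haplotype frequencies for one block.

    Initialisation is uniform over the haplotype space (product of observed
    allele sets) — deterministic, no seed.  Missing genotypes are
    marginalised in the E-step.  Convergence is declared when the largest
    absolute frequency change falls below ``tol``; hitting ``max_iter`` first
    warns with the final delta but still returns.  Returns haplotypes with
    positive final frequency, in descending-frequency order (ties broken by
    allele string); with ``return_trace`` also returns the per-iteration
    log-likelihood, which is non-decreasing.
    """
    codes, snps = _block_codes(g, block)
    space = _haplotype_space(codes)
    H = len(space)
    groups = {
        pat: idxs
        for pat, idxs in _group_patterns(codes).items()
        if any(c != MISSING for c in pat)  # all-missing samples are uninformative
    }
    pair_lists = {pat: _consistent_pairs(pat, space) for pat in groups}

    f = np.full(H, 1.0 / H)
    trace: list[float] = []
    delta = 0.0
    for _ in range(max_iter):
        counts = np.zeros(H)
        loglik = 0.0
        for pat, idxs in groups.items():
            pairs = pair_lists[pat]
            if not pairs:
                continue
            w = np.array([(2 - (a == b)) * f[a] * f[b] for a, b in pairs])
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(pairs), 1.0 / len(pairs))
                tot_ll = -np.inf
            else:
                w = w / tot
                tot_ll = np.log(tot)
            loglik += len(idxs) * tot_ll
            for (a, b), wk in zip(pairs, w):
                counts[a] += len(idxs) * wk
                counts[b] += len(idxs) * wk
        trace.append(loglik)
        if len(trace) >= 2 and np.isfinite(trace[-2]):
            # EM guarantee; tolerate last-bit float noise
            assert trace[-1] >= trace[-2] - 1e-9, "EM log-likelihood decreased"
        new = counts / counts.sum()
        delta = float(np.abs(new - f).max())
        f = new
        if delta < tol:
            break
    else:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations (delta={delta:.2e})",
            stacklevel=2,
        )

    alphabet = [s.alleles for s in snps]
    haps = [
        Haplotype("".join(alphabet[s][h[s]] for s in range(len(snps))), float(f[k]))
        for k, h in enumerate(space)
        if f[k] > 1e-12
    ]
    haps.sort(key=lambda h: (-h.frequency, h.alleles))
    if return_trace:
        return haps, trace
    return haps


def phase_samples(
    g: GenotypeMatrix, block: LDBlock, haps: list[Haplotype]
) -> list[SampleDiplotype]:
    """Assign each sample its most-likely haplotype pair under ``haps``.

    Pairs are scored ``2 f_a f_b`` (heterozygous) or ``f_a^2``; the argmax is
    returned with its normalised posterior, ties broken by the
    lexicographically smallest index pair.  Samples whose block genotypes are
    all missing — or consistent with no positive-frequency pair — are
    omitted.
    """
    codes, snps = _block_codes(g, block)
    alphabet = [s.alleles for s in snps]
    hap_codes = []
    for h in haps:
        hap_codes.append(tuple(alphabet[s].index(ch) for s, ch in enumerate(h.alleles)))
    freqs = np.array([h.frequency for h in haps])

    cache: dict[tuple[int, ...], tuple[int, int, float] | None] = {}
    out: list[SampleDiplotype] = []
    for i, row in enumerate(codes):
        pat = tuple(int(x) for x in row)
        if all(c == MISSING for c in pat):
            continue
        if pat not in cache:
            pairs = _consistent_pairs(pat, hap_codes)
            scores = np.array(
                [(2 - (a == b)) * freqs[a] * freqs[b] for a, b in pairs]
            )
            tot = scores.sum()
            if not pairs or tot <= 0:
                cache[pat] = None
            else:
                best = 0
                for k in range(1, len(pairs)):
                    if scores[k] > scores[best]:
                        best = k  # ties keep the earlier (lex-smaller) pair
                a, b = pairs[best]
                cache[pat] = (a, b, float(scores[best] / tot))
        hit = cache[pat]
        if hit is None:
            logger.warning("sample %s inconsistent with supplied haplotypes", g.samples[i])
            continue
        a, b, post = hit
        out.append(SampleDiplotype(g.samples[i], a, b, post))
    return out


def common_haplotypes(
    haps: list[Haplotype], threshold: float = 0.01
) -> tuple[list[Haplotype], list[Haplotype]]:
    """Split haplotypes into the common set H (frequency > threshold) and the rest.

    H is ordered by descending frequency, ties by allele string; it is the
    set whose nonempty subsets become haplotype clusters downstream.
    """
    common = sorted(
        (h for h in haps if h.frequency > threshold),
        key=lambda h: (-h.frequency, h.alleles),
    )
    rare = sorted(
        (h for h in haps if h.frequency <= threshold),
        key=lambda h: (-h.frequency, h.alleles),
    )
    if not common:
        raise ConfigurationError(
            f"no haplotype exceeds the {threshold} frequency threshold"
        )
    return common, rare


def write_haplotypes_tsv(block_id: int, haps: list[Haplotype], path, append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("block\thaplotype\tfrequency\n")
        for h in haps:
            fh.write(f"b{block_id}\t{h.alleles}\t{h.frequency:.4f}\n")
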