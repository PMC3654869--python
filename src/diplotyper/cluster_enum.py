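"""Exhaustive haplotype-cluster enumeration.

A haplotype cluster is any nonempty subset of a block's common haplotype set
H, treated as a single pseudo-allele.  For |H| = n there are 2^n - 1
clusters; they are enumerated in canonical order — ascending subset size,
then lexicographic order of the member index tuples — and labelled
``b{block}_H{k}`` with k following that order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

from .errors import ClusterSizeError

MAX_HAPLOTYPES = 20


@dataclass(frozen=True)
class HaplotypeCluster:
    """A nonempty subset of H, by sorted member indices."""

    member_indices: tuple[int, ...]
    label: str

    def __post_init__(self):
        if not self.member_indices:
            raise ValueError("a cluster is nonempty")
        if tuple(sorted(set(self.member_indices))) != self.member_indices:
            raise ValueError("member indices must be sorted and unique")

    @property
    def members(self) -> frozenset[int]:
        return frozenset(self.member_indices)

    @property
    def size(self) -> int:
        return len(self.member_indices)


def enumerate_clusters(H: Sequence, block_id: int = 1) -> list[HaplotypeCluster]:
    """All 2^|H| - 1 clusters in size-then-lexicographic order.

    ``H`` only needs a length; members are indices into it.  Refuses |H| >
    20 to guard the exponential blowup.
    """
    n = len(H)
    if n < 1:
        raise ValueError("H must be nonempty")
    if n > MAX_HAPLOTYPES:
        raise ClusterSizeError(
            f"|H| = {n} would enumerate 2^{n} - 1 clusters; limit is {MAX_HAPLOTYPES}"
        )
    out: list[HaplotypeCluster] = []
    k = 1
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            out.append(HaplotypeCluster(combo, f"b{block_id}_H{k}"))
            k += 1
    return out


def write_clusters_tsv(
    clusters: list[HaplotypeCluster], H, path, append: bool = False
) -> None:
    """Cluster table with member haplotype strings and summed frequency."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("label\tmembers\tsummed_frequency\n")
        for c in clusters:
            members = ",".join(H[i].alleles for i in c.member_indices)
            freq = sum(H[i].frequency for i in c.member_indices)
            fh.write(f"{c.label}\t{members}\t{freq:.4f}\n")
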