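"""Diplotype pattern generation and additive 0/1/2 recoding.

A *diplotype pattern* is a tested hypothesis about a haplotype-cluster pair:
either one cluster against the star (every other haplotype, including those
below the frequency threshold) or two disjoint clusters against each other.
Each sample's assigned haplotype pair is recoded into a minor-cluster dose
in {0, 1, 2} — the AA/AB/BB pseudo-genotype fed to regression — or MISSING
when a cluster-versus-cluster pattern does not cover both of the sample's
haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cluster_enum import HaplotypeCluster
from .em_phasing import Haplotype, SampleDiplotype

logger = logging.getLogger(__name__)

MISSING_DOSE = -1


@dataclass(frozen=True)
class DiplotypePattern:
    """cluster1 vs cluster2, or cluster1 vs the star (cluster2 is None)."""

    cluster1: HaplotypeCluster
    cluster2: HaplotypeCluster | None
    kind: str  # "versus_star" | "versus_cluster"

    def __post_init__(self):
        if self.kind == "versus_cluster":
            assert self.cluster2 is not None
            if self.cluster1.members & self.cluster2.members:
                raise ValueError("versus_cluster clusters must be disjoint")
        elif self.kind != "versus_star":
            raise ValueError(f"unknown pattern kind {self.kind!r}")

    @property
    def star_label(self) -> str:
        # b1_H12 -> b1_OH12(*)
        return self.cluster1.label.replace("_H", "_OH") + "(*)"

    @property
    def test_id(self) -> str:
        if self.kind == "versus_star":
            return f"{self.cluster1.label}/{self.star_label}"
        return f"{self.cluster1.label}/{self.cluster2.label}"


@dataclass(frozen=True)
class CodedSample:
    sample_id: str
    dose: int  # 0/1/2 count of cluster1 haplotypes, or MISSING_DOSE


def enumerate_patterns(HS: Sequence[HaplotypeCluster]) -> list[DiplotypePattern]:
    """All diplotype patterns from the cluster enumeration HS.

    One versus-star pattern per cluster (2^n - 1 of them, in HS order),
    followed by every unordered pair of disjoint clusters
    ((3^n - 2^(n+1) + 1) / 2 of them) ordered by size signature then by
    member tuples, the smaller/lex-earlier cluster first.
    """
    patterns = [DiplotypePattern(c, None, "versus_star") for c in HS]
    pairs = []
    for a in range(len(HS)):
        for b in range(a + 1, len(HS)):
            c1, c2 = HS[a], HS[b]
            if c1.members & c2.members:
                continue
            if (c1.size, c1.member_indices) > (c2.size, c2.member_indices):
                c1, c2 = c2, c1
            pairs.append((c1, c2))
    pairs.sort(
        key=lambda p: (p[0].size, p[1].size, p[0].member_indices, p[1].member_indices)
    )
    patterns.extend(DiplotypePattern(c1, c2, "versus_cluster") for c1, c2 in pairs)
    return patterns


def pattern_count(n: int) -> int:
    """Closed-form pattern count for an n-haplotype common set."""
    return (2**n - 1) + (3**n - 2 ** (n + 1) + 1) // 2


def code_samples(
    pattern: DiplotypePattern,
    diplos: Sequence[SampleDiplotype],
    H: Sequence[Haplotype],
    rare: Sequence[Haplotype] = (),
) -> list[CodedSample]:
    """Recode assigned haplotype pairs into cluster1 doses.

    Haplotype indices in ``diplos`` refer to the concatenation ``H + rare``
    (phase with that list).  Versus-star: the star side is everything outside
    cluster1, rare haplotypes included, so every phased sample gets a dose.
    Versus-cluster: a sample counts only when both haplotypes lie in
    cluster1 ∪ cluster2; anyone carrying an outside haplotype is MISSING.
    """
    n_all = len(H) + len(rare)
    c1 = pattern.cluster1.members
    c2 = pattern.cluster2.members if pattern.cluster2 is not None else None
    out = []
    for d in diplos:
        if not (0 <= d.hap1 < n_all and 0 <= d.hap2 < n_all):
            raise IndexError(f"sample {d.sample_id}: haplotype index out of range")
        in1 = (d.hap1 in c1) + (d.hap2 in c1)
        if pattern.kind == "versus_star":
            out.append(CodedSample(d.sample_id, in1))
        else:
            in2 = (d.hap1 in c2) + (d.hap2 in c2)
            if in1 + in2 == 2:
                out.append(CodedSample(d.sample_id, in1))
            else:
                out.append(CodedSample(d.sample_id, MISSING_DOSE))
    return out


@dataclass(frozen=True)
class MinorMajor:
    minor_label: str
    major_label: str
    counts: tuple[int, int, int]  # (minor-homozygote, het, major-homozygote)
    flipped: bool  # True when cluster1 is the major side


def assign_minor_major(
    pattern: DiplotypePattern, coded: Sequence[CodedSample]
) -> MinorMajor:
    """Orient a pattern by dose mass: the side with the smaller haplotype
    dose-sum over included samples is minor.  Counts follow the
    (minor-homo, het, major-homo) triplet convention.  A tie keeps cluster1
    minor, with a logged note.
    """
    doses = np.array([c.dose for c in coded if c.dose != MISSING_DOSE])
    if doses.size == 0:
        raise ValueError("no included samples after MISSING removal")
    side1 = int(doses.sum())  # cluster1 haplotype count
    side2 = int((2 - doses).sum())
    other = pattern.cluster2.label if pattern.cluster2 is not None else pattern.star_label
    if side1 == side2:
        logger.info("minor/major tie for %s; keeping cluster1 minor", pattern.test_id)
    flipped = side1 > side2
    n2, n1, n0 = int((doses == 2).sum()), int((doses == 1).sum()), int((doses == 0).sum())
    if flipped:
        return MinorMajor(other, pattern.cluster1.label, (n0, n1, n2), True)
    return MinorMajor(pattern.cluster1.label, other, (n2, n1, n0), False)


def minor_dose(coded: Sequence[CodedSample], flipped: bool) -> np.ndarray:
    """Minor-cluster dose vector (NaN where MISSING), ordered as ``coded``."""
    d = np.array([c.dose for c in coded], dtype=float)
    d[d == MISSING_DOSE] = np.nan
    return 2.0 - d if flipped else d


def write_pattern_ped_map(
    patterns: Sequence[DiplotypePattern],
    coded_per_pattern: Sequence[Sequence[CodedSample]],
    orientations: Sequence[MinorMajor],
    ped_path,
    map_path,
    chromosome: str = "0",
) -> None:
    """Export each pattern as a pseudo-SNP in PLINK PED/MAP.

    Minor cluster -> allele ``A``, major -> ``B`` (AA/AB/BB), missing doses
    -> ``0 0``; byte-compatible with PLINK for external cross-validation.
    """
    with open(map_path, "w") as fh:
        for k, p in enumerate(patterns, 1):
            fh.write(f"{chromosome}\t{p.test_id}\t0\t{k}\n")
    sample_ids = [c.sample_id for c in coded_per_pattern[0]]
    cols = []
    for coded, mm in zip(coded_per_pattern, orientations):
        d = minor_dose(coded, mm.flipped)
        geno = {0.0: "B B", 1.0: "A B", 2.0: "A A"}
        cols.append(["0 0" if np.isnan(x) else geno[x] for x in d])
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(sample_ids):
            fh.write(
                f"{sid} {sid} 0 0 0 -9 " + " ".join(col[i] for col in cols) + "\n"
            )
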