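"""Genotype and phenotype I/O plus SNP quality-control filters.

Genotypes travel as a :class:`GenotypeMatrix`: per-sample, per-SNP unordered
allele pairs with explicit missingness, read from PLINK PED/MAP text (or,
optionally, VCF).  Phenotypes and covariates travel as a
:class:`PhenotypeTable` backed by a pandas DataFrame keyed by sample id.

QC follows the standard GWAS triple filter: call rate, minor allele
frequency, and an exact Hardy-Weinberg-equilibrium test — the exact test
matters because the conventional 1e-6 alpha sits far in the tail where the
chi-square approximation is unreliable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, FormatError

logger = logging.getLogger(__name__)

MISSING = -1  # allele / genotype code for a missing call


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP locus.

    ``allele_a`` / ``allele_b`` are the two observed allele characters in
    alphabetical order; ``allele_b`` is ``None`` for a monomorphic locus
    (such loci never survive the MAF filter).
    """

    id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str | None

    def __post_init__(self):
        if self.allele_b is not None and self.allele_a == self.allele_b:
            raise DataError(f"SNP {self.id}: identical alleles {self.allele_a!r}")
        if self.position < 0:
            raise DataError(f"SNP {self.id}: negative position")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.allele_a,) if self.allele_b is None else (self.allele_a, self.allele_b)


@dataclass
class GenotypeMatrix:
    """Unphased genotype calls for ``n`` samples at ``m`` ordered SNPs.

    ``calls`` has shape ``(n, m, 2)`` with entries 0 (= ``allele_a``),
    1 (= ``allele_b``) or -1 (missing); the pair is stored sorted so the
    genotype is unordered.  SNPs are ordered by (chromosome, position).
    """

    samples: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps), 2):
            raise DataError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        # canonicalize: sorted allele pair; half-calls collapse to MISSING
        self.calls = np.sort(self.calls, axis=2)
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING
        if len({s.id for s in self.snps}) != len(self.snps):
            raise DataError("duplicate SNP ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def dosage(self) -> np.ndarray:
        """(n, m) count of ``allele_b`` per call; -1 where missing."""
        d = self.calls.sum(axis=2, dtype=np.int16)
        d[(self.calls == MISSING).any(axis=2)] = MISSING
        return d.astype(np.int8)

    def call_rate(self, j: int) -> float:
        ok = (self.calls[:, j, :] != MISSING).all(axis=1)
        return float(ok.mean()) if self.n_samples else 0.0

    def allele_counts(self, j: int) -> tuple[int, int]:
        """Counts of (allele_a, allele_b) over non-missing calls at SNP j."""
        col = self.calls[:, j, :]
        col = col[(col != MISSING).all(axis=1)]
        return int((col == 0).sum()), int((col == 1).sum())

    def maf(self, j: int) -> float:
        a, b = self.allele_counts(j)
        tot = a + b
        return min(a, b) / tot if tot else 0.0

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(hom allele_a, het, hom allele_b) over non-missing calls."""
        d = self.calls[:, j, :].sum(axis=1)
        ok = (self.calls[:, j, :] != MISSING).all(axis=1)
        d = d[ok]
        return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[j] for j in idx],
            calls=self.calls[:, idx, :].copy(),
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            snps=list(self.snps),
            calls=self.calls[idx, :, :].copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PhenotypeTable:
    """Trait + covariates keyed by sample id.

    ``data`` is a DataFrame indexed by sample id with a ``trait`` column and
    one column per covariate; unparseable cells are NaN (missing).
    """

    data: pd.DataFrame
    trait_name: str
    covariate_names: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def trait(self) -> pd.Series:
        return self.data["trait"]

    def covariates(self) -> pd.DataFrame:
        return self.data[self.covariate_names]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        return (
            self.trait_name == other.trait_name
            and self.covariate_names == other.covariate_names
            and self.data.shape == other.data.shape
            and list(self.data.index) == list(other.data.index)
            and bool(
                ((self.data == other.data) | (self.data.isna() & other.data.isna()))
                .all()
                .all()
            )
        )


# ---------------------------------------------------------------------------
# PED/MAP


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a :class:`GenotypeMatrix`.

    PED rows carry 6 leading pedigree fields (family id, individual id,
    father, mother, sex, phenotype — only the individual id is used) then two
    allele characters per MAP SNP; ``0`` marks a missing allele and a
    half-called pair collapses to a fully missing call.  Alleles per SNP are
    inferred from the observed characters; more than two raises
    :class:`DataError`.
    """
    map_rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{map_path}: line {ln}: expected >=4 MAP columns")
        map_rows.append((parts[0], parts[1], int(parts[3])))
    m = len(map_rows)

    samples: list[str] = []
    raw_calls: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise FormatError(
                f"{ped_path}: line {ln}: expected {6 + 2 * m} columns "
                f"({m} SNPs), found {len(parts)}"
            )
        samples.append(parts[1])
        raw_calls.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
        )

    snps: list[SnpRecord] = []
    calls = np.full((len(samples), m, 2), MISSING, dtype=np.int8)
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        observed = sorted(
            {a for row in raw_calls for a in row[j] if a != "0"}
        )
        if len(observed) > 2:
            raise DataError(
                f"SNP {snp_id}: more than 2 alleles observed: {observed}"
            )
        allele_a = observed[0] if observed else "A"
        allele_b = observed[1] if len(observed) == 2 else None
        snps.append(SnpRecord(snp_id, chrom, pos, allele_a, allele_b))
        code = {allele_a: 0}
        if allele_b is not None:
            code[allele_b] = 1
        for i, row in enumerate(raw_calls):
            a1, a2 = row[j]
            if a1 != "0" and a2 != "0":
                calls[i, j, 0] = code[a1]
                calls[i, j, 1] = code[a2]

    g = GenotypeMatrix(samples, snps, calls)
    return sort_snps(g)


def sort_snps(g: GenotypeMatrix) -> GenotypeMatrix:
    """Order SNPs by (chromosome, position), stably."""
    order = sorted(range(g.n_snps), key=lambda j: (g.snps[j].chromosome, g.snps[j].position))
    if order == list(range(g.n_snps)):
        return g
    return g.subset_snps(order)


def write_ped_map(g: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PLINK text PED/MAP (family id = individual id; phenotype -9)."""
    with open(map_path, "w") as fh:
        for s in g.snps:
            fh.write(f"{s.chromosome}\t{s.id}\t0\t{s.position}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.samples):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j, s in enumerate(g.snps):
                pair = g.calls[i, j]
                if pair[0] == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [s.alleles[pair[0]], s.alleles[pair[1]]]
            fh.write(" ".join(fields) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF via pysam; phase separators are ignored.

    Multi-allelic or non-SNP records are skipped with a logged count.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        ref, alt = rec.ref, alts[0]
        allele_a, allele_b = sorted((ref, alt))
        # VCF codes 0=ref, 1=alt; remap to alphabetical internal codes
        remap = {0: 0 if ref == allele_a else 1, 1: 0 if alt == allele_a else 1}
        col = np.full((len(samples), 2), MISSING, dtype=np.int8)
        for i, sample in enumerate(rec.samples.values()):
            gt = sample.get("GT")
            if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                continue
            col[i, 0] = remap[gt[0]]
            col[i, 1] = remap[gt[1]]
        snps.append(
            SnpRecord(rec.id or f"{rec.chrom}:{rec.pos}", rec.chrom, rec.pos, allele_a, allele_b)
        )
        columns.append(col)
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", skipped)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0, 2), dtype=np.int8)
    )
    return sort_snps(GenotypeMatrix(samples, snps, calls))


# ---------------------------------------------------------------------------
# QC filters


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on allele counts, sums the probabilities of all heterozygote
    counts no more likely than the observed one (the standard exact test of
    Wigginton, Cutler & Abecasis).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # possible het counts share the parity of n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    if len(hets) == 0:
        return 1.0
    log_p = np.zeros(len(hets))
    # recurrence upward in het: p(h+2)/p(h) = 4*hr*hc / ((h+2)(h+1))
    for k in range(1, len(hets)):
        h = hets[k - 1]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        log_p[k] = log_p[k - 1] + np.log(4.0 * hom_r * hom_c) - np.log(
            (h + 2.0) * (h + 1.0)
        )
    log_p -= log_p.max()
    probs = np.exp(log_p)
    probs /= probs.sum()
    obs = np.searchsorted(hets, n_het)
    p = probs[probs <= probs[obs] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def filter_snps(
    g: GenotypeMatrix,
    min_call: float = 0.95,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-6,
) -> GenotypeMatrix:
    """Apply the call-rate / MAF / HWE triple filter, keeping sample set fixed.

    A SNP is retained iff call rate >= ``min_call``, MAF >= ``min_maf``
    (computed over non-missing calls) and the exact HWE p-value >=
    ``hwe_alpha``.  Emits a warning (never an error) when nothing survives.
    """
    keep = []
    for j in range(g.n_snps):
        if g.call_rate(j) < min_call:
            continue
        if g.maf(j) < min_maf:
            continue
        hom_a, het, hom_b = g.genotype_counts(j)
        if hwe_exact_p(het, hom_a, hom_b) < hwe_alpha:
            continue
        keep.append(j)
    if not keep:
        warnings.warn("filter_snps: no SNPs pass QC", stacklevel=2)
    logger.info("filter_snps: kept %d of %d SNPs", len(keep), g.n_snps)
    return g.subset_snps(keep)


# ---------------------------------------------------------------------------
# Phenotypes


def read_phenotypes(
    path: str | Path,
    trait_name: str,
    covariate_names: Iterable[str] = (),
    sample_col: str = "sample_id",
) -> PhenotypeTable:
    """Read a header-bearing TSV of trait + covariates keyed by sample id.

    Unparseable numeric cells (``NA``, blanks, text) become missing.
    """
    covariate_names = list(covariate_names)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    for col in [sample_col, trait_name, *covariate_names]:
        if col not in df.columns:
            raise ConfigurationError(f"phenotype file {path}: missing column {col!r}")
    out = pd.DataFrame(index=df[sample_col].astype(str))
    out.index.name = "sample_id"
    out["trait"] = pd.to_numeric(df[trait_name], errors="coerce").to_numpy()
    for c in covariate_names:
        out[c] = pd.to_numeric(df[c], errors="coerce").to_numpy()
    return PhenotypeTable(out, trait_name, covariate_names)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    df = table.data.rename(columns={"trait": table.trait_name})
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def align_samples(
    g: GenotypeMatrix, table: PhenotypeTable
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Restrict both sides to the id intersection, preserving genotype order."""
    pheno_ids = set(table.sample_ids)
    keep = [i for i, s in enumerate(g.samples) if s in pheno_ids]
    dropped = g.n_samples - len(keep) + len(pheno_ids - set(g.samples))
    if dropped:
        logger.info("align_samples: dropped %d unmatched samples", dropped)
    g2 = g.subset_samples(keep)
    data = table.data.loc[[g.samples[i] for i in keep]]
    return g2, PhenotypeTable(data, table.trait_name, list(table.covariate_names))
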