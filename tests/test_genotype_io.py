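import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import diplotyper as dt
from diplotyper.errors import ConfigurationError, DataError, FormatError
from diplotyper.genotype_io import MISSING, hwe_exact_p

from conftest import matrix_from_pairs


def write_files(tmp_path, ped_text, map_text):
    ped = tmp_path / "x.ped"
    mp = tmp_path / "x.map"
    ped.write_text(ped_text)
    mp.write_text(map_text)
    return ped, mp


MAP3 = "1 snp1 0 1000\n1 snp2 0 2000\n1 snp3 0 3000\n"


class TestReadPedMap:
    def test_direct_parse(self, tmp_path):
        ped, mp = write_files(
            tmp_path, "F1 S1 0 0 1 -9 A A G A C C\n", MAP3
        )
        g = dt.read_ped_map(ped, mp)
        assert g.samples == ["S1"]
        assert [s.id for s in g.snps] == ["snp1", "snp2", "snp3"]
        # unordered pairs, canonical sorted codes
        assert g.dosage().tolist() == [[0, 1, 0]]  # A/A, A/G, C/C vs inferred alleles

    def test_zero_zero_is_missing(self, tmp_path):
        ped, mp = write_files(
            tmp_path, "F1 S1 0 0 1 -9 A A 0 0 C C\nF1 S2 0 0 1 -9 A A G G C T\n", MAP3
        )
        g = dt.read_ped_map(ped, mp)
        assert g.dosage()[0, 1] == MISSING

    def test_half_call_is_missing(self, tmp_path):
        ped, mp = write_files(
            tmp_path, "F1 S1 0 0 1 -9 A 0 G G C C\nF1 S2 0 0 1 -9 A A G G C T\n", MAP3
        )
        g = dt.read_ped_map(ped, mp)
        assert g.dosage()[0, 0] == MISSING

    def test_column_count_mismatch_names_line(self, tmp_path):
        ped, mp = write_files(
            tmp_path, "F1 S1 0 0 1 -9 A A G A C C\nF1 S2 0 0 1 -9 A A G A\n", MAP3
        )
        with pytest.raises(FormatError, match="line 2"):
            dt.read_ped_map(ped, mp)

    def test_three_alleles_rejected(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            "F1 S1 0 0 1 -9 A A G A C C\nF1 S2 0 0 1 -9 A T G A C C\n"
            "F1 S3 0 0 1 -9 A C G A C C\n",
            MAP3,
        )
        with pytest.raises(DataError, match="snp1"):
            dt.read_ped_map(ped, mp)

    def test_snps_sorted_by_position(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            "F1 S1 0 0 1 -9 A A G A C C\n",
            "1 snp1 0 3000\n1 snp2 0 1000\n1 snp3 0 2000\n",
        )
        g = dt.read_ped_map(ped, mp)
        assert [s.id for s in g.snps] == ["snp2", "snp3", "snp1"]

    def test_round_trip_identity(self, tmp_path, rng):
        haps = ["ACT", "GCT", "ATC"]
        pairs = [
            (haps[rng.integers(3)], haps[rng.integers(3)]) for _ in range(10)
        ]
        g = matrix_from_pairs(pairs)
        g.calls[3, 1] = MISSING  # inject a missing call
        dt.write_ped_map(g, tmp_path / "rt.ped", tmp_path / "rt.map")
        g2 = dt.read_ped_map(tmp_path / "rt.ped", tmp_path / "rt.map")
        assert g2 == g


class TestVcf:
    def test_read_vcf_matches_ped(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t1000\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t1|1\n"
            "1\t2000\trs2\tC\tT\t.\t.\t.\tGT\t./.\t0/0\n"
        )
        g = dt.read_vcf(vcf)
        assert g.samples == ["S1", "S2"]
        assert g.dosage().tolist() == [[1, MISSING], [2, 0]]


class TestFilterSnps:
    def build(self, rng, call_rates=(1.0, 1.0), mafs=(0.3, 0.3), n=200):
        pairs = []
        for i in range(n):
            h1 = "".join("B" if rng.random() < m else "A" for m in mafs)
            h2 = "".join("B" if rng.random() < m else "A" for m in mafs)
            pairs.append((h1, h2))
        g = matrix_from_pairs(pairs)
        for j, cr in enumerate(call_rates):
            miss = rng.choice(n, size=int(round(n * (1 - cr))), replace=False)
            g.calls[miss, j] = MISSING
        return g

    def test_low_call_rate_removed(self, rng):
        g = self.build(rng, call_rates=(0.94, 1.0))
        kept = dt.filter_snps(g)
        assert [s.id for s in kept.snps] == ["snp2"]

    def test_monomorphic_removed(self):
        # site 1 is all-A (MAF 0), site 2 polymorphic at HWE-ish counts
        g = matrix_from_pairs(
            [("AC", "AC")] * 30 + [("AC", "AT")] * 45 + [("AT", "AT")] * 25
        )
        kept = dt.filter_snps(g, hwe_alpha=0)
        assert [s.id for s in kept.snps] == ["snp2"]

    def test_hwe_outlier_removed(self):
        # all heterozygotes: extreme HWE violation
        g = matrix_from_pairs([("A", "B")] * 500)
        assert hwe_exact_p(500, 0, 0) < 1e-6
        kept = dt.filter_snps(g)
        assert kept.n_snps == 0

    def test_idempotent_and_subset(self, rng):
        g = self.build(rng, call_rates=(0.9, 1.0), mafs=(0.3, 0.2))
        once = dt.filter_snps(g)
        twice = dt.filter_snps(once)
        assert once.n_snps == 1
        assert once == twice
        assert {s.id for s in once.snps} <= {s.id for s in g.snps}

    def test_empty_result_warns(self, rng):
        g = self.build(rng, call_rates=(0.5, 0.5))
        with pytest.warns(UserWarning, match="no SNPs pass"):
            out = dt.filter_snps(g)
        assert out.n_snps == 0 and out.n_samples == g.n_samples

    def test_hwe_null_retention(self):
        """A SNP drawn exactly at HWE should essentially never hit p < 1e-6."""
        rng = np.random.default_rng(42)
        retained = 0
        reps = 1000
        for _ in range(reps):
            p_allele = 0.3
            doses = rng.binomial(2, p_allele, size=1000)
            het = int((doses == 1).sum())
            hom1 = int((doses == 2).sum())
            hom2 = int((doses == 0).sum())
            if hwe_exact_p(het, hom1, hom2) >= 1e-6:
                retained += 1
        assert retained >= 999

    def test_exact_p_matches_enumeration(self):
        """Small-count exact p agrees with direct enumeration of the
        conditional distribution."""
        def brute(het, hom1, hom2):
            n = het + hom1 + hom2
            nr = 2 * min(hom1, hom2) + het
            probs = {}
            for h in range(nr % 2, min(nr, 2 * n - nr) + 1, 2):
                r = (nr - h) // 2
                c = n - h - r
                # P(h) propto n! / (r! h! c!) * 2^h
                from math import factorial

                probs[h] = factorial(n) / (
                    factorial(r) * factorial(h) * factorial(c)
                ) * 2**h
            tot = sum(probs.values())
            obs = probs[het]
            return sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / tot

        for het, h1, h2 in [(5, 2, 13), (0, 5, 5), (10, 0, 10), (3, 3, 3)]:
            assert hwe_exact_p(het, h1, h2) == pytest.approx(brute(het, h1, h2), rel=1e-9)


class TestPhenotypes:
    def test_parse_and_missing(self, tmp_path):
        f = tmp_path / "p.tsv"
        f.write_text(
            "sample_id\tHDL\tage\tsex\tbmi\nS1\t1.2\t40\t1\t24.4\nS2\tNA\t50\t0\t22.0\n"
        )
        t = dt.read_phenotypes(f, "HDL", ["age", "sex", "bmi"])
        assert t.data.loc["S1", "trait"] == pytest.approx(1.2)
        assert list(t.data.loc["S1", ["age", "sex", "bmi"]]) == [40, 1, 24.4]
        assert np.isnan(t.data.loc["S2", "trait"])

    def test_missing_column_errors(self, tmp_path):
        f = tmp_path / "p.tsv"
        f.write_text("sample_id\tHDL\nS1\t1.2\n")
        with pytest.raises(ConfigurationError, match="age"):
            dt.read_phenotypes(f, "HDL", ["age"])

    def test_round_trip(self, tmp_path, rng):
        f = tmp_path / "p.tsv"
        f.write_text(
            "sample_id\tHDL\tage\nS1\t1.2\t40\nS2\tNA\t50\nS3\t0.9\tNA\n"
        )
        t = dt.read_phenotypes(f, "HDL", ["age"])
        dt.write_phenotypes(t, tmp_path / "q.tsv")
        t2 = dt.read_phenotypes(tmp_path / "q.tsv", "HDL", ["age"])
        assert t == t2

    def test_align_samples_drops_unmatched(self, tmp_path):
        g = matrix_from_pairs([("A", "B"), ("A", "A"), ("B", "B")], ids=["S1", "S2", "S3"])
        f = tmp_path / "p.tsv"
        f.write_text("sample_id\tHDL\nS2\t1.0\nS3\t1.1\nS9\t1.2\n")
        t = dt.read_phenotypes(f, "HDL")
        g2, t2 = dt.align_samples(g, t)
        assert g2.samples == ["S2", "S3"]
        assert t2.sample_ids == ["S2", "S3"]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 2), st.integers(0, 2)),
        min_size=4,
        max_size=30,
    )
)
def test_ped_round_trip_property(geno):
    """write -> read is the identity for arbitrary small genotype matrices."""
    strings = {0: "AA", 1: "AG", 2: "GG"}
    pairs = [(strings[a][0] + strings[b][0], strings[a][1] + strings[b][1]) for a, b in geno]
    g = matrix_from_pairs(pairs)
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        d = pathlib.Path(d)
        dt.write_ped_map(g, d / "a.ped", d / "a.map")
        assert dt.read_ped_map(d / "a.ped", d / "a.map") == g
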