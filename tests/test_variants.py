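"""Variant-file dialects, parse accounting and indel normalization."""

import gzip

import numpy as np
import pytest

from exomesieve.fixtures import FixtureSpec, generate_fixture
from exomesieve.genome import GenomeSequence
from exomesieve.variants import (
    DELETION,
    HET,
    HOM,
    INSERTION,
    ReferenceMismatchError,
    SNV,
    UNKNOWN,
    VariantRecord,
    apply_edit,
    normalize_indel,
    read_variants,
    write_vcf,
)

VCF_HEADER = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestVcfDialect:
    def test_simple_het_snv(self, tmp_path):
        p = _write(tmp_path, "a.vcf",
                   VCF_HEADER + "chr1\t101\t.\tA\tG\t.\t.\t.\tGT\t0/1\n")
        (rec,), summary = read_variants(p, "vcf", "S1")
        assert (rec.contig, rec.pos, rec.ref_allele, rec.alt_allele) == (
            "chr1", 101, "A", "G")
        assert rec.var_class == SNV and rec.zygosity == HET
        assert (summary.n_input, summary.n_unavailable) == (1, 0)

    def test_anchored_deletion_strips_to_pure_form(self, tmp_path):
        p = _write(tmp_path, "a.vcf",
                   VCF_HEADER + "chr1\t101\t.\tAT\tA\t.\t.\t.\tGT\t1/1\n")
        (rec,), _ = read_variants(p, "vcf", "S1")
        assert rec.var_class == DELETION and rec.zygosity == HOM
        assert (rec.pos, rec.ref_allele, rec.alt_allele) == (102, "T", "")

    def test_anchored_insertion(self, tmp_path):
        p = _write(tmp_path, "a.vcf",
                   VCF_HEADER + "chr1\t101\t.\tA\tACG\t.\t.\t.\tGT\t0/1\n")
        (rec,), _ = read_variants(p, "vcf", "S1")
        assert rec.var_class == INSERTION
        assert (rec.pos, rec.alt_allele) == (102, "CG")

    def test_multiallelic_split_with_genotype(self, tmp_path):
        p = _write(tmp_path, "a.vcf",
                   VCF_HEADER + "chr1\t50\t.\tA\tG,T\t.\t.\t.\tGT\t1/2\n")
        recs, _ = read_variants(p, "vcf", "S1")
        assert [(r.alt_allele, r.zygosity) for r in recs] == [
            ("G", HET), ("T", HET)]

    def test_uncarried_alt_not_emitted(self, tmp_path):
        p = _write(tmp_path, "a.vcf",
                   VCF_HEADER + "chr1\t50\t.\tA\tG,T\t.\t.\t.\tGT\t1/1\n")
        recs, _ = read_variants(p, "vcf", "S1")
        assert [(r.alt_allele, r.zygosity) for r in recs] == [("G", HOM)]

    def test_no_genotype_means_unknown(self, tmp_path):
        p = _write(tmp_path, "a.vcf",
                   "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                   "chr1\t5\t.\tC\tT\t.\t.\tDP=31\n")
        (rec,), _ = read_variants(p, "vcf", "S1")
        assert rec.zygosity == UNKNOWN and rec.support == 31

    def test_malformed_lines_counted_not_fatal(self, tmp_path):
        good = "chr1\t{}\t.\tA\tG\t.\t.\t.\tGT\t0/1\n"
        lines = [good.format(100 + i) for i in range(8)]
        lines.insert(3, "chr1\tnotanumber\t.\tA\tG\t.\t.\t.\tGT\t0/1\n")
        lines.insert(7, "chr1\t500\t.\tA\t<DEL>\t.\t.\t.\tGT\t0/1\n")
        p = _write(tmp_path, "a.vcf", VCF_HEADER + "".join(lines))
        recs, summary = read_variants(p, "vcf", "S1")
        assert (summary.n_input, summary.n_unavailable, summary.n_effective) \
            == (10, 2, 8)
        assert len(recs) == 8

    def test_gzip_input_accepted(self, tmp_path):
        p = tmp_path / "a.vcf.gz"
        with gzip.open(p, "wt") as out:
            out.write(VCF_HEADER + "chr1\t101\t.\tA\tG\t.\t.\t.\tGT\t0/1\n")
        recs, _ = read_variants(p, "vcf", "S1")
        assert len(recs) == 1

    def test_contig_alias_applied(self, tmp_path):
        p = _write(tmp_path, "a.vcf",
                   VCF_HEADER + "1\t101\t.\tA\tG\t.\t.\t.\tGT\t0/1\n")
        (rec,), _ = read_variants(p, "vcf", "S1", contig_alias={"1": "chr1"})
        assert rec.contig == "chr1"


class TestPileupDialect:
    def test_het_snv_iupac(self, tmp_path):
        # ref A, consensus R = A/G -> het A>G
        p = _write(tmp_path, "a.pileup",
                   "chr1\t101\tA\tR\t40\t40\t60\t25\t.\t.\n")
        (rec,), _ = read_variants(p, "pileup", "S1")
        assert (rec.alt_allele, rec.zygosity, rec.support) == ("G", HET, 25)

    def test_hom_snv(self, tmp_path):
        p = _write(tmp_path, "a.pileup",
                   "chr1\t101\tA\tG\t40\t40\t60\t25\t.\t.\n")
        (rec,), _ = read_variants(p, "pileup", "S1")
        assert (rec.alt_allele, rec.zygosity) == ("G", HOM)

    def test_two_nonref_alleles(self, tmp_path):
        # ref T, consensus M = A/C: two het records
        p = _write(tmp_path, "a.pileup",
                   "chr1\t101\tT\tM\t40\t40\t60\t25\t.\t.\n")
        recs, _ = read_variants(p, "pileup", "S1")
        assert sorted(r.alt_allele for r in recs) == ["A", "C"]
        assert all(r.zygosity == HET for r in recs)

    def test_het_insertion(self, tmp_path):
        p = _write(tmp_path, "a.pileup",
                   "chr1\t101\t*\t+AG/*\t40\t40\t60\t25\t.\t.\n")
        (rec,), _ = read_variants(p, "pileup", "S1")
        assert rec.var_class == INSERTION and rec.zygosity == HET
        assert (rec.pos, rec.alt_allele) == (102, "AG")

    def test_hom_deletion(self, tmp_path):
        p = _write(tmp_path, "a.pileup",
                   "chr1\t101\t*\t-CA/-CA\t40\t40\t60\t25\t.\t.\n")
        (rec,), _ = read_variants(p, "pileup", "S1")
        assert rec.var_class == DELETION and rec.zygosity == HOM
        assert (rec.pos, rec.ref_allele) == (102, "CA")


class TestSoapsnpDialect:
    def test_het_snv(self, tmp_path):
        cols = ["chr1", "101", "A", "R", "35", "G", "30", "5", "6", "A",
                "28", "4", "5", "11", "1.0", "1.0", "1"]
        p = _write(tmp_path, "a.soap", "\t".join(cols) + "\n")
        (rec,), _ = read_variants(p, "soapsnp", "S1")
        assert (rec.alt_allele, rec.zygosity, rec.support) == ("G", HET, 11)


class TestNormalizeIndel:
    GENOME = GenomeSequence({"c": "GGCAAAAGTT"})  # A-run at 1-based 4..7

    def test_deletion_left_aligned_through_run(self):
        v = VariantRecord(contig="c", pos=7, ref_allele="A", alt_allele="",
                          var_class=DELETION)
        n = normalize_indel(v, self.GENOME)
        assert (n.pos, n.ref_allele) == (4, "A")

    def test_insertion_without_repeat_unchanged(self):
        v = VariantRecord(contig="c", pos=9, ref_allele="", alt_allele="AC",
                          var_class=INSERTION)
        n = normalize_indel(v, self.GENOME)
        assert (n.pos, n.alt_allele) == (9, "AC")

    def test_idempotent(self):
        v = VariantRecord(contig="c", pos=7, ref_allele="A", alt_allele="",
                          var_class=DELETION)
        once = normalize_indel(v, self.GENOME)
        assert normalize_indel(once, self.GENOME) == once

    def test_reference_mismatch_raises(self):
        v = VariantRecord(contig="c", pos=7, ref_allele="T", alt_allele="",
                          var_class=DELETION)
        with pytest.raises(ReferenceMismatchError):
            normalize_indel(v, self.GENOME)

    @pytest.mark.parametrize("seed", range(10))
    def test_haplotype_equivalence_brute_force(self, seed):
        """Two indels normalize to the same key iff applying them to the
        reference yields identical haplotypes (checked on 50 bp windows)."""
        rng = np.random.default_rng(seed)
        bases = "ACGT"
        window = "".join(bases[i] for i in rng.integers(0, 4, size=50))
        # bias towards runs so shifts actually happen
        window = window[:10] + "AAAA" + window[14:30] + "CGCGCG" + window[36:]
        genome = GenomeSequence({"w": window})
        variants = []
        for _ in range(40):
            length = int(rng.integers(1, 5))
            pos = int(rng.integers(2, 50 - length))
            if rng.random() < 0.5:
                variants.append(VariantRecord(
                    contig="w", pos=pos,
                    ref_allele=window[pos - 1:pos - 1 + length],
                    alt_allele="", var_class=DELETION))
            else:
                seq = "".join(bases[i] for i in rng.integers(0, 4, size=length))
                variants.append(VariantRecord(
                    contig="w", pos=pos, ref_allele="", alt_allele=seq,
                    var_class=INSERTION))
        for i, a in enumerate(variants):
            na = normalize_indel(a, genome)
            # normalization preserves the haplotype
            assert apply_edit(window, 0, a) == apply_edit(window, 0, na)
            for b in variants[i + 1:]:
                nb = normalize_indel(b, genome)
                same_hap = apply_edit(window, 0, a) == apply_edit(window, 0, b)
                same_key = na.key() == nb.key()
                assert same_key == same_hap, (a, b)


class TestVcfRoundTrip:
    def test_records_survive_write_read(self, tmp_path, single_fixture):
        fx = single_fixture
        records = fx.samples["CASE1"]
        path = tmp_path / "out.vcf"
        write_vcf(records, fx.genome, path, sample_id="CASE1")
        back, summary = read_variants(path, "vcf", "CASE1")
        assert summary.n_unavailable == 0
        orig = sorted((r.key(), r.zygosity) for r in records)
        got = sorted((r.key(), r.zygosity) for r in back)
        assert got == orig

    def test_written_vcf_is_standards_valid(self, tmp_path, single_fixture):
        pysam = pytest.importorskip("pysam")
        fx = single_fixture
        path = tmp_path / "out.vcf"
        write_vcf(fx.samples["CASE1"], fx.genome, path, sample_id="CASE1")
        with pysam.VariantFile(str(path)) as vf:
            n = sum(1 for _ in vf)
        assert n == len({r.key() for r in fx.samples["CASE1"]})
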