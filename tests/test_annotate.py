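"""Functional classification, representative selection and novelty."""

import numpy as np
import pytest

from exomesieve.annotate import (
    Annotator,
    KnownVariantDB,
    classify_indel,
    classify_snv,
    gene_term_join,
    lookup_known,
    read_gene_terms,
    severity_rank,
)
from exomesieve.fixtures import random_transcript
from exomesieve.genome import Transcript, cds_offset_to_genomic, spliced_cds
from exomesieve.variants import (
    DELETION,
    INSERTION,
    ReferenceMismatchError,
    SNV,
    VariantRecord,
)

from oracles import oracle_classify_indel, oracle_classify_snv


def _snv(contig, pos, ref, alt, **kw):
    return VariantRecord(contig=contig, pos=pos, ref_allele=ref,
                         alt_allele=alt, var_class=SNV, **kw)


def _find_codon(genome, t, target_codon):
    """1-based genomic positions (in coding order) of a CDS codon equal to
    target_codon, searching all codons of the transcript."""
    cds = spliced_cds(t, genome)
    for ci in range(len(cds) // 3):
        if cds[3 * ci:3 * ci + 3] == target_codon:
            return ci, [cds_offset_to_genomic(t, 3 * ci + j) + 1
                        for j in range(3)]
    return None, None


def _first_transcript_with_codon(codon, start_seed=0):
    for seed in range(start_seed, start_seed + 80):
        rng = np.random.default_rng(seed)
        genome, t = random_transcript(rng)
        ci, positions = _find_codon(genome, t, codon)
        if ci is not None and 0 < ci < t.cds_length // 3 - 1:
            return genome, t, ci, positions
    raise AssertionError(f"no transcript containing codon {codon}")


class TestClassifySnv:
    def test_cys_to_stop_is_nonsense(self):
        """TGC (Cys) with its third base edited to A becomes TGA (stop)."""
        genome, t, ci, positions = _first_transcript_with_codon("TGC")
        pos = positions[2]
        ref = genome.base(t.contig, pos)
        alt = "A" if t.strand == "+" else "T"
        ann = classify_snv(_snv(t.contig, pos, ref, alt), t, genome)
        assert ann.category == "nonsense"
        assert ann.aa_change == f"p.Cys{ci + 1}Ter"
        assert ann.codon_change == "TGC>TGA"

    def test_stop_taa_to_gln_is_read_through(self):
        """TAA edited at its first base to CAA (Gln) reads through."""
        for seed in range(200):
            rng = np.random.default_rng(seed)
            genome, t = random_transcript(rng)
            cds = spliced_cds(t, genome)
            if cds[-3:] != "TAA":
                continue
            off = t.cds_length - 3
            pos = cds_offset_to_genomic(t, off) + 1
            ref = genome.base(t.contig, pos)
            alt = "C" if t.strand == "+" else "G"
            ann = classify_snv(_snv(t.contig, pos, ref, alt), t, genome)
            assert ann.category == "read_through"
            assert ann.codon_change == "TAA>CAA"
            return
        raise AssertionError("no TAA-terminated transcript found")

    def test_wobble_synonymous(self):
        """GCT -> GCC stays Ala."""
        genome, t, ci, positions = _first_transcript_with_codon("GCT")
        pos = positions[2]
        ref = genome.base(t.contig, pos)
        alt = "C" if t.strand == "+" else "G"
        ann = classify_snv(_snv(t.contig, pos, ref, alt), t, genome)
        assert ann.category == "syn_code"
        assert ann.aa_change == f"p.Ala{ci + 1}Ala"

    def test_start_codon_loss_flagged_missense(self):
        rng = np.random.default_rng(5)
        genome, t = random_transcript(rng)
        pos = cds_offset_to_genomic(t, 2) + 1  # third base of ATG
        ref = genome.base(t.contig, pos)
        alt = "A" if t.strand == "+" else "T"  # ATG -> ATA (Ile)
        ann = classify_snv(_snv(t.contig, pos, ref, alt), t, genome)
        assert ann.category == "missense" and ann.start_loss

    def test_reference_mismatch_raises(self):
        rng = np.random.default_rng(5)
        genome, t = random_transcript(rng)
        pos = t.tx_start + 1
        ref = genome.base(t.contig, pos)
        wrong = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        with pytest.raises(ReferenceMismatchError):
            classify_snv(_snv(t.contig, pos, wrong, ref), t, genome)


@pytest.fixture(scope="module")
def coding_site():
    rng = np.random.default_rng(9)
    genome, t = random_transcript(rng, n_exons=3)
    # an interior CDS position well inside one CDS exon
    s, e = max(t.cds_exons, key=lambda x: x[1] - x[0])
    return genome, t, (s + e) // 2


class TestClassifyIndel:
    def test_two_bp_deletion_in_cds_is_frameshift(self, coding_site):
        genome, t, p0 = coding_site
        v = VariantRecord(contig=t.contig, pos=p0 + 1,
                          ref_allele=genome.fetch(t.contig, p0, p0 + 2),
                          alt_allele="", var_class=DELETION)
        assert classify_indel(v, t, genome).category == "frame_shift"

    def test_inframe_deletion(self, coding_site):
        genome, t, p0 = coding_site
        v = VariantRecord(contig=t.contig, pos=p0 + 1,
                          ref_allele=genome.fetch(t.contig, p0, p0 + 3),
                          alt_allele="", var_class=DELETION)
        assert classify_indel(v, t, genome).category == "aa_deletion"

    def test_inframe_insertion(self, coding_site):
        genome, t, p0 = coding_site
        v = VariantRecord(contig=t.contig, pos=p0 + 1, ref_allele="",
                          alt_allele="TGA",  # stop triplet is fine in-frame
                          var_class=INSERTION)
        assert classify_indel(v, t, genome).category == "aa_insertion"

    def test_intronic_insertion_noncoding(self):
        rng = np.random.default_rng(10)
        genome, t = random_transcript(rng, n_exons=4)
        # interior of the largest intron, away from splice windows
        gaps = [(t.exons[i][1], t.exons[i + 1][0])
                for i in range(len(t.exons) - 1)]
        s, e = max(gaps, key=lambda g: g[1] - g[0])
        v = VariantRecord(contig=t.contig, pos=(s + e) // 2, ref_allele="",
                          alt_allele="ACGT", var_class=INSERTION)
        ann = classify_indel(v, t, genome)
        assert ann.category == "non_coding" and not ann.splice_adjacent

    def test_splice_adjacent_flag(self):
        rng = np.random.default_rng(10)
        genome, t = random_transcript(rng, n_exons=4)
        left_end = t.exons[0][1]
        v = VariantRecord(contig=t.contig, pos=left_end + 1,
                          ref_allele=genome.fetch(t.contig, left_end,
                                                  left_end + 2),
                          alt_allele="", var_class=DELETION)
        ann = classify_indel(v, t, genome)
        assert ann.category == "non_coding" and ann.splice_adjacent


class TestOracleEquivalence:
    """Spot-scale agreement with the splice-edit-retranslate oracle; the
    full sweep lives in the acceptance suite."""

    @pytest.mark.parametrize("seed", range(4))
    def test_snv_categories_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genome, t = random_transcript(rng)
        contig_seq = genome.contigs[t.contig]
        positions = range(t.tx_start - 20 + 1, t.tx_end + 20 + 1)
        for pos1 in positions:
            ref = genome.base(t.contig, pos1)
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = classify_snv(_snv(t.contig, pos1, ref, alt), t, genome)
                expected = oracle_classify_snv(t, contig_seq, pos1, alt)
                assert got.category == expected, (t.strand, pos1, ref, alt)

    @pytest.mark.parametrize("seed", range(4))
    def test_indel_categories_match_oracle(self, seed):
        rng = np.random.default_rng(seed + 50)
        genome, t = random_transcript(rng)
        for pos1 in range(t.tx_start - 10 + 1, t.tx_end + 10 + 1):
            for length in (1, 2, 3, 4, 6):
                del_rec = VariantRecord(
                    contig=t.contig, pos=pos1,
                    ref_allele=genome.fetch(t.contig, pos1 - 1,
                                            pos1 - 1 + length),
                    alt_allele="", var_class=DELETION)
                assert classify_indel(del_rec, t, genome).category == \
                    oracle_classify_indel(t, pos1, length, False)
                ins_rec = VariantRecord(
                    contig=t.contig, pos=pos1, ref_allele="",
                    alt_allele="A" * length, var_class=INSERTION)
                assert classify_indel(ins_rec, t, genome).category == \
                    oracle_classify_indel(t, pos1, length, True)


class TestRepresentative:
    def test_nested_gene_cds_beats_host_intron(self, single_fixture):
        """A variant in the host gene's intron that hits the nested gene's
        CDS is represented by the more severe coding annotation."""
        fx = single_fixture
        annotator = Annotator(fx.genome, fx.transcripts)
        host, nested = fx.transcripts[0], fx.transcripts[1]
        assert host.exons[0][1] <= nested.tx_start  # nested in intron 1
        p0 = (nested.cds_start + nested.cds_end) // 2
        # find a CDS base of the nested gene
        while not any(s <= p0 < e for s, e in nested.cds_exons):
            p0 += 1
        ref = fx.genome.base(nested.contig, p0 + 1)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        all_anns, rep = annotator.annotate(_snv(nested.contig, p0 + 1, ref, alt))
        assert {a.transcript_id for a in all_anns} == {
            host.transcript_id, nested.transcript_id}
        by_tx = {a.transcript_id: a for a in all_anns}
        assert by_tx[host.transcript_id].category == "intron"
        assert rep.transcript_id == nested.transcript_id
        assert severity_rank(rep.category) < severity_rank("intron")

    def test_no_overlap_is_intergenic(self, single_fixture):
        fx = single_fixture
        annotator = Annotator(fx.genome, fx.transcripts)
        pos = fx.genome.length("chr1")  # far end of contig is gene-free
        ref = fx.genome.base("chr1", pos)
        alt = "A" if ref != "A" else "C"
        _, rep = annotator.annotate(_snv("chr1", pos, ref, alt))
        assert rep.category == "intergenic" and rep.transcript_id is None

    def test_tie_breaks_lexicographic_and_order_invariant(self):
        rng = np.random.default_rng(15)
        genome, t1 = random_transcript(rng)
        t2 = Transcript(**{**t1.__dict__, "transcript_id": "AAA000"})
        pos = cds_offset_to_genomic(t1, 9) + 1
        ref = genome.base(t1.contig, pos)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        v = _snv(t1.contig, pos, ref, alt)
        for order in ([t1, t2], [t2, t1]):
            _, rep = Annotator(genome, order).annotate(v)
            assert rep.transcript_id == "AAA000"


class TestNovelty:
    DB = KnownVariantDB({
        ("chr1", 100, "A", "G"): ("rs0001", False),
        ("chr1", 200, "C", "T"): ("rs0002", True),
    })

    def test_absent_is_novel(self):
        assert lookup_known(_snv("chr1", 300, "A", "G"), self.DB) == \
            ("novel", None)

    def test_known_without_flag(self):
        assert lookup_known(_snv("chr1", 100, "A", "G"), self.DB) == \
            ("known", "rs0001")

    def test_clinical_flag_is_disease_related(self):
        assert lookup_known(_snv("chr1", 200, "C", "T"), self.DB) == \
            ("known_disease_related", "rs0002")

    def test_allele_exact_by_default(self):
        assert lookup_known(_snv("chr1", 100, "A", "T"), self.DB)[0] == "novel"

    def test_position_only_fallback(self):
        db = KnownVariantDB(self.DB.entries, allele_exact=False)
        assert lookup_known(_snv("chr1", 100, "A", "T"), db)[0] == "known"

    def test_catalogue_vcf_round_trip(self, tmp_path, single_fixture):
        from exomesieve.fixtures import write_catalogue_vcf
        fx = single_fixture
        path = tmp_path / "known.vcf"
        write_catalogue_vcf(fx.known_db, fx.genome, path)
        back = KnownVariantDB.from_vcf(path, genome=fx.genome)
        assert back.entries == fx.known_db.entries


class TestGeneTerms:
    def test_join_and_dedup(self, tmp_path):
        mapping = {"G1": ("hsa0001", "GO:1", "GO:2")}
        assert gene_term_join("G1", mapping) == ("hsa0001", "GO:1", "GO:2")
        assert gene_term_join("G9", mapping) == ()
        p = tmp_path / "terms.tsv"
        p.write_text("G1\thsa0001\nG1\tGO:1\nG1\thsa0001\nG2\tGO:9\n")
        assert read_gene_terms(p) == {"G1": ("hsa0001", "GO:1"),
                                      "G2": ("GO:9",)}
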