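"""Filter criteria semantics, tallies and the ALS-style preset."""

import pytest

from exomesieve.annotate import Annotation
from exomesieve.filtering import (
    ConfigurationError,
    FilterCriteria,
    als_preset,
    filter_variants,
    substitution_class,
)
from exomesieve.popfreq import FreqTestResult
from exomesieve.variants import DELETION, INSERTION, SNV, VariantRecord

from oracles import als_truth_predicate


def _ann(pos, category, *, ref="A", alt="G", var_class=SNV, zygosity="het",
         novelty="novel", score=None):
    if var_class == INSERTION:
        ref, alt = "", alt
    elif var_class == DELETION:
        ref, alt = ref, ""
    v = VariantRecord(contig="chr1", pos=pos, ref_allele=ref, alt_allele=alt,
                      var_class=var_class, zygosity=zygosity)
    return Annotation(variant=v, category=category, novelty=novelty,
                      deleterious_score=score)


def test_substitution_class():
    assert substitution_class("A", "G") == "transition"
    assert substitution_class("C", "T") == "transition"
    assert substitution_class("A", "C") == "transversion"
    assert substitution_class("G", "T") == "transversion"


class TestFilterVariants:
    def test_unset_criteria_keep_everything(self):
        anns = [_ann(i, "missense") for i in range(1, 11)]
        retained, report = filter_variants(anns, FilterCriteria())
        assert retained == anns
        assert report.n_before == report.n_after == 10
        assert sum(report.per_criterion_removed.values()) == 0

    def test_planted_composition_exact(self):
        """100 variants of which exactly 12 are novel missense."""
        anns = []
        pos = 1
        for _ in range(12):
            anns.append(_ann(pos, "missense", novelty="novel")); pos += 1
        for _ in range(38):
            anns.append(_ann(pos, "missense", novelty="known")); pos += 1
        for _ in range(30):
            anns.append(_ann(pos, "intron", novelty="novel")); pos += 1
        for _ in range(20):
            anns.append(_ann(pos, "syn_code", novelty="known")); pos += 1
        criteria = FilterCriteria(
            snp_novelty="novel_only",
            snp_classification=frozenset({"missense"}),
        )
        retained, report = filter_variants(anns, criteria)
        assert len(retained) == 12
        assert all(a.novelty == "novel" and a.category == "missense"
                   for a in retained)
        assert report.n_before - report.n_after == \
            sum(report.per_criterion_removed.values()) == 88

    def test_indel_coding_only(self):
        anns = [_ann(i, "frame_shift", var_class=DELETION, ref="AT")
                for i in range(1, 6)]
        anns += [_ann(i, "non_coding", var_class=INSERTION, alt="TT")
                 for i in range(10, 13)]
        retained, _ = filter_variants(
            anns, FilterCriteria(indel_coding_only=True))
        assert len(retained) == 5

    def test_novel_or_disease_mode(self):
        anns = [
            _ann(1, "missense", novelty="novel"),
            _ann(2, "missense", novelty="known"),
            _ann(3, "missense", novelty="known_disease_related"),
        ]
        retained, _ = filter_variants(
            anns, FilterCriteria(snp_novelty="novel_or_disease"))
        assert [a.variant.pos for a in retained] == [1, 3]

    def test_unknown_zygosity_fails_zygosity_criterion(self):
        anns = [_ann(1, "missense", zygosity="unknown"),
                _ann(2, "missense", zygosity="het")]
        retained, _ = filter_variants(
            anns, FilterCriteria(snp_zygosity=frozenset({"het"})))
        assert [a.variant.pos for a in retained] == [2]

    def test_impact_score_threshold(self):
        anns = [_ann(1, "missense", score=0.01),
                _ann(2, "missense", score=0.4),
                _ann(3, "missense", score=None)]
        retained, _ = filter_variants(
            anns, FilterCriteria(snp_impact_max_score=0.05))
        assert [a.variant.pos for a in retained] == [1]

    def test_impact_without_scores_is_config_error(self):
        anns = [_ann(1, "missense")]
        with pytest.raises(ConfigurationError):
            filter_variants(anns, FilterCriteria(snp_impact_max_score=0.05))

    def test_freq_without_results_is_config_error(self):
        with pytest.raises(ConfigurationError):
            filter_variants(
                [_ann(1, "missense")],
                FilterCriteria(snp_freq_population="CHB"),
            )

    def test_freq_criterion_uses_named_population(self):
        anns = [_ann(1, "missense"), _ann(2, "missense")]
        def res(sig):
            return FreqTestResult(population="CHB", panel_maf=0.1, chi2=5.0,
                                  p_value=0.01 if sig else 0.5,
                                  significant=sig)
        freq = {
            anns[0].variant.key(): {"CHB": res(True)},
            anns[1].variant.key(): {"CHB": res(False)},
        }
        retained, _ = filter_variants(
            anns, FilterCriteria(snp_freq_population="CHB"), freq_results=freq)
        assert [a.variant.pos for a in retained] == [1]

    def test_absent_site_policy(self):
        anns = [_ann(1, "missense")]
        criteria = FilterCriteria(snp_freq_population="CHB")
        kept, _ = filter_variants(anns, criteria, freq_results={})
        assert kept == anns
        dropped, _ = filter_variants(anns, criteria, freq_results={},
                                     absent_significant=False)
        assert dropped == []

    def test_monotone_and_order_independent(self):
        anns = [
            _ann(1, "missense", novelty="novel"),
            _ann(2, "nonsense", novelty="known", zygosity="hom"),
            _ann(3, "intron", novelty="novel"),
            _ann(4, "frame_shift", var_class=DELETION, ref="AT",
                 novelty="novel"),
            _ann(5, "non_coding", var_class=INSERTION, alt="T",
                 novelty="known"),
        ]
        weak = FilterCriteria(snp_novelty="novel_only")
        strong = FilterCriteria(
            snp_novelty="novel_only",
            snp_classification=frozenset({"missense", "nonsense"}),
            indel_novelty="novel_only",
            indel_coding_only=True,
        )
        kept_weak, _ = filter_variants(anns, weak)
        kept_strong, _ = filter_variants(anns, strong)
        assert {a.variant.pos for a in kept_strong} <= \
            {a.variant.pos for a in kept_weak}
        # retained set does not depend on input order
        kept_rev, _ = filter_variants(list(reversed(anns)), strong)
        assert {a.variant.pos for a in kept_rev} == \
            {a.variant.pos for a in kept_strong}


class TestAlsPreset:
    def test_fields(self):
        c = als_preset()
        assert c.snp_novelty == "novel_only"
        assert c.snp_classification == {"missense", "nonsense", "splice_site"}
        assert c.snp_zygosity == {"het"}
        assert (c.snp_freq_population, c.snp_freq_alpha) == ("CHB", 0.05)
        assert c.indel_novelty == "novel_only"
        assert c.indel_coding_only and c.indel_zygosity == {"het"}

    def test_never_retains_hom(self):
        anns = [_ann(1, "missense", zygosity="hom"),
                _ann(2, "frame_shift", var_class=DELETION, ref="A",
                     zygosity="hom")]
        retained, _ = filter_variants(anns, als_preset(), freq_results={})
        assert retained == []

    def test_single_planted_candidate_among_decoys(self):
        target = _ann(1, "nonsense", novelty="novel", zygosity="het")
        decoys = [
            _ann(2, "nonsense", novelty="known", zygosity="het"),
            _ann(3, "nonsense", novelty="novel", zygosity="hom"),
            _ann(4, "syn_code", novelty="novel", zygosity="het"),
            _ann(5, "intron", novelty="novel", zygosity="het"),
            _ann(6, "non_coding", var_class=INSERTION, alt="G",
                 novelty="novel", zygosity="het"),
        ]
        sig = FreqTestResult(population="CHB", panel_maf=0.0, chi2=100.0,
                             p_value=1e-20, significant=True)
        notsig = FreqTestResult(population="CHB", panel_maf=0.25, chi2=0.1,
                                p_value=0.9, significant=False)
        freq = {a.variant.key(): {"CHB": notsig} for a in decoys}
        freq[target.variant.key()] = {"CHB": sig}
        retained, _ = filter_variants([target] + decoys, als_preset(),
                                      freq_results=freq,
                                      absent_significant=False)
        assert retained == [target]

    def test_json_round_trip(self):
        c = als_preset()
        assert FilterCriteria.from_json(c.to_json()) == c

    def test_config_round_trip(self):
        c = als_preset()
        assert FilterCriteria.from_config(c.to_config()) == c

    def test_truth_predicate_agrees_on_fixture(self, single_fixture):
        """The preset keeps exactly the truth rows the ALS predicate keeps
        (annotation-level check; the file-level run is in acceptance)."""
        from exomesieve.annotate import Annotator
        from exomesieve.popfreq import test_all_populations

        fx = single_fixture
        annotator = Annotator(fx.genome, fx.transcripts, known=fx.known_db)
        anns = []
        freq = {}
        for rec in fx.samples["CASE1"]:
            _, rep = annotator.annotate(rec)
            anns.append(rep)
            if rec.is_snv:
                freq[rec.key()] = {
                    r.population: r
                    for r in test_all_populations(rec, fx.panel)
                }
        retained, _ = filter_variants(anns, als_preset(), freq_results=freq)
        got = {a.variant.key() for a in retained}
        truth = fx.truth[fx.truth.sample_id == "CASE1"]
        expected = {
            (r.contig, int(r.pos), r.ref_allele, r.alt_allele)
            for r in truth.itertuples() if als_truth_predicate(r)
        }
        assert got == expected
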