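"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the package's own coordinate and
classification code paths: regions are painted base by base with explicit
set arithmetic, SNV effects are obtained by editing the contig string,
re-splicing and re-translating with Biopython, indel effects by explicit
per-base CDS membership, and the chi-square by its closed 2x2 form.
"""

from __future__ import annotations

from Bio.Seq import Seq

SPLICE_WINDOW = 2


def paint_window(t, window_start1: int, window_end1: int,
                 splice_window: int = SPLICE_WINDOW) -> dict[int, str]:
    """Region label for every 1-based position in [window_start1, window_end1]
    computed by explicit interval arithmetic over the exon/CDS structure."""
    exonic: set[int] = set()
    for s, e in t.exons:
        exonic |= set(range(s, e))
    tx = set(range(t.tx_start, t.tx_end))
    intronic = tx - exonic
    cds = set(range(t.cds_start, t.cds_end)) & exonic
    splice: set[int] = set()
    for i in range(len(t.exons) - 1):
        left, right = t.exons[i][1], t.exons[i + 1][0]
        splice |= set(range(left, min(left + splice_window, right)))
        splice |= set(range(max(right - splice_window, left), right))
    splice &= intronic
    labels = {}
    for pos1 in range(window_start1, window_end1 + 1):
        p = pos1 - 1
        if p not in tx:
            labels[pos1] = "intergenic"
        elif p in cds:
            labels[pos1] = "cds"
        elif p in exonic:
            genomic_upstream = p < t.cds_start
            if t.strand == "+":
                labels[pos1] = "utr5" if genomic_upstream else "utr3"
            else:
                labels[pos1] = "utr3" if genomic_upstream else "utr5"
        elif p in splice:
            labels[pos1] = "splice_site"
        else:
            labels[pos1] = "intron"
    return labels


def splice_cds_from_contig(t, contig_seq: str) -> str:
    """Spliced CDS by direct string slicing plus Biopython strand handling."""
    parts = []
    for s, e in t.exons:
        cs, ce = max(s, t.cds_start), min(e, t.cds_end)
        if cs < ce:
            parts.append(contig_seq[cs:ce])
    cds = "".join(parts)
    if t.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def oracle_classify_snv(t, contig_seq: str, pos1: int, alt: str,
                        splice_window: int = SPLICE_WINDOW) -> str:
    """Category by mutate-contig, re-splice, re-translate."""
    label = paint_window(t, pos1, pos1, splice_window)[pos1]
    if label != "cds":
        return label
    mutated = contig_seq[:pos1 - 1] + alt + contig_seq[pos1:]
    cds_ref = splice_cds_from_contig(t, contig_seq)
    cds_alt = splice_cds_from_contig(t, mutated)
    prot_ref = str(Seq(cds_ref).translate())
    prot_alt = str(Seq(cds_alt).translate())
    diffs = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
    if not diffs:
        return "syn_code"
    (i,) = diffs
    if prot_ref[i] == "*":
        return "read_through"
    if prot_alt[i] == "*":
        return "nonsense"
    return "missense"


def oracle_classify_indel(t, pos1: int, length: int, is_insertion: bool,
                          splice_window: int = SPLICE_WINDOW) -> str:
    """Category by explicit per-base CDS membership and the mod-3 rule.

    ``pos1`` is the first deleted base for deletions and the base before
    which the sequence is inserted for insertions.
    """
    cds: set[int] = set()
    exon_starts = {s for s, _e in t.exons}
    for s, e in t.exons:
        cds |= set(range(max(s, t.cds_start), min(e, t.cds_end)))
    if is_insertion:
        p = pos1 - 1
        inside = p in cds and (p - 1) in cds and p not in exon_starts
        n = length if inside else 0
    else:
        n = len(set(range(pos1 - 1, pos1 - 1 + length)) & cds)
    if n == 0:
        return "non_coding"
    if n % 3 != 0:
        return "frame_shift"
    return "aa_insertion" if is_insertion else "aa_deletion"


def chi2_closed_form(a: float, b: float, c: float, d: float) -> float:
    """chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); 0 for degenerate margins."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


# Hand-written expectation for every non-missing child/father/mother
# genotype combination: (de_novo, recessive_hom, dominant_inherited).
TRIO_TRUTH: dict[tuple[str, str, str], tuple[bool, bool, bool]] = {
    ("hom_ref", "hom_ref", "hom_ref"): (False, False, False),
    ("hom_ref", "hom_ref", "het"): (False, False, False),
    ("hom_ref", "hom_ref", "hom_alt"): (False, False, False),
    ("hom_ref", "het", "hom_ref"): (False, False, False),
    ("hom_ref", "het", "het"): (False, False, False),
    ("hom_ref", "het", "hom_alt"): (False, False, False),
    ("hom_ref", "hom_alt", "hom_ref"): (False, False, False),
    ("hom_ref", "hom_alt", "het"): (False, False, False),
    ("hom_ref", "hom_alt", "hom_alt"): (False, False, False),
    ("het", "hom_ref", "hom_ref"): (True, False, False),
    ("het", "hom_ref", "het"): (False, False, True),
    ("het", "hom_ref", "hom_alt"): (False, False, True),
    ("het", "het", "hom_ref"): (False, False, True),
    ("het", "het", "het"): (False, False, True),
    ("het", "het", "hom_alt"): (False, False, True),
    ("het", "hom_alt", "hom_ref"): (False, False, True),
    ("het", "hom_alt", "het"): (False, False, True),
    ("het", "hom_alt", "hom_alt"): (False, False, True),
    ("hom_alt", "hom_ref", "hom_ref"): (True, False, False),
    ("hom_alt", "hom_ref", "het"): (False, False, True),
    ("hom_alt", "hom_ref", "hom_alt"): (False, False, True),
    ("hom_alt", "het", "hom_ref"): (False, False, True),
    ("hom_alt", "het", "het"): (False, True, True),
    ("hom_alt", "het", "hom_alt"): (False, False, True),
    ("hom_alt", "hom_alt", "hom_ref"): (False, False, True),
    ("hom_alt", "hom_alt", "het"): (False, False, True),
    ("hom_alt", "hom_alt", "hom_alt"): (False, False, True),
}

_MODEL_INDEX = {"de_novo": 0, "recessive_hom": 1, "dominant_inherited": 2}


def trio_truth_keeps(model: str, child: str, father: str, mother: str,
                     strict_missing: bool = True) -> bool:
    if "missing" in (child, father, mother):
        return not strict_missing
    return TRIO_TRUTH[(child, father, mother)][_MODEL_INDEX[model]]


def als_truth_predicate(row) -> bool:
    """Whether one truth-table row should survive the ALS-style preset."""
    if row.zygosity != "het" or row.novelty != "novel":
        return False
    if row.var_class == "snv":
        return row.category in ("missense", "nonsense", "splice_site") and bool(
            row.divergent
        )
    return row.category != "non_coding"
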