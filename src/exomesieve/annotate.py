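"""Functional annotation of variants against gene models.

SNVs are classified into nine disjoint categories (intergenic, intron,
utr5, utr3, splice_site, syn_code, missense, nonsense, read_through) by
locating the base on each overlapping transcript and, inside the CDS,
comparing the reference and alternate codons under the standard nuclear
genetic code.  Indels fall into four categories (non_coding, frame_shift,
aa_insertion, aa_deletion) driven by how many CDS bases the edit adds or
removes and whether that count is a multiple of 3.

Each variant is annotated against every overlapping transcript; a single
representative annotation is chosen by a fixed severity order with
lexicographic transcript-id tie-breaks, and novelty is resolved against a
known-variant catalogue (dbSNP-style VCF, clinically-associated entries
flagged ``CLN=1``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import seq3
from intervaltree import IntervalTree

from . import genome as gm
from .genome import (
    DEFAULT_SPLICE_WINDOW,
    GenomeSequence,
    SiteLocation,
    Transcript,
    cds_offset_of,
    cds_offset_to_codon,
    complement,
    locate,
    open_text,
)
from .variants import (
    DELETION,
    INSERTION,
    ReferenceMismatchError,
    VariantRecord,
    normalize_indel,
)

logger = logging.getLogger(__name__)

# codon -> one-letter amino acid, stop = '*'
_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _TABLE.stop_codons})

SNV_CATEGORIES = (
    "intergenic", "intron", "utr5", "utr3", "splice_site",
    "syn_code", "missense", "nonsense", "read_through",
)
INDEL_CATEGORIES = ("non_coding", "frame_shift", "aa_insertion", "aa_deletion")

NOVEL = "novel"
KNOWN = "known"
KNOWN_DISEASE = "known_disease_related"

# representative-annotation severity; lower rank = more severe
SEVERITY_ORDER = (
    "nonsense", "frame_shift", "read_through", "splice_site", "missense",
    "aa_insertion", "aa_deletion", "syn_code", "utr5", "utr3", "intron",
    "non_coding", "intergenic",
)
_SEVERITY = {c: i for i, c in enumerate(SEVERITY_ORDER)}
_SEVERITY["aa_deletion"] = _SEVERITY["aa_insertion"]  # explicit tie


def translate_codon(codon: str) -> str:
    return CODON_TO_AA[codon]


def aa3(aa: str) -> str:
    """Three-letter amino-acid name; stop rendered as Ter."""
    return "Ter" if aa == "*" else seq3(aa)


@dataclass
class Annotation:
    """Functional annotation of one variant on one transcript."""

    variant: VariantRecord
    category: str
    transcript_id: str | None = None
    gene_name: str | None = None
    strand: str | None = None
    aa_change: str | None = None
    codon_change: str | None = None
    novelty: str = NOVEL
    rs_id: str | None = None
    deleterious_score: float | None = None
    gene_terms: tuple[str, ...] = ()
    splice_adjacent: bool = False
    start_loss: bool = False


class KnownVariantDB:
    """Catalogue of known variants keyed by normalized (contig,pos,ref,alt).

    ``allele_exact=False`` enables a position-only fallback for catalogues
    without reliable allele detail.
    """

    def __init__(
        self,
        entries: dict[tuple[str, int, str, str], tuple[str, bool]],
        allele_exact: bool = True,
    ):
        self.entries = dict(entries)
        self.allele_exact = allele_exact
        self._by_site: dict[tuple[str, int], tuple[str, bool]] = {}
        for (contig, pos, _r, _a), value in self.entries.items():
            self._by_site.setdefault((contig, pos), value)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_vcf(
        cls, path, genome: GenomeSequence | None = None, allele_exact: bool = True
    ) -> "KnownVariantDB":
        """Load a known-variant catalogue from a VCF-like file.

        Records are reduced to pure-indel form and left-aligned when a
        genome is supplied; ``CLN=1`` in INFO marks clinically associated
        entries.
        """
        from .variants import _parse_info, _reduce_vcf_alleles, _classify_alleles

        entries: dict[tuple[str, int, str, str], tuple[str, bool]] = {}
        with open_text(path) as handle:
            for line_no, raw in enumerate(handle, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    logger.warning("catalogue line %d skipped", line_no)
                    continue
                contig, pos, rs = fields[0], int(fields[1]), fields[2]
                info = _parse_info(fields[7]) if len(fields) >= 8 else {}
                clinical = str(info.get("CLN", "0")) in ("1", "True", "true")
                for alt in fields[4].split(","):
                    rpos, ref, a = _reduce_vcf_alleles(
                        pos, fields[3].upper(), alt.upper()
                    )
                    if _classify_alleles(ref, a) is None:
                        continue
                    if genome is not None and (not ref or not a):
                        try:
                            rec = VariantRecord(
                                contig=contig,
                                pos=rpos,
                                ref_allele=ref,
                                alt_allele=a,
                                var_class=DELETION if ref else INSERTION,
                            )
                            rec = normalize_indel(rec, genome)
                            rpos, ref, a = rec.pos, rec.ref_allele, rec.alt_allele
                        except (ReferenceMismatchError, gm.GenomeError) as exc:
                            logger.warning(
                                "catalogue line %d not normalized: %s", line_no, exc
                            )
                    entries[(contig, rpos, ref, a)] = (rs, clinical)
        return cls(entries, allele_exact=allele_exact)

    def lookup(self, v: VariantRecord) -> tuple[str, str | None]:
        """Novelty status and rs id of a (normalized) variant."""
        hit = self.entries.get(v.key())
        if hit is None and not self.allele_exact:
            hit = self._by_site.get((v.contig, v.pos))
        if hit is None:
            return NOVEL, None
        rs, clinical = hit
        return (KNOWN_DISEASE if clinical else KNOWN), rs


def lookup_known(
    v: VariantRecord, db: KnownVariantDB | None
) -> tuple[str, str | None]:
    if db is None:
        return NOVEL, None
    return db.lookup(v)


def _check_reference(v: VariantRecord, genome: GenomeSequence) -> None:
    if v.is_snv:
        observed = genome.base(v.contig, v.pos)
        expected = v.ref_allele
    elif v.var_class == DELETION:
        observed = genome.fetch(v.contig, v.pos - 1, v.pos - 1 + len(v.ref_allele))
        expected = v.ref_allele
    else:
        return
    if observed != expected:
        raise ReferenceMismatchError(
            f"{v.contig}:{v.pos} expects reference {expected!r}, genome has "
            f"{observed!r}"
        )


def classify_snv(
    v: VariantRecord,
    t: Transcript,
    genome: GenomeSequence,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> Annotation:
    """Classify one SNV against one transcript.

    Inside the CDS the reference codon is read across exon junctions in
    coding orientation, the alternate base is strand-adjusted, and both
    codons are translated: same residue -> syn_code, residue to stop ->
    nonsense, stop to residue -> read_through, otherwise missense.
    """
    if not v.is_snv:
        raise ValueError("classify_snv requires an SNV")
    _check_reference(v, genome)
    loc = locate(t, v.pos, splice_window)
    ann = Annotation(
        variant=v,
        category=loc.region,
        transcript_id=t.transcript_id,
        gene_name=t.gene_name,
        strand=t.strand,
    )
    if loc.region != gm.REGION_CDS:
        return ann
    codon, within, aa_pos = cds_offset_to_codon(t, genome, loc.cds_offset)
    alt_base = complement(v.alt_allele) if t.strand == "-" else v.alt_allele
    alt_codon = codon[:within] + alt_base + codon[within + 1:]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(alt_codon)
    if aa_ref == aa_alt:
        ann.category = "syn_code"
    elif aa_ref == "*":
        ann.category = "read_through"
    elif aa_alt == "*":
        ann.category = "nonsense"
    else:
        ann.category = "missense"
    ann.aa_change = f"p.{aa3(aa_ref)}{aa_pos}{aa3(aa_alt)}"
    ann.codon_change = f"{codon}>{alt_codon}"
    if aa_pos == 1 and codon == "ATG" and alt_codon != "ATG":
        ann.start_loss = True
    return ann


def _cds_bases_affected(v: VariantRecord, t: Transcript) -> int:
    """Number of CDS bases the edit adds (insertion) or removes (deletion)."""
    if v.var_class == DELETION:
        start = v.pos - 1
        end = start + len(v.ref_allele)
        return sum(
            max(0, min(end, e) - max(start, s)) for s, e in t.cds_exons
        )
    point = v.pos - 1  # inserted before this 0-based position
    inside = any(s < point < e for s, e in t.cds_exons)
    return len(v.alt_allele) if inside else 0


def _splice_adjacent(
    v: VariantRecord, t: Transcript, splice_window: int
) -> bool:
    """Does the affected interval touch an intronic splice window?"""
    if v.var_class == DELETION:
        start, end = v.pos - 1, v.pos - 1 + len(v.ref_allele)
    else:
        start, end = v.pos - 2, v.pos  # both flanks of the insertion point
    for i in range(len(t.exons) - 1):
        left = t.exons[i][1]
        right = t.exons[i + 1][0]
        for ws, we in ((left, left + splice_window), (right - splice_window, right)):
            if max(start, ws) < min(end, we):
                return True
    return False


def classify_indel(
    v: VariantRecord,
    t: Transcript,
    genome: GenomeSequence,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> Annotation:
    """Classify one indel against one transcript.

    The category is driven by the portion of the edit intersecting CDS
    exon bases: none -> non_coding (flagged splice_adjacent when it touches
    a splice window), a non-multiple of 3 -> frame_shift, otherwise an
    in-frame aa_insertion / aa_deletion.
    """
    if not v.is_indel:
        raise ValueError("classify_indel requires an insertion or deletion")
    _check_reference(v, genome)
    ann = Annotation(
        variant=v,
        category="non_coding",
        transcript_id=t.transcript_id,
        gene_name=t.gene_name,
        strand=t.strand,
    )
    n_cds = _cds_bases_affected(v, t) if (t.is_coding and not t.broken_cds) else 0
    if n_cds == 0:
        ann.splice_adjacent = _splice_adjacent(v, t, splice_window)
        return ann
    if n_cds % 3 != 0:
        ann.category = "frame_shift"
        suffix = "fs"
    elif v.var_class == INSERTION:
        ann.category = "aa_insertion"
        suffix = "ins"
    else:
        ann.category = "aa_deletion"
        suffix = "del"
    # first affected residue, in coding orientation
    if v.var_class == DELETION:
        positions = [
            p
            for s, e in t.cds_exons
            for p in range(max(s, v.pos - 1), min(e, v.pos - 1 + len(v.ref_allele)))
        ]
    else:
        positions = [v.pos - 2, v.pos - 1]
    offsets = []
    for p in positions:
        try:
            offsets.append(cds_offset_of(t, p))
        except ValueError:
            continue
    if offsets:
        ann.aa_change = f"p.{min(offsets) // 3 + 1}{suffix}"
    return ann


def severity_rank(category: str) -> int:
    return _SEVERITY[category]


class Annotator:
    """Annotates variant records against a reference and gene-model set.

    Builds one interval tree per contig for transcript overlap queries.
    Transcripts flagged ``broken_cds`` are excluded from annotation
    entirely (region- and protein-level), as are their models from
    representative selection; contigs absent from the gene models simply
    yield intergenic annotations.
    """

    def __init__(
        self,
        genome: GenomeSequence,
        transcripts,
        known: KnownVariantDB | None = None,
        gene_terms: dict[str, tuple[str, ...]] | None = None,
        score_table: dict[tuple[str, int, str, str], float] | None = None,
        splice_window: int = DEFAULT_SPLICE_WINDOW,
    ):
        self.genome = genome
        self.known = known
        self.gene_terms = gene_terms or {}
        self.score_table = score_table or {}
        self.splice_window = splice_window
        all_transcripts = list(transcripts)
        self.transcripts = [t for t in all_transcripts if not t.broken_cds]
        n_broken = len(all_transcripts) - len(self.transcripts)
        if n_broken:
            logger.warning(
                "%d broken-CDS transcripts excluded from annotation", n_broken
            )
        self._trees: dict[str, IntervalTree] = {}
        for t in self.transcripts:
            self._trees.setdefault(t.contig, IntervalTree()).addi(
                t.tx_start, t.tx_end, t
            )

    def overlapping(self, v: VariantRecord) -> list[Transcript]:
        tree = self._trees.get(v.contig)
        if tree is None:
            return []
        start = v.pos - 1
        if v.var_class == DELETION:
            end = start + len(v.ref_allele)
        elif v.var_class == INSERTION:
            start, end = v.pos - 2, v.pos  # both flanking bases
        else:
            end = start + 1
        hits = tree.overlap(max(start, 0), end)
        return sorted((h.data for h in hits), key=lambda t: t.transcript_id)

    def annotate(self, v: VariantRecord) -> tuple[list[Annotation], Annotation]:
        """All per-transcript annotations plus the severity representative."""
        models = self.overlapping(v)
        anns: list[Annotation] = []
        for t in models:
            if v.is_snv:
                anns.append(classify_snv(v, t, self.genome, self.splice_window))
            else:
                anns.append(classify_indel(v, t, self.genome, self.splice_window))
        if not anns:
            _check_reference(v, self.genome)
            anns = [
                Annotation(
                    variant=v,
                    category="intergenic" if v.is_snv else "non_coding",
                )
            ]
        rep = min(
            anns,
            key=lambda a: (severity_rank(a.category), a.transcript_id or "~"),
        )
        vnorm = normalize_indel(v, self.genome) if v.is_indel else v
        novelty, rs = lookup_known(vnorm, self.known)
        score = self.score_table.get(vnorm.key())
        for a in anns:
            a.novelty, a.rs_id, a.deleterious_score = novelty, rs, score
            if a.gene_name:
                a.gene_terms = gene_term_join(a.gene_name, self.gene_terms)
        return anns, rep

    def annotate_all(
        self, records
    ) -> tuple[list[Annotation], int]:
        """Representative annotations for a record list.

        Records whose stated reference allele disagrees with the genome are
        counted and skipped rather than aborting the run.
        """
        reps: list[Annotation] = []
        n_mismatch = 0
        for v in records:
            try:
                _, rep = self.annotate(v)
            except ReferenceMismatchError as exc:
                n_mismatch += 1
                logger.warning("record skipped: %s", exc)
                continue
            reps.append(rep)
        return reps, n_mismatch


def gene_term_join(
    gene_name: str, mapping: dict[str, tuple[str, ...]]
) -> tuple[str, ...]:
    """Pathway/ontology terms for a gene (pure join, no statistics)."""
    return tuple(mapping.get(gene_name, ()))


def read_gene_terms(path) -> dict[str, tuple[str, ...]]:
    """Two-column gene -> term TSV; duplicate rows are de-duplicated."""
    mapping: dict[str, list[str]] = {}
    with open_text(path) as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue
            terms = mapping.setdefault(fields[0], [])
            if fields[1] not in terms:
                terms.append(fields[1])
    return {g: tuple(ts) for g, ts in mapping.items()}


def read_score_table(path) -> dict[tuple[str, int, str, str], float]:
    """Externally supplied per-variant deleteriousness scores.

    TSV columns: contig, pos, ref, alt, score — the hook for attaching
    precomputed protein-impact predictions (e.g. SIFT output) without
    re-implementing the predictor.
    """
    table: dict[tuple[str, int, str, str], float] = {}
    with open_text(path) as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                continue
            table[
                (fields[0], int(fields[1]), fields[2].upper(), fields[3].upper())
            ] = float(fields[4])
    return table
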