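"""Reference sequence and gene-model handling.

This module owns the coordinate arithmetic the rest of the pipeline relies
on: loading a reference genome from FASTA, loading transcript models from a
UCSC refGene-style flat table, and mapping a genomic position onto a
transcript (intergenic / intron / UTR / splice site / CDS) and, within the
CDS, onto a codon.

Conventions
-----------
* Internal coordinates are 0-based half-open, matching UCSC table dumps.
* All user-facing positions (``locate``, variant records, reports) are
  1-based, matching VCF.
* ``splice_site`` refers to *intronic* bases within ``splice_window`` bases
  of an exon boundary (default 2, the canonical GT/AG dinucleotides).
  Exonic bases near a boundary are classified by their exonic role — the
  output categories stay disjoint.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterator

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

REGION_INTERGENIC = "intergenic"
REGION_INTRON = "intron"
REGION_UTR5 = "utr5"
REGION_UTR3 = "utr3"
REGION_SPLICE = "splice_site"
REGION_CDS = "cds"

DEFAULT_SPLICE_WINDOW = 2


class GenomeError(ValueError):
    """Out-of-bounds or unknown-contig access."""


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


class GeneModelParseError(ValueError):
    """Malformed gene-model table; message names the offending line."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def open_text(path) -> Iterator[str]:
    """Open a possibly gzip-compressed text file for reading."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class GenomeSequence:
    """In-memory reference genome: contig name -> uppercase sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise GenomeError(f"contig {name!r} is empty")

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self._seq(contig))

    def _seq(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise GenomeError(f"unknown contig {contig!r}") from None

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of the 0-based half-open interval [start, end)."""
        seq = self._seq(contig)
        if start < 0 or end > len(seq) or start > end:
            raise GenomeError(
                f"interval [{start}, {end}) out of bounds for contig "
                f"{contig!r} of length {len(seq)}"
            )
        return seq[start:end]

    def base(self, contig: str, pos1: int) -> str:
        """Single base at a 1-based position."""
        return self.fetch(contig, pos1 - 1, pos1)


def read_fasta(path) -> GenomeSequence:
    """Load a (possibly gzipped, possibly soft-masked) FASTA file.

    Lowercase bases are uppercased; duplicate contig names, empty records
    and non-nucleotide characters raise :class:`FastaParseError` naming the
    line number.
    """
    contigs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"line {line_no}: contig {name!r} has no sequence")
        contigs[name] = seq

    with open_text(path) as handle:
        line_no = 0
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].split()
                if not header:
                    raise FastaParseError(f"line {line_no}: empty FASTA header")
                new_name = header[0]
                if new_name in contigs:
                    raise FastaParseError(
                        f"line {line_no}: duplicate contig {new_name!r}"
                    )
                name = new_name
                chunks = []
            else:
                if name is None:
                    raise FastaParseError(
                        f"line {line_no}: sequence before first FASTA header"
                    )
                seq = line.upper()
                if not set(seq) <= NUCLEOTIDES:
                    bad = sorted(set(seq) - NUCLEOTIDES)
                    raise FastaParseError(
                        f"line {line_no}: non-nucleotide characters {bad}"
                    )
                chunks.append(seq)
        flush(line_no)
    if not contigs:
        raise FastaParseError("no FASTA records found")
    return GenomeSequence(contigs)


@dataclass(frozen=True)
class Transcript:
    """One gene model in genomic coordinates (0-based half-open).

    ``exons`` are sorted, non-overlapping genomic intervals spanning
    [tx_start, tx_end).  A coding transcript has cds_start < cds_end and a
    spliced CDS length that is a positive multiple of 3; ``broken_cds``
    marks models that violate the multiple-of-3 rule and are excluded from
    protein-level annotation.
    """

    transcript_id: str
    gene_name: str
    contig: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]
    broken_cds: bool = False

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.transcript_id}: empty exon ({start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise ValueError(
                f"{self.transcript_id}: exon span does not match tx bounds"
            )
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.transcript_id}: CDS outside transcript bounds")
        if self.is_coding and not self.broken_cds and self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not a "
                "multiple of 3"
            )

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def cds_exons(self) -> tuple[tuple[int, int], ...]:
        return _cds_exons(self)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exons)


@lru_cache(maxsize=4096)
def _cds_exons(t: Transcript) -> tuple[tuple[int, int], ...]:
    out = []
    for start, end in t.exons:
        s = max(start, t.cds_start)
        e = min(end, t.cds_end)
        if s < e:
            out.append((s, e))
    return tuple(out)


def read_gene_models(path, on_invalid: str = "skip") -> list[Transcript]:
    """Parse a UCSC refGene-style tab-separated gene table.

    Accepted layouts (detected by column count):

    * 10 columns — plain genePred: name, chrom, strand, txStart, txEnd,
      cdsStart, cdsEnd, exonCount, exonStarts, exonEnds
    * 11 columns — genePred plus a trailing gene symbol
    * 16 columns — full UCSC refGene dump (leading ``bin``, symbol in
      column 13)

    Transcripts whose CDS length is not a multiple of 3 are skipped with a
    warning (``on_invalid="skip"``, default) or kept flagged ``broken_cds``
    (``on_invalid="keep"``); structurally invalid rows (unsorted exons,
    CDS outside bounds) are always skipped with a warning.
    """
    if on_invalid not in ("skip", "keep"):
        raise ValueError(f"on_invalid must be 'skip' or 'keep', got {on_invalid!r}")
    transcripts: list[Transcript] = []
    with open_text(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) == 16:
                cols = cols[1:]  # drop UCSC bin column
            if len(cols) not in (10, 11, 15):
                raise GeneModelParseError(
                    f"line {line_no}: expected 10, 11 or 16 tab-separated "
                    f"columns, got {len(cols)}"
                )
            try:
                name = cols[0]
                gene = cols[11] if len(cols) == 15 else (
                    cols[10] if len(cols) == 11 else cols[0]
                )
                exon_starts = tuple(
                    int(x) for x in cols[8].rstrip(",").split(",")
                )
                exon_ends = tuple(int(x) for x in cols[9].rstrip(",").split(","))
                if len(exon_starts) != int(cols[7]) or len(exon_ends) != int(cols[7]):
                    raise ValueError("exonCount disagrees with exon lists")
                t = Transcript(
                    transcript_id=name,
                    gene_name=gene,
                    contig=cols[1],
                    strand=cols[2],
                    tx_start=int(cols[3]),
                    tx_end=int(cols[4]),
                    cds_start=int(cols[5]),
                    cds_end=int(cols[6]),
                    exons=tuple(zip(exon_starts, exon_ends)),
                )
            except (ValueError, IndexError) as exc:
                logger.warning("gene table line %d skipped: %s", line_no, exc)
                continue
            try:
                t.validate()
            except ValueError as exc:
                if (
                    on_invalid == "keep"
                    and t.is_coding
                    and "multiple of 3" in str(exc)
                ):
                    t = Transcript(**{**t.__dict__, "broken_cds": True})
                    logger.warning(
                        "transcript %s kept with broken CDS: %s", name, exc
                    )
                else:
                    logger.warning("transcript %s skipped: %s", name, exc)
                    continue
            transcripts.append(t)
    return transcripts


@dataclass(frozen=True)
class SiteLocation:
    """Region of one genomic base relative to one transcript."""

    region: str
    exon_index: int | None = None
    intron_index: int | None = None
    cds_offset: int | None = None


def locate(
    t: Transcript, pos1: int, splice_window: int = DEFAULT_SPLICE_WINDOW
) -> SiteLocation:
    """Classify a 1-based genomic position relative to a transcript.

    Total function: every position maps to exactly one region.  UTR labels
    follow coding orientation, so the 5' UTR of a minus-strand transcript
    lies at higher genomic coordinates than its CDS.
    """
    pos0 = pos1 - 1
    if pos0 < t.tx_start or pos0 >= t.tx_end:
        return SiteLocation(REGION_INTERGENIC)
    for i, (start, end) in enumerate(t.exons):
        if start <= pos0 < end:
            if t.is_coding and t.cds_start <= pos0 < t.cds_end:
                return SiteLocation(
                    REGION_CDS, exon_index=i, cds_offset=cds_offset_of(t, pos0)
                )
            # genomic side relative to the CDS; flip for minus strand
            genomic_upstream = pos0 < t.cds_start
            if t.strand == "+":
                region = REGION_UTR5 if genomic_upstream else REGION_UTR3
            else:
                region = REGION_UTR3 if genomic_upstream else REGION_UTR5
            return SiteLocation(region, exon_index=i)
    # intronic: find the flanking exon pair
    for i in range(len(t.exons) - 1):
        left_end = t.exons[i][1]
        right_start = t.exons[i + 1][0]
        if left_end <= pos0 < right_start:
            near_left = pos0 - left_end < splice_window
            near_right = right_start - pos0 <= splice_window
            region = REGION_SPLICE if (near_left or near_right) else REGION_INTRON
            return SiteLocation(region, intron_index=i)
    raise AssertionError("unreachable: position inside tx bounds but unplaced")


def cds_offset_of(t: Transcript, pos0: int) -> int:
    """0-based offset of a genomic position into the spliced CDS, in coding
    orientation (5'->3' of the protein)."""
    if not t.is_coding:
        raise ValueError(f"{t.transcript_id} is non-coding")
    plus_offset = 0
    found = False
    for s, e in t.cds_exons:
        if s <= pos0 < e:
            plus_offset += pos0 - s
            found = True
            break
        plus_offset += e - s
    if not found:
        raise ValueError(f"position {pos0} not in CDS of {t.transcript_id}")
    if t.strand == "+":
        return plus_offset
    return t.cds_length - 1 - plus_offset


def cds_offset_to_genomic(t: Transcript, cds_offset: int) -> int:
    """Inverse of :func:`cds_offset_of`; returns a 0-based genomic position."""
    n = t.cds_length
    if not 0 <= cds_offset < n:
        raise ValueError(
            f"CDS offset {cds_offset} out of range for {t.transcript_id} "
            f"(CDS length {n})"
        )
    plus_offset = cds_offset if t.strand == "+" else n - 1 - cds_offset
    for s, e in t.cds_exons:
        if plus_offset < e - s:
            return s + plus_offset
        plus_offset -= e - s
    raise AssertionError("unreachable")


def cds_offset_to_codon(
    t: Transcript, genome: GenomeSequence, cds_offset: int
) -> tuple[str, int, int]:
    """Codon containing a CDS offset.

    Returns ``(codon, within_codon_index, aa_position)`` where the codon is
    read in coding orientation (reverse-complemented for minus-strand
    transcripts, assembled across exon junctions) and ``aa_position`` is
    1-based.
    """
    if t.broken_cds:
        raise ValueError(f"{t.transcript_id}: CDS length not a multiple of 3")
    if not 0 <= cds_offset < t.cds_length:
        raise ValueError(
            f"CDS offset {cds_offset} out of range (CDS length {t.cds_length})"
        )
    aa_position = cds_offset // 3 + 1
    within = cds_offset % 3
    first = cds_offset - within
    bases = []
    for off in (first, first + 1, first + 2):
        g = genome.base(t.contig, cds_offset_to_genomic(t, off) + 1)
        bases.append(complement(g) if t.strand == "-" else g)
    return "".join(bases), within, aa_position


def spliced_cds(t: Transcript, genome: GenomeSequence) -> str:
    """The spliced, strand-oriented coding sequence of a transcript."""
    seq = "".join(genome.fetch(t.contig, s, e) for s, e in t.cds_exons)
    return revcomp(seq) if t.strand == "-" else seq
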