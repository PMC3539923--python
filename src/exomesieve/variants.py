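"""Variant-call parsing and indel normalization.

Three call-file dialects are read into one record type:

* ``vcf`` — VCF 4.x data lines; multi-allelic rows are split, anchored
  indel alleles (REF=AT, ALT=A) are reduced to the internal pure-indel
  form, and zygosity is taken from the first sample's GT when present.
* ``pileup`` — the samtools consensus-pileup tabular layout (10+ columns;
  indel lines carry ``*`` in the reference column and ``+SEQ``/``-SEQ``
  consensus alleles).
* ``soapsnp`` — the SOAPsnp 17-column consensus table.

Malformed lines are never fatal: they are counted as "unavailable" in the
:class:`ParseSummary` and logged with their line number, mirroring how the
pipeline reports erroneous records to the user.

Indels are stored in pure form: a deletion has the deleted bases in
``ref_allele`` and an empty ``alt_allele`` with ``pos`` the first deleted
base; an insertion has empty ``ref_allele`` and the inserted bases in
``alt_allele`` with ``pos`` the reference base *before which* the sequence
is inserted.  :func:`normalize_indel` left-aligns this representation so
that equivalent edits in repeat runs compare equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .genome import GenomeSequence, open_text

logger = logging.getLogger(__name__)

SNV = "snv"
INSERTION = "insertion"
DELETION = "deletion"

HET = "het"
HOM = "hom"
UNKNOWN = "unknown"

_ALLELE_CHARS = frozenset("ACGT")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
}


class VariantFileError(ValueError):
    """Unreadable file or undecodable header (fatal, unlike bad data lines)."""


class ReferenceMismatchError(ValueError):
    """A variant's stated reference allele disagrees with the genome."""


@dataclass
class VariantRecord:
    """One called variant on one sample."""

    contig: str
    pos: int  # 1-based; anchor base (first deleted base / insertion point)
    ref_allele: str
    alt_allele: str
    var_class: str
    zygosity: str = UNKNOWN
    support: int | None = None
    sample_id: str = ""
    raw_line_no: int = 0
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.var_class == SNV:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNV alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("SNV alleles must differ")
        elif self.var_class == INSERTION:
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion must have empty ref, non-empty alt")
        elif self.var_class == DELETION:
            if self.alt_allele or not self.ref_allele:
                raise ValueError("deletion must have non-empty ref, empty alt")
        else:
            raise ValueError(f"bad var_class {self.var_class!r}")
        for allele in (self.ref_allele, self.alt_allele):
            if allele and not set(allele) <= _ALLELE_CHARS:
                raise ValueError(f"non-ACGT allele {allele!r}")

    @property
    def is_snv(self) -> bool:
        return self.var_class == SNV

    @property
    def is_indel(self) -> bool:
        return self.var_class in (INSERTION, DELETION)

    @property
    def indel_length(self) -> int:
        return len(self.ref_allele) or len(self.alt_allele)

    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class ParseSummary:
    """Input / unavailable / effective line counts for one variant file."""

    n_input: int
    n_unavailable: int
    n_effective: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_unavailable + self.n_effective:
            raise ValueError("n_input must equal n_unavailable + n_effective")


def _reduce_vcf_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip the shared prefix then shared suffix of a VCF REF/ALT pair."""
    p = 0
    while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
        p += 1
    ref, alt, pos = ref[p:], alt[p:], pos + p
    s = 0
    while s < min(len(ref), len(alt)) and ref[-1 - s] == alt[-1 - s]:
        s += 1
    if s:
        ref, alt = ref[:-s], alt[:-s]
    return pos, ref, alt


def _classify_alleles(ref: str, alt: str) -> str | None:
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    if not ref and alt:
        return INSERTION
    if ref and not alt:
        return DELETION
    return None  # MNV / complex: unsupported


def _parse_info(info_field: str) -> dict:
    info: dict = {}
    if info_field in (".", ""):
        return info
    for item in info_field.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            info[k] = v
        elif item:
            info[item] = True
    return info


def _vcf_records(
    fields: list[str], sample_id: str, line_no: int
) -> list[VariantRecord]:
    if len(fields) < 8:
        raise ValueError(f"expected >= 8 VCF columns, got {len(fields)}")
    contig = fields[0]
    pos = int(fields[1])
    ref = fields[3].upper()
    alts = [a.upper() for a in fields[4].split(",")]
    if not set(ref) <= _ALLELE_CHARS:
        raise ValueError(f"non-ACGT REF {fields[3]!r}")
    info = _parse_info(fields[7])

    gt_alleles: list[int] | None = None
    depth: int | None = None
    if len(fields) >= 10:
        fmt = fields[8].split(":")
        sample = fields[9].split(":")
        fmt_map = dict(zip(fmt, sample))
        gt = fmt_map.get("GT")
        if gt and gt not in (".", "./.", ".|."):
            try:
                gt_alleles = [
                    int(a) for a in gt.replace("|", "/").split("/") if a != "."
                ]
            except ValueError:
                gt_alleles = None
        if "DP" in fmt_map:
            try:
                depth = int(fmt_map["DP"])
            except ValueError:
                depth = None
    if depth is None and "DP" in info:
        try:
            depth = int(info["DP"])
        except (TypeError, ValueError):
            depth = None

    records = []
    for alt_index, alt in enumerate(alts, start=1):
        if alt in (".", "") or alt.startswith("<") or not set(alt) <= _ALLELE_CHARS:
            continue
        if gt_alleles is not None:
            copies = gt_alleles.count(alt_index)
            if copies == 0:
                continue  # allele not carried by this sample
            zygosity = HOM if copies >= 2 else HET
        else:
            zygosity = UNKNOWN
        rpos, rref, ralt = _reduce_vcf_alleles(pos, ref, alt)
        var_class = _classify_alleles(rref, ralt)
        if var_class is None:
            raise ValueError(f"unsupported allele pair {ref}>{alt}")
        records.append(
            VariantRecord(
                contig=contig,
                pos=rpos,
                ref_allele=rref,
                alt_allele=ralt,
                var_class=var_class,
                zygosity=zygosity,
                support=depth,
                sample_id=sample_id,
                raw_line_no=line_no,
                info=info,
            )
        )
    if not records:
        raise ValueError("no usable ALT allele on line")
    return records


def _decode_consensus(
    contig: str,
    pos: int,
    ref: str,
    consensus: str,
    depth: int | None,
    sample_id: str,
    line_no: int,
) -> list[VariantRecord]:
    """Shared SNV logic for the pileup and SOAPsnp consensus columns."""
    if ref not in _ALLELE_CHARS:
        raise ValueError(f"bad reference base {ref!r}")
    decoded = IUPAC.get(consensus)
    if decoded is None:
        raise ValueError(f"bad consensus code {consensus!r}")
    alts = [b for b in decoded if b != ref]
    if not alts:
        raise ValueError("consensus equals reference (no variant)")
    zygosity = HET if (ref in decoded or len(alts) > 1) else HOM
    return [
        VariantRecord(
            contig=contig,
            pos=pos,
            ref_allele=ref,
            alt_allele=alt,
            var_class=SNV,
            zygosity=zygosity,
            support=depth,
            sample_id=sample_id,
            raw_line_no=line_no,
        )
        for alt in alts
    ]


def _pileup_records(
    fields: list[str], sample_id: str, line_no: int
) -> list[VariantRecord]:
    if len(fields) < 8:
        raise ValueError(f"expected >= 8 pileup columns, got {len(fields)}")
    contig = fields[0]
    pos = int(fields[1])
    ref = fields[2].upper()
    consensus = fields[3].upper()
    try:
        depth = int(fields[7])
    except ValueError:
        depth = None
    if ref != "*":
        return _decode_consensus(
            contig, pos, ref, consensus, depth, sample_id, line_no
        )
    # indel line: consensus like "+AG/+AG", "-C/*"
    alleles = consensus.split("/")
    called = [a for a in alleles if a != "*"]
    if not called:
        raise ValueError("indel line with no called allele")
    zygosity = HOM if len(set(alleles)) == 1 else HET
    records = []
    for allele in dict.fromkeys(called):
        if len(allele) < 2 or allele[0] not in "+-":
            raise ValueError(f"bad indel allele {allele!r}")
        seq = allele[1:]
        if not set(seq) <= _ALLELE_CHARS:
            raise ValueError(f"bad indel sequence {seq!r}")
        if allele[0] == "+":
            rec = VariantRecord(
                contig=contig,
                pos=pos + 1,  # inserted before the base after the anchor
                ref_allele="",
                alt_allele=seq,
                var_class=INSERTION,
                zygosity=zygosity,
                support=depth,
                sample_id=sample_id,
                raw_line_no=line_no,
            )
        else:
            rec = VariantRecord(
                contig=contig,
                pos=pos + 1,  # first deleted base
                ref_allele=seq,
                alt_allele="",
                var_class=DELETION,
                zygosity=zygosity,
                support=depth,
                sample_id=sample_id,
                raw_line_no=line_no,
            )
        records.append(rec)
    return records


def _soapsnp_records(
    fields: list[str], sample_id: str, line_no: int
) -> list[VariantRecord]:
    if len(fields) < 14:
        raise ValueError(f"expected >= 14 SOAPsnp columns, got {len(fields)}")
    contig = fields[0]
    pos = int(fields[1])
    ref = fields[2].upper()
    consensus = fields[3].upper()
    try:
        depth = int(fields[13])
    except ValueError:
        depth = None
    return _decode_consensus(contig, pos, ref, consensus, depth, sample_id, line_no)


_DIALECTS = {
    "vcf": _vcf_records,
    "pileup": _pileup_records,
    "soapsnp": _soapsnp_records,
}


def read_variants(
    path,
    dialect: str,
    sample_id: str,
    contig_alias: dict[str, str] | None = None,
) -> tuple[list[VariantRecord], ParseSummary]:
    """Parse one per-sample variant file.

    Returns the well-formed records plus a :class:`ParseSummary` counting
    input, unavailable (malformed, logged with line numbers) and effective
    data lines.  ``contig_alias`` maps source contig names onto reference
    names (e.g. ``{"1": "chr1"}``).
    """
    if dialect not in _DIALECTS:
        raise VariantFileError(f"unknown dialect {dialect!r}")
    parse_line = _DIALECTS[dialect]
    records: list[VariantRecord] = []
    n_input = n_unavailable = 0
    try:
        handle = open_text(path)
    except OSError as exc:
        raise VariantFileError(f"cannot read {path}: {exc}") from exc
    with handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_input += 1
            try:
                recs = parse_line(line.split("\t"), sample_id, line_no)
            except (ValueError, IndexError) as exc:
                n_unavailable += 1
                logger.warning("%s line %d unavailable: %s", path, line_no, exc)
                continue
            if contig_alias:
                recs = [
                    replace(r, contig=contig_alias.get(r.contig, r.contig))
                    for r in recs
                ]
            records.extend(recs)
    summary = ParseSummary(
        n_input=n_input,
        n_unavailable=n_unavailable,
        n_effective=n_input - n_unavailable,
    )
    return records, summary


def normalize_indel(v: VariantRecord, genome: GenomeSequence) -> VariantRecord:
    """Left-align an indel to its minimal leftmost representation.

    The edit is shifted left one base at a time while the resulting
    haplotype is unchanged (the classical rotate-while-equal rule).
    Idempotent; SNVs are returned unchanged.  Raises
    :class:`ReferenceMismatchError` when a deletion's stated bases disagree
    with the genome.
    """
    if v.is_snv:
        return v
    seq = v.ref_allele if v.var_class == DELETION else v.alt_allele
    pos = v.pos
    if v.var_class == DELETION:
        observed = genome.fetch(v.contig, pos - 1, pos - 1 + len(seq))
        if observed != seq:
            raise ReferenceMismatchError(
                f"{v.contig}:{pos} deletion claims {seq!r} but genome has "
                f"{observed!r}"
            )
    while pos > 1 and genome.base(v.contig, pos - 1) == seq[-1]:
        seq = genome.base(v.contig, pos - 1) + seq[:-1]
        pos -= 1
    if v.var_class == DELETION:
        return replace(v, pos=pos, ref_allele=seq)
    return replace(v, pos=pos, alt_allele=seq)


def apply_edit(sequence: str, start0: int, v: VariantRecord) -> str:
    """Apply a variant to a sequence window beginning at 0-based ``start0``.

    Utility shared by the normalizer's haplotype semantics, the fixture
    generator and the brute-force test oracles.
    """
    i = v.pos - 1 - start0
    if v.is_snv:
        return sequence[:i] + v.alt_allele + sequence[i + 1:]
    if v.var_class == DELETION:
        return sequence[:i] + sequence[i + len(v.ref_allele):]
    return sequence[:i] + v.alt_allele + sequence[i:]


# --- VCF output -----------------------------------------------------------

VCF_INFO_KEYS = ("EA_FUNC", "EA_GENE", "EA_AAC", "EA_NOVEL", "EA_MAFP")

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=EA_FUNC,Number=1,Type=String,Description="Functional category">
##INFO=<ID=EA_GENE,Number=1,Type=String,Description="Gene name">
##INFO=<ID=EA_AAC,Number=1,Type=String,Description="Amino-acid change">
##INFO=<ID=EA_NOVEL,Number=1,Type=String,Description="Novelty vs known-variant catalogue">
##INFO=<ID=EA_MAFP,Number=1,Type=String,Description="Population MAF chi-square p-values">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def vcf_alleles(v: VariantRecord, genome: GenomeSequence) -> tuple[int, str, str]:
    """Convert a record to VCF (pos, REF, ALT) with anchor base for indels."""
    if v.is_snv:
        return v.pos, v.ref_allele, v.alt_allele
    if v.pos <= 1:
        raise ValueError("cannot anchor an indel at position 1")
    anchor = genome.base(v.contig, v.pos - 1)
    if v.var_class == DELETION:
        return v.pos - 1, anchor + v.ref_allele, anchor
    return v.pos - 1, anchor, anchor + v.alt_allele


def write_vcf(
    records,
    genome: GenomeSequence,
    path,
    sample_id: str = "SAMPLE",
    info_of=None,
) -> None:
    """Write records as a sorted VCF 4.2 file.

    ``info_of(record) -> dict`` may supply per-record INFO annotations
    (typically the EA_* keys); records keep their zygosity in a GT field.
    """
    gt = {HET: "0/1", HOM: "1/1", UNKNOWN: "./."}
    rows = []
    for v in records:
        pos, ref, alt = vcf_alleles(v, genome)
        info_items = info_of(v) if info_of else {}
        info = (
            ";".join(f"{k}={info_items[k]}" for k in info_items if info_items[k])
            or "."
        )
        rows.append((v.contig, pos, ref, alt, info, gt[v.zygosity]))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "wt") as out:
        out.write(_VCF_HEADER)
        for name in sorted({r[0] for r in rows}):
            out.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_id}\n"
        )
        for contig, pos, ref, alt, info, gt_field in rows:
            out.write(
                f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\tGT\t{gt_field}\n"
            )
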