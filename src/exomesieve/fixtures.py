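"""Deterministic synthetic data with complete truth labels.

Generates everything the pipeline consumes — a reference genome, a
refGene-style gene table, per-sample variant files, a known-variant
catalogue and a population allele-count panel — with a truth table
recording every planted variant's intended category, novelty, zygosity,
cohort membership and frequency-test outcome.  All randomness flows
through one ``numpy`` generator seeded from the spec, so the same spec
always yields byte-identical files.

Genes are built so that every CDS starts with ATG, ends with a stop, has
no internal stop and a length divisible by 3; both strands are
represented, and one gene is nested inside another gene's intron whenever
four or more genes are requested.  Planted variants are verified at
generation time: each proposed site is annotated with the real annotator
and re-proposed until the representative category matches the intent, and
each panel entry is checked with the real chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import (
    Annotator,
    CODON_TO_AA,
    KNOWN,
    KNOWN_DISEASE,
    KnownVariantDB,
    NOVEL,
    translate_codon,
)
from .genome import (
    GenomeSequence,
    Transcript,
    cds_offset_to_genomic,
    complement,
    spliced_cds,
)
from .popfreq import PopulationPanel, test_all_populations
from .variants import (
    DELETION,
    HET,
    HOM,
    INSERTION,
    SNV,
    VariantRecord,
    normalize_indel,
    vcf_alleles,
    write_vcf,
)

SENSE_CODONS = tuple(sorted(c for c, a in CODON_TO_AA.items() if a != "*"))
STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"

DEFAULT_SNV_COUNTS = {
    "missense": 30, "syn_code": 25, "nonsense": 8, "read_through": 4,
    "splice_site": 10, "intron": 40, "utr5": 15, "utr3": 15, "intergenic": 20,
}
DEFAULT_INDEL_COUNTS = {
    "frame_shift": 10, "aa_insertion": 5, "aa_deletion": 5, "non_coding": 12,
}

_TRIO_DECOY_PATTERNS = (
    ("het", "het", "hom_ref"),       # inherited from father (dominant)
    ("het", "hom_ref", "het"),       # inherited from mother (dominant)
    ("hom_alt", "het", "hom_alt"),   # dominant, not recessive pattern
    ("hom_ref", "het", "het"),       # carrier parents, unaffected child
    ("het", "hom_alt", "hom_alt"),   # dominant
    ("hom_alt", "hom_alt", "het"),   # dominant
)


class FixtureError(RuntimeError):
    """Requested composition is infeasible for the generated geometry."""


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic study.

    Counts are per sample; cohort fields add variants shared across case
    samples and, optionally, a child/father/mother trio with planted
    de novo and recessive-homozygous variants.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 50_000
    n_genes: int = 8
    exons_per_gene: tuple[int, int] = (2, 5)
    snv_counts: dict = field(default_factory=lambda: dict(DEFAULT_SNV_COUNTS))
    indel_counts: dict = field(default_factory=lambda: dict(DEFAULT_INDEL_COUNTS))
    hom_fraction: float = 0.3
    known_fraction: float = 0.35
    clinical_fraction: float = 0.25  # of known entries
    panel_absent_fraction: float = 0.15
    divergent_fraction: float = 0.5
    n_catalogue_decoys: int = 40
    panel_populations: tuple[str, ...] = ("YRI", "JPT", "CHB", "CEU")
    panel_chromosomes: int = 200  # alleles per population
    n_cases: int = 1
    n_controls: int = 0
    n_shared_cases: int = 0          # planted in every case
    n_shared_partial: int = 0        # planted in exactly two cases
    n_shared_with_controls: int = 0  # in every case and the first control
    trio: bool = False
    n_denovo: int = 2
    n_recessive: int = 2
    n_trio_decoys: int = 6


@dataclass
class Fixture:
    """Generated study: in-memory objects plus writers for the file forms."""

    spec: FixtureSpec
    genome: GenomeSequence
    transcripts: list[Transcript]
    samples: dict[str, list[VariantRecord]]
    truth: pd.DataFrame
    trio_truth: pd.DataFrame
    known_db: KnownVariantDB
    panel: PopulationPanel

    @property
    def case_ids(self) -> list[str]:
        return [f"CASE{i+1}" for i in range(self.spec.n_cases)]

    @property
    def control_ids(self) -> list[str]:
        return [f"CTRL{i+1}" for i in range(self.spec.n_controls)]

    def write(self, outdir) -> dict[str, Path]:
        """Write every pipeline input format plus the truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "reference.fa",
            "genes": outdir / "genes.txt",
            "known": outdir / "known.vcf",
            "panel": outdir / "panel.tsv",
            "manifest": outdir / "manifest.tsv",
            "truth": outdir / "truth_table.tsv",
        }
        write_fasta(self.genome, paths["fasta"])
        write_gene_table(self.transcripts, paths["genes"])
        write_catalogue_vcf(self.known_db, self.genome, paths["known"])
        self.panel.write(paths["panel"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        roles = {}
        for sid in self.case_ids:
            roles[sid] = "case"
        for sid in self.control_ids:
            roles[sid] = "control"
        if self.spec.trio:
            roles.update(CHILD="child", FATHER="father", MOTHER="mother")
        with open(paths["manifest"], "wt") as out:
            for sid in self.samples:
                vcf_path = outdir / f"{sid}.vcf"
                write_vcf(self.samples[sid], self.genome, vcf_path, sample_id=sid)
                paths[f"vcf:{sid}"] = vcf_path
                out.write(f"{sid}\t{roles[sid]}\t{vcf_path}\n")
        return paths


# --- reference construction ----------------------------------------------


def _random_contig(rng: np.random.Generator, n: int) -> bytearray:
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytearray(lookup[rng.integers(0, 4, size=n)].tobytes())


def _make_transcript(
    rng: np.random.Generator,
    name: str,
    gene: str,
    contig: str,
    strand: str,
    start: int,
    n_exons: int,
    exon_len: tuple[int, int] = (120, 240),
    intron_len: tuple[int, int] = (150, 400),
    forced_intron0: int | None = None,
) -> Transcript:
    exon_lens = [int(rng.integers(exon_len[0], exon_len[1] + 1))
                 for _ in range(n_exons)]
    intron_lens = [int(rng.integers(intron_len[0], intron_len[1] + 1))
                   for _ in range(max(n_exons - 1, 0))]
    if forced_intron0 is not None and intron_lens:
        intron_lens[0] = forced_intron0
    exons = []
    pos = start
    for i, length in enumerate(exon_lens):
        exons.append((pos, pos + length))
        pos += length + (intron_lens[i] if i < len(intron_lens) else 0)
    total_exonic = sum(exon_lens)
    low = int(rng.integers(20, 61))   # UTR bases on the low-coordinate side
    high = int(rng.integers(20, 61))
    low = min(low, exon_lens[0] - 6, total_exonic // 4)
    high = min(high, exon_lens[-1] - 6, total_exonic // 4)
    cds_len = total_exonic - low - high
    high += cds_len % 3
    cds_len -= cds_len % 3
    if cds_len < 15:
        raise FixtureError("gene geometry leaves too short a CDS")
    t = Transcript(
        transcript_id=name,
        gene_name=gene,
        contig=contig,
        strand=strand,
        tx_start=exons[0][0],
        tx_end=exons[-1][1],
        cds_start=exons[0][0] + low,
        cds_end=exons[-1][1] - high,
        exons=tuple(exons),
    )
    t.validate()
    return t


def _write_cds(
    rng: np.random.Generator, t: Transcript, seq: bytearray
) -> None:
    """Overwrite the transcript's CDS bases with ATG + sense codons + stop."""
    n_codons = t.cds_length // 3
    codons = ["ATG"]
    codons += [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS),
                                                     size=n_codons - 2)]
    codons.append(STOP_CODONS[int(rng.integers(0, 3))])
    cds = "".join(codons)
    for off in range(t.cds_length):
        g = cds_offset_to_genomic(t, off)
        base = cds[off] if t.strand == "+" else complement(cds[off])
        seq[g] = ord(base)


def generate_reference(
    spec: FixtureSpec, rng: np.random.Generator
) -> tuple[GenomeSequence, list[Transcript]]:
    """Random genome plus gene models honouring the construction invariants."""
    raw = {
        f"chr{i+1}": _random_contig(rng, spec.contig_length)
        for i in range(spec.n_contigs)
    }
    contig_names = list(raw)
    cursors = {c: 1000 for c in contig_names}
    transcripts: list[Transcript] = []
    lo, hi = spec.exons_per_gene
    nest = spec.n_genes >= 4
    g = 0
    attempt = 0
    while len(transcripts) < spec.n_genes:
        attempt += 1
        if attempt > spec.n_genes * 20:
            raise FixtureError("cannot place requested genes on the contigs")
        if nest and len(transcripts) == 1:
            # nest gene 2 inside gene 1's (forced-large) first intron
            host = transcripts[0]
            intron = (host.exons[0][1], host.exons[1][0])
            t = _make_transcript(
                rng, "TX0002", "GENE2", host.contig,
                "-" if host.strand == "+" else "+",
                start=intron[0] + 60,
                n_exons=int(rng.integers(1, 3)),
                exon_len=(120, 200),
                intron_len=(80, 150),
            )
            if t.tx_end > intron[1] - 60:
                raise FixtureError("nested gene does not fit the host intron")
            transcripts.append(t)
            g += 1
            continue
        contig = contig_names[g % spec.n_contigs]
        n_exons = int(rng.integers(lo, hi + 1))
        forced = None
        if nest and not transcripts:
            n_exons = max(n_exons, 2)
            forced = int(rng.integers(2600, 3200))
        strand = "+" if rng.random() < 0.5 else "-"
        t = _make_transcript(
            rng, f"TX{len(transcripts)+1:04d}", f"GENE{len(transcripts)+1}",
            contig, strand, start=cursors[contig], n_exons=n_exons,
            forced_intron0=forced,
        )
        if t.tx_end > spec.contig_length - 1000:
            raise FixtureError(
                "contigs too short for the requested gene count"
            )
        cursors[contig] = t.tx_end + 400
        transcripts.append(t)
        g += 1
    for t in transcripts:
        _write_cds(rng, t, raw[t.contig])
    genome = GenomeSequence({c: raw[c].decode() for c in raw})
    for t in transcripts:
        protein = [translate_codon(spliced_cds(t, genome)[i:i + 3])
                   for i in range(0, t.cds_length, 3)]
        assert protein[0] == "M" and protein[-1] == "*"
        assert "*" not in protein[:-1]
    return genome, transcripts


def random_transcript(
    rng: np.random.Generator,
    contig: str = "chrT",
    contig_length: int = 3000,
    n_exons: int | None = None,
    exon_len: tuple[int, int] = (30, 90),
    intron_len: tuple[int, int] = (20, 60),
) -> tuple[GenomeSequence, Transcript]:
    """One small random gene on its own contig (for oracle-scale tests)."""
    if n_exons is None:
        n_exons = int(rng.integers(1, 7))
    raw = _random_contig(rng, contig_length)
    strand = "+" if rng.random() < 0.5 else "-"
    t = _make_transcript(
        rng, "TXT001", "GENET", contig, strand,
        start=300, n_exons=n_exons, exon_len=exon_len, intron_len=intron_len,
    )
    if t.tx_end > contig_length - 200:
        raise FixtureError("toy transcript does not fit its contig")
    _write_cds(rng, t, raw)
    return GenomeSequence({contig: raw.decode()}), t


# --- file writers ---------------------------------------------------------


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    with open(path, "wt") as out:
        for name in sorted(genome.contigs):
            out.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def write_gene_table(transcripts, path) -> None:
    """refGene-style 11-column dump (genePred + gene symbol)."""
    with open(path, "wt") as out:
        for t in transcripts:
            starts = ",".join(str(s) for s, _e in t.exons) + ","
            ends = ",".join(str(e) for _s, e in t.exons) + ","
            out.write("\t".join([
                t.transcript_id, t.contig, t.strand,
                str(t.tx_start), str(t.tx_end),
                str(t.cds_start), str(t.cds_end),
                str(len(t.exons)), starts, ends, t.gene_name,
            ]) + "\n")


def write_catalogue_vcf(db: KnownVariantDB, genome: GenomeSequence, path) -> None:
    rows = []
    for (contig, pos, ref, alt), (rs, clinical) in db.entries.items():
        var_class = SNV if ref and alt else (DELETION if ref else INSERTION)
        rec = VariantRecord(contig=contig, pos=pos, ref_allele=ref,
                            alt_allele=alt, var_class=var_class)
        vpos, vref, valt = vcf_alleles(rec, genome)
        info = "CLN=1" if clinical else "."
        rows.append((contig, vpos, rs, vref, valt, info))
    rows.sort()
    with open(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(
            '##INFO=<ID=CLN,Number=1,Type=Integer,'
            'Description="Clinically associated">\n'
        )
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos, rs, ref, alt, info in rows:
            out.write(f"{contig}\t{pos}\t{rs}\t{ref}\t{alt}\t.\t.\t{info}\n")


# --- variant planting -----------------------------------------------------


class _Planner:
    """Places variants whose representative annotation matches an intent."""

    def __init__(self, spec, genome, transcripts, rng):
        self.spec = spec
        self.genome = genome
        self.transcripts = transcripts
        self.coding = [t for t in transcripts if t.is_coding]
        self.rng = rng
        self.annotator = Annotator(genome, transcripts)
        self.occupied: dict[str, set[int]] = {c: set() for c in genome.contigs}
        self._nonsense_cache: dict[str, list[tuple[int, str]]] = {}
        self._readthrough_cache: dict[str, list[tuple[int, str]]] = {}

    def _free(self, contig: str, pos: int, margin: int = 9) -> bool:
        occ = self.occupied[contig]
        return not any((pos + d) in occ for d in range(-margin, margin + 1))

    def _reserve(self, contig: str, pos: int) -> None:
        self.occupied[contig].add(pos)

    def _random_alt(self, ref: str) -> str:
        choices = [b for b in _BASES if b != ref]
        return choices[int(self.rng.integers(0, 3))]

    def _stop_edits(self, t: Transcript, to_stop: bool) -> list[tuple[int, str]]:
        """(cds_offset, coding_alt) single-base edits creating (or removing)
        a stop codon, computed from the spliced CDS string."""
        cache = self._nonsense_cache if to_stop else self._readthrough_cache
        if t.transcript_id in cache:
            return cache[t.transcript_id]
        cds = spliced_cds(t, self.genome)
        edits = []
        codon_range = (
            range(1, len(cds) // 3 - 1) if to_stop
            else range(len(cds) // 3 - 1, len(cds) // 3)
        )
        for ci in codon_range:
            codon = cds[3 * ci:3 * ci + 3]
            for within in range(3):
                for alt in _BASES:
                    if alt == codon[within]:
                        continue
                    mutated = codon[:within] + alt + codon[within + 1:]
                    made_stop = translate_codon(mutated) == "*"
                    if to_stop and made_stop and translate_codon(codon) != "*":
                        edits.append((3 * ci + within, alt))
                    if not to_stop and not made_stop and (
                        translate_codon(codon) == "*"
                    ):
                        edits.append((3 * ci + within, alt))
        cache[t.transcript_id] = edits
        return edits

    def _coding_edit(self, t: Transcript, category: str):
        """Pick (genomic pos1, ref, alt) for a CDS-category SNV intent."""
        rng = self.rng
        if category in ("nonsense", "read_through"):
            edits = self._stop_edits(t, to_stop=category == "nonsense")
            if not edits:
                return None
            off, coding_alt = edits[int(rng.integers(0, len(edits)))]
        else:
            if t.cds_length < 12:
                return None
            off = int(rng.integers(3, t.cds_length - 3))
            cds = spliced_cds(t, self.genome)
            ci, within = divmod(off, 3)
            codon = cds[3 * ci:3 * ci + 3]
            if translate_codon(codon) == "*":
                return None
            wanted_same = category == "syn_code"
            options = []
            for alt in _BASES:
                if alt == codon[within]:
                    continue
                mutated = codon[:within] + alt + codon[within + 1:]
                aa_ref, aa_alt = translate_codon(codon), translate_codon(mutated)
                if wanted_same and aa_ref == aa_alt:
                    options.append(alt)
                if not wanted_same and aa_alt not in ("*", aa_ref):
                    options.append(alt)
            if not options:
                return None
            coding_alt = options[int(rng.integers(0, len(options)))]
        pos0 = cds_offset_to_genomic(t, off)
        ref = self.genome.base(t.contig, pos0 + 1)
        alt = coding_alt if t.strand == "+" else complement(coding_alt)
        if alt == ref:
            return None
        return t.contig, pos0 + 1, ref, alt

    def _region_ranges(self, t: Transcript, category: str) -> list[tuple[int, int]]:
        """Genomic 0-based half-open ranges whose bases carry a region label."""
        w = self.annotator.splice_window
        if category in ("utr5", "utr3"):
            genomic_low = (category == "utr5") == (t.strand == "+")
            ranges = []
            for s, e in t.exons:
                if genomic_low:
                    lo, hi = s, min(e, t.cds_start)
                else:
                    lo, hi = max(s, t.cds_end), e
                if lo < hi:
                    ranges.append((lo, hi))
            return ranges
        if category == "intron":
            return [
                (t.exons[i][1] + w, t.exons[i + 1][0] - w)
                for i in range(len(t.exons) - 1)
                if t.exons[i][1] + w < t.exons[i + 1][0] - w
            ]
        if category == "splice_site":
            ranges = []
            for i in range(len(t.exons) - 1):
                left, right = t.exons[i][1], t.exons[i + 1][0]
                ranges.append((left, min(left + w, right)))
                ranges.append((max(right - w, left), right))
            return ranges
        raise ValueError(category)

    def _propose_snv(self, category: str):
        rng = self.rng
        if category == "intergenic":
            contig = f"chr{int(rng.integers(0, self.spec.n_contigs)) + 1}"
            pos = int(rng.integers(2, self.genome.length(contig) - 1)) + 1
            ref = self.genome.base(contig, pos)
            return contig, pos, ref, self._random_alt(ref)
        t = self.coding[int(rng.integers(0, len(self.coding)))]
        if category in ("missense", "syn_code", "nonsense", "read_through"):
            return self._coding_edit(t, category)
        ranges = self._region_ranges(t, category)
        ranges = [r for r in ranges if r[0] < r[1]]
        if not ranges:
            return None
        lengths = np.array([e - s for s, e in ranges], dtype=float)
        i = int(rng.choice(len(ranges), p=lengths / lengths.sum()))
        pos0 = int(rng.integers(ranges[i][0], ranges[i][1]))
        ref = self.genome.base(t.contig, pos0 + 1)
        return t.contig, pos0 + 1, ref, self._random_alt(ref)

    def plant_snv(self, category: str, zygosity: str, sample_id: str,
                  max_attempts: int = 400) -> VariantRecord:
        for _ in range(max_attempts):
            proposal = self._propose_snv(category)
            if proposal is None:
                continue
            contig, pos, ref, alt = proposal
            # SNVs only need distinct positions; a 1 bp guard keeps codon
            # edits from stacking up in one frame
            if not self._free(contig, pos, margin=1):
                continue
            rec = VariantRecord(
                contig=contig, pos=pos, ref_allele=ref, alt_allele=alt,
                var_class=SNV, zygosity=zygosity, sample_id=sample_id,
                support=int(self.rng.integers(10, 80)),
            )
            _, rep = self.annotator.annotate(rec)
            if rep.category != category:
                continue
            self._reserve(contig, pos)
            return rec
        raise FixtureError(f"no available site for SNV category {category!r}")

    def _propose_indel(self, category: str):
        rng = self.rng
        is_insertion = bool(rng.integers(0, 2))
        if category == "frame_shift":
            length = int(rng.choice([1, 2, 4]))
        elif category in ("aa_insertion", "aa_deletion"):
            length = 3
            is_insertion = category == "aa_insertion"
        else:  # non_coding
            length = int(rng.integers(1, 5))
        t = self.coding[int(rng.integers(0, len(self.coding)))]
        if category == "non_coding":
            ranges = self._region_ranges(t, "intron")
            ranges = [
                (s + length + 4, e - length - 4) for s, e in ranges
                if e - s > 2 * length + 10
            ]
            if not ranges:
                return None
            s, e = ranges[int(rng.integers(0, len(ranges)))]
            pos0 = int(rng.integers(s, e))
        else:
            exons = [
                (s, e) for s, e in t.cds_exons if e - s > 2 * length + 12
            ]
            if not exons:
                return None
            s, e = exons[int(rng.integers(0, len(exons)))]
            pos0 = int(rng.integers(s + length + 4, e - length - 4))
        if is_insertion:
            seq = "".join(
                _BASES[i] for i in rng.integers(0, 4, size=length)
            )
            return VariantRecord(
                contig=t.contig, pos=pos0 + 1, ref_allele="", alt_allele=seq,
                var_class=INSERTION,
            )
        seq = self.genome.fetch(t.contig, pos0, pos0 + length)
        return VariantRecord(
            contig=t.contig, pos=pos0 + 1, ref_allele=seq, alt_allele="",
            var_class=DELETION,
        )

    def plant_indel(self, category: str, zygosity: str, sample_id: str,
                    max_attempts: int = 400) -> VariantRecord:
        from dataclasses import replace

        for _ in range(max_attempts):
            rec = self._propose_indel(category)
            if rec is None:
                continue
            rec = normalize_indel(rec, self.genome)
            if rec.pos <= 1 or not self._free(rec.contig, rec.pos):
                continue
            rec = replace(
                rec, zygosity=zygosity, sample_id=sample_id,
                support=int(self.rng.integers(10, 80)),
            )
            _, rep = self.annotator.annotate(rec)
            if rep.category != category:
                continue
            self._reserve(rec.contig, rec.pos)
            return rec
        raise FixtureError(f"no available site for indel category {category!r}")


# --- panel ----------------------------------------------------------------


def generate_panel(
    spec: FixtureSpec,
    genome: GenomeSequence,
    site_plan: dict[tuple[str, int, str, str], tuple[str, bool]],
) -> PopulationPanel:
    """Panel whose per-site counts realize the planted divergence intents.

    ``site_plan`` maps a planted SNV key to (zygosity, divergent).  A
    divergent site gets counts maximally skewed away from the sample's
    alleles; a matching site gets counts at exactly the sample's allele
    frequency, so its chi-square statistic is 0.  Each entry is verified
    by running the production chi-square test.
    """
    n = spec.panel_chromosomes
    sites = {}
    for (contig, pos, ref, alt), (zygosity, divergent) in site_plan.items():
        if divergent:
            counts = (n, 0)
        elif zygosity == HOM:
            counts = (0, n)
        else:
            counts = (n // 2, n - n // 2)
        sites[(contig, pos)] = (
            ref, alt, {p: counts for p in spec.panel_populations}
        )
    panel = PopulationPanel(spec.panel_populations, sites)
    for (contig, pos, ref, alt), (zygosity, divergent) in site_plan.items():
        probe = VariantRecord(
            contig=contig, pos=pos, ref_allele=ref, alt_allele=alt,
            var_class=SNV, zygosity=zygosity,
        )
        results = test_all_populations(probe, panel)
        assert results and all(r.significant == divergent for r in results), (
            f"panel self-check failed at {contig}:{pos}"
        )
    return panel


# --- top-level generation -------------------------------------------------


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the complete study described by the spec."""
    rng = np.random.default_rng(spec.seed)
    genome, transcripts = generate_reference(spec, rng)
    planner = _Planner(spec, genome, transcripts, rng)

    case_ids = [f"CASE{i+1}" for i in range(spec.n_cases)]
    control_ids = [f"CTRL{i+1}" for i in range(spec.n_controls)]
    samples: dict[str, list[VariantRecord]] = {
        sid: [] for sid in case_ids + control_ids
    }
    truth_rows: list[dict] = []
    catalogue: dict[tuple[str, int, str, str], tuple[str, bool]] = {}
    site_plan: dict[tuple[str, int, str, str], tuple[str, bool]] = {}
    rs_counter = [0]

    def decide_novelty(key) -> tuple[str, str | None]:
        if rng.random() < spec.known_fraction:
            rs_counter[0] += 1
            rs = f"rs{rs_counter[0]:06d}"
            clinical = rng.random() < spec.clinical_fraction
            catalogue[key] = (rs, clinical)
            return (KNOWN_DISEASE if clinical else KNOWN), rs
        return NOVEL, None

    def decide_zygosity() -> str:
        return HOM if rng.random() < spec.hom_fraction else HET

    def register(rec: VariantRecord, members: list[str]) -> None:
        """Plant one site in the given samples and record its truth row."""
        from dataclasses import replace

        key = rec.key()
        novelty, rs = decide_novelty(key)
        _, rep = planner.annotator.annotate(rec)
        if rec.is_snv:
            in_panel = rng.random() >= spec.panel_absent_fraction
            divergent = (
                rng.random() < spec.divergent_fraction if in_panel else True
            )
            if in_panel:
                site_plan[key] = (rec.zygosity, divergent)
        else:
            in_panel, divergent = False, True
        for sid in members:
            samples[sid].append(replace(rec, sample_id=sid))
            truth_rows.append({
                "sample_id": sid,
                "contig": key[0], "pos": key[1],
                "ref_allele": key[2], "alt_allele": key[3],
                "var_class": rec.var_class,
                "category": rep.category,
                "zygosity": rec.zygosity,
                "novelty": novelty,
                "rs_id": rs or ".",
                "in_panel": in_panel,
                "divergent": divergent,
            })

    shared_categories = ("missense", "syn_code", "intron")

    def plant_shared(count: int, members: list[str]) -> None:
        for i in range(count):
            category = shared_categories[i % len(shared_categories)]
            rec = planner.plant_snv(category, decide_zygosity(), members[0])
            register(rec, members)

    if spec.n_cases >= 2:
        plant_shared(spec.n_shared_cases, case_ids)
        plant_shared(spec.n_shared_partial, case_ids[:2])
        if spec.n_controls:
            plant_shared(
                spec.n_shared_with_controls, case_ids + control_ids[:1]
            )

    for sid in case_ids + control_ids:
        for category, count in spec.snv_counts.items():
            for _ in range(count):
                rec = planner.plant_snv(category, decide_zygosity(), sid)
                register(rec, [sid])
        for category, count in spec.indel_counts.items():
            for _ in range(count):
                rec = planner.plant_indel(category, decide_zygosity(), sid)
                register(rec, [sid])

    trio_rows: list[dict] = []
    if spec.trio:
        for sid in ("CHILD", "FATHER", "MOTHER"):
            samples[sid] = []
        patterns = (
            [("het", "hom_ref", "hom_ref")] * spec.n_denovo
            + [("hom_alt", "het", "het")] * spec.n_recessive
            + [
                _TRIO_DECOY_PATTERNS[i % len(_TRIO_DECOY_PATTERNS)]
                for i in range(spec.n_trio_decoys)
            ]
        )
        trio_categories = ("missense", "intron", "syn_code", "utr3")
        from dataclasses import replace

        for i, (c_gt, f_gt, m_gt) in enumerate(patterns):
            category = trio_categories[i % len(trio_categories)]
            carrier_zyg = {"het": HET, "hom_alt": HOM}
            rec = planner.plant_snv(category, HET, "CHILD")
            for sid, gt in (("CHILD", c_gt), ("FATHER", f_gt), ("MOTHER", m_gt)):
                if gt in carrier_zyg:
                    samples[sid].append(
                        replace(rec, sample_id=sid, zygosity=carrier_zyg[gt])
                    )
            key = rec.key()
            trio_rows.append({
                "contig": key[0], "pos": key[1],
                "ref_allele": key[2], "alt_allele": key[3],
                "child_gt": c_gt, "father_gt": f_gt, "mother_gt": m_gt,
            })

    # catalogue decoys: known entries at sites no sample carries
    for _ in range(spec.n_catalogue_decoys):
        for _attempt in range(200):
            contig = f"chr{int(rng.integers(0, spec.n_contigs)) + 1}"
            pos = int(rng.integers(2, genome.length(contig) - 1)) + 1
            if not planner._free(contig, pos):
                continue
            ref = genome.base(contig, pos)
            alt = planner._random_alt(ref)
            rs_counter[0] += 1
            catalogue[(contig, pos, ref, alt)] = (
                f"rs{rs_counter[0]:06d}",
                rng.random() < spec.clinical_fraction,
            )
            planner._reserve(contig, pos)
            break
        else:
            raise FixtureError("no room for catalogue decoys")

    truth_columns = [
        "sample_id", "contig", "pos", "ref_allele", "alt_allele", "var_class",
        "category", "zygosity", "novelty", "rs_id", "in_panel", "divergent",
    ]
    trio_columns = [
        "contig", "pos", "ref_allele", "alt_allele",
        "child_gt", "father_gt", "mother_gt",
    ]
    return Fixture(
        spec=spec,
        genome=genome,
        transcripts=transcripts,
        samples=samples,
        truth=pd.DataFrame(truth_rows, columns=truth_columns),
        trio_truth=pd.DataFrame(trio_rows, columns=trio_columns),
        known_db=KnownVariantDB(catalogue),
        panel=generate_panel(spec, genome, site_plan),
    )
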