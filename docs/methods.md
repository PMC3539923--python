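# Methods

## Coordinate model

Gene models are UCSC-style: internally everything is 0-based half-open
(matching refGene dumps), while all user-facing positions are 1-based
(matching VCF). A transcript's exons must be sorted, non-overlapping and
span exactly [txStart, txEnd); a coding transcript's spliced CDS length
must be a positive multiple of 3. Transcripts violating the frame rule
are real in public refGene dumps; by default they are skipped at load
time with a warning (`on_invalid="keep"` retains them flagged
`broken_cds`, and flagged models are excluded from annotation entirely —
a silent wrong codon is worse than a missing annotation).

`locate()` is a total function mapping any genomic base to exactly one
region per transcript. Design choices:

* **splice_site** means *intronic* bases within `splice_window` of an
  exon boundary (default 2 bp — the canonical GT/AG dinucleotides; the
  window is configurable). An exonic base near a boundary keeps its
  exonic label, so the nine SNV categories partition every position.
* UTR labels follow coding orientation: on a minus-strand transcript the
  5' UTR lies at higher genomic coordinates than the CDS. For
  non-coding transcripts (cdsStart == cdsEnd) exonic bases degenerate to
  the same side rule; they carry no protein-level calls.
* Codons are read across exon junctions in coding orientation and
  reverse-complemented for minus-strand transcripts; concatenating all
  codons reproduces the spliced CDS exactly (a tested invariant).

## Variant representation

Indels are stored in pure form (deletion: deleted bases + empty alt,
position = first deleted base; insertion: inserted bases, position = the
base before which they go) and left-aligned by the rotate-while-equal
rule. Left-alignment is idempotent and haplotype-preserving (brute-force
checked on 50 bp windows), and the normalized (contig, pos, ref, alt)
tuple is the identity used for novelty lookup and all cross-sample set
operations. VCF output re-anchors indels on the preceding reference base.

Parsers are deliberately tolerant: a malformed line is counted as
"unavailable" with its line number logged, and the parse summary
(input = unavailable + effective) is part of every report. Multi-allelic
VCF rows split into one record per alternate allele carrying the
genotype's zygosity with respect to that allele; alleles with zero
copies in the genotype are not emitted. The pileup and SOAPsnp dialects
implement the contemporaneous de facto column layouts (consensus-pileup
10+ columns with `*`-reference indel lines; SOAPsnp 17 columns), with
IUPAC ambiguity codes decoded to zygosity (R at an A reference means a
heterozygous A/G call). Records on contigs absent from the reference are
errors only at annotation time; a contig-alias map (`{"1": "chr1"}`)
absorbs naming drift.

## Classification

SNVs in the CDS are classified by translating the reference and
alternate codons: same residue → `syn_code`; residue→stop → `nonsense`;
stop→residue → `read_through`; otherwise `missense`. A start-codon
disruption is reported as missense with a `start_loss` flag (the
category set has no start-loss class). Amino-acid changes use
three-letter p. notation with `Ter` for stops.

Indels are classified by the number of CDS bases the edit adds or
removes: zero → `non_coding` (with a `splice_adjacent` flag when the
affected interval touches an intronic splice window — the four-way indel
taxonomy has no splice class, so the signal is preserved without
breaking the partition); non-multiple of 3 → `frame_shift`; otherwise
`aa_insertion` / `aa_deletion`. An indel spanning a CDS/intron boundary
is classified by its CDS-intersecting portion. An insertion counts as
coding only when its insertion point is strictly inside a CDS exon;
insertions exactly at an exon/intron junction are non-coding (the
ambiguity is resolved conservatively).

Each variant is annotated against all overlapping transcripts; the
representative is the maximum under the severity order

    nonsense > frame_shift > read_through > splice_site > missense >
    aa_insertion = aa_deletion > syn_code > utr5 > utr3 > intron >
    non_coding > intergenic

with ties broken by lexicographic transcript id, so the choice is
independent of input order. (`non_coding`, absent from the original
ordering, is ranked just above `intergenic`.)

Novelty is an exact-allele lookup on normalized keys against the
catalogue; a position-only fallback exists for catalogues without
reliable allele detail. Entries flagged clinically associated return
`known_disease_related`, which the novelty filters can retain alongside
novel variants. Protein-impact prediction is not re-implemented: a
per-variant score table (e.g. precomputed SIFT output) can be attached
and threshold-filtered (score ≤ threshold = damaging, retained).

## Population-frequency test

Each SNV's two sample alleles are tabulated against one population's
panel counts in a 2x2 table and tested with Pearson's chi-square (1 df,
continuity correction off by default, Yates optional). A site is
significant when p < alpha (default 0.05). With a row total of 2 the
chi-square approximation is crude; whenever an expected cell falls below
`min_expected` (default 1) the result carries a `low_count` flag. The
flag is advisory by default: making it veto significance would make the
single-sample test *unable* to flag any site (with two sample alleles,
expected cells ≥ 1 force near-balanced columns, capping chi² at about
2(P+2)/P ≈ 2.03 for panel size P, below the 3.84 critical value), which
would defeat the frequency-divergence filter outright. A strict
`low_count_veto` mode is available, as is a pooled mode that sums allele
counts across case samples before testing. A site absent from the panel
has no test; the filter layer's default policy treats it as unexplained
by the panel — i.e. it passes the divergence criterion — with the
opposite policy one flag away.

## Filtering

Criteria are conjunctive and declarative; unset criteria pass
everything. The retained set is order-independent; the per-criterion
removal tally attributes each removed variant to the first failing
criterion in the documented order (SNP: novelty, frequency, mutation
type, classification, impact; indel: novelty, coding region, mutation
type, impact). "Mutation type" combines two independently settable
facets: substitution class (transition/transversion, or
insertion/deletion) and zygosity; records with unknown zygosity fail any
zygosity-restricted criterion as not assessable. A criterion referencing
data that was never supplied (frequency without a panel, impact without
scores) is a configuration error raised before any filtering.

## Cohort semantics

"Shared" identity is the normalized variant key — position and alleles —
not gene-level sharing (gene names are report columns, not the matching
unit). Multi-case candidates are variants retained (post-filter) in at
least k ≥ 2 cases and present in no control; controls exclude by mere
presence, i.e. their pre-filter effective keys. Trio filtering is
applied over the members' effective genotypes *before* any criteria
filtering, since filtering a parent's calls away first would fabricate
de novo support. A site absent from a member's call file is read as
hom_ref by default (exome call files omit reference-matching sites;
`absent="missing"` documents the risk), and sites with an explicitly
missing genotype are dropped under the default strictness. The three
models are explicit rather than one opaque switch; compound
heterozygotes are out of scope (they require phase).

## Synthetic studies

The generator emulates the *shape* of a small exome study, not human
genome statistics: two 50 kb contigs, eight genes (2–5 exons, both
strands, one gene nested inside another gene's intron to exercise
overlapping-transcript resolution), every CDS starting ATG, ending with
a stop, frame-clean and free of internal stops. Per sample it plants a
configurable per-category composition (defaults total ≈ 200 variants);
every proposed site is verified by annotating it with the production
annotator and re-proposed until the representative category matches the
intent, so truth labels are correct by construction. Novelty is planted
by inserting or omitting catalogue entries (some clinically flagged),
frequency divergence by skewing panel counts (maximally divergent vs
exactly frequency-matched, verified at generation time with the
production chi-square test), cohort structure by planting shared keys
across case/control samples, and trio structure by planting genotype
patterns including de novo and recessive-homozygous variants. All
randomness flows through a single seeded generator; identical specs
yield byte-identical files.

What passing these tests does **not** show: performance on real human
data with realistic mutation spectra, repeat-induced ambiguous
alignments beyond simple runs, multi-nucleotide/complex variants
(counted as unavailable by design), structural variants, or canonical
splice-motif sequence content (classification is coordinate-based; the
generator does not write GT/AG dinucleotides).

## Numerical and scale choices

Chi-square p-values come from the chi-square survival function; the
statistic is computed from expected counts and cross-checked in tests
against an independent implementation at 1e-9 relative tolerance and
against the closed 2x2 form. Degenerate tables (a zero margin) have
chi² = 0, p = 1. Oracle sweeps in the test and acceptance suites use 20
random transcripts (1–6 exons, both strands, ~3 kb contigs) with every
SNV over each span ±50 bp and every 1–6 bp indel — about 115,000
classifications — and complete in seconds; the end-to-end studies use
three cases, two controls and a trio at ~45 variants per sample. These
sizes were chosen to keep the full suite fast while exercising every
code path; all agreement requirements are exact (100%).
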