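"""End-to-end orchestration: single-case, two-case, multi-case and trio runs.

The single-case run is the backbone: parse one sample's calls, left-align
indels, annotate every effective record against the gene models, attach
novelty and population-frequency tests, apply the filter criteria and
assemble the three-part report.  The cohort runs compose single-case
results: two-case compares the retained sets; multi-case keeps variants
retained in at least ``k`` cases and excludes anything *present* (before
filtering) in a control; trio mode applies a Mendelian model over the
members' effective genotypes, since filtering a parent's calls away first
would fabricate de novo candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotate import Annotation, Annotator, KnownVariantDB, read_gene_terms, \
    read_score_table
from .cohort import (
    SharedUniqueResult,
    TrioSpec,
    VariantKey,
    genotype_of,
    key_of,
    shared_and_unique,
    shared_by_k,
    trio_filter,
)
from .filtering import FilterCriteria, FilterReport, filter_variants
from .genome import GenomeSequence, read_fasta, read_gene_models
from .popfreq import PopulationPanel, test_all_populations
from .reporting import (
    SampleReport,
    bundle_members,
    category_distribution,
    detail_frame,
    export_bundle,
)
from .variants import ParseSummary, ReferenceMismatchError, VariantRecord, \
    normalize_indel, read_variants, write_vcf

logger = logging.getLogger(__name__)


@dataclass
class Resources:
    """Shared reference data for a run."""

    genome: GenomeSequence
    annotator: Annotator
    panel: PopulationPanel | None = None

    @classmethod
    def load(
        cls,
        genome_path,
        genes_path,
        known_path=None,
        panel_path=None,
        gene_terms_path=None,
        score_path=None,
        splice_window: int = 2,
    ) -> "Resources":
        genome = read_fasta(genome_path)
        transcripts = read_gene_models(genes_path)
        known = (
            KnownVariantDB.from_vcf(known_path, genome=genome)
            if known_path else None
        )
        annotator = Annotator(
            genome,
            transcripts,
            known=known,
            gene_terms=read_gene_terms(gene_terms_path) if gene_terms_path else None,
            score_table=read_score_table(score_path) if score_path else None,
            splice_window=splice_window,
        )
        panel = PopulationPanel.read(panel_path) if panel_path else None
        return cls(genome=genome, annotator=annotator, panel=panel)


@dataclass
class SingleCaseResult:
    """Everything one sample's analysis produced."""

    sample_id: str
    parse_summary: ParseSummary
    n_reference_mismatch: int
    records: list[VariantRecord]
    annotations: list[Annotation]  # representative, pre-filter
    freq_results: dict[tuple, dict]
    retained: list[Annotation]
    filter_report: FilterReport
    criteria: FilterCriteria

    @property
    def effective_keys(self) -> set[VariantKey]:
        return {key_of(a) for a in self.annotations}

    @property
    def retained_keys(self) -> set[VariantKey]:
        return {key_of(a) for a in self.retained}

    def report(self) -> SampleReport:
        before_snv = [a for a in self.annotations if a.variant.is_snv]
        before_indel = [a for a in self.annotations if a.variant.is_indel]
        after_snv = [a for a in self.retained if a.variant.is_snv]
        after_indel = [a for a in self.retained if a.variant.is_indel]
        return SampleReport(
            sample_id=self.sample_id,
            parse_summary=self.parse_summary,
            criteria=self.criteria,
            filter_report=self.filter_report,
            distribution_snv=category_distribution(before_snv, after_snv, "snv"),
            distribution_indel=category_distribution(
                before_indel, after_indel, "indel"
            ),
            detail_snv=detail_frame(after_snv, "snv", self.freq_results),
            detail_indel=detail_frame(after_indel, "indel"),
        )


def annotate_sample(
    resources: Resources,
    variant_path,
    sample_id: str,
    dialect: str = "vcf",
    contig_alias: dict[str, str] | None = None,
) -> tuple[list[VariantRecord], ParseSummary, int]:
    """Parse, left-align and reference-check one sample's records."""
    records, summary = read_variants(
        variant_path, dialect, sample_id, contig_alias=contig_alias
    )
    normalized: list[VariantRecord] = []
    n_mismatch = 0
    for v in records:
        try:
            normalized.append(
                normalize_indel(v, resources.genome) if v.is_indel else v
            )
        except ReferenceMismatchError as exc:
            n_mismatch += 1
            logger.warning("%s: %s", sample_id, exc)
    return normalized, summary, n_mismatch


def run_single(
    resources: Resources,
    variant_path,
    sample_id: str,
    criteria: FilterCriteria | None = None,
    dialect: str = "vcf",
    contig_alias: dict[str, str] | None = None,
) -> SingleCaseResult:
    criteria = criteria or FilterCriteria()
    records, summary, n_mismatch = annotate_sample(
        resources, variant_path, sample_id, dialect, contig_alias
    )
    annotations, n_bad_ref = resources.annotator.annotate_all(records)
    n_mismatch += n_bad_ref
    freq_results: dict[tuple, dict] = {}
    if resources.panel is not None:
        for a in annotations:
            if not a.variant.is_snv:
                continue
            results = test_all_populations(a.variant, resources.panel)
            freq_results[a.variant.key()] = {r.population: r for r in results}
    retained, report = filter_variants(
        annotations,
        criteria,
        freq_results=freq_results if resources.panel is not None else None,
    )
    return SingleCaseResult(
        sample_id=sample_id,
        parse_summary=summary,
        n_reference_mismatch=n_mismatch,
        records=records,
        annotations=annotations,
        freq_results=freq_results,
        retained=retained,
        filter_report=report,
        criteria=criteria,
    )


@dataclass
class TwoCaseResult:
    case_a: SingleCaseResult
    case_b: SingleCaseResult
    comparison: SharedUniqueResult


def run_two(
    resources: Resources,
    path_a,
    path_b,
    sample_a: str,
    sample_b: str,
    criteria: FilterCriteria | None = None,
    dialect: str = "vcf",
) -> TwoCaseResult:
    a = run_single(resources, path_a, sample_a, criteria, dialect)
    b = run_single(resources, path_b, sample_b, criteria, dialect)
    return TwoCaseResult(
        case_a=a,
        case_b=b,
        comparison=shared_and_unique(a.retained_keys, b.retained_keys),
    )


@dataclass
class MultiCaseResult:
    cases: dict[str, SingleCaseResult]
    controls: dict[str, SingleCaseResult]
    k: int
    candidates: set[VariantKey]
    trio_candidates: set[VariantKey] | None = None
    trio_spec: TrioSpec | None = None


def run_multi(
    resources: Resources,
    case_paths: dict[str, object],
    control_paths: dict[str, object] | None = None,
    k: int = 2,
    criteria: FilterCriteria | None = None,
    dialect: str = "vcf",
) -> MultiCaseResult:
    """Shared-by-at-least-k analysis with control exclusion.

    Cases contribute their *retained* (filtered) variant keys; controls
    exclude by mere presence, i.e. their effective pre-filter keys.
    """
    cases = {
        sid: run_single(resources, path, sid, criteria, dialect)
        for sid, path in case_paths.items()
    }
    controls = {
        sid: run_single(resources, path, sid, None, dialect)
        for sid, path in (control_paths or {}).items()
    }
    candidates = shared_by_k(
        [r.retained_keys for r in cases.values()],
        k,
        [r.effective_keys for r in controls.values()],
    )
    return MultiCaseResult(
        cases=cases, controls=controls, k=k, candidates=candidates
    )


def run_trio(
    resources: Resources,
    member_paths: dict[str, object],
    spec: TrioSpec,
    dialect: str = "vcf",
    strict_missing: bool = True,
) -> MultiCaseResult:
    """Mendelian filtering over a child/father/mother trio.

    Genotype maps are built from each member's effective records (absent
    site = hom_ref); the model is applied before any criteria filtering so
    that parental calls removed by a filter cannot masquerade as de novo
    support.
    """
    members = {}
    for role in ("child", "father", "mother"):
        sid = getattr(spec, f"{role}_id")
        if sid not in member_paths:
            raise ValueError(f"trio member {sid!r} missing from inputs")
        members[role] = run_single(resources, member_paths[sid], sid, None, dialect)
    genotype_maps = {
        role: {key_of(v): genotype_of(v) for v in result.records}
        for role, result in members.items()
    }
    candidates = trio_filter(
        genotype_maps["child"],
        genotype_maps["father"],
        genotype_maps["mother"],
        spec,
        strict_missing=strict_missing,
    )
    return MultiCaseResult(
        cases={r.sample_id: r for r in members.values()},
        controls={},
        k=2,
        candidates=candidates,
        trio_candidates=candidates,
        trio_spec=spec,
    )


def write_annotated_vcf(result: SingleCaseResult, genome: GenomeSequence,
                        path) -> None:
    """Write the sample's annotated variants as VCF.

    Annotations travel in INFO keys: EA_FUNC (category), EA_GENE, EA_AAC
    (amino-acid change), EA_NOVEL (novelty) and EA_MAFP (per-population
    chi-square p-values, ``POP:p`` joined with ``|``).
    """
    by_key = {a.variant.key(): a for a in result.annotations}

    def info_of(v: VariantRecord) -> dict:
        a = by_key[v.key()]
        per_pop = result.freq_results.get(v.key(), {})
        mafp = "|".join(
            f"{pop}:{per_pop[pop].p_value:.4g}" for pop in sorted(per_pop)
        )
        return {
            "EA_FUNC": a.category,
            "EA_GENE": a.gene_name or "",
            "EA_AAC": a.aa_change or "",
            "EA_NOVEL": a.novelty,
            "EA_MAFP": mafp,
        }

    write_vcf([a.variant for a in result.annotations], genome, path,
              sample_id=result.sample_id, info_of=info_of)


def comparison_frame(result: SharedUniqueResult) -> pd.DataFrame:
    rows = []
    for label, keys in (
        ("shared", result.shared),
        ("unique_a", result.unique_a),
        ("unique_b", result.unique_b),
    ):
        for key in sorted(keys):
            rows.append({
                "set": label, "contig": key.contig, "pos": key.pos,
                "ref_allele": key.ref_allele, "alt_allele": key.alt_allele,
            })
    return pd.DataFrame(
        rows, columns=["set", "contig", "pos", "ref_allele", "alt_allele"]
    )


def write_sample_outputs(
    result: SingleCaseResult,
    outdir,
    input_echo: str = "",
    extra_tables: dict[str, pd.DataFrame] | None = None,
) -> Path:
    """Write one sample's tables and its gzip bundle; returns the bundle path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = result.report()
    intermediate = pd.concat(
        [
            detail_frame(
                [a for a in result.annotations if a.variant.is_snv],
                "snv", result.freq_results,
            ).assign(kind="snv"),
            detail_frame(
                [a for a in result.annotations if a.variant.is_indel], "indel"
            ).assign(kind="indel"),
        ],
        ignore_index=True,
    )
    members = bundle_members(report, input_echo, intermediate, extra_tables)
    for name, content in members.items():
        target = outdir / Path(name).name
        target.write_text(content)
    bundle_path = outdir / f"{result.sample_id}.tar.gz"
    export_bundle(members, bundle_path)
    return bundle_path
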