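"""Per-sample result tables and the gzip export bundle.

A single-case result has three parts: the parse summary (input /
unavailable / effective counts plus the criteria used), the category
distribution before and after filtering, and a detail table with one row
per retained variant.  Cohort runs add shared/unique comparison tables.
Everything is emitted as TSV; the bundle is a deterministic ``.tar.gz``
(fixed metadata, sorted members) so that re-running a job reproduces the
archive byte for byte.
"""

from __future__ import annotations

import gzip
import io
import tarfile
from dataclasses import dataclass

import pandas as pd

from .annotate import Annotation
from .filtering import FilterCriteria, FilterReport, substitution_class
from .variants import ParseSummary

# fixed display orders for the distribution histograms
SNV_CATEGORY_ORDER = (
    "intergenic", "utr3", "intron", "syn_code", "nonsense",
    "splice_site", "utr5", "read_through", "missense",
)
INDEL_CATEGORY_ORDER = ("aa_insertion", "non_coding", "frame_shift", "aa_deletion")

SNV_DETAIL_COLUMNS = (
    "contig", "pos", "ref_allele", "alt_allele",
    "rs_id", "gene_name", "transcript_id", "aa_change",
    "frequency", "mutation_type", "function", "damage_prediction",
)
INDEL_DETAIL_COLUMNS = (
    "sn", "contig", "pos", "strand", "indel_seq", "substitution_class",
    "rs_id", "support", "gene_name", "region",
)

MISSING_FIELD = "."


def _is_snv_kind(kind: str) -> bool:
    if kind not in ("snv", "indel"):
        raise ValueError("kind must be 'snv' or 'indel'")
    return kind == "snv"


def category_distribution(
    annotations_before,
    annotations_after,
    kind: str,
) -> pd.DataFrame:
    """Counts and percentages per fixed category, before and after filtering.

    Expects representative annotations (one per variant); zero-count
    categories are included, and percentages of an empty state are 0.
    """
    order = SNV_CATEGORY_ORDER if _is_snv_kind(kind) else INDEL_CATEGORY_ORDER
    rows = []
    counts = {}
    for state, annotations in (
        ("before", annotations_before), ("after", annotations_after)
    ):
        per_cat = dict.fromkeys(order, 0)
        for a in annotations:
            if a.category not in per_cat:
                raise ValueError(
                    f"{a.category!r} is not a {kind} category"
                )
            per_cat[a.category] += 1
        counts[state] = per_cat
    total = {state: sum(counts[state].values()) for state in counts}
    for cat in order:
        rows.append(
            {
                "category": cat,
                "n_before": counts["before"][cat],
                "pct_before": (
                    100.0 * counts["before"][cat] / total["before"]
                    if total["before"] else 0.0
                ),
                "n_after": counts["after"][cat],
                "pct_after": (
                    100.0 * counts["after"][cat] / total["after"]
                    if total["after"] else 0.0
                ),
            }
        )
    return pd.DataFrame(rows, columns=[
        "category", "n_before", "pct_before", "n_after", "pct_after"
    ])


def _frequency_field(ann: Annotation, freq_results) -> str:
    per_pop = (freq_results or {}).get(ann.variant.key(), {})
    if not per_pop:
        return MISSING_FIELD
    parts = []
    for pop in sorted(per_pop):
        r = per_pop[pop]
        parts.append(f"{pop}:{r.panel_maf:.4f}(p={r.p_value:.3g})")
    return ";".join(parts)


def detail_frame(annotations, kind: str, freq_results=None) -> pd.DataFrame:
    """Detail table rows for retained variants of one class."""
    rows = []
    if _is_snv_kind(kind):
        for a in annotations:
            v = a.variant
            rows.append({
                "contig": v.contig,
                "pos": v.pos,
                "ref_allele": v.ref_allele,
                "alt_allele": v.alt_allele,
                "rs_id": a.rs_id or MISSING_FIELD,
                "gene_name": a.gene_name or MISSING_FIELD,
                "transcript_id": a.transcript_id or MISSING_FIELD,
                "aa_change": a.aa_change or MISSING_FIELD,
                "frequency": _frequency_field(a, freq_results),
                "mutation_type": (
                    f"{substitution_class(v.ref_allele, v.alt_allele)}:"
                    f"{v.zygosity}"
                ),
                "function": a.category,
                "damage_prediction": (
                    f"{a.deleterious_score:g}"
                    if a.deleterious_score is not None else MISSING_FIELD
                ),
            })
        return pd.DataFrame(rows, columns=list(SNV_DETAIL_COLUMNS))
    for sn, a in enumerate(annotations, start=1):
        v = a.variant
        rows.append({
            "sn": sn,
            "contig": v.contig,
            "pos": v.pos,
            "strand": a.strand or MISSING_FIELD,
            "indel_seq": v.ref_allele or v.alt_allele,
            "substitution_class": v.var_class,
            "rs_id": a.rs_id or MISSING_FIELD,
            "support": v.support if v.support is not None else MISSING_FIELD,
            "gene_name": a.gene_name or MISSING_FIELD,
            "region": a.category,
        })
    return pd.DataFrame(rows, columns=list(INDEL_DETAIL_COLUMNS))


def write_detail_table(annotations, kind: str, path, freq_results=None) -> None:
    """Write the fixed-column detail TSV; missing values rendered as '.'."""
    detail_frame(annotations, kind, freq_results).to_csv(
        path, sep="\t", index=False
    )


def read_detail_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


@dataclass
class SampleReport:
    """The three-part single-sample result."""

    sample_id: str
    parse_summary: ParseSummary
    criteria: FilterCriteria
    filter_report: FilterReport
    distribution_snv: pd.DataFrame
    distribution_indel: pd.DataFrame
    detail_snv: pd.DataFrame
    detail_indel: pd.DataFrame

    def summary_text(self) -> str:
        s = self.parse_summary
        lines = [
            f"sample\t{self.sample_id}",
            f"n_input\t{s.n_input}",
            f"n_unavailable\t{s.n_unavailable}",
            f"n_effective\t{s.n_effective}",
            f"n_before_filter\t{self.filter_report.n_before}",
            f"n_after_filter\t{self.filter_report.n_after}",
        ]
        for crit, removed in self.filter_report.per_criterion_removed.items():
            lines.append(f"removed_by_{crit}\t{removed}")
        return "\n".join(lines) + "\n"


def _frame_tsv(frame: pd.DataFrame) -> str:
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def bundle_members(
    report: SampleReport,
    input_echo: str,
    intermediate: pd.DataFrame,
    extra_tables: dict[str, pd.DataFrame] | None = None,
) -> dict[str, str]:
    """Archive member name -> content for one sample.

    Five members for a single-case run: the input echo, the intermediate
    (pre-filter) annotation table, the final detail tables (one combined
    file), the category distribution, and the criteria echo.  Cohort runs
    add shared/unique tables via ``extra_tables``.
    """
    prefix = report.sample_id
    distribution = pd.concat(
        [
            report.distribution_snv.assign(kind="snv"),
            report.distribution_indel.assign(kind="indel"),
        ],
        ignore_index=True,
    )
    final = (
        report.summary_text()
        + "\n[snv]\n" + _frame_tsv(report.detail_snv)
        + "\n[indel]\n" + _frame_tsv(report.detail_indel)
    )
    members = {
        f"{prefix}/input_echo.txt": input_echo,
        f"{prefix}/annotation_intermediate.tsv": _frame_tsv(intermediate),
        f"{prefix}/final_results.txt": final,
        f"{prefix}/category_distribution.tsv": _frame_tsv(distribution),
        f"{prefix}/criteria.cfg": report.criteria.to_config(),
    }
    for name, frame in (extra_tables or {}).items():
        members[f"{prefix}/{name}.tsv"] = _frame_tsv(frame)
    return members


def export_bundle(members: dict[str, str], path) -> None:
    """Write members as a deterministic gzip-compressed tar archive.

    The gzip header mtime and all tar metadata are pinned so re-running
    the same job reproduces the archive byte for byte.
    """
    with open(path, "wb") as raw, gzip.GzipFile(
        fileobj=raw, mode="wb", mtime=0
    ) as gz, tarfile.open(fileobj=gz, mode="w") as tar:
        for name in sorted(members):
            data = members[name].encode()
            info = tarfile.TarInfo(name=name)
            info.size = len(data)
            info.mtime = 0
            info.uid = info.gid = 0
            info.uname = info.gname = ""
            tar.addfile(info, io.BytesIO(data))


def list_bundle(path) -> list[str]:
    with tarfile.open(path, "r:gz") as tar:
        return sorted(tar.getnames())


def read_bundle_member(path, name: str) -> str:
    with tarfile.open(path, "r:gz") as tar:
        handle = tar.extractfile(name)
        if handle is None:
            raise KeyError(name)
        return handle.read().decode()
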