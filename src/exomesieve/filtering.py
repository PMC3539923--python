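"""Declarative SNP / indel filter criteria and their sequential tally.

Criteria are conjunctive: a variant is retained only if it passes every
*set* criterion; unset criteria pass everything.  The per-criterion removal
tally is computed by applying criteria in a fixed order (SNP: novelty,
population frequency, mutation type, classification, protein impact;
indel: novelty, coding region, mutation type, impact) — the retained set
itself is order-independent.

"Mutation type" covers two independently settable facets: substitution
class (transition / transversion for SNVs, insertion / deletion for
indels) and zygosity.  Protein impact filters on an externally supplied
per-variant deleteriousness score for SNVs (score <= threshold retained,
SIFT-style "low means damaging") and on the impact subcategory for indels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields

from .annotate import (
    Annotation,
    INDEL_CATEGORIES,
    KNOWN_DISEASE,
    NOVEL,
    SNV_CATEGORIES,
)
from .popfreq import DEFAULT_ALPHA
from .variants import DELETION, HET, HOM, INSERTION

NOVELTY_MODES = ("any", "novel_or_disease", "novel_only")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class ConfigurationError(ValueError):
    """A criterion references data that was never supplied."""


def substitution_class(ref: str, alt: str) -> str:
    """transition (purine<->purine / pyrimidine<->pyrimidine) or transversion."""
    pair = {ref, alt}
    if pair <= PURINES or pair <= PYRIMIDINES:
        return "transition"
    return "transversion"


@dataclass(frozen=True)
class FilterCriteria:
    """Configuration of the SNP and indel filters.

    ``None`` / ``"any"`` fields are unset and pass everything; set-valued
    fields must be non-empty subsets of their domain.
    """

    snp_novelty: str = "any"
    snp_freq_population: str | None = None  # population code or "ALL"
    snp_freq_alpha: float = DEFAULT_ALPHA
    snp_mutation_type: frozenset[str] | None = None  # {transition, transversion}
    snp_zygosity: frozenset[str] | None = None  # {het, hom}
    snp_classification: frozenset[str] | None = None  # SNV categories
    snp_impact_max_score: float | None = None
    indel_novelty: str = "any"
    indel_coding_only: bool = False
    indel_mutation_type: frozenset[str] | None = None  # {insertion, deletion}
    indel_zygosity: frozenset[str] | None = None
    indel_impact: frozenset[str] | None = None  # coding indel categories

    def __post_init__(self) -> None:
        for name in ("snp_novelty", "indel_novelty"):
            if getattr(self, name) not in NOVELTY_MODES:
                raise ValueError(f"{name} must be one of {NOVELTY_MODES}")
        domains = {
            "snp_mutation_type": {"transition", "transversion"},
            "snp_zygosity": {HET, HOM},
            "snp_classification": set(SNV_CATEGORIES),
            "indel_mutation_type": {INSERTION, DELETION},
            "indel_zygosity": {HET, HOM},
            "indel_impact": set(INDEL_CATEGORIES) - {"non_coding"},
        }
        for name, domain in domains.items():
            value = getattr(self, name)
            if value is None:
                continue
            value = frozenset(value)
            object.__setattr__(self, name, value)
            if not value:
                raise ValueError(f"{name} must be a non-empty subset when set")
            if not value <= domain:
                raise ValueError(f"{name} contains values outside {sorted(domain)}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in dc_fields(self):
            value = getattr(self, f.name)
            if isinstance(value, frozenset):
                value = sorted(value)
            out[f.name] = value
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "FilterCriteria":
        kwargs = {}
        for f in dc_fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if isinstance(value, (list, tuple, set)):
                value = frozenset(value)
            kwargs[f.name] = value
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FilterCriteria":
        return cls.from_dict(json.loads(text))

    def to_config(self) -> str:
        """Flat key=value text form (lists comma-separated, None omitted)."""
        lines = []
        for name, value in self.to_dict().items():
            if value is None:
                continue
            if isinstance(value, list):
                value = ",".join(value)
            lines.append(f"{name}={value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "FilterCriteria":
        set_fields = {
            "snp_mutation_type", "snp_zygosity", "snp_classification",
            "indel_mutation_type", "indel_zygosity", "indel_impact",
        }
        data: dict = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key in set_fields:
                data[key] = frozenset(v for v in value.split(",") if v)
            elif key in ("snp_freq_alpha", "snp_impact_max_score"):
                data[key] = float(value)
            elif key == "indel_coding_only":
                data[key] = value.lower() in ("1", "true", "yes")
            else:
                data[key] = value
        return cls.from_dict(data)


def als_preset() -> FilterCriteria:
    """The ALS-exome filter configuration.

    Keeps heterozygous novel SNVs classified missense / nonsense / splice
    site whose allele frequency differs significantly from the CHB panel
    (p < 0.05), and heterozygous novel coding indels.
    """
    return FilterCriteria(
        snp_novelty="novel_only",
        snp_freq_population="CHB",
        snp_freq_alpha=0.05,
        snp_zygosity=frozenset({HET}),
        snp_classification=frozenset({"missense", "nonsense", "splice_site"}),
        indel_novelty="novel_only",
        indel_coding_only=True,
        indel_zygosity=frozenset({HET}),
    )


@dataclass
class FilterReport:
    """Before/after counts plus sequential per-criterion removals."""

    n_before: int
    n_after: int
    per_criterion_removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_before - self.n_after != sum(self.per_criterion_removed.values()):
            raise ValueError("criterion removals do not sum to n_before - n_after")

    def to_tsv(self) -> str:
        lines = ["criterion\tremoved"]
        lines += [f"{k}\t{v}" for k, v in self.per_criterion_removed.items()]
        lines.append(f"n_before\t{self.n_before}")
        lines.append(f"n_after\t{self.n_after}")
        return "\n".join(lines) + "\n"


def _novelty_passes(novelty: str, mode: str) -> bool:
    if mode == "any":
        return True
    if mode == "novel_or_disease":
        return novelty in (NOVEL, KNOWN_DISEASE)
    return novelty == NOVEL


def _freq_passes(
    ann: Annotation, criteria: FilterCriteria, freq_results, absent_significant: bool
) -> bool:
    per_pop = (freq_results or {}).get(ann.variant.key(), {})
    target = criteria.snp_freq_population
    if target == "ALL":
        wanted = list(per_pop.values())
    else:
        wanted = [per_pop[target]] if target in per_pop else []
    if not wanted:
        return absent_significant
    return all(r.significant for r in wanted)


def _criterion_list(criteria: FilterCriteria, freq_results, absent_significant):
    """Ordered (name, applies-to-snv, predicate) list of the set criteria."""
    crits = []
    if criteria.snp_novelty != "any":
        crits.append(
            ("snp_novelty", True,
             lambda a: _novelty_passes(a.novelty, criteria.snp_novelty))
        )
    if criteria.snp_freq_population is not None:
        crits.append(
            ("snp_frequency", True,
             lambda a: _freq_passes(a, criteria, freq_results, absent_significant))
        )
    if criteria.snp_mutation_type is not None or criteria.snp_zygosity is not None:
        def snp_mutation(a: Annotation) -> bool:
            v = a.variant
            if criteria.snp_mutation_type is not None:
                if substitution_class(v.ref_allele, v.alt_allele) not in (
                    criteria.snp_mutation_type
                ):
                    return False
            if criteria.snp_zygosity is not None:
                if v.zygosity not in criteria.snp_zygosity:
                    return False  # unknown zygosity is not assessable
            return True
        crits.append(("snp_mutation_type", True, snp_mutation))
    if criteria.snp_classification is not None:
        crits.append(
            ("snp_classification", True,
             lambda a: a.category in criteria.snp_classification)
        )
    if criteria.snp_impact_max_score is not None:
        crits.append(
            ("snp_impact", True,
             lambda a: a.deleterious_score is not None
             and a.deleterious_score <= criteria.snp_impact_max_score)
        )
    if criteria.indel_novelty != "any":
        crits.append(
            ("indel_novelty", False,
             lambda a: _novelty_passes(a.novelty, criteria.indel_novelty))
        )
    if criteria.indel_coding_only:
        crits.append(
            ("indel_coding", False, lambda a: a.category != "non_coding")
        )
    if (
        criteria.indel_mutation_type is not None
        or criteria.indel_zygosity is not None
    ):
        def indel_mutation(a: Annotation) -> bool:
            v = a.variant
            if criteria.indel_mutation_type is not None:
                if v.var_class not in criteria.indel_mutation_type:
                    return False
            if criteria.indel_zygosity is not None:
                if v.zygosity not in criteria.indel_zygosity:
                    return False
            return True
        crits.append(("indel_mutation_type", False, indel_mutation))
    if criteria.indel_impact is not None:
        crits.append(
            ("indel_impact", False, lambda a: a.category in criteria.indel_impact)
        )
    return crits


def filter_variants(
    annotated,
    criteria: FilterCriteria,
    freq_results: dict | None = None,
    absent_significant: bool = True,
) -> tuple[list[Annotation], FilterReport]:
    """Apply the criteria to representative annotations.

    ``freq_results`` maps variant key -> {population: FreqTestResult};
    sites absent from the panel pass or fail the frequency criterion per
    ``absent_significant`` (default: absent means unexplained, retained).

    Raises :class:`ConfigurationError` before any filtering when a set
    criterion references data that was never supplied (a frequency
    criterion without panel results, an impact criterion when no variant
    carries a score).
    """
    annotated = list(annotated)
    if criteria.snp_freq_population is not None and freq_results is None:
        raise ConfigurationError(
            "snp_freq_population set but no frequency results supplied"
        )
    if criteria.snp_impact_max_score is not None:
        snvs = [a for a in annotated if a.variant.is_snv]
        if snvs and all(a.deleterious_score is None for a in snvs):
            raise ConfigurationError(
                "snp_impact_max_score set but no deleteriousness scores supplied"
            )
    crits = _criterion_list(criteria, freq_results, absent_significant)
    removed = {name: 0 for name, _s, _p in crits}
    retained = []
    for ann in annotated:
        is_snv = ann.variant.is_snv
        for name, applies_to_snv, predicate in crits:
            if applies_to_snv != is_snv:
                continue
            if not predicate(ann):
                removed[name] += 1
                break
        else:
            retained.append(ann)
    report = FilterReport(
        n_before=len(annotated),
        n_after=len(retained),
        per_criterion_removed=removed,
    )
    return retained, report
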