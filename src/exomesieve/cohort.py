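"""Cross-sample variant comparison: two-case, multi-case and trio modes.

"Shared" identity is the normalized variant key — contig, position and
alleles after indel left-alignment — not gene-level sharing.  The
multi-case rule keeps variants present in at least ``k`` case samples
(k >= 2) and absent from every control.  Trio filtering applies one of
three explicit Mendelian models over child/father/mother genotype maps:

* ``de_novo`` — child carries the allele (het or hom-alt), both parents
  hom-ref;
* ``recessive_hom`` — child hom-alt, both parents het carriers;
* ``dominant_inherited`` — child carries the allele and at least one
  parent carries it too.

Sites missing a genotype are dropped by default (``strict_missing=True``)
or kept for manual review when strictness is relaxed.  A site absent from
a sample's calls is read as hom-ref by default, since exome call files
normally omit reference-matching sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from .genome import open_text

logger = logging.getLogger(__name__)

HOM_REF = "hom_ref"
HET_GT = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"
GENOTYPES = (HOM_REF, HET_GT, HOM_ALT, MISSING)

TRIO_MODELS = ("de_novo", "recessive_hom", "dominant_inherited")

MANIFEST_ROLES = ("case", "control", "child", "father", "mother")


class VariantKey(NamedTuple):
    """Identity of a normalized edit: equal keys mean identical haplotype
    effect on the reference."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str


def key_of(v) -> VariantKey:
    """VariantKey of a record, annotation or plain 4-tuple (records must be
    normalized)."""
    v = getattr(v, "variant", v)
    if isinstance(v, tuple):
        return VariantKey(*v)
    return VariantKey(v.contig, v.pos, v.ref_allele, v.alt_allele)


@dataclass
class SharedUniqueResult:
    """Exact partition of two samples' variant keys."""

    shared: set[VariantKey]
    unique_a: set[VariantKey]
    unique_b: set[VariantKey]
    pct_shared_a: float
    pct_shared_b: float
    pct_unique_a: float
    pct_unique_b: float


def _as_key_set(variants: Iterable, label: str) -> set[VariantKey]:
    if isinstance(variants, (set, frozenset)) and all(
        isinstance(k, VariantKey) for k in variants
    ):
        return set(variants)
    keys = [key_of(v) for v in variants]
    unique = set(keys)
    if len(unique) < len(keys):
        logger.warning(
            "%s: %d duplicate variant keys de-duplicated",
            label, len(keys) - len(unique),
        )
    return unique


def shared_and_unique(a: Iterable, b: Iterable) -> SharedUniqueResult:
    """Two-case comparison: shared and sample-unique variant keys, with
    percentages relative to each sample's effective count."""
    set_a = _as_key_set(a, "sample A")
    set_b = _as_key_set(b, "sample B")
    shared = set_a & set_b

    def pct(n: int, total: int) -> float:
        return 100.0 * n / total if total else 0.0

    return SharedUniqueResult(
        shared=shared,
        unique_a=set_a - set_b,
        unique_b=set_b - set_a,
        pct_shared_a=pct(len(shared), len(set_a)),
        pct_shared_b=pct(len(shared), len(set_b)),
        pct_unique_a=pct(len(set_a - set_b), len(set_a)),
        pct_unique_b=pct(len(set_b - set_a), len(set_b)),
    )


def shared_by_k(
    cases: Sequence[Iterable],
    k: int,
    controls: Sequence[Iterable] = (),
) -> set[VariantKey]:
    """Variants present in at least ``k`` cases and in no control."""
    if k < 2:
        raise ValueError("minimum number of sharing cases is two")
    case_sets = [_as_key_set(c, f"case {i}") for i, c in enumerate(cases)]
    if k > len(case_sets):
        raise ValueError(
            f"k={k} exceeds the number of case samples ({len(case_sets)})"
        )
    counts: dict[VariantKey, int] = {}
    for s in case_sets:
        for key in s:
            counts[key] = counts.get(key, 0) + 1
    candidates = {key for key, n in counts.items() if n >= k}
    for i, c in enumerate(controls):
        candidates -= _as_key_set(c, f"control {i}")
    return candidates


@dataclass(frozen=True)
class TrioSpec:
    """Child/father/mother sample ids and the Mendelian model to apply."""

    child_id: str
    father_id: str
    mother_id: str
    model: str

    def __post_init__(self) -> None:
        if len({self.child_id, self.father_id, self.mother_id}) != 3:
            raise ValueError("trio requires three distinct sample ids")
        if self.model not in TRIO_MODELS:
            raise ValueError(f"model must be one of {TRIO_MODELS}")


def _model_keeps(model: str, child: str, father: str, mother: str) -> bool:
    carries_child = child in (HET_GT, HOM_ALT)
    if model == "de_novo":
        return carries_child and father == HOM_REF and mother == HOM_REF
    if model == "recessive_hom":
        return child == HOM_ALT and father == HET_GT and mother == HET_GT
    if model == "dominant_inherited":
        return carries_child and (
            father in (HET_GT, HOM_ALT) or mother in (HET_GT, HOM_ALT)
        )
    raise ValueError(f"unknown model {model!r}")


def trio_filter(
    child: Mapping[VariantKey, str],
    father: Mapping[VariantKey, str],
    mother: Mapping[VariantKey, str],
    spec: TrioSpec,
    strict_missing: bool = True,
    absent: str = HOM_REF,
) -> set[VariantKey]:
    """Apply a Mendelian model over the union of the trio's variant keys.

    ``absent`` is the genotype assumed for a key missing from a member's
    map (default hom_ref); explicit ``missing`` genotypes drop the key
    under ``strict_missing`` and keep it otherwise.
    """
    if absent not in GENOTYPES:
        raise ValueError(f"absent genotype must be one of {GENOTYPES}")
    kept: set[VariantKey] = set()
    for key in set(child) | set(father) | set(mother):
        gts = (
            child.get(key, absent),
            father.get(key, absent),
            mother.get(key, absent),
        )
        for g in gts:
            if g not in GENOTYPES:
                raise ValueError(f"bad genotype {g!r} at {key}")
        if MISSING in gts:
            if not strict_missing:
                kept.add(key)
            continue
        if _model_keeps(spec.model, *gts):
            kept.add(key)
    return kept


def genotype_of(record) -> str:
    """Map a variant record's zygosity onto a trio genotype."""
    return {"het": HET_GT, "hom": HOM_ALT, "unknown": MISSING}[record.zygosity]


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    role: str
    path: str


def read_manifest(path) -> list[ManifestEntry]:
    """Cohort manifest TSV: sample_id, role, path per line."""
    entries = []
    with open_text(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"manifest line {line_no}: need 3 columns")
            if fields[1] not in MANIFEST_ROLES:
                raise ValueError(
                    f"manifest line {line_no}: role must be one of "
                    f"{MANIFEST_ROLES}, got {fields[1]!r}"
                )
            entries.append(ManifestEntry(fields[0], fields[1], fields[2]))
    ids = [e.sample_id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("manifest contains duplicate sample ids")
    return entries
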