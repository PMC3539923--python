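"""Population minor-allele frequencies and the per-site chi-square test.

A :class:`PopulationPanel` carries per-site, per-population reference and
alternate allele counts (HapMap-style: YRI / JPT / CHB / CEU by default).
For each sample variant, the sample's two alleles are tabulated against a
population's counts in a 2x2 contingency table and tested with Pearson's
chi-square (1 df, no continuity correction unless requested):

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))

A site is flagged significant when p < alpha (default 0.05).  With only two
sample alleles the chi-square approximation is crude; whenever any expected
cell falls below ``min_expected`` (default 1) the result carries a
``low_count`` flag, and a strict mode (``low_count_veto=True``) treats such
sites as not significant.  A site absent from the panel has no test; the
filter layer's default policy treats it as unexplained by the panel, i.e.
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2 as chi2_dist

from .genome import open_text
from .variants import HET, HOM, UNKNOWN, VariantRecord

DEFAULT_ALPHA = 0.05
DEFAULT_POPULATIONS = ("YRI", "JPT", "CHB", "CEU")


class UndefinedSiteError(ValueError):
    """Allele-frequency request at a site with zero total count."""


@dataclass
class FreqTestResult:
    """One population's MAF and chi-square comparison for one variant."""

    population: str
    panel_maf: float
    chi2: float
    p_value: float
    significant: bool
    low_count: bool = False
    absent: bool = False
    alpha: float = DEFAULT_ALPHA


def minor_allele_frequency(ref_count: int, alt_count: int) -> float:
    """min(ref, alt) / total; raises on an empty site."""
    total = ref_count + alt_count
    if total <= 0:
        raise UndefinedSiteError("zero total allele count")
    return min(ref_count, alt_count) / total


def pearson_chi2_2x2(
    a: float, b: float, c: float, d: float, yates: bool = False
) -> tuple[float, float, float]:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]].

    Returns ``(chi2, p_value, min_expected)``.  Degenerate tables (a zero
    row or column margin) have chi2 = 0 and p = 1.
    """
    n = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    if n == 0 or 0 in rows or 0 in cols:
        return 0.0, 1.0, 0.0
    chi2 = 0.0
    min_expected = float("inf")
    for obs, r, col in ((a, 0, 0), (b, 0, 1), (c, 1, 0), (d, 1, 1)):
        expected = rows[r] * cols[col] / n
        min_expected = min(min_expected, expected)
        delta = abs(obs - expected)
        if yates:
            delta = max(delta - 0.5, 0.0)
        chi2 += delta * delta / expected
    return chi2, float(chi2_dist.sf(chi2, 1)), min_expected


def sample_allele_counts(zygosity: str) -> tuple[int, int]:
    """(ref, alt) allele counts of a diploid sample from its zygosity.

    Unknown zygosity is counted as heterozygous for testing purposes (one
    of two alleles); filters that require known zygosity handle the
    distinction separately.
    """
    if zygosity == HOM:
        return 0, 2
    if zygosity in (HET, UNKNOWN):
        return 1, 1
    raise ValueError(f"bad zygosity {zygosity!r}")


def chi_square_allele_test(
    sample_alt_alleles: int,
    sample_total_alleles: int,
    panel: tuple[int, int],
    alpha: float = DEFAULT_ALPHA,
    yates: bool = False,
    min_expected: float = 1.0,
    low_count_veto: bool = False,
    population: str = "",
) -> FreqTestResult:
    """Test a sample's alleles against one population's panel counts."""
    panel_ref, panel_alt = panel
    if panel_ref + panel_alt <= 0:
        raise UndefinedSiteError("panel site has zero total count")
    if not 0 <= sample_alt_alleles <= sample_total_alleles:
        raise ValueError("sample allele counts out of range")
    sample_ref = sample_total_alleles - sample_alt_alleles
    chi2, p, cell_min = pearson_chi2_2x2(
        sample_ref, sample_alt_alleles, panel_ref, panel_alt, yates=yates
    )
    low_count = cell_min < min_expected
    significant = p < alpha and not (low_count and low_count_veto)
    return FreqTestResult(
        population=population,
        panel_maf=minor_allele_frequency(panel_ref, panel_alt),
        chi2=chi2,
        p_value=p,
        significant=significant,
        low_count=low_count,
        alpha=alpha,
    )


class PopulationPanel:
    """Per-site, per-population allele counts.

    ``sites`` maps (contig, pos) -> (ref_allele, alt_allele,
    {population: (ref_count, alt_count)}).
    """

    def __init__(
        self,
        populations,
        sites: dict[tuple[str, int], tuple[str, str, dict[str, tuple[int, int]]]],
    ):
        self.populations = tuple(populations)
        self.sites = dict(sites)
        for (contig, pos), (_r, _a, counts) in self.sites.items():
            for pop, (rc, ac) in counts.items():
                if rc + ac <= 0:
                    raise UndefinedSiteError(
                        f"{contig}:{pos} {pop} has zero total count"
                    )

    def __len__(self) -> int:
        return len(self.sites)

    @classmethod
    def read(cls, path) -> "PopulationPanel":
        """Read the TSV panel format.

        Header: ``contig  pos  ref  alt  POP_ref  POP_alt ...`` — one
        ref/alt count column pair per population.
        """
        with open_text(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            if header[:4] != ["contig", "pos", "ref", "alt"]:
                raise ValueError(
                    "panel header must begin: contig pos ref alt"
                )
            populations = []
            for i in range(4, len(header), 2):
                name = header[i].removesuffix("_ref")
                if (
                    not header[i].endswith("_ref")
                    or i + 1 >= len(header)
                    or header[i + 1] != f"{name}_alt"
                ):
                    raise ValueError(f"bad panel count columns near {header[i]!r}")
                populations.append(name)
            sites = {}
            for raw in handle:
                line = raw.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                counts = {
                    pop: (int(fields[4 + 2 * i]), int(fields[5 + 2 * i]))
                    for i, pop in enumerate(populations)
                    if fields[4 + 2 * i] != "."  # site absent in this panel
                }
                sites[(fields[0], int(fields[1]))] = (
                    fields[2].upper(),
                    fields[3].upper(),
                    counts,
                )
        return cls(populations, sites)

    def write(self, path) -> None:
        with open(path, "wt") as out:
            cols = ["contig", "pos", "ref", "alt"]
            for pop in self.populations:
                cols += [f"{pop}_ref", f"{pop}_alt"]
            out.write("\t".join(cols) + "\n")
            for (contig, pos) in sorted(self.sites):
                ref, alt, counts = self.sites[(contig, pos)]
                row = [contig, str(pos), ref, alt]
                for pop in self.populations:
                    if pop in counts:
                        rc, ac = counts[pop]
                        row += [str(rc), str(ac)]
                    else:
                        row += [".", "."]
                out.write("\t".join(row) + "\n")

    def site(self, contig: str, pos: int):
        return self.sites.get((contig, pos))


def test_all_populations(
    v: VariantRecord,
    panel: PopulationPanel,
    alpha: float = DEFAULT_ALPHA,
    populations=None,
    yates: bool = False,
    min_expected: float = 1.0,
    low_count_veto: bool = False,
) -> list[FreqTestResult]:
    """Chi-square results for one variant in each requested population.

    Returns one result per population where the site is present with
    matching alleles; an empty list means the site (or allele) is absent
    from the panel entirely.
    """
    entry = panel.site(v.contig, v.pos)
    if entry is None:
        return []
    ref, alt, counts = entry
    if v.is_snv and (ref != v.ref_allele or alt != v.alt_allele):
        return []  # different alleles catalogued at this site
    wanted = tuple(populations) if populations else panel.populations
    sample_ref, sample_alt = sample_allele_counts(v.zygosity)
    results = []
    for pop in wanted:
        if pop not in counts:
            continue
        results.append(
            chi_square_allele_test(
                sample_alt,
                sample_ref + sample_alt,
                counts[pop],
                alpha=alpha,
                yates=yates,
                min_expected=min_expected,
                low_count_veto=low_count_veto,
                population=pop,
            )
        )
    return results


def pooled_chi_square(
    zygosities,
    panel: tuple[int, int],
    alpha: float = DEFAULT_ALPHA,
    **kwargs,
) -> FreqTestResult:
    """Cohort mode: pool allele counts across case samples, then test."""
    sample_ref = sample_alt = 0
    for z in zygosities:
        r, a = sample_allele_counts(z)
        sample_ref += r
        sample_alt += a
    return chi_square_allele_test(
        sample_alt, sample_ref + sample_alt, panel, alpha=alpha, **kwargs
    )
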