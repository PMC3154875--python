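"""Allele-profile classification of candidate SNPs in two tetraploid genotypes.

A variant column observed in two pooled genotypes is summarized by the set of
alleles seen in each genotype. Because each genotype is autotetraploid it can
be homozygous (one allele across the four haplotypes) or heterozygous (two or
more alleles). The classification below follows the standard four-way scheme
for two-genotype EST SNP catalogs:

* Category 1 — two alleles overall, each genotype homozygous for a different
  one (fixed difference between genotypes).
* Category 2 — two alleles overall, heterozygous within exactly one genotype
  and homozygous in the other.
* Category 3 — two alleles overall, both genotypes heterozygous for the same
  pair (biallelic, shared heterozygosity).
* Category 4 — more than two distinct alleles across the two genotypes.

Category 2 sites are the ones suitable for mapping in an F1 population from a
cross of the two genotypes: the heterozygous parent segregates while the other
does not. Category 1 sites are heterozygous in every F1 individual and
therefore uninformative for linkage; Categories 3 and 4 segregate in complex
tetrasomic ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .errors import InputError

VALID_BASES = frozenset("ACGT")

#: Category 2 is the mapping-suitable class (het-in-one, hom-in-other).
MAPPING_SUITABLE_CATEGORY = 2


@dataclass(frozen=True)
class AlleleProfile:
    """Per-genotype allele sets at one variant column."""

    genotype_a_alleles: frozenset
    genotype_b_alleles: frozenset

    def __post_init__(self):
        for name, alleles in (("genotype_a", self.genotype_a_alleles),
                              ("genotype_b", self.genotype_b_alleles)):
            alleles = frozenset(alleles)
            if not alleles:
                raise InputError(f"{name}: allele set is empty")
            bad = alleles - VALID_BASES
            if bad:
                raise InputError(f"{name}: invalid alleles {sorted(bad)}")
            object.__setattr__(self, f"{name}_alleles", alleles)


@dataclass(frozen=True)
class SNPCategory:
    """Category index (1-4, or None for a monomorphic profile)."""

    value: int | None
    mapping_suitable: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "mapping_suitable", self.value == MAPPING_SUITABLE_CATEGORY
        )


def classify_profile(profile: AlleleProfile) -> SNPCategory:
    """Assign the four-way category from the two per-genotype allele sets.

    Let ``D`` be the number of distinct alleles pooled over both genotypes:

    * ``D == 1`` — not a SNP (category ``None``);
    * ``D > 2``  — Category 4 (more than two variants);
    * ``D == 2`` and both sets singletons — Category 1;
    * ``D == 2`` and exactly one set of size two — Category 2;
    * ``D == 2`` and both sets of size two — Category 3.

    Total and deterministic over all ordered pairs of non-empty subsets of
    {A, C, G, T}.
    """
    a = profile.genotype_a_alleles
    b = profile.genotype_b_alleles
    distinct = len(a | b)
    if distinct == 1:
        return SNPCategory(None)
    if distinct > 2:
        return SNPCategory(4)
    # exactly two alleles overall
    if len(a) == 1 and len(b) == 1:
        return SNPCategory(1)
    if len(a) == 2 and len(b) == 2:
        return SNPCategory(3)
    return SNPCategory(2)


def classify_allele_sets(a, b) -> int | None:
    """Convenience wrapper: classify two iterables of alleles."""
    return classify_profile(AlleleProfile(frozenset(a), frozenset(b))).value


def _round_half_up(x: float, places: int = 1) -> float:
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CatalogSummary:
    """Totals of a classified SNP catalog, optionally split by chromosome."""

    total_snps: int
    contigs_with_snps: int
    category_counts: dict
    category_percent: dict
    per_chromosome: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": cat,
                "count": self.category_counts.get(cat, 0),
                "percent": self.category_percent.get(cat, 0.0),
            }
            for cat in (1, 2, 3, 4)
        ]
        return pd.DataFrame(rows)


def summarize_catalog(snps, anchors=None) -> CatalogSummary:
    """Tally a classified candidate-SNP list.

    Parameters
    ----------
    snps
        Iterable of objects with ``contig_id`` and ``category`` attributes
        (``category`` in {1, 2, 3, 4, None}); typically called
        :class:`~tetrasnp.discovery.CandidateSNP` records after
        classification. Records with ``category is None`` are ignored.
    anchors
        Optional resolved :class:`~tetrasnp.anchoring.Anchor` records; when
        given, a per-chromosome table is attached (see
        :func:`~tetrasnp.anchoring.tally_by_chromosome`).

    Percentages are reported to one decimal, rounding half away from zero.
    """
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    contigs = set()
    for snp in snps:
        if snp.category is None:
            continue
        counts[snp.category] += 1
        contigs.add(snp.contig_id)
    total = sum(counts.values())
    percent = {
        cat: (_round_half_up(100.0 * n / total) if total else 0.0)
        for cat, n in counts.items()
    }
    per_chrom = None
    if anchors is not None:
        from .anchoring import tally_by_chromosome

        per_chrom = tally_by_chromosome(anchors, snps)
    return CatalogSummary(
        total_snps=total,
        contigs_with_snps=len(contigs),
        category_counts=counts,
        category_percent=percent,
        per_chromosome=per_chrom,
    )
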