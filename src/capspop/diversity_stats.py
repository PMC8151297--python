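"""Per-locus and panel-level diversity statistics.

For each marker: major allele frequency (MAF), number of observed genotype
classes (NG), number of alleles (NA), gene diversity (GD = 1 - sum p_u^2)
and observed heterozygosity (He).  Panel summaries distinguish all loci
from polymorphic loci and can stratify GD by substitution class when
marker definitions are supplied.  A cross-marker-type rescaling divides GD
by the equifrequent-allele maximum (k-1)/k.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from capspop.genotype_data import GenotypeMatrix, MarkerDefinition


class DiversityError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    marker_id: str
    frequencies: dict[str, float]
    n_copies: int

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-12:
            raise DiversityError(f"{self.marker_id}: frequencies sum to {total}")
        if any(f < 0 for f in self.frequencies.values()):
            raise DiversityError(f"{self.marker_id}: negative frequency")
        if self.n_copies % 2:
            raise DiversityError(f"{self.marker_id}: odd allele-copy count")


@dataclass(frozen=True)
class LocusStats:
    marker_id: str
    maf: float
    major_allele: str
    n_genotypes: int
    n_alleles: int
    gene_diversity: float
    heterozygosity: float

    @property
    def is_monomorphic(self) -> bool:
        return self.n_alleles == 1


@dataclass(frozen=True)
class PanelSummary:
    n_loci: int
    n_polymorphic: int
    n_monomorphic: int
    mean_all: dict[str, float]
    mean_polymorphic: dict[str, float]
    gd_by_class: dict[str, float] | None = None


def allele_frequencies(gm: GenotypeMatrix, marker_id: str) -> AlleleFrequencySpectrum:
    """Allele-frequency spectrum at a locus; each non-missing diploid call
    contributes two copies, missing calls are excluded."""
    counts: Counter[str] = Counter()
    for call in gm.marker_column(marker_id):
        if not call.is_missing:
            counts.update(call.alleles)
    n = sum(counts.values())
    if n == 0:
        raise DiversityError(f"{marker_id}: all calls missing")
    return AlleleFrequencySpectrum(
        marker_id=marker_id,
        frequencies={a: c / n for a, c in sorted(counts.items())},
        n_copies=n,
    )


def gene_diversity(frequencies: dict[str, float]) -> float:
    """GD = 1 - sum of squared allele proportions."""
    return 1.0 - sum(p * p for p in frequencies.values())


def compute_locus_stats(gm: GenotypeMatrix, marker_id: str) -> LocusStats:
    spectrum = allele_frequencies(gm, marker_id)
    freqs = spectrum.frequencies
    maf = max(freqs.values())
    # ties broken lexicographically for the reported major allele
    major = min(a for a, p in freqs.items() if p == maf)
    calls = [c for c in gm.marker_column(marker_id) if not c.is_missing]
    genotype_classes = {c.alleles for c in calls}
    n_het = sum(c.is_heterozygous for c in calls)
    return LocusStats(
        marker_id=marker_id,
        maf=maf,
        major_allele=major,
        n_genotypes=len(genotype_classes),
        n_alleles=len(freqs),
        gene_diversity=gene_diversity(freqs),
        heterozygosity=n_het / len(calls),
    )


def compute_all_locus_stats(gm: GenotypeMatrix) -> list[LocusStats]:
    return [compute_locus_stats(gm, m) for m in gm.marker_ids]


_SUMMARY_FIELDS = {
    "maf": "maf",
    "ng": "n_genotypes",
    "na": "n_alleles",
    "gd": "gene_diversity",
    "he": "heterozygosity",
}


def _means(stats: Sequence[LocusStats]) -> dict[str, float]:
    n = len(stats)
    if n == 0:
        return {k: float("nan") for k in _SUMMARY_FIELDS}
    return {
        key: sum(getattr(s, attr) for s in stats) / n
        for key, attr in _SUMMARY_FIELDS.items()
    }


def summarize_panel(
    stats: Sequence[LocusStats],
    defs: Sequence[MarkerDefinition] | None = None,
) -> PanelSummary:
    """Panel means over all loci and over polymorphic loci only.

    A locus is monomorphic iff MAF = 1.  With marker definitions, also
    reports mean GD per recomputed substitution class.
    """
    if not stats:
        raise DiversityError("empty locus-stats list")
    poly = [s for s in stats if s.maf < 1.0]
    gd_by_class = None
    if defs is not None:
        cls_by_id = {d.marker_id: d.substitution_class for d in defs}
        gd_by_class = {}
        for cls in ("transition", "transversion"):
            members = [s for s in stats if cls_by_id.get(s.marker_id) == cls]
            if members:
                gd_by_class[cls] = sum(s.gene_diversity for s in members) / len(members)
    return PanelSummary(
        n_loci=len(stats),
        n_polymorphic=len(poly),
        n_monomorphic=len(stats) - len(poly),
        mean_all=_means(stats),
        mean_polymorphic=_means(poly),
        gd_by_class=gd_by_class,
    )


def scaled_gene_diversity(gd: float, max_alleles: int) -> float:
    """Rescale GD by the equifrequent maximum (k-1)/k of a k-allele locus.

    Allows diversity comparisons between marker systems whose allele
    numbers (and hence attainable GD) differ.
    """
    if max_alleles < 2:
        raise DiversityError("max_alleles must be >= 2")
    ceiling = (max_alleles - 1) / max_alleles
    if gd < 0 or gd > ceiling + 1e-12:
        raise DiversityError(f"GD {gd} outside [0, {ceiling}] for k={max_alleles}")
    return gd / ceiling


def stats_table(stats: Sequence[LocusStats], decimals: int = 3) -> pd.DataFrame:
    """Report-style data frame (values rounded; internal stats keep full precision)."""
    return pd.DataFrame(
        {
            "marker_id": [s.marker_id for s in stats],
            "maf": [round(s.maf, decimals) for s in stats],
            "ng": [s.n_genotypes for s in stats],
            "na": [s.n_alleles for s in stats],
            "gd": [round(s.gene_diversity, decimals) for s in stats],
            "he": [round(s.heterozygosity, decimals) for s in stats],
        }
    )
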