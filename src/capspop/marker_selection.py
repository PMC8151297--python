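"""Genotype accumulation curves and minimum discriminating marker sets.

Accessions are discriminated when their multilocus genotypes (MLGs) — the
vectors of calls over a marker subset, with missing matching only missing —
are pairwise distinct.  The greedy selector starts from the most diverse
marker and repeatedly adds the marker that splits the most accession
classes; an exhaustive breadth-first search over subsets provides an
optimality oracle for small panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from capspop.diversity_stats import LocusStats, compute_all_locus_stats
from capspop.genotype_data import GenotypeDataError, GenotypeMatrix


@dataclass
class AccumulationCurve:
    subset_sizes: list[int]
    counts: dict[int, list[int]]  # size -> MLG counts across sampled subsets
    full_panel_count: int
    n_accessions: int

    @property
    def mean_curve(self) -> list[float]:
        return [float(np.mean(self.counts[n])) for n in self.subset_sizes]

    def quantiles(self, qs=(0.025, 0.5, 0.975)) -> dict[float, list[float]]:
        return {
            q: [float(np.quantile(self.counts[n], q)) for n in self.subset_sizes]
            for q in qs
        }


@dataclass
class SelectionResult:
    selected: list[str]
    step_counts: list[int]
    complete: bool

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def distinct_mlg_count(gm: GenotypeMatrix, marker_subset: Sequence[str]) -> int:
    """Number of distinct multilocus genotypes over a marker subset."""
    if not marker_subset:
        raise GenotypeDataError("marker subset must be non-empty")
    cols = [gm._marker_index.get(m) for m in marker_subset]
    unknown = [m for m, c in zip(marker_subset, cols) if c is None]
    if unknown:
        raise GenotypeDataError(f"unknown marker ids: {unknown}")
    return len({tuple(row[c] for c in cols) for row in gm.calls})


def accumulation_curve(
    gm: GenotypeMatrix, r: int = 100, seed: int | None = None
) -> AccumulationCurve:
    """Distinct-MLG counts of r random locus subsets at each size 1..L-1."""
    if r < 1:
        raise GenotypeDataError("r must be >= 1")
    if gm.n_markers < 2:
        raise GenotypeDataError("need at least two loci")
    rng = np.random.default_rng(seed)
    sizes = list(range(1, gm.n_markers))
    counts: dict[int, list[int]] = {}
    markers = np.array(gm.marker_ids)
    for n in sizes:
        counts[n] = [
            distinct_mlg_count(gm, list(rng.choice(markers, size=n, replace=False)))
            for _ in range(r)
        ]
    return AccumulationCurve(
        subset_sizes=sizes,
        counts=counts,
        full_panel_count=distinct_mlg_count(gm, gm.marker_ids),
        n_accessions=gm.n_accessions,
    )


def greedy_minimal_marker_set(
    gm: GenotypeMatrix,
    stats: Sequence[LocusStats] | None = None,
    first_marker: str | None = None,
) -> SelectionResult:
    """Greedy forward selection of a discriminating marker subset.

    The first marker maximizes (GD, NG, NA) with marker-id order as the
    final tie-break (or is pinned via ``first_marker``); each subsequent
    marker maximizes the resulting distinct-MLG count, ties broken by GD
    then id.  Stops when all accessions are distinct or no marker helps.
    """
    if stats is None:
        stats = compute_all_locus_stats(gm)
    by_id = {s.marker_id: s for s in stats}
    polymorphic = [m for m in gm.marker_ids if by_id[m].n_alleles > 1]
    if not polymorphic:
        return SelectionResult(selected=[], step_counts=[], complete=False)
    if first_marker is None:
        # max() keeps the first maximum, so id order breaks exact stat ties
        first_marker = max(
            sorted(polymorphic),
            key=lambda m: (
                by_id[m].gene_diversity,
                by_id[m].n_genotypes,
                by_id[m].n_alleles,
            ),
        )
    elif first_marker not in gm._marker_index:
        raise GenotypeDataError(f"unknown first marker {first_marker!r}")
    selected = [first_marker]
    step_counts = [distinct_mlg_count(gm, selected)]
    target = gm.n_accessions
    remaining = sorted(m for m in gm.marker_ids if m != first_marker)
    while step_counts[-1] < target:
        best = None
        for m in remaining:  # id order: first maximum wins exact ties
            count = distinct_mlg_count(gm, selected + [m])
            key = (count, by_id[m].gene_diversity)
            if best is None or key > best[0]:
                best = (key, m)
        (count, _), marker = best  # type: ignore[misc]
        if count <= step_counts[-1]:
            break  # no marker splits anything further
        selected.append(marker)
        step_counts.append(count)
        remaining.remove(marker)
    return SelectionResult(
        selected=selected,
        step_counts=step_counts,
        complete=step_counts[-1] == target,
    )


def exhaustive_minimal_marker_set(
    gm: GenotypeMatrix, max_loci: int = 15
) -> tuple[int, list[str]]:
    """Smallest marker subset achieving the full-panel MLG count.

    Breadth-first over subset sizes, combinations enumerated in marker-id
    order so the witness is the lexicographically first optimum.
    """
    if gm.n_markers > max_loci:
        raise GenotypeDataError(
            f"exhaustive search limited to {max_loci} loci (panel has {gm.n_markers})"
        )
    target = distinct_mlg_count(gm, gm.marker_ids)
    for size in range(1, gm.n_markers + 1):
        for subset in combinations(gm.marker_ids, size):
            if distinct_mlg_count(gm, subset) == target:
                return size, list(subset)
    raise AssertionError("unreachable: full set always attains its own MLG count")
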