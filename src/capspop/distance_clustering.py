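"""Nei's standard genetic distance between diploid accessions and UPGMA trees.

Each accession is reduced to per-locus within-individual allele frequencies
(1 for a homozygote's allele, 0.5/0.5 for a heterozygote), Nei's standard
distance D = -ln(J_XY / sqrt(J_X * J_Y)) is computed over loci typed in both
accessions (pairwise deletion), and the resulting matrix is clustered with
classic size-weighted UPGMA into a rooted ultrametric tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from capspop.genotype_data import GenotypeMatrix

Profile = dict[str, dict[str, float]]


class DistanceError(ValueError):
    pass


def individual_allele_profile(gm: GenotypeMatrix, accession_id: str) -> Profile:
    """Per-locus allele-frequency vectors within one diploid individual.

    Homozygote -> {allele: 1.0}; heterozygote -> 0.5 each; missing loci
    are omitted from the profile.
    """
    profile: Profile = {}
    for marker, call in zip(gm.marker_ids, gm.accession_row(accession_id)):
        if call.is_missing:
            continue
        a, b = call.alleles
        profile[marker] = {a: 1.0} if a == b else {a: 0.5, b: 0.5}
    return profile


def nei_standard_distance(x_profile: Profile, y_profile: Profile) -> float:
    """Nei (1972) standard distance between two allele-frequency profiles.

    J_X, J_Y and J_XY are means over the loci present in both profiles of
    the within/between identity probabilities sum(x^2), sum(y^2), sum(x*y).
    Returns +inf when no allele is shared at any common locus.
    """
    shared = sorted(set(x_profile) & set(y_profile))
    if not shared:
        raise DistanceError("profiles share no typed locus")
    jx = jy = jxy = 0.0
    for locus in shared:
        x, y = x_profile[locus], y_profile[locus]
        jx += sum(v * v for v in x.values())
        jy += sum(v * v for v in y.values())
        jxy += sum(x[a] * y.get(a, 0.0) for a in x)
    jx /= len(shared)
    jy /= len(shared)
    jxy /= len(shared)
    if jxy == 0.0:
        return math.inf
    return max(0.0, -math.log(jxy / math.sqrt(jx * jy)))


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DistanceError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise DistanceError("matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise DistanceError("nonzero diagonal")
        if np.any(self.d < 0):
            raise DistanceError("negative distance")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs Nei standard distance matrix over a genotype matrix."""
    if gm.n_accessions < 2:
        raise DistanceError("need at least two accessions")
    profiles = [individual_allele_profile(gm, a) for a in gm.accession_ids]
    n = len(profiles)
    d = np.zeros((n, n))
    infinite_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            dij = nei_standard_distance(profiles[i], profiles[j])
            if math.isinf(dij):
                infinite_pairs.append((gm.accession_ids[i], gm.accession_ids[j]))
            d[i, j] = d[j, i] = dij
    if infinite_pairs:
        raise DistanceError(
            f"infinite distance (no shared alleles) for pairs: {infinite_pairs}"
        )
    return DistanceMatrix(list(gm.accession_ids), d)


@dataclass
class TreeNode:
    height: float
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out


@dataclass
class UltrametricTree:
    root: TreeNode
    labels: list[str]

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (equal for all leaves when ultrametric)."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            if node.is_leaf:
                depths[node.label] = acc + node.height  # leaf height is 0
                return
            for c in node.children:
                walk(c, acc + (node.height - c.height))

        walk(self.root, 0.0)
        return depths

    def cophenetic_matrix(self) -> DistanceMatrix:
        """Pairwise cophenetic distances: twice the height of the MRCA."""
        n = len(self.labels)
        idx = {l: i for i, l in enumerate(self.labels)}
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2 * node.height
            return [l for g in groups for l in g]

        walk(self.root)
        return DistanceMatrix(list(self.labels), d)


def upgma(dm: DistanceMatrix) -> UltrametricTree:
    """Size-weighted (classic) UPGMA agglomeration of a finite distance matrix.

    Ties are broken by the lowest (row, col) index pair in current cluster
    order, so output is deterministic.  Node height = merge distance / 2.
    """
    if np.any(np.isnan(dm.d)) or np.any(np.isinf(dm.d)):
        raise DistanceError("distance matrix contains NaN or infinite values")
    n = len(dm.labels)
    if n < 2:
        raise DistanceError("need at least two taxa")
    nodes: list[TreeNode] = [TreeNode(height=0.0, label=l) for l in dm.labels]
    sizes = [1] * n
    d = dm.d.astype(float).copy()
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                val = d[active[ii], active[jj]]
                if best is None or val < best[0]:
                    best = (val, ii, jj)
        dist, ii, jj = best  # type: ignore[misc]
        a, b = active[ii], active[jj]
        merged = TreeNode(height=dist / 2.0, children=[nodes[a], nodes[b]])
        # weighted average linkage: new distances are cluster-size-weighted means
        sa, sb = sizes[a], sizes[b]
        for k in active:
            if k in (a, b):
                continue
            d_new = (sa * d[a, k] + sb * d[b, k]) / (sa + sb)
            d[a, k] = d[k, a] = d_new
        nodes[a] = merged
        sizes[a] = sa + sb
        active.pop(jj)
    return UltrametricTree(root=nodes[active[0]], labels=list(dm.labels))


def _needs_quoting(label: str) -> bool:
    return any(c in label for c in " \t()[]':;,")


def _format_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: UltrametricTree, digits: int = 6) -> str:
    """Newick serialization; children ordered by their smallest leaf label,
    branch lengths are parent-child height differences."""

    def render(node: TreeNode, parent_height: float) -> str:
        blen = format(parent_height - node.height, f".{digits}g")
        if node.is_leaf:
            return f"{_format_label(node.label)}:{blen}"
        kids = sorted(node.children, key=lambda c: min(c.leaf_labels()))
        inner = ",".join(render(c, node.height) for c in kids)
        return f"({inner}):{blen}"

    root = tree.root
    kids = sorted(root.children, key=lambda c: min(c.leaf_labels()))
    inner = ",".join(render(c, root.height) for c in kids)
    return f"({inner});"
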