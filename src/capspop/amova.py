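"""Three-level codominant AMOVA with F_ST and permutation testing.

Molecular variance is partitioned among populations, among individuals
within populations, and within individuals.  The distance between two
allele copies is the infinite-allele mismatch indicator (0/1 per locus,
summed over loci).  Sums of squares are computed per level from average
squared distances within groups of allele copies; variance components are
solved from the expected mean squares with the unequal-sample-size
coefficient n0 = (2N - sum_p (2N_p)^2 / 2N) / (P - 1), and negative
components are truncated to zero before percentages and F_ST.

Significance of F_ST is assessed by permuting whole individuals among
populations (sizes preserved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from capspop.genotype_data import GenotypeMatrix

MAX_ALLELES = 4


class AmovaError(ValueError):
    pass


@dataclass
class AmovaResult:
    rows: list[dict]  # source, df, SS, MS, est_variance, percent
    f_st: float
    n_individuals: int
    n_populations: int
    p_value: float | None = None
    n_permutations: int = 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


class _AmovaData:
    """One-hot allele-copy encoding enabling fast SS recomputation under
    label permutation (total SS and the within-individual SS are invariant)."""

    def __init__(self, gm: GenotypeMatrix):
        if gm.population_labels is None:
            raise AmovaError("population labels required for AMOVA")
        n, l = gm.n_accessions, gm.n_markers
        # per-locus allele symbol -> code
        codes: list[dict[str, int]] = [dict() for _ in range(l)]
        onehot = np.zeros((2 * n, l, MAX_ALLELES), dtype=np.float64)
        het = np.zeros((n, l), dtype=np.float64)
        n_missing = 0
        for i, row in enumerate(gm.calls):
            for j, call in enumerate(row):
                if call.is_missing:
                    n_missing += 1
                    continue
                for copy, allele in enumerate(call.alleles):
                    code = codes[j].setdefault(allele, len(codes[j]))
                    onehot[2 * i + copy, j, code] = 1.0
                if call.is_heterozygous:
                    het[i, j] = 1.0
        self.onehot = onehot
        self.n = n
        self.l = l
        self.n_missing_calls = n_missing
        self.ss_within_individuals = float(het.sum() / 2.0)
        self.ss_total = self._group_ss(np.arange(n))
        labels = list(gm.population_labels)
        self.pop_names = sorted(set(labels))
        self.pop_of = np.array([self.pop_names.index(p) for p in labels])

    def _group_ss(self, individuals: np.ndarray) -> float:
        """SS within one group of individuals: per locus, (mismatching copy
        pairs) / (copies present), summed over loci."""
        rows = np.concatenate([2 * individuals, 2 * individuals + 1])
        counts = self.onehot[rows].sum(axis=0)  # (L, A)
        c = counts.sum(axis=1)  # copies present per locus
        pairs_total = c * (c - 1) / 2.0
        pairs_same = (counts * (counts - 1) / 2.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_locus = np.where(c > 0, (pairs_total - pairs_same) / np.maximum(c, 1), 0.0)
        return float(per_locus.sum())

    def components(self, pop_of: np.ndarray) -> tuple[float, float, float, dict[str, float]]:
        """Raw (untruncated) variance components for a label assignment."""
        n, p = self.n, len(self.pop_names)
        sizes = np.bincount(pop_of, minlength=p)
        if np.any(sizes < 2):
            raise AmovaError("every population needs at least 2 individuals")
        ss_within_pops = sum(
            self._group_ss(np.flatnonzero(pop_of == g)) for g in range(p)
        )
        ss_ap = self.ss_total - ss_within_pops
        ss_ai = ss_within_pops - self.ss_within_individuals
        ss_wi = self.ss_within_individuals
        df_ap, df_ai, df_wi = p - 1, n - p, n
        ms_ap, ms_ai, ms_wi = ss_ap / df_ap, ss_ai / df_ai, ss_wi / df_wi
        n0 = (2 * n - np.sum((2 * sizes) ** 2) / (2 * n)) / (p - 1)
        sigma_c = ms_wi
        sigma_b = (ms_ai - ms_wi) / 2.0
        sigma_a = (ms_ap - ms_ai) / n0
        detail = {
            "ss_ap": ss_ap, "ss_ai": ss_ai, "ss_wi": ss_wi,
            "ms_ap": ms_ap, "ms_ai": ms_ai, "ms_wi": ms_wi, "n0": n0,
        }
        return sigma_a, sigma_b, sigma_c, detail

    def fst(self, pop_of: np.ndarray, truncated: bool = True) -> float:
        """F_ST for a label assignment.

        ``truncated=False`` keeps negative components (the permutation-test
        statistic: truncation would tie every null replicate at zero).
        """
        sigma_a, sigma_b, sigma_c, _ = self.components(pop_of)
        if truncated:
            sigma_a, sigma_b, sigma_c = (
                max(sigma_a, 0.0), max(sigma_b, 0.0), max(sigma_c, 0.0)
            )
        total = sigma_a + sigma_b + sigma_c
        return sigma_a / total if total > 0 else 0.0


def amova_codominant(gm: GenotypeMatrix) -> AmovaResult:
    """Three-level AMOVA of a genotype matrix with attached population labels."""
    data = _AmovaData(gm)
    if len(data.pop_names) < 2:
        raise AmovaError("need at least 2 populations")
    sigma_a, sigma_b, sigma_c, d = data.components(data.pop_of)
    n, p = data.n, len(data.pop_names)
    est = np.maximum([sigma_a, sigma_b, sigma_c], 0.0)
    total_var = est.sum()
    percent = 100.0 * est / total_var if total_var > 0 else np.zeros(3)
    f_st = est[0] / total_var if total_var > 0 else 0.0
    rows = [
        {"source": "Among Pops", "df": p - 1, "SS": d["ss_ap"], "MS": d["ms_ap"],
         "est_variance": est[0], "percent": percent[0]},
        {"source": "Among Indiv", "df": n - p, "SS": d["ss_ai"], "MS": d["ms_ai"],
         "est_variance": est[1], "percent": percent[1]},
        {"source": "Within Indiv", "df": n, "SS": d["ss_wi"], "MS": d["ms_wi"],
         "est_variance": est[2], "percent": percent[2]},
        {"source": "Total", "df": 2 * n - 1, "SS": d["ss_ap"] + d["ss_ai"] + d["ss_wi"],
         "MS": float("nan"), "est_variance": total_var, "percent": 100.0},
    ]
    return AmovaResult(rows=rows, f_st=float(f_st), n_individuals=n, n_populations=p)


def permute_fst(
    gm: GenotypeMatrix,
    observed: AmovaResult | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for F_ST: individuals shuffled among populations.

    p = (#{permuted F_ST >= observed} + 1) / (n_perm + 1).  Observed and
    permuted statistics are both computed without negative-component
    truncation so null replicates are not tied at zero.
    """
    if n_perm < 1:
        raise AmovaError("n_perm must be >= 1")
    data = _AmovaData(gm)
    rng = np.random.default_rng(seed)
    obs = data.fst(data.pop_of, truncated=False)
    count = 0
    pop_of = data.pop_of.copy()
    for _ in range(n_perm):
        rng.shuffle(pop_of)
        if data.fst(pop_of, truncated=False) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
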