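"""Bayesian admixture-model clustering with Gibbs sampling and Evanno's delta-K.

The model: each individual i has admixture proportions q_i over K clusters
(Dirichlet(alpha,...,alpha) prior, shared alpha with a uniform prior on
(0, 10]); each cluster k has per-locus allele frequencies with a uniform
Dirichlet prior; each allele copy independently originates from cluster k
with probability q_ik and then carries allele u with probability p_klu.

One Gibbs sweep: (i) sample the cluster of origin of every allele copy,
(ii) sample cluster allele frequencies from their Dirichlet posteriors,
(iii) sample q rows from Dirichlet(alpha + per-cluster copy counts),
(iv) Metropolis-update alpha.  The data log-likelihood recorded after
burn-in is log P(X | P, Q) with copy origins marginalized out; the model
log-evidence is estimated as mean - variance/2 of that trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from capspop.genotype_data import GenotypeMatrix


class StructureError(ValueError):
    pass


@dataclass
class StructureRun:
    k: int
    q: np.ndarray  # posterior-mean admixture proportions, accessions x K
    accession_ids: list[str]
    alpha_mean: float
    log_lik_trace: np.ndarray
    ln_pd: float
    seed: int | None = None

    def to_q_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.q,
            index=self.accession_ids,
            columns=[f"cluster_{i + 1}" for i in range(self.k)],
        )


@dataclass
class EvannoTable:
    k_values: list[int]
    mean_ln_pd: list[float]
    sd_ln_pd: list[float]
    l_prime: list[float]  # first difference, NaN at K_min
    l_double_prime: list[float]  # |second difference|, NaN at endpoints
    delta_k: list[float]  # NaN where undefined
    optimal_k: int

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "K": self.k_values,
                "mean_ln_pd": self.mean_ln_pd,
                "sd_ln_pd": self.sd_ln_pd,
                "l_prime": self.l_prime,
                "abs_l_double_prime": self.l_double_prime,
                "delta_k": self.delta_k,
            }
        )


def _encode_copies(gm: GenotypeMatrix):
    """Flatten non-missing allele copies into parallel index arrays."""
    allele_codes: list[dict[str, int]] = [dict() for _ in range(gm.n_markers)]
    ind_idx, loc_idx, allele_idx = [], [], []
    for i, row in enumerate(gm.calls):
        for j, call in enumerate(row):
            if call.is_missing:
                continue
            for allele in call.alleles:
                code = allele_codes[j].setdefault(allele, len(allele_codes[j]))
                ind_idx.append(i)
                loc_idx.append(j)
                allele_idx.append(code)
    n_alleles = np.array([max(len(c), 1) for c in allele_codes])
    return (
        np.asarray(ind_idx, dtype=np.intp),
        np.asarray(loc_idx, dtype=np.intp),
        np.asarray(allele_idx, dtype=np.intp),
        n_alleles,
    )


def run_admixture_gibbs(
    gm: GenotypeMatrix,
    k: int,
    burn_in: int = 10_000,
    n_iter: int = 100_000,
    seed: int | None = None,
    thin: int = 10,
    alpha_init: float = 1.0,
    alpha_max: float = 10.0,
    alpha_proposal_sd: float = 0.25,
) -> StructureRun:
    """Run one seeded admixture-model Gibbs chain and summarize it."""
    if k < 1:
        raise StructureError("K must be >= 1")
    if k > gm.n_accessions:
        raise StructureError(f"K={k} exceeds number of accessions ({gm.n_accessions})")
    rng = np.random.default_rng(seed)
    n, l = gm.n_accessions, gm.n_markers
    ind_idx, loc_idx, allele_idx, n_alleles = _encode_copies(gm)
    m = ind_idx.size
    a_max = int(n_alleles.max())
    allowed = np.arange(a_max)[None, :] < n_alleles[:, None]  # (L, A)

    # initial state
    q = np.full((n, k), 1.0 / k)
    p = np.where(allowed, 1.0 / n_alleles[:, None], 0.0)[None].repeat(k, axis=0)
    alpha = float(alpha_init)
    copy_offset = loc_idx * a_max + allele_idx  # (M,)

    log_lik: list[float] = []
    alpha_trace: list[float] = []
    q_sum = np.zeros_like(q)
    n_recorded = 0

    # with a single cluster the copy origins and q are fixed, so the
    # frequency-count vector never changes
    fixed_counts = None
    if k == 1:
        fixed_counts = np.bincount(copy_offset, minlength=l * a_max).reshape(1, l, a_max)

    total_iters = burn_in + n_iter
    for it in range(total_iters):
        if k == 1:
            shape = np.where(allowed[None], 1.0 + fixed_counts, 0.0)
            g = rng.gamma(shape)
            p = g / np.maximum(g.sum(axis=2, keepdims=True), 1e-300)
        else:
            # (i) cluster of origin for each allele copy
            w = q[ind_idx] * p[:, loc_idx, allele_idx].T  # (M, K)
            cum = np.cumsum(w, axis=1)
            u = rng.random(m) * cum[:, -1]
            z = (cum < u[:, None]).sum(axis=1)

            # (ii) cluster allele frequencies ~ Dirichlet(1 + counts)
            counts = np.bincount(z * (l * a_max) + copy_offset, minlength=k * l * a_max)
            counts = counts.reshape(k, l, a_max)
            shape = np.where(allowed[None], 1.0 + counts, 0.0)
            g = rng.gamma(shape)
            p = g / np.maximum(g.sum(axis=2, keepdims=True), 1e-300)

            # (iii) admixture proportions ~ Dirichlet(alpha + counts)
            n_ik = np.bincount(ind_idx * k + z, minlength=n * k).reshape(n, k)
            gq = rng.gamma(alpha + n_ik)
            q = gq / np.maximum(gq.sum(axis=1, keepdims=True), 1e-300)
            np.clip(q, 1e-12, None, out=q)
            q /= q.sum(axis=1, keepdims=True)

        # (iv) Metropolis update of the shared alpha (uniform prior on (0, alpha_max])
        if k > 1:
            prop = alpha + rng.normal(0.0, alpha_proposal_sd)
            if 0.0 < prop <= alpha_max:
                sum_log_q = float(np.log(q).sum())
                def _log_post(a: float) -> float:
                    return n * (math.lgamma(k * a) - k * math.lgamma(a)) + (a - 1.0) * sum_log_q
                if math.log(rng.random()) < _log_post(prop) - _log_post(alpha):
                    alpha = prop

        if it >= burn_in and (it - burn_in) % thin == 0:
            mix = np.einsum("mk,mk->m", q[ind_idx], p[:, loc_idx, allele_idx].T)
            log_lik.append(float(np.log(np.maximum(mix, 1e-300)).sum()))
            alpha_trace.append(alpha)
            q_sum += q
            n_recorded += 1

    if n_recorded == 0:
        raise StructureError("no recorded iterations (n_iter too small for thinning)")
    q_mean = q_sum / n_recorded
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    trace = np.asarray(log_lik)
    return StructureRun(
        k=k,
        q=q_mean,
        accession_ids=list(gm.accession_ids),
        alpha_mean=float(np.mean(alpha_trace)),
        log_lik_trace=trace,
        ln_pd=estimate_log_evidence(trace),
        seed=seed,
    )


def estimate_log_evidence(log_lik_trace: np.ndarray) -> float:
    """STRUCTURE-style model log-evidence: mean(L) - var(L)/2 (population var)."""
    trace = np.asarray(log_lik_trace, dtype=float)
    if trace.size < 1:
        raise StructureError("empty log-likelihood trace")
    return float(trace.mean() - trace.var(ddof=0) / 2.0)


def evanno_delta_k(runs_by_k: dict[int, list[float]]) -> EvannoTable:
    """Evanno's delta-K over replicate log-evidence values per K.

    delta_K = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)) with the
    sample (n-1) standard deviation; defined only at interior K with sd > 0.
    """
    ks = sorted(runs_by_k)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise StructureError("K range must be contiguous")
    for kk in ks:
        if len(runs_by_k[kk]) < 2:
            raise StructureError(f"K={kk}: need >=2 replicate runs")
    means = [float(np.mean(runs_by_k[kk])) for kk in ks]
    sds = [float(np.std(runs_by_k[kk], ddof=1)) for kk in ks]
    l_prime, l_dprime, delta = [], [], []
    for idx, kk in enumerate(ks):
        lp = means[idx] - means[idx - 1] if idx > 0 else float("nan")
        if 0 < idx < len(ks) - 1:
            ldp = abs(means[idx + 1] - 2 * means[idx] + means[idx - 1])
            dk = ldp / sds[idx] if sds[idx] > 0 else float("nan")
        else:
            ldp, dk = float("nan"), float("nan")
        l_prime.append(lp)
        l_dprime.append(ldp)
        delta.append(dk)
    finite = [(d, -kk) for kk, d in zip(ks, delta) if not math.isnan(d)]
    if not finite:
        raise StructureError("delta-K undefined everywhere (need interior K with sd > 0)")
    optimal_k = -max(finite)[1]
    return EvannoTable(
        k_values=ks,
        mean_ln_pd=means,
        sd_ln_pd=sds,
        l_prime=l_prime,
        l_double_prime=l_dprime,
        delta_k=delta,
        optimal_k=optimal_k,
    )


def classify_membership(run: StructureRun, threshold: float = 0.7) -> dict[str, str]:
    """Assign each accession to its max-q cluster, or "Admix" below threshold."""
    if not 0.5 < threshold <= 1.0:
        raise StructureError("threshold must be in (0.5, 1]")
    out = {}
    for acc, row in zip(run.accession_ids, run.q):
        kbest = int(np.argmax(row))
        out[acc] = f"POP{kbest + 1}" if row[kbest] >= threshold else "Admix"
    return out
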