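"""Seeded generator of genotype matrices, marker panels and CAPS amplicons.

Population divergence follows the Balding-Nichols model: for target
differentiation F, each population's allele frequency at a locus is drawn
from Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral frequency p, giving
E[freq] = p and Var[freq] = p(1-p)F.  Genotypes within populations follow
Hardy-Weinberg proportions deformed by a homozygote-excess coefficient
(P(het) = 2pq(1-f_excess)); admixed individuals draw each allele copy from
a two-population mixture with uniform weights.  All randomness flows from
the single config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from capspop.caps_insilico import (
    IUPAC_EXPAND,
    Amplicon,
    RestrictionEnzyme,
    assess_caps_marker,
    load_enzyme_table,
)
from capspop.genotype_data import AlleleCall, GenotypeMatrix, MarkerDefinition

_NUC = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Defaults emulate a 41-accession, 70-locus panel: two core populations
    plus an admixed tail, 6 monomorphic loci, F_ST 0.15 and a homozygote
    excess tuned so mean observed heterozygosity lands near 0.26."""

    seed: int
    n_populations: int = 2
    population_sizes: tuple[int, ...] = (16, 14)
    n_admixed: int = 11
    n_loci: int = 70
    monomorphic_fraction: float = 6 / 70
    target_fst: float = 0.15
    ancestral_freq_range: tuple[float, float] = (0.15, 0.85)
    f_excess: float = 0.35
    missing_rate: float = 0.0
    amplicon_length_range: tuple[int, int] = (180, 420)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if not 0.0 <= self.target_fst < 1.0:
            raise SimulationError("target_fst must be in [0, 1)")
        for frac in (self.monomorphic_fraction, self.missing_rate, self.f_excess):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError("fractions must be in [0, 1]")
        if len(self.population_sizes) != self.n_populations:
            raise SimulationError("population_sizes length must equal n_populations")
        if any(s < 2 for s in self.population_sizes):
            raise SimulationError("each population needs >= 2 individuals")

    @property
    def n_individuals(self) -> int:
        return sum(self.population_sizes) + self.n_admixed


@dataclass
class SimulatedFrequencies:
    marker_ids: list[str]
    ref_alleles: list[str]
    alt_alleles: list[str]
    ancestral: np.ndarray  # ref-allele frequency, (L,)
    pop_freqs: np.ndarray  # (K, L)
    monomorphic: np.ndarray  # bool mask, (L,)


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def simulate_allele_frequencies(cfg: SimulationConfig) -> SimulatedFrequencies:
    """Draw ancestral and per-population ref-allele frequencies."""
    rng = _spawn(cfg.seed, 0)
    l = cfg.n_loci
    lo, hi = cfg.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=l)
    n_mono = int(round(cfg.monomorphic_fraction * l))
    monomorphic = np.zeros(l, dtype=bool)
    if n_mono:
        monomorphic[rng.choice(l, size=n_mono, replace=False)] = True
    ancestral[monomorphic] = 1.0
    f = cfg.target_fst
    if f == 0.0:
        pop = np.tile(ancestral, (cfg.n_populations, 1))
    else:
        scale = (1.0 - f) / f
        pop = rng.beta(
            np.maximum(ancestral * scale, 1e-9),
            np.maximum((1.0 - ancestral) * scale, 1e-9),
            size=(cfg.n_populations, l),
        )
    pop[:, monomorphic] = 1.0
    # ref/alt nucleotide symbols per locus (random, ref != alt)
    ref_idx = rng.integers(0, 4, size=l)
    alt_idx = (ref_idx + rng.integers(1, 4, size=l)) % 4
    return SimulatedFrequencies(
        marker_ids=[f"SYN-{i + 1:03d}" for i in range(l)],
        ref_alleles=[_NUC[i] for i in ref_idx],
        alt_alleles=[_NUC[i] for i in alt_idx],
        ancestral=ancestral,
        pop_freqs=pop,
        monomorphic=monomorphic,
    )


def simulate_genotypes(cfg: SimulationConfig, freqs: SimulatedFrequencies) -> GenotypeMatrix:
    """Draw a genotype matrix with population labels attached."""
    rng = _spawn(cfg.seed, 1)
    l = cfg.n_loci
    accession_ids: list[str] = []
    labels: list[str] = []
    calls: list[list[AlleleCall]] = []

    def genotype(p_ref: float, idx: int) -> AlleleCall:
        ref, alt = freqs.ref_alleles[idx], freqs.alt_alleles[idx]
        q = 1.0 - p_ref
        p_het = 2.0 * p_ref * q * (1.0 - cfg.f_excess)
        p_rr = p_ref * p_ref + cfg.f_excess * p_ref * q
        u = rng.random()
        if u < p_rr:
            return AlleleCall(ref, ref)
        if u < p_rr + p_het:
            return AlleleCall(ref, alt)
        return AlleleCall(alt, alt)

    counter = 0
    for pop_i, size in enumerate(cfg.population_sizes):
        for _ in range(size):
            counter += 1
            accession_ids.append(f"ACC{counter:03d}")
            labels.append(f"POP{pop_i + 1}")
            calls.append([genotype(freqs.pop_freqs[pop_i, j], j) for j in range(l)])
    for _ in range(cfg.n_admixed):
        counter += 1
        accession_ids.append(f"ACC{counter:03d}")
        labels.append("Admix")
        if cfg.n_populations >= 2:
            pa, pb = rng.choice(cfg.n_populations, size=2, replace=False)
        else:
            pa = pb = 0
        w = rng.random()
        row = []
        for j in range(l):
            ref, alt = freqs.ref_alleles[j], freqs.alt_alleles[j]

            def draw_copy() -> str:
                src = pa if rng.random() < w else pb
                return ref if rng.random() < freqs.pop_freqs[src, j] else alt

            first = draw_copy()
            # homozygote excess as copy correlation: P(het) scales by 1-f
            second = first if rng.random() < cfg.f_excess else draw_copy()
            row.append(AlleleCall(first, second))
        calls.append(row)

    if cfg.missing_rate > 0:
        mask = rng.random((len(calls), l)) < cfg.missing_rate
        for i in range(len(calls)):
            for j in range(l):
                if mask[i, j]:
                    calls[i][j] = AlleleCall.missing()

    return GenotypeMatrix(
        accession_ids=accession_ids,
        marker_ids=list(freqs.marker_ids),
        calls=calls,
        population_labels=labels,
    )


def parametric_fst(freqs: SimulatedFrequencies) -> float:
    """Realized differentiation of the drawn population frequencies.

    Ratio-of-sums over loci of (between-population minus within-population)
    pairwise allele-mismatch probability to the between-population one;
    its expectation under the Balding-Nichols draw equals the target F.
    This is the parameter a genotype-based estimator can actually recover
    from one simulated dataset (the frequency draw itself fluctuates
    around the nominal F when loci are few).
    """
    p = freqs.pop_freqs
    k = p.shape[0]
    if k < 2:
        raise SimulationError("need >= 2 populations")
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    d_b = np.mean([p[i] * (1 - p[j]) + p[j] * (1 - p[i]) for i, j in pairs], axis=0)
    d_w = np.mean([2 * p[i] * (1 - p[i]) for i in range(k)], axis=0)
    denom = d_b.sum()
    if denom == 0:
        return 0.0
    return float((d_b - d_w).sum() / denom)


def _instantiate_motif(motif: str, pin: int, base: str, rng: np.random.Generator) -> str:
    """Concrete A/C/G/T site matching the motif, with position ``pin`` = base."""
    out = []
    for i, sym in enumerate(motif):
        if i == pin:
            out.append(base)
        else:
            choices = IUPAC_EXPAND[sym]
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def simulate_caps_panel(
    cfg: SimulationConfig,
    freqs: SimulatedFrequencies,
    enzymes: dict[str, RestrictionEnzyme] | None = None,
    max_attempts: int = 200,
) -> tuple[list[Amplicon], list[MarkerDefinition]]:
    """Construct, per locus, an amplicon whose SNP creates a recognition site
    for the reference allele and destroys it for the alternate allele, with
    no other site of the chosen enzyme anywhere on either allele sequence.
    Digestion of such markers is differential by construction."""
    rng = _spawn(cfg.seed, 2)
    if enzymes is None:
        enzymes = load_enzyme_table()
    # within-site cutters with an interior cut make unambiguous band patterns
    usable = [
        e for _, e in sorted(enzymes.items())
        if not e.outside_cutter and 0 < e.cut_offset < len(e.recognition_motif)
    ]
    amplicons: list[Amplicon] = []
    defs: list[MarkerDefinition] = []
    lo, hi = cfg.amplicon_length_range
    for j, marker in enumerate(freqs.marker_ids):
        ref, alt = freqs.ref_alleles[j], freqs.alt_alleles[j]
        placed = None
        for _attempt in range(max_attempts):
            enzyme = usable[rng.integers(len(usable))]
            motif = enzyme.recognition_motif
            pins = [
                i for i, sym in enumerate(motif)
                if ref in IUPAC_EXPAND[sym] and alt not in IUPAC_EXPAND[sym]
            ]
            if not pins:
                continue
            pin = pins[rng.integers(len(pins))]
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(20, length - len(motif) - 20))
            site = _instantiate_motif(motif, pin, ref, rng)
            seq = "".join(_NUC[k] for k in rng.integers(0, 4, size=length))
            seq = seq[:start] + site + seq[start + len(motif):]
            snp_offset = start + pin
            try:
                amp = Amplicon(seq, snp_offset, ref, alt, marker_id=marker)
            except ValueError:
                continue
            assessment = assess_caps_marker(amp, enzyme)
            # exactly one differential cut; band patterns must stay distinguishable
            if (
                assessment.differential
                and len(assessment.ref_pattern.lengths) == 2
                and len(assessment.alt_pattern.lengths) == 1
                and assessment.het_band_set != assessment.ref_pattern.band_set
                and assessment.het_band_set != assessment.alt_pattern.band_set
            ):
                placed = (amp, enzyme)
                break
        if placed is None:
            raise SimulationError(f"{marker}: could not place a differential site")
        amp, enzyme = placed
        amplicons.append(amp)
        defs.append(
            MarkerDefinition(
                marker_id=marker,
                locus_desc="synthetic locus",
                chromosome=f"Chr{j % 13 + 1:02d}",
                ref_allele=ref,
                alt_allele=alt,
                enzyme_name=enzyme.name,
                incubation_temp=37.0,
                primer_left=amp.sequence[:20],
                primer_right=amp.sequence[-20:],
            )
        )
    return amplicons, defs


def write_amplicon_fasta(amplicons: list[Amplicon], path) -> None:
    with open(path, "w") as fh:
        for amp in amplicons:
            fh.write(f">{amp.marker_id} snp_offset={amp.snp_offset}\n")
            for i in range(0, len(amp.sequence), 70):
                fh.write(amp.sequence[i : i + 70] + "\n")


def write_truth_json(cfg: SimulationConfig, freqs: SimulatedFrequencies, gm, path) -> None:
    truth = {
        "config": asdict(cfg),
        "population_labels": dict(zip(gm.accession_ids, gm.population_labels)),
        "ancestral_freq": freqs.ancestral.tolist(),
        "population_freqs": freqs.pop_freqs.tolist(),
        "monomorphic": freqs.monomorphic.astype(int).tolist(),
        "ref_alleles": freqs.ref_alleles,
        "alt_alleles": freqs.alt_alleles,
    }
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
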