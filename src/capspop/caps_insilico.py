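"""In-silico CAPS assay: site scanning, digestion, and genotype calling.

A CAPS marker is usable when the two SNP alleles of an amplicon yield
different restriction-fragment patterns.  This module scans IUPAC
recognition motifs on both strands, predicts fragment-length patterns for
each allele, and converts observed band patterns back into diploid
genotype calls.

Coordinates are 0-based, half-open.  A gel band pattern is abstracted as
a multiset of fragment lengths; band intensity (dosage) is not modeled.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from capspop.genotype_data import (
    MISSING,
    NUCLEOTIDES,
    PURINES,
    PYRIMIDINES,
    AlleleCall,
    GenotypeDataError,
)

logger = logging.getLogger(__name__)

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_matches(symbol: str, base: str) -> bool:
    return base in IUPAC_EXPAND[symbol]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: name, IUPAC recognition motif, top-strand cut offset."""

    name: str
    recognition_motif: str
    cut_offset: int
    outside_cutter: bool = False

    def __post_init__(self) -> None:
        motif = self.recognition_motif.upper()
        if not motif or not set(motif) <= set(IUPAC_EXPAND):
            raise ValueError(f"{self.name}: invalid motif {self.recognition_motif!r}")
        object.__setattr__(self, "recognition_motif", motif)
        if not self.outside_cutter and not 0 <= self.cut_offset <= len(motif):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside motif "
                "(flag as outside_cutter to allow)"
            )

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition_motif) == self.recognition_motif


@dataclass(frozen=True)
class Amplicon:
    """Reference-allele PCR product carrying one biallelic SNP."""

    sequence: str
    snp_offset: int
    ref_allele: str
    alt_allele: str
    marker_id: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if not set(seq) <= NUCLEOTIDES:
            raise ValueError(f"{self.marker_id}: amplicon must be plain A/C/G/T")
        if not 0 <= self.snp_offset < len(seq):
            raise ValueError(f"{self.marker_id}: SNP offset {self.snp_offset} out of range")
        if seq[self.snp_offset] != self.ref_allele:
            raise ValueError(
                f"{self.marker_id}: sequence has {seq[self.snp_offset]} at SNP "
                f"offset, expected ref allele {self.ref_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.marker_id}: ref and alt allele are equal")

    @property
    def alt_sequence(self) -> str:
        s = self.sequence
        return s[: self.snp_offset] + self.alt_allele + s[self.snp_offset + 1 :]


class FragmentPattern:
    """Multiset of fragment lengths (bp) summing to the digested length."""

    __slots__ = ("_lengths",)

    def __init__(self, lengths) -> None:
        lengths = tuple(sorted(int(x) for x in lengths))
        if not lengths or any(x <= 0 for x in lengths):
            raise ValueError("fragment pattern needs >=1 positive length")
        self._lengths = lengths

    @property
    def lengths(self) -> tuple[int, ...]:
        return self._lengths

    @property
    def total_length(self) -> int:
        return sum(self._lengths)

    @property
    def band_set(self) -> frozenset[int]:
        """Distinct band lengths — what a gel lane actually shows."""
        return frozenset(self._lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, FragmentPattern) and self._lengths == other._lengths

    def __hash__(self) -> int:
        return hash(self._lengths)

    def __repr__(self) -> str:
        return f"FragmentPattern({list(self._lengths)})"


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a biallelic SNP as ``transition`` or ``transversion``.

    Transitions stay within the purines {A, G} or within the pyrimidines
    {C, T}; every purine<->pyrimidine change is a transversion.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise ValueError(f"alleles must be A/C/G/T, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt allele are both {ref!r}")
    pair = {ref, alt}
    return "transition" if pair <= PURINES or pair <= PYRIMIDINES else "transversion"


def _motif_regex(motif: str) -> re.Pattern:
    pattern = "".join(
        IUPAC_EXPAND[s] if len(IUPAC_EXPAND[s]) == 1 else f"[{IUPAC_EXPAND[s]}]"
        for s in motif
    )
    return re.compile(f"(?=({pattern}))")  # lookahead: overlapping matches


def _scan_oriented(seq: str, enzyme: RestrictionEnzyme) -> list[tuple[int, str]]:
    """All motif matches as (forward-strand start, orientation) pairs.

    A position matching on both strands (palindromic site) is reported once
    with orientation ``+``.
    """
    seq = seq.upper()
    fwd = {m.start() for m in _motif_regex(enzyme.recognition_motif).finditer(seq)}
    rev = {
        m.start()
        for m in _motif_regex(reverse_complement(enzyme.recognition_motif)).finditer(seq)
    }
    hits = [(p, "+") for p in fwd]
    hits += [(p, "-") for p in rev - fwd]
    return sorted(hits)


def find_recognition_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Forward-strand start coordinates of all recognition sites (both strands)."""
    return [p for p, _ in _scan_oriented(seq, enzyme)]


def digest_amplicon(seq: str, enzyme: RestrictionEnzyme) -> FragmentPattern:
    """Fragment-length pattern of a complete digest of a linear sequence.

    Top-strand cut coordinates: ``site + cut_offset`` for forward-oriented
    sites, mirrored for reverse-only sites.  Cut coordinates falling outside
    the sequence (an outside cutter near an end) are skipped with a warning;
    fragment lengths always partition the input length.
    """
    seq = seq.upper()
    n = len(seq)
    cuts: set[int] = set()
    for pos, orient in _scan_oriented(seq, enzyme):
        if orient == "+":
            cut = pos + enzyme.cut_offset
        else:
            cut = pos + len(enzyme.recognition_motif) - enzyme.cut_offset
        if 0 < cut < n:
            cuts.add(cut)
        else:
            logger.warning(
                "%s: cut coordinate %d outside sequence of length %d; site at %d skipped",
                enzyme.name, cut, n, pos,
            )
    bounds = [0] + sorted(cuts) + [n]
    return FragmentPattern(b - a for a, b in zip(bounds, bounds[1:]))


@dataclass(frozen=True)
class CapsAssessment:
    """Predicted per-allele digestion patterns of a CAPS marker."""

    marker_id: str
    ref_allele: str
    alt_allele: str
    ref_pattern: FragmentPattern
    alt_pattern: FragmentPattern
    differential: bool
    min_length_delta: int

    @property
    def het_band_set(self) -> frozenset[int]:
        """Band lengths of a heterozygote lane (comigrating bands collapse)."""
        return self.ref_pattern.band_set | self.alt_pattern.band_set


def assess_caps_marker(amp: Amplicon, enzyme: RestrictionEnzyme) -> CapsAssessment:
    """Digest both allele sequences and test whether the patterns differ.

    ``min_length_delta`` is the smallest difference between distinct band
    lengths across the union of both patterns — a proxy for whether the
    difference is resolvable on a gel (0 when fewer than two distinct bands).
    """
    ref_pattern = digest_amplicon(amp.sequence, enzyme)
    alt_pattern = digest_amplicon(amp.alt_sequence, enzyme)
    union = sorted(ref_pattern.band_set | alt_pattern.band_set)
    delta = min((b - a for a, b in zip(union, union[1:])), default=0)
    return CapsAssessment(
        marker_id=amp.marker_id,
        ref_allele=amp.ref_allele,
        alt_allele=amp.alt_allele,
        ref_pattern=ref_pattern,
        alt_pattern=alt_pattern,
        differential=ref_pattern != alt_pattern,
        min_length_delta=delta,
    )


@dataclass(frozen=True)
class FragmentCall:
    """Genotype call derived from an observed band pattern."""

    call: AlleleCall
    diagnostic: str | None = None


def call_genotype_from_fragments(
    observed: FragmentPattern, assessment: CapsAssessment
) -> FragmentCall:
    """Convert an observed fragment pattern into a diploid genotype call.

    Homozygotes must match an allele pattern exactly (as multisets); a
    heterozygote lane is the union of both patterns with comigrating bands
    collapsed, so it is matched on distinct band lengths.  Unexplained
    patterns yield a missing call with a diagnostic.
    """
    if not assessment.differential:
        raise ValueError(
            f"{assessment.marker_id}: non-differential marker cannot be genotyped"
        )
    ref, alt = assessment.ref_allele, assessment.alt_allele
    if observed == assessment.ref_pattern:
        return FragmentCall(AlleleCall(ref, ref))
    if observed == assessment.alt_pattern:
        return FragmentCall(AlleleCall(alt, alt))
    if observed.band_set == assessment.het_band_set:
        return FragmentCall(AlleleCall(ref, alt))
    return FragmentCall(
        AlleleCall(MISSING, MISSING),
        diagnostic=(
            f"{assessment.marker_id}: observed bands {sorted(observed.band_set)} match "
            f"neither allele pattern nor their union"
        ),
    )


def load_enzyme_table(path: str | Path | None = None) -> dict[str, RestrictionEnzyme]:
    """Load the packaged (or a user-supplied) enzyme definition table."""
    if path is None:
        with resources.as_file(
            resources.files("capspop.data").joinpath("enzymes.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    enzymes = {}
    for _, row in df.iterrows():
        enzymes[row["name"]] = RestrictionEnzyme(
            name=row["name"],
            recognition_motif=row["motif"],
            cut_offset=int(row["cut_offset"]),
            outside_cutter=bool(int(row.get("outside_cutter", 0))),
        )
    return enzymes


def read_amplicon_fasta(path: str | Path, defs_by_id: dict) -> list[Amplicon]:
    """Read amplicons from FASTA; record id = marker id, description carries
    ``snp_offset=<int>``; ref/alt come from the marker definitions."""
    from Bio import SeqIO

    amps = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = re.search(r"snp_offset=(\d+)", rec.description)
        if m is None:
            raise GenotypeDataError(f"{rec.id}: missing snp_offset tag in FASTA header")
        d = defs_by_id[rec.id]
        amps.append(
            Amplicon(
                sequence=str(rec.seq),
                snp_offset=int(m.group(1)),
                ref_allele=d.ref_allele,
                alt_allele=d.alt_allele,
                marker_id=rec.id,
            )
        )
    return amps
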