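"""Genotype-matrix and marker-definition data model with TSV/CSV I/O.

The central object is :class:`GenotypeMatrix`: a rectangular grid of
codominant diploid calls (unordered nucleotide pairs, e.g. ``A/G``) for a
set of accessions typed at a set of CAPS markers.  Marker metadata
(reference/alternate allele, restriction enzyme, primers) lives in
:class:`MarkerDefinition` rows.  Packaged reference tables for a 70-marker
button-mushroom panel are exposed via :func:`load_table2_markers` and
:func:`load_table3_stats`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical missing-allele sentinel (one symbol per allele copy; a fully
#: missing call renders as ``-/-`` on disk).
MISSING = "-"

NUCLEOTIDES = frozenset("ACGT")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")


class GenotypeDataError(ValueError):
    """Raised for malformed genotype or marker tables."""


@dataclass(frozen=True, order=True)
class AlleleCall:
    """An unordered diploid allele pair; both copies present or both missing."""

    allele_1: str
    allele_2: str

    def __post_init__(self) -> None:
        a, b = self.allele_1, self.allele_2
        if (a == MISSING) != (b == MISSING):
            raise GenotypeDataError(f"half-missing call {a}/{b} is not allowed")
        for x in (a, b):
            if x != MISSING and x not in NUCLEOTIDES:
                raise GenotypeDataError(f"non-nucleotide allele symbol {x!r}")
        if b < a:  # canonical sorted order: unordered pair
            object.__setattr__(self, "allele_1", b)
            object.__setattr__(self, "allele_2", a)

    @classmethod
    def missing(cls) -> "AlleleCall":
        return cls(MISSING, MISSING)

    @classmethod
    def parse(cls, cell: str) -> "AlleleCall":
        """Parse a ``X/Y`` cell; whitespace-trimmed, case-folded to upper."""
        parts = cell.strip().upper().split("/")
        if len(parts) != 2 or not all(p.strip() for p in parts):
            raise GenotypeDataError(f"cannot parse genotype cell {cell!r}")
        return cls(parts[0].strip(), parts[1].strip())

    @property
    def is_missing(self) -> bool:
        return self.allele_1 == MISSING

    @property
    def is_heterozygous(self) -> bool:
        return not self.is_missing and self.allele_1 != self.allele_2

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_1, self.allele_2)

    def __str__(self) -> str:
        return f"{self.allele_1}/{self.allele_2}"


@dataclass
class MarkerDefinition:
    """One row of a CAPS marker panel table."""

    marker_id: str
    locus_desc: str
    chromosome: str
    ref_allele: str
    alt_allele: str
    enzyme_name: str
    incubation_temp: float
    primer_left: str
    primer_right: str

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise GenotypeDataError(
                f"{self.marker_id}: alleles must be A/C/G/T, got "
                f"{self.ref_allele}/{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise GenotypeDataError(f"{self.marker_id}: ref and alt allele are equal")
        for p in (self.primer_left, self.primer_right):
            if not p or not set(p.upper()) <= IUPAC_ALPHABET:
                raise GenotypeDataError(f"{self.marker_id}: invalid primer {p!r}")

    @property
    def substitution_class(self) -> str:
        """``transition`` or ``transversion``, recomputed from ref/alt."""
        pair = {self.ref_allele, self.alt_allele}
        return "transition" if pair <= PURINES or pair <= PYRIMIDINES else "transversion"


@dataclass
class GenotypeMatrix:
    """Accessions x markers grid of diploid :class:`AlleleCall` values."""

    accession_ids: list[str]
    marker_ids: list[str]
    calls: list[list[AlleleCall]]
    population_labels: list[str] | None = None
    _marker_index: dict[str, int] = field(default_factory=dict, repr=False)
    _accession_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise GenotypeDataError("duplicate accession ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise GenotypeDataError("duplicate marker ids")
        if len(self.calls) != len(self.accession_ids):
            raise GenotypeDataError("row count does not match accession ids")
        for acc, row in zip(self.accession_ids, self.calls):
            if len(row) != len(self.marker_ids):
                raise GenotypeDataError(f"row {acc}: column count mismatch")
        if self.population_labels is not None and len(self.population_labels) != len(
            self.accession_ids
        ):
            raise GenotypeDataError("population label count mismatch")
        self._marker_index = {m: j for j, m in enumerate(self.marker_ids)}
        self._accession_index = {a: i for i, a in enumerate(self.accession_ids)}

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_column(self, marker_id: str) -> list[AlleleCall]:
        try:
            j = self._marker_index[marker_id]
        except KeyError:
            raise GenotypeDataError(f"unknown marker id {marker_id!r}") from None
        return [row[j] for row in self.calls]

    def accession_row(self, accession_id: str) -> list[AlleleCall]:
        try:
            i = self._accession_index[accession_id]
        except KeyError:
            raise GenotypeDataError(f"unknown accession id {accession_id!r}") from None
        return self.calls[i]

    def call(self, accession_id: str, marker_id: str) -> AlleleCall:
        return self.accession_row(accession_id)[self._marker_index[marker_id]]

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self._marker_index[m] if m in self._marker_index else None for m in marker_ids]
        if any(c is None for c in cols):
            bad = [m for m, c in zip(marker_ids, cols) if c is None]
            raise GenotypeDataError(f"unknown marker ids: {bad}")
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            marker_ids=list(marker_ids),
            calls=[[row[c] for c in cols] for row in self.calls],
            population_labels=(
                list(self.population_labels) if self.population_labels is not None else None
            ),
        )

    def with_population_labels(self, labels: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            marker_ids=list(self.marker_ids),
            calls=self.calls,
            population_labels=list(labels),
        )


@dataclass
class ValidationReport:
    """Per-marker consistency report of a matrix against a marker panel."""

    off_panel: list[tuple[str, str, str]]  # (accession, marker, call)
    missing_rate: float
    n_missing: int
    monomorphic_markers: list[str]

    @property
    def ok(self) -> bool:
        return not self.off_panel


def _infer_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_genotype_table(path: str | Path, sep: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix.

    Layout: header row is ``<id-column>, marker ids...``; each following row
    is an accession id plus one ``X/Y`` cell per marker.  ``-/-`` encodes a
    missing call.  Separator is inferred from the extension unless given.
    """
    sep = _infer_sep(path, sep)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        raise GenotypeDataError(f"{path}: empty genotype table")
    marker_ids = [c.strip() for c in rows[0][1:]]
    accession_ids: list[str] = []
    calls: list[list[AlleleCall]] = []
    for r in rows[1:]:
        acc = r[0].strip()
        accession_ids.append(acc)
        row_calls = []
        for marker, cell in zip(marker_ids, r[1:]):
            try:
                row_calls.append(AlleleCall.parse(cell))
            except GenotypeDataError as exc:
                raise GenotypeDataError(
                    f"{path}: cell ({acc}, {marker}): {exc}"
                ) from None
        if len(row_calls) != len(marker_ids):
            raise GenotypeDataError(f"{path}: row {acc}: wrong number of cells")
        calls.append(row_calls)
    gm = GenotypeMatrix(accession_ids, marker_ids, calls)
    logger.info(
        "read genotype table %s: %d accessions x %d markers", path, gm.n_accessions, gm.n_markers
    )
    return gm


def write_genotype_table(gm: GenotypeMatrix, path: str | Path, sep: str | None = None) -> None:
    """Write a genotype matrix in the layout accepted by :func:`read_genotype_table`."""
    sep = _infer_sep(path, sep)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(["accession"] + list(gm.marker_ids))
        for acc, row in zip(gm.accession_ids, gm.calls):
            writer.writerow([acc] + [str(c) for c in row])


MARKER_TABLE_COLUMNS = [
    "marker_id",
    "locus_desc",
    "chromosome",
    "substitution",
    "ref_allele",
    "alt_allele",
    "enzyme",
    "temp_c",
    "primer_left",
    "primer_right",
]


def read_marker_table(path: str | Path, sep: str | None = None) -> list[MarkerDefinition]:
    """Read a marker-definition table.

    The stated substitution column (transition/transversion) is checked
    against the class recomputed from ref/alt; a conflict is an error.
    """
    sep = _infer_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing_cols = set(MARKER_TABLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise GenotypeDataError(f"{path}: missing columns {sorted(missing_cols)}")
    defs: list[MarkerDefinition] = []
    for _, row in df.iterrows():
        md = MarkerDefinition(
            marker_id=row["marker_id"],
            locus_desc=row["locus_desc"],
            chromosome=row["chromosome"],
            ref_allele=row["ref_allele"],
            alt_allele=row["alt_allele"],
            enzyme_name=row["enzyme"],
            incubation_temp=float(row["temp_c"]),
            primer_left=row["primer_left"],
            primer_right=row["primer_right"],
        )
        stated = str(row["substitution"]).strip().lower()
        if stated and stated != md.substitution_class:
            raise GenotypeDataError(
                f"{md.marker_id}: stated substitution class {stated!r} conflicts "
                f"with recomputed {md.substitution_class!r}"
            )
        defs.append(md)
    if len({d.marker_id for d in defs}) != len(defs):
        raise GenotypeDataError(f"{path}: duplicate marker ids")
    return defs


def write_marker_table(defs: Iterable[MarkerDefinition], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MARKER_TABLE_COLUMNS)
        for d in defs:
            writer.writerow(
                [
                    d.marker_id,
                    d.locus_desc,
                    d.chromosome,
                    d.substitution_class.capitalize(),
                    d.ref_allele,
                    d.alt_allele,
                    d.enzyme_name,
                    f"{d.incubation_temp:g}",
                    d.primer_left,
                    d.primer_right,
                ]
            )


def validate_against_markers(
    gm: GenotypeMatrix, defs: Sequence[MarkerDefinition]
) -> ValidationReport:
    """Check observed alleles against a marker panel's ref/alt definitions."""
    by_id = {d.marker_id: d for d in defs}
    unknown = [m for m in gm.marker_ids if m not in by_id]
    if unknown:
        raise GenotypeDataError(f"markers not in definition table: {unknown}")
    off_panel: list[tuple[str, str, str]] = []
    n_missing = 0
    monomorphic: list[str] = []
    for marker in gm.marker_ids:
        d = by_id[marker]
        panel = {d.ref_allele, d.alt_allele}
        observed: set[str] = set()
        for acc, call in zip(gm.accession_ids, gm.marker_column(marker)):
            if call.is_missing:
                n_missing += 1
                continue
            observed.update(call.alleles)
            if not set(call.alleles) <= panel:
                off_panel.append((acc, marker, str(call)))
        if len(observed) <= 1:
            monomorphic.append(marker)
    n_cells = gm.n_accessions * gm.n_markers
    return ValidationReport(
        off_panel=off_panel,
        missing_rate=n_missing / n_cells if n_cells else 0.0,
        n_missing=n_missing,
        monomorphic_markers=monomorphic,
    )


def _data_path(name: str):
    return resources.files("capspop.data").joinpath(name)


def load_table2_markers() -> list[MarkerDefinition]:
    """Packaged 70-marker CAPS panel definition table."""
    with resources.as_file(_data_path("table2_markers.tsv")) as p:
        return read_marker_table(p)


def load_table3_stats() -> pd.DataFrame:
    """Packaged per-locus diversity reference table (MAF/NG/NA/GD/He)."""
    with resources.as_file(_data_path("table3_stats.tsv")) as p:
        return pd.read_csv(p, sep="\t")
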