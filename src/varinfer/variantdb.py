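"""Variant sequence databases: FASTA I/O, redundancy collapse, pairwise
identity, relationship classification and tryptic-peptide census.

A "variant database" is the restricted search space used to disambiguate
closely related protein sequence variants (e.g. isoallergens of a major
allergen): an ordered collection of accessioned amino-acid sequences.
Identity-based relationship classes follow the allergen-nomenclature
convention: two forms of the same allergen are isoallergens above 67%
identity and variants (of the same isoallergen) above 90%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .digestion import DigestionParams, digest, validate_sequence


class DatabaseError(ValueError):
    """Raised for malformed or inconsistent variant databases."""


@dataclass(frozen=True)
class VariantEntry:
    accession: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise DatabaseError("empty accession")
        try:
            validate_sequence(self.sequence, f"record {self.accession!r}")
        except ValueError as exc:
            raise DatabaseError(str(exc)) from None


@dataclass
class VariantDatabase:
    """Ordered collection of variant entries with distinct accessions."""

    entries: list[VariantEntry]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for entry in self.entries:
            if entry.accession in seen:
                raise DatabaseError(f"duplicate accession {entry.accession}")
            seen.add(entry.accession)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def accessions(self) -> list[str]:
        return [e.accession for e in self.entries]

    def get(self, accession: str) -> VariantEntry:
        for entry in self.entries:
            if entry.accession == accession:
                return entry
        raise KeyError(accession)

    def sequences(self) -> dict[str, str]:
        return {e.accession: e.sequence for e in self.entries}


def _parse_header(record) -> tuple[str, str]:
    """Accession and free-text name from a FASTA record.

    UniProt pipe-delimited headers (``db|ACCESSION|ENTRY ...``) yield the
    second pipe field; plain headers yield the first whitespace token.
    """
    token = record.id
    if "|" in token:
        fields = token.split("|")
        if len(fields) >= 2 and fields[1]:
            accession = fields[1]
        else:
            accession = token
    else:
        accession = token
    description = record.description
    name = description.split(None, 1)[1] if len(description.split(None, 1)) > 1 else ""
    return accession, name


def read_fasta(path) -> VariantDatabase:
    """Read a FASTA file into a :class:`VariantDatabase`.

    Raises :class:`DatabaseError` on duplicate accessions, empty sequences or
    non-canonical residues (the error names the offending record).
    """
    entries: list[VariantEntry] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession, name = _parse_header(record)
        if accession in seen:
            raise DatabaseError(f"duplicate accession {accession}")
        seen.add(accession)
        entries.append(VariantEntry(accession, name, str(record.seq).upper()))
    return VariantDatabase(entries, provenance=f"read from {path}")


def write_fasta(db: VariantDatabase, path) -> None:
    """Write a database as FASTA with 60-column sequence wrapping."""
    with open(path, "w", encoding="utf-8") as handle:
        for entry in db:
            header = entry.accession if not entry.name else f"{entry.accession} {entry.name}"
            handle.write(f">{header}\n")
            for i in range(0, len(entry.sequence), 60):
                handle.write(entry.sequence[i:i + 60] + "\n")


def collapse_redundant(
    db: VariantDatabase,
    prefer: Sequence[str] = (),
) -> tuple[VariantDatabase, list[tuple[str, str]]]:
    """Collapse entries with 100% identical sequences to a single entry.

    The kept entry per sequence group is the first-seen one unless an
    accession from *prefer* is present in the group.  Returns the collapsed
    database and a removal report of ``(removed_accession, kept_accession)``
    pairs in input order.
    """
    preferred = list(prefer)
    groups: dict[str, list[VariantEntry]] = {}
    for entry in db:
        groups.setdefault(entry.sequence, []).append(entry)

    keeper: dict[str, VariantEntry] = {}
    for sequence, members in groups.items():
        chosen = members[0]
        for acc in preferred:
            hit = next((m for m in members if m.accession == acc), None)
            if hit is not None:
                chosen = hit
                break
        keeper[sequence] = chosen

    kept_entries = [e for e in db if keeper[e.sequence] is e]
    report = [(e.accession, keeper[e.sequence].accession)
              for e in db if keeper[e.sequence] is not e]
    collapsed = VariantDatabase(
        kept_entries,
        provenance=(db.provenance + "; collapsed redundant sequences").strip("; "),
    )
    return collapsed, report


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of two sequences under global alignment.

    Identity = 100 x identical aligned positions / alignment length
    (gap columns included).  BLOSUM62 scoring, gap open 10, gap extend 1.
    Symmetric in its arguments.
    """
    validate_sequence(a, "first sequence")
    validate_sequence(b, "second sequence")
    if a == b:
        return 100.0
    # canonical argument order guarantees exact symmetry under tied optima
    x, y = (a, b) if a <= b else (b, a)
    alignment = _ALIGNER.align(x, y)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


@dataclass
class IdentityMatrix:
    """Square matrix of pairwise percent identities."""

    accessions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accessions)
        if self.values.shape != (n, n):
            raise DatabaseError("identity matrix shape mismatch")

    def lookup(self, a: str, b: str) -> float:
        i = self.accessions.index(a)
        j = self.accessions.index(b)
        return float(self.values[i, j])

    def off_diagonal_range(self, accession: str) -> tuple[float, float]:
        """(min, max) identity of one entry against all others."""
        i = self.accessions.index(accession)
        row = np.delete(self.values[i], i)
        if row.size == 0:
            raise DatabaseError("no off-diagonal values in a 1-entry matrix")
        return float(row.min()), float(row.max())

    def to_rows(self) -> list[dict]:
        rows = []
        for i, acc in enumerate(self.accessions):
            row = {"accession": acc}
            row.update({other: round(float(self.values[i, j]), 1)
                        for j, other in enumerate(self.accessions)})
            rows.append(row)
        return rows


def identity_matrix(db: VariantDatabase) -> IdentityMatrix:
    """All pairwise identities of a database (symmetric, diagonal 100)."""
    if len(db) == 0:
        raise DatabaseError("cannot build identity matrix of empty database")
    n = len(db)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(db.entries[i].sequence,
                                      db.entries[j].sequence)
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(db.accessions, values)


RELATION_LABELS = ("identical", "variant", "isoallergen", "distinct")


def classify_relation(identity: float) -> str:
    """Relationship class for a percent identity.

    identical at 100; variant strictly above 90; isoallergen strictly above
    67; distinct at or below 67 (strict thresholds, so exactly 90 is an
    isoallergen and exactly 67 is distinct).
    """
    if not 0 <= identity <= 100:
        raise DatabaseError(f"identity {identity} outside [0, 100]")
    if identity == 100:
        return "identical"
    if identity > 90:
        return "variant"
    if identity > 67:
        return "isoallergen"
    return "distinct"


@dataclass
class PeptideCensus:
    """Which fully tryptic peptides occur in which database entries.

    ``members`` maps each peptide sequence to the sorted tuple of accessions
    containing it; ``specific`` lists, per accession, the peptides occurring
    in exactly that one entry (variant-specific peptides).
    """

    members: dict[str, tuple[str, ...]]
    specific: dict[str, list[str]]

    def shared_count(self, peptide: str) -> int:
        return len(self.members[peptide])

    def to_rows(self) -> list[dict]:
        rows = []
        for peptide in sorted(self.members):
            accs = self.members[peptide]
            rows.append({
                "peptide": peptide,
                "n_entries": len(accs),
                "accessions": ";".join(accs),
                "specific_to": accs[0] if len(accs) == 1 else "",
            })
        return rows


def peptide_census(db: VariantDatabase,
                   params: DigestionParams | None = None) -> PeptideCensus:
    """Census of shared and variant-specific tryptic peptides.

    Digests every entry with *params* and maps each peptide sequence to the
    set of entries whose digest contains it.  A peptide mapping to exactly
    one entry is variant-specific for that entry.
    """
    params = params or DigestionParams()
    members: dict[str, set[str]] = {}
    for entry in db:
        for pep in digest(entry.sequence, params, entry.accession):
            members.setdefault(pep.sequence, set()).add(entry.accession)
    sorted_members = {p: tuple(sorted(accs)) for p, accs in members.items()}
    specific: dict[str, list[str]] = {acc: [] for acc in db.accessions}
    for peptide, accs in sorted_members.items():
        if len(accs) == 1:
            specific[accs[0]].append(peptide)
    for acc in specific:
        specific[acc].sort()
    return PeptideCensus(sorted_members, specific)
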