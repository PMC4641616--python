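"""Peptide-spectrum-match tables: reading, validation, tier filtering and
mapping onto the variant database.

The TSV dialect emulates a search-engine export: UTF-8, one header row,
columns ``spot_id  peptide  tier  score  modifications  observed_mass
spectrum_id``.  Tier 1 marks pass-one matches (reliable enough to identify a
protein on their own); tier 2 marks pass-two matches (supplementary only).
Modifications use the syntax ``Oxidation(M)@3;Deamidation(N)@7``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .digestion import DigestionParams, MODIFICATIONS, digest, validate_sequence
from .variantdb import VariantDatabase


class PsmError(ValueError):
    """Raised for malformed PSM tables or records."""


_MOD_RE = re.compile(r"^(?P<name>[A-Za-z]+)\((?P<residue>[A-Z])\)@(?P<pos>\d+)$")

REQUIRED_COLUMNS = ("spot_id", "peptide", "tier", "score")
ALL_COLUMNS = ("spot_id", "peptide", "tier", "score",
               "modifications", "observed_mass", "spectrum_id")


@dataclass(frozen=True)
class PSM:
    """One peptide-level identification record."""

    spot_id: str
    peptide: str
    tier: int
    score: float
    modifications: tuple[tuple[str, int], ...] = ()
    observed_mass: float | None = None
    spectrum_id: str = ""

    def __post_init__(self) -> None:
        validate_sequence(self.peptide, "PSM peptide")
        if self.tier not in (1, 2):
            raise PsmError(f"tier must be 1 or 2, got {self.tier}")
        if self.score < 0:
            raise PsmError(f"score must be >= 0, got {self.score}")


@dataclass
class PsmTableMeta:
    """Provenance carried alongside a PSM table (never enforced)."""

    source: str = ""
    search_parameters: dict = field(default_factory=dict)


def parse_modifications(text: str, peptide: str) -> tuple[tuple[str, int], ...]:
    """Parse ``Name(Residue)@Pos;...`` into ``((name, pos), ...)``.

    Validates that each position carries the annotated residue and that the
    modification is known and targets that residue.
    """
    text = (text or "").strip()
    if not text:
        return ()
    mods = []
    for token in text.split(";"):
        token = token.strip()
        m = _MOD_RE.match(token)
        if m is None:
            raise PsmError(f"malformed modification token {token!r}")
        name = m.group("name").lower()
        residue = m.group("residue")
        pos = int(m.group("pos"))
        if name not in MODIFICATIONS:
            raise PsmError(f"unknown modification {m.group('name')!r}")
        if not 1 <= pos <= len(peptide):
            raise PsmError(
                f"modification position {pos} outside peptide {peptide!r}")
        if peptide[pos - 1] != residue:
            raise PsmError(
                f"modification {token!r} annotates residue {residue!r} but "
                f"peptide {peptide!r} has {peptide[pos - 1]!r} at position {pos}")
        if residue not in MODIFICATIONS[name].targets:
            raise PsmError(
                f"{m.group('name')} does not target residue {residue!r}")
        mods.append((name, pos))
    return tuple(mods)


def format_modifications(mods: Iterable[tuple[str, int]], peptide: str) -> str:
    return ";".join(
        f"{name.capitalize()}({peptide[pos - 1]})@{pos}" for name, pos in mods)


def read_psm_table(path) -> tuple[list[PSM], PsmTableMeta]:
    """Read and validate a PSM TSV table.

    Leading ``#`` comment lines are captured as provenance.  Hard errors
    (naming the data row) on missing required columns, invalid tier and
    inconsistent modification annotations.
    """
    comments = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if line.startswith("#"):
                comments.append(line[1:].strip())
            else:
                break
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                        keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise PsmError(f"missing required column(s): {', '.join(missing)}")
    psms: list[PSM] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        record = row._asdict()
        try:
            tier = int(record["tier"])
            if tier not in (1, 2):
                raise PsmError(f"tier must be 1 or 2, got {tier}")
            peptide = record["peptide"]
            mods = parse_modifications(record.get("modifications", ""), peptide)
            observed = record.get("observed_mass", "")
            psms.append(PSM(
                spot_id=record["spot_id"],
                peptide=peptide,
                tier=tier,
                score=float(record["score"]),
                modifications=mods,
                observed_mass=float(observed) if observed else None,
                spectrum_id=record.get("spectrum_id", ""),
            ))
        except (PsmError, ValueError) as exc:
            raise PsmError(f"row {row_number}: {exc}") from exc
    meta = PsmTableMeta(source=str(path),
                        search_parameters={"comments": comments})
    return psms, meta


def write_psm_table(psms: Sequence[PSM], path,
                    header_comments: Sequence[str] = ()) -> None:
    """Write PSMs in the canonical TSV dialect (round-trips losslessly)."""
    with open(path, "w", encoding="utf-8") as handle:
        for comment in header_comments:
            handle.write(f"# {comment}\n")
        handle.write("\t".join(ALL_COLUMNS) + "\n")
        for psm in psms:
            observed = (repr(psm.observed_mass)
                        if psm.observed_mass is not None else "")
            handle.write("\t".join([
                psm.spot_id, psm.peptide, str(psm.tier), repr(psm.score),
                format_modifications(psm.modifications, psm.peptide),
                observed, psm.spectrum_id,
            ]) + "\n")


def filter_pass_two(psms: Sequence[PSM]) -> list[PSM]:
    """Remove all pass-two (tier-2) matches, preserving order."""
    return [p for p in psms if p.tier == 1]


def group_by_spot(psms: Sequence[PSM]) -> dict[str, list[PSM]]:
    """Group PSMs by spot identifier, preserving first-seen spot order."""
    groups: dict[str, list[PSM]] = {}
    for psm in psms:
        groups.setdefault(psm.spot_id, []).append(psm)
    return groups


@dataclass
class IncidenceMatrix:
    """Boolean peptide x variant membership structure driving inference.

    Rows are distinct PSM peptide sequences (first-seen order); columns are
    database accessions.  A cell is true iff the peptide occurs in the fully
    tryptic digest of that variant.  ``psm_support`` maps each peptide row to
    its supporting PSMs; ``sequences`` retains the variant sequences so that
    downstream tie-breaking and coverage can be computed.
    """

    peptides: list[str]
    variants: list[str]
    membership: np.ndarray
    psm_support: dict[str, list[PSM]]
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.size == 0:
            self.membership = self.membership.reshape(
                len(self.peptides), len(self.variants))
        if self.membership.shape != (len(self.peptides), len(self.variants)):
            raise PsmError("incidence matrix shape mismatch")

    def peptide_set(self, accession: str) -> frozenset:
        j = self.variants.index(accession)
        return frozenset(p for i, p in enumerate(self.peptides)
                         if self.membership[i, j])

    def variants_of(self, peptide: str) -> frozenset:
        i = self.peptides.index(peptide)
        return frozenset(v for j, v in enumerate(self.variants)
                         if self.membership[i, j])

    def restrict(self, keep_variants: Sequence[str]) -> "IncidenceMatrix":
        """Sub-matrix keeping only the given variant columns (row set kept)."""
        keep = [v for v in self.variants if v in set(keep_variants)]
        cols = [self.variants.index(v) for v in keep]
        return IncidenceMatrix(
            peptides=list(self.peptides),
            variants=keep,
            membership=self.membership[:, cols] if cols else
            np.zeros((len(self.peptides), 0), dtype=bool),
            psm_support={p: list(s) for p, s in self.psm_support.items()},
            sequences={v: self.sequences[v] for v in keep if v in self.sequences},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.membership, index=self.peptides,
                            columns=self.variants)


@dataclass
class OrphanReport:
    """PSM peptides matching no database variant."""

    rows: list[dict]

    def peptides(self) -> list[str]:
        return [r["peptide"] for r in self.rows]


def _normalise(seq: str, il_equivalent: bool) -> str:
    return seq.replace("I", "L") if il_equivalent else seq


def build_incidence(
    psms: Sequence[PSM],
    db: VariantDatabase,
    params: DigestionParams | None = None,
    substring: bool = False,
    il_equivalent: bool = False,
) -> tuple[IncidenceMatrix, OrphanReport]:
    """Map distinct PSM peptides onto the variant database.

    Membership requires fully tryptic occurrence in the variant's digest
    (exact sequence equality; modifications never affect matching).  With
    ``substring=True`` a bare substring match suffices (fallback for
    non-tryptic exports).  With ``il_equivalent=True`` leucine and isoleucine
    are merged for matching.  Peptides matching no variant are returned in
    the orphan report rather than as matrix rows.
    """
    if len(db) == 0:
        raise PsmError("variant database is empty")
    params = params or DigestionParams()

    distinct: list[str] = []
    support: dict[str, list[PSM]] = {}
    for psm in psms:
        if psm.peptide not in support:
            distinct.append(psm.peptide)
            support[psm.peptide] = []
        support[psm.peptide].append(psm)

    digest_sets: dict[str, set[str]] = {}
    for entry in db:
        if substring:
            digest_sets[entry.accession] = set()
        else:
            digest_sets[entry.accession] = {
                _normalise(p.sequence, il_equivalent)
                for p in digest(entry.sequence, params, entry.accession)}

    matched_rows: list[str] = []
    cells: list[list[bool]] = []
    orphan_rows: list[dict] = []
    for peptide in distinct:
        probe = _normalise(peptide, il_equivalent)
        if substring:
            row = [probe in _normalise(e.sequence, il_equivalent) for e in db]
        else:
            row = [probe in digest_sets[e.accession] for e in db]
        if any(row):
            matched_rows.append(peptide)
            cells.append(row)
        else:
            spots = sorted({p.spot_id for p in support[peptide]})
            orphan_rows.append({"peptide": peptide,
                                "n_psms": len(support[peptide]),
                                "spot_ids": ";".join(spots)})

    matrix = IncidenceMatrix(
        peptides=matched_rows,
        variants=db.accessions,
        membership=np.array(cells, dtype=bool).reshape(len(matched_rows), len(db)),
        psm_support={p: support[p] for p in matched_rows},
        sequences=db.sequences(),
    )
    return matrix, OrphanReport(orphan_rows)
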