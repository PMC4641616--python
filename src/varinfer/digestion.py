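"""In silico tryptic digestion and peptide mass arithmetic.

Trypsin cleaves C-terminal to lysine (K) and arginine (R); by default the
Keil rule is applied, i.e. a K/R followed by proline (P) is not cleaved.
Peptides carry 1-based inclusive coordinates on their parent sequence and a
monoisotopic mass.  Modification handling covers the three modifications
relevant for standard alkylated tryptic digests: carbamidomethylation of
cysteine (fixed), deamidation of asparagine/glutamine and oxidation of
methionine (variable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic residue masses in Da (peptide-bond residues, i.e. minus water).
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MONOISOTOPIC = 18.010565


class DigestionError(ValueError):
    """Raised for invalid sequences or inconsistent modification assignments."""


@dataclass(frozen=True)
class ModificationSpec:
    """A post-translational or chemical modification.

    Parameters
    ----------
    name : str
        Lower-case modification name.
    targets : frozenset of str
        Residues the modification may occur on.
    mass_delta : float
        Monoisotopic mass shift in Da.
    fixed : bool
        Fixed modifications apply to every target residue; variable ones are
        sampled/observed per peptide.
    """

    name: str
    targets: frozenset
    mass_delta: float
    fixed: bool


MODIFICATIONS: dict[str, ModificationSpec] = {
    "carbamidomethyl": ModificationSpec(
        "carbamidomethyl", frozenset("C"), 57.02146, fixed=True),
    "deamidation": ModificationSpec(
        "deamidation", frozenset("NQ"), 0.98402, fixed=False),
    "oxidation": ModificationSpec(
        "oxidation", frozenset("M"), 15.99491, fixed=False),
}


@dataclass(frozen=True)
class DigestionParams:
    """Digestion settings; defaults mirror a standard one-missed-cleavage
    tryptic search."""

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 1
    min_length: int = 1
    proline_rule: bool = True
    strip_initial_met: bool = False

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise DigestionError(f"unsupported enzyme: {self.enzyme!r}")
        if self.max_missed_cleavages < 0:
            raise DigestionError("max_missed_cleavages must be >= 0")
        if self.min_length < 0:
            raise DigestionError("min_length must be >= 0")


@dataclass(frozen=True)
class Peptide:
    """A proteolytic fragment with parent coordinates (1-based inclusive)."""

    sequence: str
    parent_accession: str
    start: int
    end: int
    missed_cleavages: int
    monoisotopic_mass: float


def validate_sequence(sequence: str, context: str = "sequence") -> None:
    """Raise :class:`DigestionError` unless *sequence* is non-empty and uses
    only the 20 canonical residue letters."""
    if not sequence:
        raise DigestionError(f"{context} is empty")
    for pos, residue in enumerate(sequence, start=1):
        if residue not in CANONICAL_RESIDUES:
            raise DigestionError(
                f"{context} contains non-canonical residue "
                f"{residue!r} at position {pos}")


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """Tryptic cleavage sites as 0-based indices of the residue *after* the
    cut (i.e. the bond between sequence[i-1] and sequence[i])."""
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR" and not (proline_rule and sequence[i] == "P"):
            sites.append(i)
    return sites


def digest(sequence: str, params: DigestionParams | None = None,
           parent_accession: str = "") -> list[Peptide]:
    """Fully tryptic peptides of *sequence* with up to the configured number
    of missed cleavages.

    Returns peptides ordered by start position, then length.  Coordinates are
    1-based inclusive; ``missed_cleavages`` counts the internal cleavage
    sites a peptide spans.
    """
    params = params or DigestionParams()
    validate_sequence(sequence)
    if params.strip_initial_met and sequence.startswith("M") and len(sequence) > 1:
        return [
        Peptide(p.sequence, p.parent_accession, p.start + 1, p.end + 1,
                p.missed_cleavages, p.monoisotopic_mass)
        for p in digest(sequence[1:],
                        DigestionParams(params.enzyme,
                                        params.max_missed_cleavages,
                                        params.min_length,
                                        params.proline_rule,
                                        strip_initial_met=False),
                        parent_accession)
        ]
    sites = cleavage_sites(sequence, params.proline_rule)
    bounds = [0] + sites + [len(sequence)]
    peptides: list[Peptide] = []
    for i in range(len(bounds) - 1):
        for missed in range(params.max_missed_cleavages + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            pep = sequence[start:end]
            if len(pep) < params.min_length:
                continue
            peptides.append(Peptide(
                sequence=pep,
                parent_accession=parent_accession,
                start=start + 1,
                end=end,
                missed_cleavages=missed,
                monoisotopic_mass=peptide_mass(pep),
            ))
    peptides.sort(key=lambda p: (p.start, p.end - p.start))
    return peptides


def peptide_mass(sequence: str,
                 mods: Iterable[tuple[str, int]] = ()) -> float:
    """Monoisotopic mass of a peptide in Da.

    *mods* is an iterable of ``(modification name, 1-based position)`` pairs.
    The modification must target the residue actually present at that
    position, otherwise a :class:`DigestionError` is raised.
    """
    validate_sequence(sequence, "peptide")
    mass = WATER_MONOISOTOPIC + sum(
        MONOISOTOPIC_RESIDUE_MASS[r] for r in sequence)
    for name, pos in mods:
        key = name.lower()
        if key not in MODIFICATIONS:
            raise DigestionError(f"unknown modification {name!r}")
        spec = MODIFICATIONS[key]
        if not 1 <= pos <= len(sequence):
            raise DigestionError(
                f"modification position {pos} outside peptide of length "
                f"{len(sequence)}")
        residue = sequence[pos - 1]
        if residue not in spec.targets:
            raise DigestionError(
                f"{name} cannot modify residue {residue!r} at position {pos}")
        mass += spec.mass_delta
    return mass


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise DigestionError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def peptides_to_rows(peptides: Sequence[Peptide]) -> list[dict]:
    """Rows for the TSV peptide-list report."""
    return [
        {"accession": p.parent_accession, "start": p.start, "end": p.end,
         "sequence": p.sequence, "missed_cleavages": p.missed_cleavages,
         "mass": round(p.monoisotopic_mass, 5)}
        for p in peptides
    ]
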