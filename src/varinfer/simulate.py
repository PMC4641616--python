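"""Synthetic homologous variant families and ground-truth PSM tables.

The generator emulates the data situation the inference workflow targets: a
family of highly similar (67-99% identical) protein sequences of realistic
pollen-allergen size, a known mixture of truly present variants, and a
peptide-level identification table with per-peptide detection, tier-2
supplementary matches, score and ppm-error distributions and contaminant
records.  All randomness is driven by explicit seeds, so every table is
byte-identically reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .digestion import (CANONICAL_RESIDUES, DigestionParams, digest,
                        peptide_mass)
from .inference import InferenceResult
from .psm import PSM
from .variantdb import VariantDatabase, VariantEntry


class SimulationError(ValueError):
    """Raised for invalid simulation specifications."""


_ALPHABET = sorted(CANONICAL_RESIDUES)


@dataclass(frozen=True)
class FamilySpec:
    """Specification of a synthetic homologous protein family.

    ``base_length`` defaults to 160 residues (typical for a PR-10 pollen
    allergen); ``kr_frequency`` is the combined K+R proportion of the base
    sequence (default 0.11, yielding realistic tryptic peptide lengths);
    ``substitutions_per_variant`` is either one integer for all variants or
    a per-variant list.
    """

    n_variants: int
    substitutions_per_variant: int | Sequence[int] = 5
    base_length: int = 160
    kr_frequency: float = 0.11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise SimulationError("n_variants must be >= 1")
        if not 0 < self.kr_frequency < 1:
            raise SimulationError("kr_frequency must be in (0, 1)")
        for s in self.substitution_counts():
            if not 0 <= s < self.base_length:
                raise SimulationError(
                    "substitutions_per_variant must lie in [0, base_length)")

    def substitution_counts(self) -> list[int]:
        if isinstance(self.substitutions_per_variant, int):
            return [self.substitutions_per_variant] * self.n_variants
        counts = list(self.substitutions_per_variant)
        if len(counts) != self.n_variants:
            raise SimulationError(
                "substitutions_per_variant list length must equal n_variants")
        return counts


@dataclass(frozen=True)
class SimulationSpec:
    """Specification of a synthetic PSM table for one sample/spot.

    Detected peptides yield one PSM each (times ``replicates``); a detected
    peptide is downgraded to a tier-2 (pass-two) match with probability
    ``tier2_rate``.  Scores follow a log-normal law loosely spanning the
    score range of a typical search-engine export; observed masses carry a
    normal ppm error (sd 3 ppm, the scale of routinely reported mass
    accuracy).  ``contaminant_psm_rate`` is the expected (Poisson) count of
    PSMs whose peptides match no database variant.
    """

    true_variants: tuple[str, ...]
    detection_prob: float = 0.7
    tier2_rate: float = 0.1
    contaminant_psm_rate: float = 0.0
    score_log_mean: float = math.log(1000.0)
    score_log_sigma: float = 1.0
    ppm_sd: float = 3.0
    deamidation_rate: float = 0.05
    oxidation_rate: float = 0.05
    replicates: int = 1
    spot_id: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detection_prob", "tier2_rate", "deamidation_rate",
                     "oxidation_rate"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.contaminant_psm_rate < 0:
            raise SimulationError("contaminant_psm_rate must be >= 0")
        if self.replicates < 1:
            raise SimulationError("replicates must be >= 1")


@dataclass
class GroundTruth:
    """True variant sets per spot and per-PSM origins.

    ``origins`` is aligned with the emitted PSM list: each element is
    ``(origin_accession, is_contaminant)`` with ``origin_accession`` None
    for contaminants.
    """

    true_variants: dict[str, tuple[str, ...]]
    origins: list[tuple[str | None, bool]]


def make_family(spec: FamilySpec) -> tuple[VariantDatabase, list[dict]]:
    """Generate a family of point-substituted variants of a random base.

    Returns the database (accessions ``VAR01``, ``VAR02``, ...) and a
    mutation log of ``{accession, position, from, to}`` records (1-based
    positions).  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    kr = spec.kr_frequency
    probs = np.array([kr / 2 if r in "KR" else (1 - kr) / 18
                      for r in _ALPHABET])
    probs /= probs.sum()
    base = "".join(rng.choice(_ALPHABET, size=spec.base_length, p=probs))

    entries: list[VariantEntry] = []
    log: list[dict] = []
    width = max(2, len(str(spec.n_variants)))
    for k, n_subs in enumerate(spec.substitution_counts(), start=1):
        accession = f"VAR{k:0{width}d}"
        residues = list(base)
        positions = rng.choice(spec.base_length, size=n_subs, replace=False)
        for pos in sorted(int(p) for p in positions):
            original = residues[pos]
            choices = [r for r in _ALPHABET if r != original]
            replacement = str(rng.choice(choices))
            residues[pos] = replacement
            log.append({"accession": accession, "position": pos + 1,
                        "from": original, "to": replacement})
        entries.append(VariantEntry(
            accession, f"synthetic variant {k} ({n_subs} substitutions)",
            "".join(residues)))
    db = VariantDatabase(entries, provenance=f"synthetic family seed={spec.seed}")
    return db, log


def _random_contaminant(rng: np.random.Generator,
                        forbidden: set[str]) -> str:
    """A tryptic-looking random peptide matching no database digest."""
    for _ in range(1000):
        length = int(rng.integers(8, 16))
        body = "".join(rng.choice([r for r in _ALPHABET if r not in "KR"],
                                  size=length - 1))
        peptide = body + str(rng.choice(["K", "R"]))
        if peptide not in forbidden:
            return peptide
    raise SimulationError("could not draw a non-matching contaminant peptide")


def simulate_psms(
    db: VariantDatabase,
    spec: SimulationSpec,
    params: DigestionParams | None = None,
) -> tuple[list[PSM], GroundTruth]:
    """Simulate a PSM table for a known mixture of variants.

    Every digest peptide of every true variant is detected independently
    with ``detection_prob``; peptide sequences shared between true variants
    are sampled once per variant (duplicates across variants collapse at the
    incidence level exactly as in real data).  Deterministic given the seed.
    """
    params = params or DigestionParams()
    missing = [a for a in spec.true_variants
               if a not in set(db.accessions)]
    if missing:
        raise SimulationError(
            f"true variants not in database: {', '.join(missing)}")
    rng = np.random.default_rng(spec.seed)

    psms: list[PSM] = []
    origins: list[tuple[str | None, bool]] = []
    counter = 0
    for accession in spec.true_variants:
        entry = db.get(accession)
        for pep in digest(entry.sequence, params, accession):
            if rng.random() >= spec.detection_prob:
                continue
            for _ in range(spec.replicates):
                counter += 1
                mods: list[tuple[str, int]] = [
                    ("carbamidomethyl", i + 1)
                    for i, r in enumerate(pep.sequence) if r == "C"]
                nq = [i + 1 for i, r in enumerate(pep.sequence) if r in "NQ"]
                if nq and rng.random() < spec.deamidation_rate:
                    mods.append(("deamidation", int(rng.choice(nq))))
                mpos = [i + 1 for i, r in enumerate(pep.sequence) if r == "M"]
                if mpos and rng.random() < spec.oxidation_rate:
                    mods.append(("oxidation", int(rng.choice(mpos))))
                mods.sort(key=lambda m: m[1])
                theoretical = peptide_mass(pep.sequence, mods)
                ppm = rng.normal(0.0, spec.ppm_sd)
                observed = theoretical * (1.0 + ppm * 1e-6)
                tier = 2 if rng.random() < spec.tier2_rate else 1
                score = float(rng.lognormal(spec.score_log_mean,
                                            spec.score_log_sigma))
                psms.append(PSM(
                    spot_id=spec.spot_id,
                    peptide=pep.sequence,
                    tier=tier,
                    score=round(score, 2),
                    modifications=tuple(mods),
                    observed_mass=round(observed, 5),
                    spectrum_id=f"sim{counter:05d}",
                ))
                origins.append((accession, False))

    if spec.contaminant_psm_rate > 0:
        all_digest_peptides = {
            p.sequence for e in db for p in digest(e.sequence, params)}
        n_contaminants = int(rng.poisson(spec.contaminant_psm_rate))
        for _ in range(n_contaminants):
            counter += 1
            peptide = _random_contaminant(rng, all_digest_peptides)
            theoretical = peptide_mass(peptide)
            observed = theoretical * (1.0 + rng.normal(0.0, spec.ppm_sd) * 1e-6)
            tier = 2 if rng.random() < spec.tier2_rate else 1
            psms.append(PSM(
                spot_id=spec.spot_id,
                peptide=peptide,
                tier=tier,
                score=round(float(rng.lognormal(spec.score_log_mean,
                                                spec.score_log_sigma)), 2),
                modifications=(),
                observed_mass=round(observed, 5),
                spectrum_id=f"sim{counter:05d}",
            ))
            origins.append((None, True))

    truth = GroundTruth(
        true_variants={spec.spot_id: tuple(spec.true_variants)},
        origins=origins,
    )
    return psms, truth


def random_incidence_matrix(
    rng: np.random.Generator,
    max_variants: int = 10,
    max_peptides: int = 15,
    density: float = 0.3,
):
    """A random peptide x variant incidence matrix for oracle validation.

    Dimensions are drawn uniformly (2..max), each membership cell is true
    with probability *density*, and every peptide row carries one tier-1
    supporting PSM with a random score.  Used to compare greedy parsimony
    against the exhaustive minimum-cover oracle.
    """
    from .psm import IncidenceMatrix

    n_variants = int(rng.integers(2, max_variants + 1))
    n_peptides = int(rng.integers(2, max_peptides + 1))
    membership = rng.random((n_peptides, n_variants)) < density
    peptides = [f"p{i + 1}" for i in range(n_peptides)]
    variants = [f"V{j + 1}" for j in range(n_variants)]
    support = {
        p: [PSM(spot_id="S1", peptide="GK", tier=1,
                score=float(np.round(rng.random() * 100, 3)))]
        for p in peptides
    }
    return IncidenceMatrix(peptides, variants, membership, support)


def evaluate_recovery(result: InferenceResult, truth: GroundTruth,
                      spot_id: str = "S1") -> tuple[float, float]:
    """Precision and recall of the selected variant set against the truth.

    Precision is 1.0 for an empty selection (no false positives); recall is
    1.0 when the true set is empty.
    """
    if spot_id not in truth.true_variants:
        raise SimulationError(f"spot {spot_id!r} not in ground truth")
    selected = set(result.accessions)
    true = set(truth.true_variants[spot_id])
    hit = len(selected & true)
    precision = hit / len(selected) if selected else 1.0
    recall = hit / len(true) if true else 1.0
    return precision, recall
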