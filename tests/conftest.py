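import numpy as np
import pytest

from varinfer import (DigestionParams, PSM, VariantDatabase, VariantEntry,
                      build_incidence)

# Worked example structure: five identified peptides; entry A contains all
# five (including the N-terminal one), entry B the four non-N-terminal ones,
# entry C only the last.
FIG_PEPTIDES = ("AAAK", "CCDK", "EEFK", "GGHK", "IIMK")


@pytest.fixture
def worked_example_db() -> VariantDatabase:
    p1, p2, p3, p4, p5 = FIG_PEPTIDES
    return VariantDatabase([
        VariantEntry("A", "full-length entry", p1 + p2 + p3 + p4 + p5),
        VariantEntry("B", "N-terminally incomplete entry", "WK" + p2 + p3 + p4 + p5),
        VariantEntry("C", "fragment entry", "YK" + p5),
    ])


@pytest.fixture
def worked_example_psms() -> list[PSM]:
    return [PSM(spot_id="28", peptide=p, tier=1, score=500.0 + i,
                spectrum_id=f"sp{i}")
            for i, p in enumerate(FIG_PEPTIDES, start=1)]


@pytest.fixture
def worked_example_incidence(worked_example_db, worked_example_psms):
    matrix, orphans = build_incidence(worked_example_psms, worked_example_db,
                                      DigestionParams(max_missed_cleavages=1))
    assert not orphans.rows
    return matrix


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def random_protein(rng: np.random.Generator, length: int = 60,
                   kr: float = 0.15) -> str:
    alphabet = sorted("ACDEFGHIKLMNPQRSTVWY")
    probs = np.array([kr / 2 if r in "KR" else (1 - kr) / 18
                      for r in alphabet])
    probs /= probs.sum()
    return "".join(rng.choice(alphabet, size=length, p=probs))
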