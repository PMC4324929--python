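import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hmconf import (
    TorsionRecord,
    build_conformer,
    builtin_sequences,
    get_sequence,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hm_sequences():
    return builtin_sequences()


@pytest.fixture(scope="session")
def hm_a1():
    return get_sequence("HM A-1")


@pytest.fixture(scope="session")
def hm_a2():
    return get_sequence("HM A-2")


def make_torsions(seq, phi, psi, omega=180.0, chi1=-60.0):
    """Uniform backbone torsions for every residue (Ψ undefined at the end)."""
    n = len(seq)
    return [
        TorsionRecord(
            residue_index=i,
            phi=phi,
            psi=psi if i < n else None,
            omega=omega if i < n else None,
            chi1=chi1 if seq.residue(i).chi1_defined else None,
        )
        for i in range(1, n + 1)
    ]


def random_torsions(seq, rng):
    n = len(seq)
    return [
        TorsionRecord(
            residue_index=i,
            phi=float(rng.uniform(-180.0, 180.0)),
            psi=float(rng.uniform(-180.0, 180.0)) if i < n else None,
            omega=float(rng.uniform(-180.0, 180.0)) if i < n else None,
            chi1=float(rng.uniform(-180.0, 180.0))
            if seq.residue(i).chi1_defined
            else None,
        )
        for i in range(1, n + 1)
    ]


@pytest.fixture(scope="session")
def ideal_310_conformer(hm_a1):
    """All residues at the 3_10 window centre (Φ=-60°, Ψ=-30°)."""
    return build_conformer(hm_a1, make_torsions(hm_a1, -60.0, -30.0))


@pytest.fixture(scope="session")
def extended_conformer(hm_a1):
    return build_conformer(hm_a1, make_torsions(hm_a1, 180.0, 180.0))
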