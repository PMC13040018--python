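"""Shared fixtures: all structural test inputs are generated in-process."""

from pathlib import Path

import numpy as np
import pytest

from epifab import (
    CdrMap,
    KineticParams,
    make_groove_complex,
    make_hairpin,
)

EPITOPE_SEQUENCE = "ACGADSYEMEEDGVRKCK"  # EGFR 286-303 cystine-loop peptide
STRUCTURES_DIR = Path(__file__).resolve().parents[1] / "data" / "structures"


@pytest.fixture(scope="session")
def hairpin():
    return make_hairpin(EPITOPE_SEQUENCE, start_resnum=286, seed=0)


@pytest.fixture(scope="session")
def groove():
    """(complex, manifest) for the docked-peptide groove scene."""
    hp = make_hairpin(EPITOPE_SEQUENCE, start_resnum=286, seed=0)
    return make_groove_complex(hp, groove_gap=4.0, seed=0)


@pytest.fixture(scope="session")
def cdr_map():
    return CdrMap({
        "heavy": [("H1", (26, 35)), ("H2", (50, 58)), ("H3", (95, 105))],
        "light": [("L1", (24, 34)), ("L2", (50, 56)), ("L3", (89, 97))],
    })


@pytest.fixture(scope="session")
def a10_params():
    """Rate constants of the best-binding humanized candidate (A10 row of
    the packaged kinetics table)."""
    return KineticParams(ka=2.44e5, kd=6.16e-4, rmax=100.0)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation via QR with sign fix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
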