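import numpy as np
import pytest

from methylflex.prmtop import read_prmtop
from methylflex.synth.duplex import DuplexBuildSpec, build_ideal_duplex
from methylflex.synth.fixtures import make_prmtop_fixture

AT_CASE_SEQUENCE = "CGCGCATATACGCGC"  # 15-mer with central ATATA block


@pytest.fixture(scope="session")
def thymine_top():
    return read_prmtop(make_prmtop_fixture("thymine"))


@pytest.fixture(scope="session")
def ta_top():
    return read_prmtop(make_prmtop_fixture("ta-dinucleotide"))


@pytest.fixture(scope="session")
def ta_solvated_top():
    return read_prmtop(make_prmtop_fixture("ta-solvated"))


@pytest.fixture(scope="session")
def at_duplex():
    return build_ideal_duplex(DuplexBuildSpec(AT_CASE_SEQUENCE))


def independent_torsion(p1, p2, p3, p4):
    """Second, independently written torsion formula (Gram-Schmidt frame)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b = p3 - p2
    b = b / np.linalg.norm(b)
    v = (p1 - p2) - np.dot(p1 - p2, b) * b
    w = (p4 - p3) - np.dot(p4 - p3, b) * b
    x = np.dot(v, w)
    y = np.dot(np.cross(b, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def raw_lj_energy(top, i, j, r):
    """Brute-force 12-6 evaluation straight from the raw sections."""
    n = top.pointers["NTYPES"]
    ti = top.sections["ATOM_TYPE_INDEX"].data[i]
    tj = top.sections["ATOM_TYPE_INDEX"].data[j]
    k = top.sections["NONBONDED_PARM_INDEX"].data[n * (ti - 1) + (tj - 1)]
    a = top.sections["LENNARD_JONES_ACOEF"].data[k - 1]
    b = top.sections["LENNARD_JONES_BCOEF"].data[k - 1]
    return a / r**12 - b / r**6
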