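"""Self-consistent parm7 fixtures for topology-masking tests.

A small catalog of hand-parameterized nucleic-acid fragments (single
thymine nucleoside, ApT dinucleotide, solvated ApT) is emitted as valid
prmtop text with every mandatory section, a declared total charge, and
Lorentz-Berthelot combined Lennard-Jones tables.  Charges and LJ well
depths are force-field-plausible but synthetic; the point is structural
self-consistency (pointer counts, exclusion lists, type tables), not
reproduction of any published parameter set.
"""

from __future__ import annotations

import math
from collections import defaultdict

from ..prmtop import (FortranFormat, Section, Topology, write_prmtop)

__all__ = ["make_prmtop_fixture", "FIXTURE_CATALOG"]

# LJ types: name -> (Rmin/2 Angstrom, epsilon kcal/mol)
_LJ = {
    "CT": (1.9080, 0.1094), "C": (1.9080, 0.0860), "CM": (1.9080, 0.0860),
    "CA": (1.9080, 0.0860), "CB": (1.9080, 0.0860), "CK": (1.9080, 0.0860),
    "CQ": (1.9080, 0.0860),
    "N*": (1.8240, 0.1700), "NA": (1.8240, 0.1700), "NB": (1.8240, 0.1700),
    "NC": (1.8240, 0.1700), "N2": (1.8240, 0.1700),
    "O": (1.6612, 0.2100), "O2": (1.6612, 0.2100), "OH": (1.7210, 0.2104),
    "OS": (1.6837, 0.1700),
    "H1": (1.3870, 0.0157), "HC": (1.4870, 0.0157), "H4": (1.4090, 0.0150),
    "H5": (1.3590, 0.0150), "H": (0.6000, 0.0157), "HO": (0.0001, 0.0000),
    "P": (2.1000, 0.2000), "OW": (1.7683, 0.1520), "HW": (0.0001, 0.0000),
}

_ELEMENT_Z = {"C": 6, "H": 1, "N": 7, "O": 8, "P": 15}
_ELEMENT_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999,
                 "P": 30.973762}


def _atom(name, lj, q):
    elem = "P" if name == "P" else name.lstrip("0123456789")[0]
    return (name, lj, q, elem)


# sugar fragments (charges approximate a bsc1-style deoxyribose)
_SUGAR_CORE = [
    _atom("C5'", "CT", -0.0069), _atom("H5'", "H1", 0.0754),
    _atom("H5''", "H1", 0.0754),
    _atom("C4'", "CT", 0.1629), _atom("H4'", "H1", 0.1176),
    _atom("O4'", "OS", -0.3691),
    _atom("C1'", "CT", 0.0680), _atom("H1'", "H1", 0.1804),
    _atom("C3'", "CT", 0.0713), _atom("H3'", "H1", 0.0985),
    _atom("C2'", "CT", -0.0854), _atom("H2'", "HC", 0.0718),
    _atom("H2''", "HC", 0.0718),
]
_SUGAR_BONDS = [
    ("C5'", "H5'"), ("C5'", "H5''"), ("C5'", "C4'"), ("C4'", "H4'"),
    ("C4'", "O4'"), ("C4'", "C3'"), ("O4'", "C1'"), ("C1'", "H1'"),
    ("C1'", "C2'"), ("C2'", "H2'"), ("C2'", "H2''"), ("C2'", "C3'"),
    ("C3'", "H3'"), ("C3'", "O3'"),
]

_THYMINE_BASE = [
    _atom("N1", "N*", -0.0239), _atom("C6", "CM", -0.2209),
    _atom("H6", "H4", 0.2607), _atom("C5", "CM", 0.0025),
    _atom("C7", "CT", -0.2269), _atom("H71", "HC", 0.0770),
    _atom("H72", "HC", 0.0770), _atom("H73", "HC", 0.0770),
    _atom("C4", "C", 0.5194), _atom("O4", "O", -0.5563),
    _atom("N3", "NA", -0.4340), _atom("H3", "H", 0.3420),
    _atom("C2", "C", 0.5677), _atom("O2", "O", -0.5881),
]
_THYMINE_BONDS = [
    ("C1'", "N1"), ("N1", "C6"), ("C6", "H6"), ("C6", "C5"), ("C5", "C7"),
    ("C7", "H71"), ("C7", "H72"), ("C7", "H73"), ("C5", "C4"), ("C4", "O4"),
    ("C4", "N3"), ("N3", "H3"), ("N3", "C2"), ("C2", "O2"), ("C2", "N1"),
]

_ADENINE_BASE = [
    _atom("N9", "N*", -0.0268), _atom("C8", "CK", 0.1607),
    _atom("H8", "H5", 0.1877), _atom("N7", "NB", -0.6175),
    _atom("C5", "CB", 0.0725), _atom("C6", "CA", 0.6897),
    _atom("N6", "N2", -0.9123), _atom("H61", "H", 0.4167),
    _atom("H62", "H", 0.4167), _atom("N1", "NC", -0.7624),
    _atom("C2", "CQ", 0.5716), _atom("H2", "H5", 0.0598),
    _atom("N3", "NC", -0.7417), _atom("C4", "CB", 0.3800),
]
_ADENINE_BONDS = [
    ("C1'", "N9"), ("N9", "C8"), ("C8", "H8"), ("C8", "N7"), ("N7", "C5"),
    ("C5", "C6"), ("C6", "N6"), ("N6", "H61"), ("N6", "H62"), ("C6", "N1"),
    ("N1", "C2"), ("C2", "H2"), ("C2", "N3"), ("N3", "C4"), ("C4", "N9"),
    ("C4", "C5"),
]

_HO5_CAP = [_atom("HO5'", "HO", 0.4422), _atom("O5'", "OH", -0.6318)]
_PHOSPHATE = [
    _atom("P", "P", 1.1659), _atom("OP1", "O2", -0.7761),
    _atom("OP2", "O2", -0.7761), _atom("O5'", "OS", -0.4954),
]
_O3_INTERNAL = [_atom("O3'", "OS", -0.5232)]
_O3_CAP = [_atom("O3'", "OH", -0.6549), _atom("HO3'", "HO", 0.4396)]

_WATER = [_atom("O", "OW", -0.8340), _atom("H1", "HW", 0.4170),
          _atom("H2", "HW", 0.4170)]
_WATER_BONDS = [("O", "H1"), ("O", "H2")]


def _residue(label, five_prime, base, three_prime):
    cap5 = _HO5_CAP if five_prime == "oh" else _PHOSPHATE
    cap3 = _O3_CAP if three_prime == "oh" else _O3_INTERNAL
    base_atoms, base_bonds = ((_THYMINE_BASE, _THYMINE_BONDS)
                              if base == "T" else
                              (_ADENINE_BASE, _ADENINE_BONDS))
    atoms = cap5 + _SUGAR_CORE + cap3 + base_atoms
    bonds = list(_SUGAR_BONDS) + list(base_bonds)
    bonds.append(("O5'", "C5'"))
    if five_prime == "oh":
        bonds.append(("HO5'", "O5'"))
    else:
        bonds += [("P", "OP1"), ("P", "OP2"), ("P", "O5'")]
    if three_prime == "oh":
        bonds.append(("O3'", "HO3'"))
    return label, atoms, bonds


def _catalog():
    thy = [_residue("DT", "oh", "T", "oh")]
    ta = [_residue("DA", "oh", "A", "p3"), _residue("DT", "p5", "T", "oh")]
    wat = ("WAT", _WATER, _WATER_BONDS)
    return {
        "thymine": {"residues": thy, "total_charge": 0.0},
        "ta-dinucleotide": {"residues": ta, "total_charge": -1.0},
        "ta-solvated": {"residues": ta + [wat] * 3, "total_charge": -1.0},
    }


#: kind -> {"total_charge": declared total charge in e}
FIXTURE_CATALOG = {k: {"total_charge": v["total_charge"]}
                   for k, v in _catalog().items()}


def _bond_graph(bonds, natom):
    adj = defaultdict(set)
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _exclusions(bonds, natom):
    """1-2, 1-3 and 1-4 exclusion lists in Amber layout (1-based, j > i)."""
    adj = _bond_graph(bonds, natom)
    counts, flat = [], []
    for i in range(natom):
        near = set()
        for j in adj[i]:
            near.add(j)
            for k in adj[j]:
                near.add(k)
                near.update(adj[k])
        near.discard(i)
        excl = sorted(j + 1 for j in near if j > i)
        if not excl:
            counts.append(1)
            flat.append(0)
        else:
            counts.append(len(excl))
            flat.extend(excl)
    return counts, flat


def make_prmtop_fixture(kind: str) -> str:
    """Emit the named fixture from the catalog as parm7 text."""
    cat = _catalog()
    if kind not in cat:
        raise KeyError(
            f"unknown fixture kind {kind!r}; available: {sorted(cat)}")
    entry = cat[kind]

    atom_names, type_names, charges, elements = [], [], [], []
    res_labels, res_pointers = [], []
    bonds = []  # 0-based atom index pairs
    prev_o3 = None
    for label, atoms, res_bonds in entry["residues"]:
        offset = len(atom_names)
        res_labels.append(label)
        res_pointers.append(offset + 1)
        local = {}
        for name, lj, q, elem in atoms:
            local[name] = len(atom_names)
            atom_names.append(name)
            type_names.append(lj)
            charges.append(q)
            elements.append(elem)
        for a, b in res_bonds:
            bonds.append((local[a], local[b]))
        if "P" in local and prev_o3 is not None:
            bonds.append((prev_o3, local["P"]))
        prev_o3 = local.get("O3'") if label != "WAT" else prev_o3

    natom = len(atom_names)
    # absorb the template-rounding residual into the first C4' so the
    # total charge matches the declared catalog value exactly
    residual = sum(charges) - entry["total_charge"]
    c4 = atom_names.index("C4'") if "C4'" in atom_names else 0
    charges[c4] -= residual

    lj_names = sorted(set(type_names))
    ntypes = len(lj_names)
    type_index = [lj_names.index(t) + 1 for t in type_names]
    acoef, bcoef, nbidx = [], [], [0] * (ntypes * ntypes)
    for j in range(1, ntypes + 1):
        for i in range(1, j + 1):
            ri, ei = _LJ[lj_names[i - 1]]
            rj, ej = _LJ[lj_names[j - 1]]
            rmin, eps = ri + rj, math.sqrt(ei * ej)
            acoef.append(eps * rmin**12)
            bcoef.append(2.0 * eps * rmin**6)
            k = i + j * (j - 1) // 2
            nbidx[ntypes * (i - 1) + (j - 1)] = k
            nbidx[ntypes * (j - 1) + (i - 1)] = k

    with_h = [(i, j) for i, j in bonds
              if elements[i] == "H" or elements[j] == "H"]
    without_h = [(i, j) for i, j in bonds if (i, j) not in set(with_h)]
    counts, flat = _exclusions(bonds, natom)

    pointers = [0] * 31
    pointers[0] = natom
    pointers[1] = ntypes
    pointers[2] = len(with_h)      # NBONH
    pointers[3] = len(without_h)   # MBONA
    pointers[10] = len(flat)       # NNB
    pointers[11] = len(res_labels)
    pointers[12] = len(without_h)  # NBONA
    pointers[15] = 1               # NUMBND (one generic bond type)
    pointers[18] = ntypes          # NATYP
    pointers[28] = max(
        (res_pointers[i + 1] if i + 1 < len(res_pointers) else natom + 1)
        - res_pointers[i] for i in range(len(res_pointers)))  # NMXRS

    def bond_records(pairs):
        out = []
        for i, j in pairs:
            out.extend([3 * i, 3 * j, 1])
        return out

    i10 = FortranFormat.parse("10I8")
    e5 = FortranFormat.parse("5E16.8")
    a20 = FortranFormat.parse("20a4")

    sections = {}

    def add(flag, fmt, data, comments=()):
        sections[flag] = Section(flag, fmt, list(data), list(comments))

    add("TITLE", a20, [f"synthetic fixture: {kind}"])
    add("POINTERS", i10, pointers)
    add("ATOM_NAME", a20, atom_names)
    add("CHARGE", e5, [q * 18.2223 for q in charges])
    add("ATOMIC_NUMBER", i10, [_ELEMENT_Z[e] for e in elements])
    add("MASS", e5, [_ELEMENT_MASS[e] for e in elements])
    add("ATOM_TYPE_INDEX", i10, type_index)
    add("NUMBER_EXCLUDED_ATOMS", i10, counts)
    add("NONBONDED_PARM_INDEX", i10, nbidx)
    add("RESIDUE_LABEL", a20, res_labels)
    add("RESIDUE_POINTER", i10, res_pointers)
    add("BOND_FORCE_CONSTANT", e5, [300.0])
    add("BOND_EQUIL_VALUE", e5, [1.5])
    add("ANGLE_FORCE_CONSTANT", e5, [])
    add("ANGLE_EQUIL_VALUE", e5, [])
    add("DIHEDRAL_FORCE_CONSTANT", e5, [])
    add("DIHEDRAL_PERIODICITY", e5, [])
    add("DIHEDRAL_PHASE", e5, [])
    add("SCEE_SCALE_FACTOR", e5, [])
    add("SCNB_SCALE_FACTOR", e5, [])
    add("SOLTY", e5, [0.0] * ntypes)
    add("LENNARD_JONES_ACOEF", e5, acoef)
    add("LENNARD_JONES_BCOEF", e5, bcoef)
    add("BONDS_INC_HYDROGEN", i10, bond_records(with_h))
    add("BONDS_WITHOUT_HYDROGEN", i10, bond_records(without_h))
    add("ANGLES_INC_HYDROGEN", i10, [])
    add("ANGLES_WITHOUT_HYDROGEN", i10, [])
    add("DIHEDRALS_INC_HYDROGEN", i10, [])
    add("DIHEDRALS_WITHOUT_HYDROGEN", i10, [])
    add("EXCLUDED_ATOMS_LIST", i10, flat)
    add("HBOND_ACOEF", e5, [])
    add("HBOND_BCOEF", e5, [])
    add("HBCUT", e5, [])
    add("AMBER_ATOM_TYPE", a20, type_names)
    add("TREE_CHAIN_CLASSIFICATION", a20, ["BLA"] * natom)
    add("JOIN_ARRAY", i10, [0] * natom)
    add("IROTAT", i10, [0] * natom)

    top = Topology("VERSION_STAMP = V0001.000  DATE = 01/01/00  00:00:00",
                   sections)
    return write_prmtop(top)
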