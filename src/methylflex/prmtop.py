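"""Reading, validating, writing and diffing Amber prmtop (parm7) topologies.

The parm7 dialect is a sequence of ``%FLAG <NAME>`` sections, each carrying a
Fortran ``%FORMAT(...)`` descriptor followed by fixed-width data records.  The
parser keeps every section — including ones it does not interpret — so that a
read/write round trip is semantically lossless; bonded-term tables are carried
opaquely and never evaluated.  Charges are exposed in elementary-charge units
(the file stores them multiplied by 18.2223); Lennard-Jones parameters are
exposed both as raw A/B coefficients and as (R_min, epsilon) pairs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .constants import AMBER_CHARGE_SCALE

__all__ = [
    "PrmtopError",
    "FortranFormat",
    "Section",
    "Topology",
    "read_prmtop",
    "write_prmtop",
    "validate_topology",
    "diff_topologies",
    "lj_pair_energy",
]

#: Names of the POINTERS entries, in file order (31 mandatory + IFBOX extras).
POINTER_NAMES = [
    "NATOM", "NTYPES", "NBONH", "MBONA", "NTHETH", "MTHETA", "NPHIH",
    "MPHIA", "NHPARM", "NPARM", "NNB", "NRES", "NBONA", "NTHETA", "NPHIA",
    "NUMBND", "NUMANG", "NPTRA", "NATYP", "NPHB", "IFPERT", "NBPER",
    "NGPER", "NDPER", "MBPER", "MGPER", "MDPER", "IFBOX", "NMXRS", "IFCAP",
    "NUMEXTRA",
]

#: Sections every self-consistent topology must carry.
MANDATORY_SECTIONS = [
    "POINTERS", "ATOM_NAME", "CHARGE", "MASS", "ATOM_TYPE_INDEX",
    "NUMBER_EXCLUDED_ATOMS", "NONBONDED_PARM_INDEX", "RESIDUE_LABEL",
    "RESIDUE_POINTER", "LENNARD_JONES_ACOEF", "LENNARD_JONES_BCOEF",
    "EXCLUDED_ATOMS_LIST", "AMBER_ATOM_TYPE",
]


class PrmtopError(ValueError):
    """Raised for malformed or inconsistent parm7 content."""


_FMT_RE = re.compile(r"^\s*(\d+)\s*([aAiIeEfF])\s*(\d+)(?:\.(\d+))?\s*$")


@dataclass(frozen=True)
class FortranFormat:
    """A simple Fortran edit descriptor like 10I8, 5E16.8 or 20a4."""

    count: int
    kind: str  # 'a', 'I', 'E' or 'F'
    width: int
    decimals: int = 0

    @classmethod
    def parse(cls, text: str) -> "FortranFormat":
        m = _FMT_RE.match(text)
        if m is None:
            raise PrmtopError(f"unsupported FORMAT descriptor: {text!r}")
        kind = m.group(2).upper()
        kind = "a" if kind == "A" else kind
        return cls(int(m.group(1)), kind, int(m.group(3)),
                   int(m.group(4) or 0))

    def __str__(self) -> str:
        if self.kind in ("E", "F"):
            return f"{self.count}{self.kind}{self.width}.{self.decimals}"
        return f"{self.count}{self.kind}{self.width}"

    def parse_values(self, lines: list[str], flag: str) -> list:
        values: list = []
        for line in lines:
            if self.kind == "a":
                for start in range(0, len(line.rstrip("\n")), self.width):
                    values.append(line[start:start + self.width].strip())
            else:
                for token in line.split():
                    try:
                        if self.kind == "I":
                            values.append(int(token))
                        else:
                            values.append(float(token.replace("D", "E")))
                    except ValueError as exc:
                        raise PrmtopError(
                            f"section {flag}: cannot parse {token!r}") from exc
        return values

    def format_value(self, value) -> str:
        if self.kind == "a":
            return f"{str(value):<{self.width}}"
        if self.kind == "I":
            return f"{int(value):>{self.width}d}"
        if self.kind == "E":
            return f"{value:>{self.width}.{self.decimals}E}"
        return f"{value:>{self.width}.{self.decimals}f}"

    def format_values(self, values) -> list[str]:
        lines = []
        for start in range(0, len(values), self.count):
            chunk = values[start:start + self.count]
            lines.append("".join(self.format_value(v) for v in chunk))
        if not lines:
            lines = [""]
        return lines


@dataclass
class Section:
    flag: str
    fmt: FortranFormat
    data: list
    comments: list[str] = field(default_factory=list)

    def copy(self) -> "Section":
        return Section(self.flag, self.fmt, list(self.data),
                       list(self.comments))


@dataclass
class Topology:
    """An Amber parm7 topology held as an ordered set of sections.

    Semantic accessors interpret the handful of sections the masking
    machinery needs; everything else rides along untouched.
    """

    version: str
    sections: dict[str, Section]

    # -- pointer block ----------------------------------------------------
    @property
    def pointers(self) -> dict[str, int]:
        vals = self.sections["POINTERS"].data
        return {name: vals[i] for i, name in enumerate(POINTER_NAMES)
                if i < len(vals)}

    def _pointer(self, name: str) -> int:
        return self.pointers[name]

    @property
    def natom(self) -> int:
        return self._pointer("NATOM")

    @property
    def ntypes(self) -> int:
        return self._pointer("NTYPES")

    @property
    def nres(self) -> int:
        return self._pointer("NRES")

    def set_pointer(self, name: str, value: int) -> None:
        idx = POINTER_NAMES.index(name)
        self.sections["POINTERS"].data[idx] = int(value)

    # -- atoms and residues -----------------------------------------------
    @property
    def atom_names(self) -> list[str]:
        return list(self.sections["ATOM_NAME"].data)

    @property
    def residue_labels(self) -> list[str]:
        return list(self.sections["RESIDUE_LABEL"].data)

    @property
    def residue_pointers(self) -> list[int]:
        return list(self.sections["RESIDUE_POINTER"].data)

    def residue_of_atom(self) -> np.ndarray:
        """1-based residue number for every atom."""
        starts = np.asarray(self.residue_pointers, dtype=int)
        out = np.zeros(self.natom, dtype=int)
        bounds = np.append(starts, self.natom + 1)
        for r in range(len(starts)):
            out[bounds[r] - 1:bounds[r + 1] - 1] = r + 1
        return out

    def select_atoms(self, atom_names, residue_numbers=None,
                     residue_labels=None) -> np.ndarray:
        """0-based indices of atoms matching name and residue filters."""
        names = np.asarray(self.atom_names)
        res_of = self.residue_of_atom()
        labels = np.asarray(self.residue_labels)
        mask = np.isin(names, list(atom_names))
        if residue_numbers is not None:
            mask &= np.isin(res_of, list(residue_numbers))
        if residue_labels is not None:
            mask &= np.isin(labels[res_of - 1], list(residue_labels))
        return np.flatnonzero(mask)

    # -- charges ----------------------------------------------------------
    @property
    def charges(self) -> np.ndarray:
        """Partial charges in elementary-charge units."""
        return np.asarray(self.sections["CHARGE"].data) / AMBER_CHARGE_SCALE

    @charges.setter
    def charges(self, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.natom,):
            raise PrmtopError(
                f"charge array must have length NATOM={self.natom}")
        self.sections["CHARGE"].data = list(values * AMBER_CHARGE_SCALE)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    # -- Lennard-Jones tables ----------------------------------------------
    @property
    def atom_type_indices(self) -> np.ndarray:
        """1-based LJ type index per atom."""
        return np.asarray(self.sections["ATOM_TYPE_INDEX"].data, dtype=int)

    def lj_pair_coefficients(self, type_i: int, type_j: int):
        """Raw (A, B) 12-6 coefficients for a 1-based type pair."""
        n = self.ntypes
        nb = self.sections["NONBONDED_PARM_INDEX"].data
        idx = nb[n * (type_i - 1) + (type_j - 1)]
        if idx < 0:
            raise PrmtopError("10-12 hydrogen-bond pair types are not supported")
        a = self.sections["LENNARD_JONES_ACOEF"].data[idx - 1]
        b = self.sections["LENNARD_JONES_BCOEF"].data[idx - 1]
        return float(a), float(b)

    def lj_pair_rmin_eps(self, type_i: int, type_j: int):
        """(R_min_ij Angstrom, epsilon_ij kcal/mol); (0, 0) for a null pair."""
        a, b = self.lj_pair_coefficients(type_i, type_j)
        if a == 0.0 or b == 0.0:
            return 0.0, 0.0
        rmin = (2.0 * a / b) ** (1.0 / 6.0)
        eps = b * b / (4.0 * a)
        return rmin, eps

    def copy(self) -> "Topology":
        return Topology(self.version,
                        {k: s.copy() for k, s in self.sections.items()})


# ---------------------------------------------------------------------------
# parsing / writing


def read_prmtop(text: str, strict: bool = True) -> Topology:
    """Parse parm7 text into a :class:`Topology`.

    With ``strict`` (default) the parsed topology is validated and any
    finding raises :class:`PrmtopError` naming the offending section.
    """
    lines = text.splitlines()
    version = ""
    sections: dict[str, Section] = {}
    i = 0
    current: Section | None = None
    body: list[str] = []

    def close_current():
        nonlocal current, body
        if current is not None:
            current.data = current.fmt.parse_values(
                [l for l in body if l.strip() != "" or current.fmt.kind == "a"],
                current.flag)
            sections[current.flag] = current
        current, body = None, []

    while i < len(lines):
        line = lines[i]
        if line.startswith("%VERSION"):
            version = line[len("%VERSION"):].strip()
        elif line.startswith("%FLAG"):
            close_current()
            flag = line[len("%FLAG"):].strip()
            comments = []
            i += 1
            while i < len(lines) and lines[i].startswith("%COMMENT"):
                comments.append(lines[i][len("%COMMENT"):].strip())
                i += 1
            if i >= len(lines) or not lines[i].startswith("%FORMAT"):
                raise PrmtopError(
                    f"section {flag}: missing %FORMAT descriptor "
                    f"(line {i + 1})")
            fmt_text = lines[i].strip()
            m = re.match(r"%FORMAT\((.*)\)", fmt_text)
            if m is None:
                raise PrmtopError(
                    f"section {flag}: malformed FORMAT {fmt_text!r} "
                    f"(line {i + 1})")
            current = Section(flag, FortranFormat.parse(m.group(1)), [],
                              comments)
        elif current is not None:
            body.append(line)
        i += 1
    close_current()

    if "POINTERS" not in sections:
        raise PrmtopError("missing mandatory section POINTERS")
    top = Topology(version or "VERSION_STAMP = V0001.000", sections)
    if strict:
        findings = validate_topology(top)
        if findings:
            raise PrmtopError("; ".join(findings))
    return top


def write_prmtop(top: Topology) -> str:
    """Emit parm7 text; refuses a topology that fails validation."""
    findings = validate_topology(top)
    if findings:
        raise PrmtopError("refusing to write invalid topology: "
                          + "; ".join(findings))
    out = [f"%VERSION {top.version}"]
    for sec in top.sections.values():
        out.append(f"%FLAG {sec.flag}")
        for c in sec.comments:
            out.append(f"%COMMENT {c}")
        out.append(f"%FORMAT({sec.fmt})")
        out.extend(sec.fmt.format_values(sec.data))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# validation / diff


def validate_topology(top: Topology) -> list[str]:
    """Return a list of invariant violations; empty iff the topology is valid."""
    findings: list[str] = []
    for name in MANDATORY_SECTIONS:
        if name not in top.sections:
            findings.append(f"missing mandatory section {name}")
    if findings:
        return findings

    ptr = top.pointers
    natom, ntypes, nres = ptr["NATOM"], ptr["NTYPES"], ptr["NRES"]
    expected_lengths = {
        "ATOM_NAME": natom,
        "CHARGE": natom,
        "MASS": natom,
        "ATOM_TYPE_INDEX": natom,
        "NUMBER_EXCLUDED_ATOMS": natom,
        "AMBER_ATOM_TYPE": natom,
        "RESIDUE_LABEL": nres,
        "RESIDUE_POINTER": nres,
        "NONBONDED_PARM_INDEX": ntypes * ntypes,
        "LENNARD_JONES_ACOEF": ntypes * (ntypes + 1) // 2,
        "LENNARD_JONES_BCOEF": ntypes * (ntypes + 1) // 2,
        "EXCLUDED_ATOMS_LIST": max(ptr["NNB"], 0),
    }
    for name, expected in expected_lengths.items():
        actual = len(top.sections[name].data)
        if actual != expected:
            findings.append(
                f"section {name}: pointer mismatch, expected {expected} "
                f"entries, found {actual}")

    ati = top.sections["ATOM_TYPE_INDEX"].data
    if ati and (min(ati) < 1 or max(ati) > ntypes):
        findings.append(
            f"section ATOM_TYPE_INDEX: type index out of range 1..{ntypes}")

    nb = top.sections["NONBONDED_PARM_INDEX"].data
    ncoef = len(top.sections["LENNARD_JONES_ACOEF"].data)
    if any(abs(v) > ncoef or v == 0 for v in nb) if nb else False:
        findings.append(
            "section NONBONDED_PARM_INDEX: coefficient index out of range "
            f"1..{ncoef}")
    if len(nb) == ntypes * ntypes:
        for i in range(ntypes):
            for j in range(i + 1, ntypes):
                if nb[ntypes * i + j] != nb[ntypes * j + i]:
                    findings.append(
                        "section NONBONDED_PARM_INDEX: asymmetric entry for "
                        f"type pair ({i + 1},{j + 1})")
                    break

    for name in ("CHARGE", "MASS", "LENNARD_JONES_ACOEF",
                 "LENNARD_JONES_BCOEF"):
        vals = top.sections[name].data
        if any(not math.isfinite(v) for v in vals):
            findings.append(f"section {name}: non-finite parameter")
    return findings


@dataclass
class TopologyDiff:
    """Per-section change report between two topologies."""

    entries: dict[str, list]

    @property
    def is_empty(self) -> bool:
        return not self.entries

    def changed_sections(self) -> list[str]:
        return sorted(self.entries)

    def n_changed(self, section: str) -> int:
        return len(self.entries.get(section, []))

    def summary(self) -> str:
        if self.is_empty:
            return "topologies are identical"
        lines = []
        for name in self.changed_sections():
            lines.append(f"{name}: {len(self.entries[name])} changed entries")
        return "\n".join(lines)


def diff_topologies(a: Topology, b: Topology) -> TopologyDiff:
    """Entry-level diff; charges are compared in elementary-charge units."""
    if a.natom != b.natom:
        raise PrmtopError(
            f"atom-count mismatch: {a.natom} vs {b.natom}")
    entries: dict[str, list] = {}
    qa, qb = a.charges, b.charges
    charge_changes = [(int(i), float(qa[i]), float(qb[i]))
                      for i in np.flatnonzero(~np.isclose(qa, qb, atol=1e-10))]
    if charge_changes:
        entries["CHARGE"] = charge_changes

    for flag in sorted(set(a.sections) | set(b.sections)):
        if flag == "CHARGE":
            continue
        sa = a.sections.get(flag)
        sb = b.sections.get(flag)
        if sa is None or sb is None:
            entries[flag] = [("section", "absent" if sa is None else "present",
                              "present" if sb is not None else "absent")]
            continue
        if len(sa.data) != len(sb.data):
            entries[flag] = [("length", len(sa.data), len(sb.data))]
            continue
        changed = []
        for i, (va, vb) in enumerate(zip(sa.data, sb.data)):
            same = (math.isclose(va, vb, rel_tol=0, abs_tol=1e-12)
                    if isinstance(va, float) and isinstance(vb, float)
                    else va == vb)
            if not same:
                changed.append((i, va, vb))
        if changed:
            entries[flag] = changed
    return TopologyDiff(entries)


# ---------------------------------------------------------------------------
# brute-force pairwise energy (oracle-grade, independent of the editor)


def lj_pair_energy(top: Topology, i: int, j: int, r: float) -> float:
    """12-6 energy (kcal/mol) of one atom pair at separation r Angstrom.

    Evaluated directly from the topology's coefficient tables,
    eps*[(Rmin/r)^12 - 2(Rmin/r)^6] = A/r^12 - B/r^6.
    """
    if r <= 0:
        raise ValueError("separation must be positive")
    ti = int(top.atom_type_indices[i])
    tj = int(top.atom_type_indices[j])
    a, b = top.lj_pair_coefficients(ti, tj)
    return a / r**12 - b / r**6
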