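"""Selective masking of methyl-group non-bonded interactions in a topology.

The editing technique mirrors comparative force-field variation studies of
DNA methylation: the partial charges of a pyrimidine C5-methyl group
(C7, H71, H72, H73) are removed and redistributed onto adjacent base atoms
so that the total molecular charge is conserved, and the pairwise
Lennard-Jones interaction between the methyl group and a chosen partner
group (all water molecules, the C2' atom and its hydrogens of the
5'-neighboring sugar, or the 5'-neighboring base) is set to exactly zero.

Pairwise vdW zeroing is implemented by atom-type splitting: methyl and
partner atoms receive fresh LJ types that duplicate their originals in
every pair coefficient except the methyl-partner cross terms, which are
nulled.  Because 1-4 scaled interactions draw on the same type-pair
tables, masked 1-4 vdW terms vanish as well; bonded terms are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .prmtop import PrmtopError, Topology

__all__ = ["MaskSpec", "MaskError", "apply_mask", "resolve_selections",
            "balanced_redistribution"]

#: Default methyl-group atom names (thymine / 5-methylcytosine numbering).
METHYL_ATOMS = ("C7", "H71", "H72", "H73")

#: Residue labels recognised as water for the all-water partner group.
WATER_RESIDUES = ("WAT", "HOH")

#: Default partner atom names for the 5'-sugar C2' group.
SUGAR_C2_ATOMS = ("C2'", "H2'", "H2''")

#: Sugar/backbone atom names; base atoms are everything else in a nucleotide.
BACKBONE_SUGAR_ATOMS = frozenset({
    "P", "OP1", "OP2", "O1P", "O2P", "O5'", "C5'", "H5'", "H5''", "C4'",
    "H4'", "O4'", "C1'", "H1'", "C2'", "H2'", "H2''", "C3'", "H3'", "O3'",
    "HO3'", "HO5'", "H5T", "H3T",
})


class MaskError(PrmtopError):
    """Raised when a mask specification cannot be applied."""


@dataclass
class MaskSpec:
    """What to mask and how.

    ``partner`` selects the partner group: ``"water"`` (all water
    molecules), ``"sugar-c2"`` (C2' + H2'/H2'' of the 5'-neighboring
    residue of every methyl-bearing residue) or ``"base"`` (base atoms of
    the 5' neighbor).  ``redistribution`` maps atom names (within each
    methyl-bearing residue) to charge increments in elementary-charge
    units; its per-residue sum must balance the removed methyl charge.
    """

    methyl_atoms: tuple[str, ...] = METHYL_ATOMS
    methyl_residues: tuple[str, ...] = ("DT", "T", "5CM", "DC5", "C5M")
    partner: str = "sugar-c2"
    zero_charges: bool = False
    redistribution: dict[str, float] = field(default_factory=dict)
    zero_pair_vdw: bool = True
    water_residues: tuple[str, ...] = WATER_RESIDUES
    sugar_c2_atoms: tuple[str, ...] = SUGAR_C2_ATOMS

    @classmethod
    def water(cls, **kw) -> "MaskSpec":
        return cls(partner="water", **kw)

    @classmethod
    def sugar_c2(cls, **kw) -> "MaskSpec":
        return cls(partner="sugar-c2", **kw)

    @classmethod
    def neighbor_base(cls, **kw) -> "MaskSpec":
        return cls(partner="base", **kw)


def _methyl_residue_numbers(top: Topology, spec: MaskSpec) -> list[int]:
    labels = top.residue_labels
    res_of = top.residue_of_atom()
    names = np.asarray(top.atom_names)
    out = []
    for r in range(1, top.nres + 1):
        if labels[r - 1] not in spec.methyl_residues:
            continue
        in_res = names[res_of == r]
        if all(a in in_res for a in spec.methyl_atoms):
            out.append(r)
    return out


def resolve_selections(top: Topology, spec: MaskSpec):
    """Resolve a MaskSpec to 0-based (methyl, partner) atom index arrays."""
    methyl_res = _methyl_residue_numbers(top, spec)
    methyl_idx = top.select_atoms(spec.methyl_atoms,
                                  residue_numbers=methyl_res)
    if methyl_idx.size == 0:
        raise MaskError("methyl selection resolved to zero atoms")

    if spec.partner == "water":
        labels = np.asarray(top.residue_labels)
        water_res = [r for r in range(1, top.nres + 1)
                     if labels[r - 1] in spec.water_residues]
        partner_idx = top.select_atoms(set(top.atom_names),
                                       residue_numbers=water_res)
    elif spec.partner in ("sugar-c2", "base"):
        neighbors = [r - 1 for r in methyl_res if r >= 2]
        if spec.partner == "sugar-c2":
            partner_idx = top.select_atoms(spec.sugar_c2_atoms,
                                           residue_numbers=neighbors)
        else:
            names = np.asarray(top.atom_names)
            res_of = top.residue_of_atom()
            mask = np.isin(res_of, neighbors) & ~np.isin(
                names, list(BACKBONE_SUGAR_ATOMS))
            partner_idx = np.flatnonzero(mask)
    else:
        raise MaskError(f"unknown partner group {spec.partner!r}")

    if partner_idx.size == 0:
        raise MaskError(
            f"partner selection {spec.partner!r} resolved to zero atoms")
    if np.intersect1d(methyl_idx, partner_idx).size:
        raise MaskError("methyl and partner selections overlap")
    return methyl_idx, partner_idx


def balanced_redistribution(top: Topology, spec: MaskSpec,
                            targets=("C5",)) -> dict[str, float]:
    """Build a redistribution map that exactly balances the methyl charge.

    The removed per-residue methyl charge is split equally over the named
    target atoms.  Methyl-bearing residues are assumed charge-equivalent
    (true for any topology built from per-residue templates).
    """
    methyl_res = _methyl_residue_numbers(top, spec)
    if not methyl_res:
        raise MaskError("no methyl-bearing residues found")
    q = top.charges
    idx = top.select_atoms(spec.methyl_atoms,
                           residue_numbers=[methyl_res[0]])
    removed = float(q[idx].sum())
    return {name: removed / len(targets) for name in targets}


def _split_types_zero_cross(top: Topology, methyl_idx, partner_idx,
                            log: list[str]) -> None:
    """Give methyl/partner atoms fresh LJ types and null their cross terms."""
    n = top.ntypes
    ati = top.atom_type_indices
    acoef = top.sections["LENNARD_JONES_ACOEF"].data
    bcoef = top.sections["LENNARD_JONES_BCOEF"].data
    nbidx = top.sections["NONBONDED_PARM_INDEX"].data

    def pair_coef(i: int, j: int):
        k = nbidx[n * (i - 1) + (j - 1)]
        if k < 0:
            raise MaskError("10-12 hydrogen-bond pair types are not supported")
        return acoef[k - 1], bcoef[k - 1]

    # already masked (idempotent re-application): nothing to do
    if all(pair_coef(int(ati[i]), int(ati[j])) == (0.0, 0.0)
           for i in methyl_idx for j in partner_idx):
        log.append("vdW cross terms already zero; type tables unchanged")
        return

    methyl_types = sorted({int(ati[i]) for i in methyl_idx})
    partner_types = sorted({int(ati[i]) for i in partner_idx})
    new_of_methyl = {t: n + 1 + k for k, t in enumerate(methyl_types)}
    new_of_partner = {t: n + 1 + len(methyl_types) + k
                      for k, t in enumerate(partner_types)}
    n_new = n + len(methyl_types) + len(partner_types)
    origin = {t: t for t in range(1, n + 1)}
    origin.update({v: k for k, v in new_of_methyl.items()})
    origin.update({v: k for k, v in new_of_partner.items()})
    methyl_new = set(new_of_methyl.values())
    partner_new = set(new_of_partner.values())

    new_acoef, new_bcoef = [], []
    new_nbidx = [0] * (n_new * n_new)
    # canonical Amber triangular layout: pair (i<=j) -> i + j(j-1)/2, 1-based
    for j in range(1, n_new + 1):
        for i in range(1, j + 1):
            masked = ((i in methyl_new and j in partner_new)
                      or (i in partner_new and j in methyl_new))
            if masked:
                a, b = 0.0, 0.0
            else:
                a, b = pair_coef(origin[i], origin[j])
            new_acoef.append(a)
            new_bcoef.append(b)
            k = i + j * (j - 1) // 2
            new_nbidx[n_new * (i - 1) + (j - 1)] = k
            new_nbidx[n_new * (j - 1) + (i - 1)] = k

    new_ati = ati.copy()
    for i in methyl_idx:
        new_ati[i] = new_of_methyl[int(ati[i])]
    for i in partner_idx:
        new_ati[i] = new_of_partner[int(ati[i])]

    top.sections["ATOM_TYPE_INDEX"].data = [int(v) for v in new_ati]
    top.sections["NONBONDED_PARM_INDEX"].data = new_nbidx
    top.sections["LENNARD_JONES_ACOEF"].data = new_acoef
    top.sections["LENNARD_JONES_BCOEF"].data = new_bcoef
    top.set_pointer("NTYPES", n_new)
    log.append(
        f"split {len(methyl_types)} methyl and {len(partner_types)} partner "
        f"LJ types ({n} -> {n_new}); zeroed "
        f"{len(methyl_types) * len(partner_types)} cross coefficient pairs")


def apply_mask(top: Topology, spec: MaskSpec,
               log: list[str] | None = None) -> Topology:
    """Return a new topology with the requested interactions masked.

    Charge removal conserves the total molecular charge to 1e-6 e; vdW
    masking changes no pair coefficient other than the methyl-partner
    cross terms.  Applying the same spec twice is a no-op the second time.
    """
    log = log if log is not None else []
    methyl_idx, partner_idx = resolve_selections(top, spec)
    out = top.copy()

    if spec.zero_charges:
        q = out.charges
        res_of = out.residue_of_atom()
        names = np.asarray(out.atom_names)
        methyl_res = sorted({int(res_of[i]) for i in methyl_idx})
        removed_total = float(q[methyl_idx].sum())
        if abs(removed_total) < 1e-12 and spec.redistribution:
            log.append("methyl charges already zero; charge edit skipped")
        else:
            increment_total = sum(spec.redistribution.values()) * len(methyl_res)
            if abs(removed_total - increment_total) > 1e-6:
                raise MaskError(
                    "unbalanced redistribution map: removes "
                    f"{removed_total:.8f} e but adds {increment_total:.8f} e")
            q[methyl_idx] = 0.0
            for r in methyl_res:
                for name, dq in spec.redistribution.items():
                    tgt = np.flatnonzero((res_of == r) & (names == name))
                    if tgt.size != 1:
                        raise MaskError(
                            f"redistribution target {name!r} resolves to "
                            f"{tgt.size} atoms in residue {r}")
                    q[tgt[0]] += dq
            out.charges = q
            log.append(
                f"zeroed charges on {methyl_idx.size} methyl atoms; "
                f"redistributed {removed_total:+.6f} e over "
                f"{sorted(spec.redistribution)} in {len(methyl_res)} residues")

    if spec.zero_pair_vdw:
        _split_types_zero_cross(out, methyl_idx, partner_idx, log)

    return out
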