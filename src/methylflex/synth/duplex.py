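"""Idealized all-atom B-DNA duplex builder and Cartesian noise generator.

Bases are planar templates expressed in a base-fixed standard frame (the
same templates the helical-parameter fitter uses, so builder/measure
closure is exact for the rigid-body step parameters).  Each nucleotide
carries a deoxyribose built at a prescribed pseudorotation phase
(C2'-endo by default) and a 5'-phosphate placed by fiber-B-like backbone
torsions; the backbone torsion set is calibrated once so that the
emergent epsilon/zeta fall in the canonical BI basin.  Base pairs are
stacked by per-step twist/rise about the global z axis; strand II is the
complementary template flipped 180 deg about x, which makes the two
strands antiparallel and chemically equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

try:  # biotite is the PDB I/O backend; templates work without it
    import biotite.structure as bst
except ImportError:  # pragma: no cover
    bst = None

from ..geom3d import place_atom, rotation_about_axis, torsion
from ..geometry import pucker_phase, ring_torsions

__all__ = ["DuplexBuildSpec", "BackboneGeometry", "build_ideal_duplex",
           "perturb_ensemble", "base_ring_atoms", "base_template",
           "WC_COMPLEMENT"]

#: Watson-Crick complement; M is 5-methylcytosine and pairs as cytosine.
WC_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A", "M": "G"}

RESIDUE_NAMES = {"A": "DA", "T": "DT", "G": "DG", "C": "DC", "U": "DU",
                 "M": "5CM"}

_PURINES = frozenset("AG")

# base-fixed standard frame anchors shared by all bases
_C1P = np.array([-2.477, 5.402, 0.0])
_GLYC_N = np.array([-1.291, 4.498, 0.0])

# planar ring geometries in the standard frame (idealized; z = 0)
_PURINE_RING = {
    "N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
    "C5": (0.071, 2.771), "C4": (-1.291, 3.121), "N3": (-2.342, 2.364),
    "C2": (-1.985, 1.087), "N1": (-0.700, 0.641), "C6": (0.424, 1.388),
}
_PYRIMIDINE_RING = {
    "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "N3": (-0.391, 2.344),
    "C4": (0.837, 2.868), "C5": (1.056, 4.275), "C6": (-0.023, 5.068),
}

# ring-bond neighbors used to aim in-plane exocyclic substituents
_RING_NEIGHBORS = {
    "pur": {"C2": ("N1", "N3"), "C6": ("N1", "C5"), "C8": ("N7", "N9"),
            "N1": ("C2", "C6")},
    "pyr": {"C2": ("N1", "N3"), "C4": ("N3", "C5"), "C5": ("C4", "C6"),
            "C6": ("C5", "N1"), "N3": ("C2", "C4")},
}

# per-base exocyclic atoms: (name, ring anchor, bond length) placed on the
# exterior bisector; amino/methyl hydrogens handled separately
_EXOCYCLIC = {
    "A": [("N6", "C6", 1.34), ("H2", "C2", 1.08), ("H8", "C8", 1.08)],
    "G": [("O6", "C6", 1.23), ("N2", "C2", 1.34), ("H1", "N1", 1.03),
          ("H8", "C8", 1.08)],
    "T": [("O2", "C2", 1.22), ("O4", "C4", 1.23), ("H3", "N3", 1.03),
          ("C7", "C5", 1.50), ("H6", "C6", 1.08)],
    "U": [("O2", "C2", 1.22), ("O4", "C4", 1.23), ("H3", "N3", 1.03),
          ("H5", "C5", 1.08), ("H6", "C6", 1.08)],
    "C": [("O2", "C2", 1.22), ("N4", "C4", 1.34), ("H5", "C5", 1.08),
          ("H6", "C6", 1.08)],
    "M": [("O2", "C2", 1.22), ("N4", "C4", 1.34), ("C7", "C5", 1.50),
          ("H6", "C6", 1.08)],
}
_AMINO_H = {"A": ("N6", "C6"), "G": ("N2", "C2"), "C": ("N4", "C4"),
            "M": ("N4", "C4")}


def base_ring_atoms(code: str) -> list[str]:
    """Ring atom names used for reference-frame fitting."""
    return list(_PURINE_RING if code in _PURINES else _PYRIMIDINE_RING)


def _exterior(ring: dict, anchor: str, nb: tuple[str, str],
              bond: float) -> np.ndarray:
    x = ring[anchor]
    d = 2 * x - ring[nb[0]] - ring[nb[1]]
    return x + bond * d / np.linalg.norm(d)


def base_template(code: str) -> dict[str, np.ndarray]:
    """All base atoms (plus C1') of one nucleobase in the standard frame."""
    if code not in WC_COMPLEMENT:
        raise ValueError(f"unknown residue token {code!r}")
    kind = "pur" if code in _PURINES else "pyr"
    ring2d = _PURINE_RING if kind == "pur" else _PYRIMIDINE_RING
    atoms = {k: np.array([v[0], v[1], 0.0]) for k, v in ring2d.items()}
    nbs = _RING_NEIGHBORS[kind]
    for name, anchor, bond in _EXOCYCLIC[code]:
        atoms[name] = _exterior(atoms, anchor, nbs[anchor], bond)
    if code in _AMINO_H:
        n, c = _AMINO_H[code]
        suffix = "1" if n != "N2" else "2"
        ref = atoms[nbs[c][0]]
        for i, dih in enumerate((0.0, 180.0)):
            atoms[f"H{n[1]}{i + 1}"] = place_atom(
                ref, atoms[c], atoms[n], 1.01, 120.0, dih)
    if code in ("T", "M"):  # methyl hydrogens, staggered about C5-C7
        for i, dih in enumerate((180.0, 60.0, -60.0)):
            atoms[f"H7{i + 1}"] = place_atom(
                atoms["C4"], atoms["C5"], atoms["C7"], 1.09, 110.0, dih)
    atoms["C1'"] = _C1P.copy()
    return atoms


@dataclass(frozen=True)
class BackboneGeometry:
    """Sugar and backbone internal coordinates of the nucleotide template.

    Torsions in degrees; the defaults are a fiber-B-like set calibrated
    once so an idealized duplex lands in the BI basin (epsilon - zeta < 0)
    with a closed O3'-P junction.
    """

    chi: float = -67.478        # O4'-C1'-N glycosidic torsion
    gamma: float = 29.738       # O5'-C5'-C4'-C3'
    beta: float = 141.633       # P-O5'-C5'-C4'
    alpha_offset: float = -65.0  # phosphate oxygen placement about P-O5'
    delta: float = 93.899       # C5'-C4'-C3'-O3'
    c5_torsion: float = -37.924  # C5'-C4'-C3'-C2'
    pucker_phase_deg: float = 162.0  # Altona-Sundaralingam target
    pucker_q: float = 0.38      # Cremer-Pople puckering amplitude, Angstrom

    @classmethod
    def preset(cls, name: str) -> "BackboneGeometry":
        presets = {
            "c2'-endo": cls(),
            "c3'-endo": cls(pucker_phase_deg=18.0),
        }
        if name not in presets:
            raise ValueError(f"unknown backbone preset {name!r}")
        return presets[name]


from functools import lru_cache


@lru_cache(maxsize=32)
def _ring_local_cached(phase_target: float, q: float):
    ring = _ring_local_solve(phase_target, q)
    return tuple((k, tuple(v)) for k, v in ring.items())


def _ring_local(phase_target: float, q: float) -> dict[str, np.ndarray]:
    return {k: np.array(v) for k, v in _ring_local_cached(phase_target, q)}


def _ring_local_solve(phase_target: float, q: float) -> dict[str, np.ndarray]:
    """Closed furanose ring at the requested AS phase (CP construction).

    Ring order (O4', C1', C2', C3', C4') on a planar pentagon with
    out-of-plane displacements z_j ~ q cos(phi + 4 pi j / 5); phi is
    solved so the measured Altona-Sundaralingam phase hits the target.
    """
    order = ["O4'", "C1'", "C2'", "C3'", "C4'"]
    radius = 1.53 / (2.0 * np.sin(np.pi / 5.0))

    def coords_for(phi):
        ring = {}
        for j, name in enumerate(order):
            th = 2.0 * np.pi * j / 5.0
            z = np.sqrt(0.4) * q * np.cos(phi + 4.0 * np.pi * j / 5.0)
            ring[name] = np.array([radius * np.cos(th),
                                   radius * np.sin(th), z])
        return ring

    def phase_of(phi):
        ring = coords_for(phi)
        p, _ = pucker_phase(ring_torsions(lambda a: ring[a]))
        return p

    # the measured phase is phi plus a constant convention offset
    phis = np.linspace(0.0, 2.0 * np.pi, 721)
    errs = [abs((phase_of(f) - phase_target + 180.0) % 360.0 - 180.0)
            for f in phis]
    phi0 = phis[int(np.argmin(errs))]
    # refine by golden-section-free local scan
    fine = np.linspace(phi0 - 0.01, phi0 + 0.01, 201)
    errs = [abs((phase_of(f) - phase_target + 180.0) % 360.0 - 180.0)
            for f in fine]
    return coords_for(fine[int(np.argmin(errs))])


def _tetra_one(center, n1, n2, n3, bond):
    d = 3 * center - n1 - n2 - n3
    return center + bond * d / np.linalg.norm(d)


def _tetra_two(center, n1, n2, bond):
    """Two substituents completing a tetrahedral center with two neighbors."""
    u1 = (n1 - center) / np.linalg.norm(n1 - center)
    u2 = (n2 - center) / np.linalg.norm(n2 - center)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    half = np.radians(109.47 / 2.0)
    d1 = np.cos(half) * bis + np.sin(half) * perp
    d2 = np.cos(half) * bis - np.sin(half) * perp
    return center + bond * d1, center + bond * d2


def nucleotide_template(code: str, bb: BackboneGeometry,
                        five_prime: bool = False,
                        three_prime: bool = False) -> dict[str, np.ndarray]:
    """Full nucleotide (base + sugar + backbone) in the base-fixed frame.

    Non-terminal residues carry a 5'-phosphate (P, OP1, OP2); the
    5'-terminus is capped with HO5' and the 3'-terminus with HO3'.
    """
    atoms = base_template(code)
    glyc = "N9" if code in _PURINES else "N1"
    cnb = "C4" if code in _PURINES else "C2"

    ring = _ring_local(bb.pucker_phase_deg, bb.pucker_q)
    # attach the glycosidic nitrogen to the local ring (placement torsion is
    # arbitrary: the axial rotation below sets chi exactly)
    n_local = place_atom(ring["C4'"], ring["O4'"], ring["C1'"],
                         1.475, 108.2, 120.0)

    # rigid placement: C1'_local -> template C1', N_local -> glycosidic N
    v_loc = n_local - ring["C1'"]
    v_tgt = atoms[glyc] - atoms["C1'"]
    axis = np.cross(v_loc, v_tgt)
    if np.linalg.norm(axis) < 1e-10:
        R0 = np.eye(3)
    else:
        ang = np.degrees(np.arccos(np.clip(
            np.dot(v_loc, v_tgt)
            / (np.linalg.norm(v_loc) * np.linalg.norm(v_tgt)), -1, 1)))
        R0 = rotation_about_axis(axis, ang)
    placed = {k: R0 @ (v - ring["C1'"]) + atoms["C1'"]
              for k, v in ring.items()}
    # remaining degree of freedom: rotation about the C1'-N axis sets chi
    chi_now = torsion(placed["O4'"], atoms["C1'"], atoms[glyc], atoms[cnb])
    R1 = rotation_about_axis(v_tgt, -(bb.chi - chi_now))
    for k in placed:
        placed[k] = R1 @ (placed[k] - atoms["C1'"]) + atoms["C1'"]
    placed["C1'"] = atoms["C1'"]
    atoms.update(placed)

    # backbone heavy atoms by internal coordinates
    atoms["C5'"] = place_atom(atoms["C2'"], atoms["C3'"], atoms["C4'"],
                              1.51, 115.0, bb.c5_torsion)
    atoms["O3'"] = place_atom(atoms["C5'"], atoms["C4'"], atoms["C3'"],
                              1.42, 110.0, bb.delta)
    atoms["O5'"] = place_atom(atoms["C3'"], atoms["C4'"], atoms["C5'"],
                              1.44, 110.0, bb.gamma)
    if five_prime:
        atoms["HO5'"] = place_atom(atoms["C4'"], atoms["C5'"], atoms["O5'"],
                                   0.96, 108.0, 180.0)
    else:
        atoms["P"] = place_atom(atoms["C4'"], atoms["C5'"], atoms["O5'"],
                                1.59, 119.0, bb.beta)
        for name, off in (("OP1", 120.0), ("OP2", -120.0)):
            atoms[name] = place_atom(atoms["C5'"], atoms["O5'"], atoms["P"],
                                     1.48, 108.0, bb.alpha_offset + off)
    if three_prime:
        atoms["HO3'"] = place_atom(atoms["C4'"], atoms["C3'"], atoms["O3'"],
                                   0.96, 108.0, 180.0)

    # sugar hydrogens by tetrahedral completion
    atoms["H1'"] = _tetra_one(atoms["C1'"], atoms["O4'"], atoms["C2'"],
                              atoms[glyc], 1.09)
    atoms["H3'"] = _tetra_one(atoms["C3'"], atoms["C2'"], atoms["C4'"],
                              atoms["O3'"], 1.09)
    atoms["H4'"] = _tetra_one(atoms["C4'"], atoms["C3'"], atoms["O4'"],
                              atoms["C5'"], 1.09)
    atoms["H2'"], atoms["H2''"] = _tetra_two(atoms["C2'"], atoms["C1'"],
                                             atoms["C3'"], 1.09)
    atoms["H5'"], atoms["H5''"] = _tetra_two(atoms["C5'"], atoms["C4'"],
                                             atoms["O5'"], 1.09)
    return atoms


@dataclass
class DuplexBuildSpec:
    """Sequence and target geometry of an idealized duplex.

    ``sequence`` is strand I, 5'->3', over tokens A/C/G/T/U/M (M =
    5-methylcytosine).  ``twist`` and ``rise`` are scalars or per-step
    arrays of length len(sequence) - 1.  ``strand2``, if given, is
    validated as the Watson-Crick reverse complement (M pairs as C).
    """

    sequence: str
    twist: float | np.ndarray = 36.0
    rise: float | np.ndarray = 3.38
    backbone: str = "c2'-endo"
    strand2: str | None = None
    geometry: BackboneGeometry | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(WC_COMPLEMENT)
        if bad:
            raise ValueError(f"unknown residue token(s) {sorted(bad)}")
        if len(self.sequence) < 2:
            raise ValueError("need at least two base pairs")
        comp = self.complement()
        if self.strand2 is None:
            self.strand2 = comp
        else:
            self.strand2 = self.strand2.upper()
            # compare through pairing identity (M reads as C on strand 2)
            canon = str.maketrans("MU", "CT")
            if self.strand2.translate(canon) != comp.translate(canon):
                raise ValueError(
                    "strand2 is not the Watson-Crick reverse complement")
        n_steps = len(self.sequence) - 1
        self.twist = np.broadcast_to(
            np.asarray(self.twist, dtype=float), (n_steps,)).copy()
        self.rise = np.broadcast_to(
            np.asarray(self.rise, dtype=float), (n_steps,)).copy()

    def complement(self) -> str:
        """Reverse complement of strand I (5'->3' of strand II)."""
        return "".join(WC_COMPLEMENT[c] for c in reversed(self.sequence))


_FLIP = np.diag([1.0, -1.0, -1.0])  # 180 deg about x: strand II placement


def _element_of(name: str) -> str:
    return "P" if name == "P" else name.lstrip("0123456789'")[0]


def build_ideal_duplex(spec: DuplexBuildSpec):
    """Build the duplex as a biotite AtomArray (chains A and B).

    Chain A is strand I with residues 1..N in 5'->3' order; chain B is
    strand II, also numbered 1..N in its own 5'->3' order (residue j of
    chain B pairs with residue N+1-j of chain A).
    """
    if bst is None:  # pragma: no cover
        raise ImportError("biotite is required to build coordinate output")
    bb = spec.geometry or BackboneGeometry.preset(spec.backbone)
    n = len(spec.sequence)
    cum_twist = np.concatenate([[0.0], np.cumsum(spec.twist)])
    cum_rise = np.concatenate([[0.0], np.cumsum(spec.rise)])

    records = []  # (chain, res_id, res_name, atom_name, xyz)

    def helical(xyz, i):
        R = rotation_about_axis([0, 0, 1], cum_twist[i])
        return R @ xyz + np.array([0.0, 0.0, cum_rise[i]])

    template_cache: dict = {}

    def template(code, five_prime, three_prime):
        key = (code, five_prime, three_prime)
        if key not in template_cache:
            template_cache[key] = nucleotide_template(
                code, bb, five_prime, three_prime)
        return template_cache[key]

    for i, code in enumerate(spec.sequence):  # strand I, bp index i
        tpl = template(code, i == 0, i == n - 1)
        for name, xyz in tpl.items():
            records.append(("A", i + 1, RESIDUE_NAMES[code], name,
                            helical(xyz, i)))
    for j, code in enumerate(spec.strand2):  # strand II residue j -> bp
        i = n - 1 - j  # paired base-pair index
        tpl = template(code, j == 0, j == n - 1)
        for name, xyz in tpl.items():
            records.append(("B", j + 1, RESIDUE_NAMES[code], name,
                            helical(_FLIP @ xyz, i)))

    arr = bst.AtomArray(len(records))
    arr.coord = np.array([r[4] for r in records], dtype=np.float32)
    arr.chain_id = np.array([r[0] for r in records])
    arr.res_id = np.array([r[1] for r in records], dtype=int)
    arr.res_name = np.array([r[2] for r in records])
    arr.atom_name = np.array([r[3] for r in records])
    arr.element = np.array([_element_of(r[3]) for r in records])
    arr.hetero = np.zeros(len(records), dtype=bool)
    return arr


def perturb_ensemble(frame, amplitude: float, n_frames: int, seed: int):
    """Isotropic Gaussian Cartesian noise around one frame.

    Returns a biotite AtomArrayStack with ``n_frames`` models; amplitude
    is the per-coordinate standard deviation in Angstrom (so the
    expected per-atom RMSF is amplitude * sqrt(3)).  Amplitude 0 yields
    identical copies.
    """
    if amplitude < 0:
        raise ValueError(f"noise amplitude must be >= 0, got {amplitude}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    base = frame.coord.astype(float)
    noise = rng.normal(0.0, amplitude, size=(n_frames,) + base.shape)
    stack = bst.stack([frame] * n_frames)
    stack.coord = (base[None] + noise).astype(np.float32)
    return stack
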