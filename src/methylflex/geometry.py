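"""Sugar pseudorotation, unconventional C-H...O hydrogen bonds,
methyl-sugar distances and 2-D density maps.

The pseudorotation phase follows the Altona-Sundaralingam five-torsion
analysis with the convention anchored so that C3'-endo sits near 18 deg
and C2'-endo near 162 deg.  Weak C-H...O hydrogen bonds (H6/H8 donors to
backbone O3'/O5' acceptors) are detected with configurable geometric
criteria whose defaults follow the weak-donor literature: H...O <= 2.7 A,
C...O <= 3.5 A, C-H...O angle >= 120 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import circmean

from .constants import MASS
from .geom3d import angle_between, torsion, wrap360

__all__ = [
    "global_res_ids",
    "pucker_phase", "ring_torsions", "pucker_series",
    "HBondCriteria", "hbond_flags", "hbond_series",
    "methyl_sugar_distance", "DensityMap2D", "density_map_2d",
    "substate_coupling_stats",
]

#: Endocyclic torsion atom quadruples of the furanose ring, nu0..nu4.
RING_TORSION_ATOMS = [
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
]

_AS_DENOM = 2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))


def global_res_ids(chain_ids, res_ids, stride: int = 1000) -> np.ndarray:
    """Map per-chain residue numbers to globally unique integer keys.

    The geometry operations address residues by a single integer; for a
    duplex whose two chains both number residues 1..N, chain k
    contributes key res_id + k*stride.
    """
    chain_ids = np.asarray(chain_ids)
    res_ids = np.asarray(res_ids, dtype=int)
    chains = {c: k for k, c in enumerate(np.unique(chain_ids))}
    offsets = np.array([chains[c] for c in chain_ids]) * stride
    return res_ids + offsets


def pucker_phase(nu) -> tuple[float, float]:
    """Altona-Sundaralingam pseudorotation (phase deg in [0,360), amplitude deg).

    ``nu`` is the ordered endocyclic torsion tuple nu0..nu4 in degrees.
    A near-planar ring (amplitude < 1 deg) has no defined phase and
    returns (nan, amplitude).
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (5,):
        raise ValueError("expected five endocyclic torsions nu0..nu4")
    num = (nu[4] + nu[1]) - (nu[3] + nu[0])
    den = nu[2] * _AS_DENOM
    if abs(num) < 1e-12 and abs(den) < 1e-12:
        return float("nan"), 0.0
    p = math.degrees(math.atan2(num, den))
    cosp = math.cos(math.radians(p))
    amplitude = nu[2] / cosp if abs(cosp) > 1e-12 else num / (
        _AS_DENOM * math.sin(math.radians(p)))
    if amplitude < 1.0:
        return float("nan"), float(abs(amplitude))
    return wrap360(p), float(amplitude)


def ring_torsions(get_coord) -> np.ndarray:
    """nu0..nu4 for one ring; ``get_coord(atom_name) -> xyz``."""
    return np.array([torsion(*(get_coord(a) for a in quad))
                     for quad in RING_TORSION_ATOMS])


def pucker_series(coords: np.ndarray, atom_names, res_ids,
                  residues=None) -> pd.DataFrame:
    """Per-residue, per-frame pseudorotation from an ensemble.

    ``coords`` has shape (n_frames, n_atoms, 3); residues lacking a full
    furanose ring are skipped.  Returns columns
    [residue, frame, phase, amplitude].
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    atom_names = np.asarray(atom_names)
    res_ids = np.asarray(res_ids)
    rows = []
    ring_names = {"C1'", "C2'", "C3'", "C4'", "O4'"}
    for res in (np.unique(res_ids) if residues is None else residues):
        sel = {}
        for name in ring_names:
            idx = np.flatnonzero((res_ids == res) & (atom_names == name))
            if idx.size != 1:
                sel = None
                break
            sel[name] = idx[0]
        if sel is None:
            continue
        for f in range(coords.shape[0]):
            frame = coords[f]
            nu = ring_torsions(lambda a, _s=sel, _f=frame: _f[_s[a]])
            p, amp = pucker_phase(nu)
            rows.append((int(res), f, p, amp))
    return pd.DataFrame(rows, columns=["residue", "frame", "phase",
                                       "amplitude"])


# ---------------------------------------------------------------------------
# weak hydrogen bonds


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria for weak C-H...O hydrogen bonds."""

    max_h_acceptor: float = 2.7   # Angstrom
    max_donor_acceptor: float = 3.5  # Angstrom
    min_angle: float = 120.0      # deg, at the hydrogen

    def __post_init__(self):
        if self.max_h_acceptor <= 0 or self.max_donor_acceptor <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not 0.0 < self.min_angle <= 180.0:
            raise ValueError("angle cutoff must lie in (0, 180]")


def hbond_flags(donor: np.ndarray, hydrogen: np.ndarray,
                acceptor: np.ndarray,
                criteria: HBondCriteria = HBondCriteria()) -> pd.DataFrame:
    """Evaluate the criteria frame-wise on (n_frames, 3) coordinate arrays.

    Returns columns [frame, d_h_acceptor, d_donor_acceptor, angle, bonded].
    """
    donor, hydrogen, acceptor = (np.atleast_2d(np.asarray(x, float))
                                 for x in (donor, hydrogen, acceptor))
    d_ha = np.linalg.norm(acceptor - hydrogen, axis=1)
    d_da = np.linalg.norm(acceptor - donor, axis=1)
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    bonded = ((d_ha <= criteria.max_h_acceptor)
              & (d_da <= criteria.max_donor_acceptor)
              & (ang >= criteria.min_angle))
    return pd.DataFrame({
        "frame": np.arange(len(d_ha)),
        "d_h_acceptor": d_ha,
        "d_donor_acceptor": d_da,
        "angle": ang,
        "bonded": bonded,
    })


def hbond_series(coords: np.ndarray, atom_names, res_ids,
                 donor: tuple[int, str], hydrogen_name: str,
                 acceptor: tuple[int, str],
                 criteria: HBondCriteria = HBondCriteria()):
    """Occupancy and per-frame geometry of one C-H...O bond in an ensemble.

    ``donor``/``acceptor`` are (residue id, atom name) pairs, e.g.
    (7, "C6") with hydrogen "H6" donating to (6, "O3'").  Returns
    (occupancy fraction, flags DataFrame).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    atom_names = np.asarray(atom_names)
    res_ids = np.asarray(res_ids)

    def locate(res, name):
        idx = np.flatnonzero((res_ids == res) & (atom_names == name))
        if idx.size != 1:
            raise KeyError(
                f"atom {name!r} of residue {res} resolves to {idx.size} atoms")
        return idx[0]

    di = locate(*donor)
    hi = locate(donor[0], hydrogen_name)
    ai = locate(*acceptor)
    flags = hbond_flags(coords[:, di], coords[:, hi], coords[:, ai], criteria)
    return float(flags["bonded"].mean()), flags


# ---------------------------------------------------------------------------
# methyl - sugar distance


def methyl_sugar_distance(coords: np.ndarray, atom_names, res_ids,
                          thymine_res: int, neighbor_res: int,
                          mass_weighted: bool = True):
    """Distance from the thymine methyl center of mass to the 5'-neighbor C2'.

    Returns an (n_frames,) array, or None when the residue carries no
    methyl group (e.g. uracil) so callers can mark the series
    not-applicable.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    atom_names = np.asarray(atom_names)
    res_ids = np.asarray(res_ids)
    methyl = []
    weights = []
    for name in ("C7", "H71", "H72", "H73"):
        idx = np.flatnonzero((res_ids == thymine_res) & (atom_names == name))
        if idx.size != 1:
            return None
        methyl.append(idx[0])
        weights.append(MASS[name[0]] if mass_weighted else 1.0)
    c2 = np.flatnonzero((res_ids == neighbor_res) & (atom_names == "C2'"))
    if c2.size != 1:
        return None
    w = np.asarray(weights)
    com = (coords[:, methyl] * w[None, :, None]).sum(axis=1) / w.sum()
    return np.linalg.norm(com - coords[:, c2[0]], axis=1)


# ---------------------------------------------------------------------------
# density maps


@dataclass
class DensityMap2D:
    """Normalized joint histogram with named axes."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # shape (nx, ny), sums to 1
    x_name: str = "x"
    y_name: str = "y"
    x_units: str = ""
    y_units: str = ""

    def marginal_x(self) -> np.ndarray:
        return self.density.sum(axis=1)

    def marginal_y(self) -> np.ndarray:
        return self.density.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame({
            "x_bin": xx.ravel(), "y_bin": yy.ravel(),
            "density": self.density.ravel(),
        })


def density_map_2d(x, y, bins=50, ranges=None, x_name="x", y_name="y",
                   x_units="", y_units="") -> DensityMap2D:
    """Joint histogram of two equal-length series, normalized to mass 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(
            f"length mismatch: {x.shape} vs {y.shape}")
    h, xe, ye = np.histogram2d(x, y, bins=bins, range=ranges)
    total = h.sum()
    if total == 0:
        raise ValueError("no samples fall inside the histogram range")
    return DensityMap2D(xe, ye, h / total, x_name, y_name, x_units, y_units)


# ---------------------------------------------------------------------------
# substate-conditional pucker statistics


def substate_coupling_stats(pucker: pd.DataFrame, track: pd.DataFrame,
                            residue: int, step: int,
                            n_blocks: int = 5) -> dict:
    """Circular mean pucker phase of one ring conditioned on BI vs BII.

    ``pucker`` and ``track`` are frame-aligned (same frame index set for
    the chosen residue and step).  Returns conditional circular means,
    the BI - BII shift (wrapped to (-180, 180]) and a block-resampled
    standard error of the shift; a substate with no frames yields nan
    conditionals.
    """
    from .geom3d import wrap180

    p = pucker[pucker["residue"] == residue].set_index("frame")["phase"]
    t = track[track["step"] == step].set_index("frame")["label"]
    common = p.index.intersection(t.index)
    if len(common) == 0:
        raise ValueError("no aligned frames between pucker and track")
    p, t = p.loc[common], t.loc[common]

    def cmean(values):
        if len(values) == 0:
            return float("nan")
        return float(np.degrees(circmean(np.radians(values))))

    mean_bi = cmean(p[t == "BI"].to_numpy())
    mean_bii = cmean(p[t == "BII"].to_numpy())
    shift = (wrap180(mean_bi - mean_bii)
             if np.isfinite(mean_bi) and np.isfinite(mean_bii)
             else float("nan"))

    shifts = []
    bounds = np.linspace(0, len(common), n_blocks + 1, dtype=int)
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        pb, tb = p.iloc[sl], t.iloc[sl]
        mb_i, mb_ii = cmean(pb[tb == "BI"].to_numpy()), cmean(
            pb[tb == "BII"].to_numpy())
        if np.isfinite(mb_i) and np.isfinite(mb_ii):
            shifts.append(wrap180(mb_i - mb_ii))
    err = (float(np.std(shifts, ddof=1) / math.sqrt(len(shifts)))
           if len(shifts) >= 2 else float("nan"))
    return {
        "mean_phase_BI": mean_bi,
        "mean_phase_BII": mean_bii,
        "shift_BI_minus_BII": shift,
        "shift_block_error": err,
        "n_frames": int(len(common)),
    }
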