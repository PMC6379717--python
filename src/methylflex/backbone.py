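"""BI/BII backbone substate analysis.

A dinucleotide step is classified by the sign of epsilon - zeta
(BI: eps - zeta < 0, BII: eps - zeta > 0; the measure-zero boundary is
assigned to BI).  Free-energy profiles along eps - zeta come from
Boltzmann inversion of the sampled histogram, F = -kB*T*ln p, anchored
at the occupied minimum; statistical errors use block averaging over
contiguous frame blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import kbt
from .geom3d import torsion, wrap180, wrap360

__all__ = [
    "compute_dihedral", "extract_epsilon_zeta", "classify_substates",
    "population_stats", "transition_stats", "free_energy_profile",
    "block_error", "basin_free_energy_difference", "FreeEnergyProfile",
    "delta_g_bii",
]

#: Default central-segment steps for pooled statistics.
CENTRAL_SEGMENT = (6, 7, 8, 9)

compute_dihedral = torsion  # signed torsion, (-180, 180], IUPAC convention


def extract_epsilon_zeta(coords: np.ndarray, atom_names, res_ids,
                         chain_ids) -> pd.DataFrame:
    """Per-step epsilon/zeta series from a coordinate ensemble.

    epsilon = C4'(i)-C3'(i)-O3'(i)-P(i+1) and
    zeta = C3'(i)-O3'(i)-P(i+1)-O5'(i+1), per strand; residue numbering
    is 5'->3' within each chain and the step is identified by its 5'
    residue.  Terminal residues without a 3' phosphate are skipped.
    Angles are reported in [0, 360) with eps - zeta wrapped to
    (-180, 180].
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    atom_names = np.asarray(atom_names)
    res_ids = np.asarray(res_ids)
    chain_ids = np.asarray(chain_ids)

    rows = []
    for strand_no, chain in enumerate(np.unique(chain_ids), start=1):
        in_chain = chain_ids == chain
        residues = np.unique(res_ids[in_chain])

        def locate(res, name):
            idx = np.flatnonzero(in_chain & (res_ids == res)
                                 & (atom_names == name))
            return idx[0] if idx.size == 1 else None

        for res in residues[:-1]:
            nxt = res + 1
            if nxt not in residues:
                continue
            needed = [(res, "C4'"), (res, "C3'"), (res, "O3'"),
                      (nxt, "P"), (nxt, "O5'")]
            idx = [locate(r, n) for r, n in needed]
            if idx[3] is None:  # no 3' phosphate: terminal junction
                continue
            missing = [f"{n} of residue {r}"
                       for (r, n), i in zip(needed, idx) if i is None]
            if missing:
                raise ValueError(
                    f"chain {chain}: unresolvable atoms: "
                    + ", ".join(missing))
            c4, c3, o3, p, o5 = idx
            for f in range(coords.shape[0]):
                xyz = coords[f]
                eps = wrap360(torsion(xyz[c4], xyz[c3], xyz[o3], xyz[p]))
                zet = wrap360(torsion(xyz[c3], xyz[o3], xyz[p], xyz[o5]))
                rows.append((int(res), strand_no, f, eps, zet))
    df = pd.DataFrame(rows, columns=["step", "strand", "frame",
                                     "epsilon", "zeta"])
    df["eps_zeta"] = wrap180(df["epsilon"] - df["zeta"])
    return df


def extract_epsilon_zeta_stack(stack) -> pd.DataFrame:
    """Convenience wrapper for a biotite AtomArray / AtomArrayStack."""
    coords = stack.coord
    return extract_epsilon_zeta(coords, stack.atom_name, stack.res_id,
                                stack.chain_id)


def classify_substates(series: pd.DataFrame) -> pd.DataFrame:
    """Label every record BI (eps - zeta <= 0) or BII (> 0)."""
    track = series[[c for c in ("step", "strand", "frame")
                    if c in series.columns]].copy()
    track["label"] = np.where(series["eps_zeta"].to_numpy() > 0, "BII", "BI")
    return track


def population_stats(track: pd.DataFrame, segment=None,
                     n_blocks: int = 5) -> dict:
    """Pooled P(BI) percent over (step in segment, strand, frame).

    The error is the standard error of P(BI) over ``n_blocks``
    contiguous frame blocks.
    """
    sub = track if segment is None else track[track["step"].isin(segment)]
    if len(sub) == 0:
        raise ValueError("segment selects no records")
    is_bi = (sub["label"].to_numpy() == "BI")
    p_bi = 100.0 * is_bi.mean()
    frames = sub["frame"].to_numpy()
    edges = np.quantile(frames, np.linspace(0, 1, n_blocks + 1))
    block_p = []
    for b in range(n_blocks):
        lo, hi = edges[b], edges[b + 1]
        m = (frames >= lo) & ((frames < hi) | (b == n_blocks - 1))
        if m.sum():
            block_p.append(100.0 * is_bi[m].mean())
    err = (float(np.std(block_p, ddof=1) / math.sqrt(len(block_p)))
           if len(block_p) >= 2 else 0.0)
    return {"p_bi_percent": float(p_bi),
            "p_bii_percent": float(100.0 - p_bi),
            "error_percent": err,
            "n_records": int(len(sub))}


def transition_stats(track: pd.DataFrame) -> pd.DataFrame:
    """Per-step substate transition counts and mean dwell lengths."""
    rows = []
    group_cols = [c for c in ("step", "strand") if c in track.columns]
    for key, g in track.sort_values("frame").groupby(group_cols):
        labels = g["label"].to_numpy()
        if len(labels) < 2:
            raise ValueError("transition statistics need >= 2 frames")
        flips = labels[1:] != labels[:-1]
        n_trans = int(flips.sum())
        bi_to_bii = int(((labels[:-1] == "BI") & flips).sum())
        dwell = len(labels) / (n_trans + 1)
        key = key if isinstance(key, tuple) else (key,)
        rows.append((*key, n_trans, bi_to_bii, n_trans - bi_to_bii, dwell))
    return pd.DataFrame(rows, columns=[*group_cols, "n_transitions",
                                       "bi_to_bii", "bii_to_bi",
                                       "mean_dwell_frames"])


@dataclass
class FreeEnergyProfile:
    """Boltzmann-inversion free energy along eps - zeta.

    Empty bins carry F = nan (never 0); occupied bins are anchored so
    min F = 0.  ``counts`` keeps the raw histogram so basin populations
    can be recomputed without round-tripping through F.
    """

    edges: np.ndarray
    free_energy: np.ndarray  # kcal/mol, nan where unoccupied
    error: np.ndarray        # kcal/mol, nan where undefined
    counts: np.ndarray
    temperature: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def basin_populations(self, boundary: float = 0.0):
        """(P(BI), P(BII)) by basin-integrated counts about the boundary."""
        bi = self.counts[self.centers < boundary].sum()
        bii = self.counts[self.centers > boundary].sum()
        total = bi + bii
        if total == 0:
            raise ValueError("profile has no occupied bins")
        return bi / total, bii / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_deg": self.centers,
            "free_energy_kcal_mol": self.free_energy,
            "error_kcal_mol": self.error,
            "count": self.counts,
        })


def free_energy_profile(eps_zeta, bin_width: float = 5.0,
                        temperature: float = 300.0,
                        frames=None, n_blocks: int = 5) -> FreeEnergyProfile:
    """Boltzmann inversion F = -kB*T*ln p of the eps - zeta histogram.

    ``eps_zeta`` are samples in (-180, 180].  When per-sample ``frames``
    are given, per-bin errors are block-averaged over ``n_blocks``
    contiguous frame blocks (standard error of per-block F with a
    common anchoring bin).
    """
    x = np.asarray(eps_zeta, dtype=float)
    if x.size == 0:
        raise ValueError("no samples")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    kT = kbt(temperature)
    with np.errstate(divide="ignore"):
        logp = np.where(counts > 0, np.log(counts / counts.sum()), np.nan)
    F = -kT * logp
    F -= np.nanmin(F)

    err = np.full(n_bins, np.nan)
    if frames is not None:
        frames = np.asarray(frames)
        order = np.argsort(frames, kind="stable")
        xs = x[order]
        bounds = np.linspace(0, xs.size, n_blocks + 1, dtype=int)
        anchor = int(np.nanargmin(np.where(counts > 0, F, np.inf)))
        block_F = []
        for b in range(n_blocks):
            c, _ = np.histogram(xs[bounds[b]:bounds[b + 1]], bins=edges)
            with np.errstate(divide="ignore"):
                lp = np.where(c > 0, np.log(c / max(c.sum(), 1)), np.nan)
            Fb = -kT * lp
            if c[anchor] > 0:
                Fb -= Fb[anchor]
            block_F.append(Fb)
        block_F = np.array(block_F)
        finite = np.isfinite(block_F)
        n_ok = finite.sum(axis=0)
        filled = np.where(finite, block_F, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_b = filled.sum(axis=0) / np.maximum(n_ok, 1)
            ssq = (np.where(finite, block_F - mean_b, 0.0) ** 2).sum(axis=0)
            err = np.where(n_ok >= 2,
                           np.sqrt(ssq / np.maximum(n_ok - 1, 1))
                           / np.sqrt(np.maximum(n_ok, 1)), np.nan)
    return FreeEnergyProfile(edges, F, err, counts, temperature)


def block_error(series, n_blocks: int = 5) -> float:
    """Standard error of contiguous block means of a per-frame series."""
    x = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if x.size < n_blocks:
        raise ValueError(
            f"cannot split {x.size} frames into {n_blocks} blocks")
    bounds = np.linspace(0, x.size, n_blocks + 1, dtype=int)
    means = [x[bounds[b]:bounds[b + 1]].mean() for b in range(n_blocks)]
    return float(np.std(means, ddof=1) / math.sqrt(n_blocks))


def delta_g_bii(profile: FreeEnergyProfile, boundary: float = 0.0) -> float:
    """Free-energy cost of BI -> BII, -kB*T*ln(P(BII)/P(BI)), kcal/mol."""
    p_bi, p_bii = profile.basin_populations(boundary)
    if p_bi == 0 or p_bii == 0:
        raise ValueError("a basin is unoccupied; Delta G undefined")
    return -kbt(profile.temperature) * math.log(p_bii / p_bi)


def basin_free_energy_difference(profile_a: FreeEnergyProfile,
                                 profile_b: FreeEnergyProfile,
                                 boundary: float = 0.0) -> dict:
    """Delta-Delta-G of BII stabilization between two profiles.

    Positive values mean condition b pays more to reach BII than
    condition a.  Both profiles must share the temperature.
    """
    if abs(profile_a.temperature - profile_b.temperature) > 1e-9:
        raise ValueError("profiles are at different temperatures")
    dg_a = delta_g_bii(profile_a, boundary)
    dg_b = delta_g_bii(profile_b, boundary)
    return {"delta_g_a": dg_a, "delta_g_b": dg_b,
            "delta_delta_g": dg_b - dg_a}
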