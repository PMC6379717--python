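"""Base-pair step helical parameters, segment aggregates and harmonic
stiffness matrices.

Step parameters follow the mid-frame (CEHS/3DNA-style) construction:
an orthonormal reference frame is fitted to each base by superposing
the planar standard-base template onto the observed ring atoms, the two
frames of a pair are averaged (strand II z/y flipped), and the six
rigid-body parameters (shift, slide, rise, tilt, roll, twist) are read
off the mid-frame between consecutive pair frames.  Twist is positive
for a right-handed helix.

The harmonic stiffness model maps the covariance C of helical-parameter
fluctuations to a stiffness matrix K = kB*T*C^-1 (kcal/mol per squared
unit); it presumes near-Gaussian fluctuations, which the Gaussianity
diagnostics check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import kbt
from .geom3d import kabsch, rotation_about_axis
from .synth.duplex import base_ring_atoms, base_template

__all__ = [
    "base_pair_frames", "step_parameters_from_frames",
    "compute_step_parameters", "segment_aggregate", "step_rotation",
    "stiffness", "StiffnessResult", "relative_change",
    "conditional_twist_stats", "gaussianity_check",
]

_FLIP_YZ = np.diag([1.0, -1.0, -1.0])

_CODE_OF = {"DA": "A", "DT": "T", "DG": "G", "DC": "C", "DU": "U",
            "5CM": "M", "A": "A", "T": "T", "G": "G", "C": "C", "U": "U"}


def _orthonormalize(R: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(R)
    return U @ Vt


def _fit_base_frame(obs: np.ndarray, ref: np.ndarray):
    """Rotation/origin of a base from observed vs template ring atoms."""
    R, t, rmsd = kabsch(ref, obs)
    return R, t, rmsd


def base_pair_frames(coords: np.ndarray, atom_names, res_ids, chain_ids,
                     res_names):
    """Fit per-frame base-pair reference frames for a two-chain duplex.

    Chain residues are paired positionally: residue i of the first chain
    with residue N+1-i of the second.  Returns (rotations, origins) with
    shapes (n_frames, n_bp, 3, 3) and (n_frames, n_bp, 3).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    atom_names = np.asarray(atom_names)
    res_ids = np.asarray(res_ids)
    chain_ids = np.asarray(chain_ids)
    res_names = np.asarray(res_names)
    chains = np.unique(chain_ids)
    if len(chains) != 2:
        raise ValueError(f"expected a two-chain duplex, found {len(chains)}")
    res_a = np.unique(res_ids[chain_ids == chains[0]])
    res_b = np.unique(res_ids[chain_ids == chains[1]])
    if len(res_a) != len(res_b):
        raise ValueError("strands have different residue counts")
    n_bp = len(res_a)

    def ring_indices(chain, res):
        m = (chain_ids == chain) & (res_ids == res)
        code = _CODE_OF[res_names[m][0]]
        tpl = base_template(code)
        names = base_ring_atoms(code)
        idx = []
        for name in names:
            k = np.flatnonzero(m & (atom_names == name))
            if k.size != 1:
                raise KeyError(
                    f"fitting atom {name!r} unresolvable in chain {chain} "
                    f"residue {res}")
            idx.append(k[0])
        ref = np.array([tpl[name] for name in names])
        return np.array(idx), ref

    pairs = []
    for i in range(n_bp):
        ia, ra = ring_indices(chains[0], res_a[i])
        ib, rb = ring_indices(chains[1], res_b[n_bp - 1 - i])
        pairs.append((ia, ra, ib, rb))

    n_frames = coords.shape[0]
    rotations = np.zeros((n_frames, n_bp, 3, 3))
    origins = np.zeros((n_frames, n_bp, 3))
    for f in range(n_frames):
        xyz = coords[f]
        for i, (ia, ra, ib, rb) in enumerate(pairs):
            R1, t1, _ = _fit_base_frame(xyz[ia], ra)
            R2, t2, _ = _fit_base_frame(xyz[ib], rb)
            R2 = R2 @ _FLIP_YZ  # strand II frame flipped onto strand I
            rotations[f, i] = _orthonormalize((R1 + R2) / 2.0)
            origins[f, i] = (t1 + t2) / 2.0
    return rotations, origins


def step_parameters_from_frames(rotations: np.ndarray,
                                origins: np.ndarray) -> pd.DataFrame:
    """Six step parameters between consecutive pair frames (mid-frame)."""
    rotations = np.asarray(rotations, dtype=float)
    origins = np.asarray(origins, dtype=float)
    if rotations.ndim == 3:
        rotations, origins = rotations[None], origins[None]
    n_frames, n_bp = rotations.shape[:2]
    rows = []
    for f in range(n_frames):
        for i in range(n_bp - 1):
            R1, R2 = rotations[f, i], rotations[f, i + 1]
            o1, o2 = origins[f, i], origins[f, i + 1]
            z1, z2 = R1[:, 2], R2[:, 2]
            cross = np.cross(z1, z2)
            gamma = math.degrees(math.atan2(
                np.linalg.norm(cross), float(np.dot(z1, z2))))
            if np.linalg.norm(cross) > 1e-12:
                hinge = cross / np.linalg.norm(cross)
                R1p = rotation_about_axis(hinge, +gamma / 2.0) @ R1
                R2p = rotation_about_axis(hinge, -gamma / 2.0) @ R2
            else:
                hinge = R1[:, 1]
                R1p, R2p = R1, R2
            Rm = _orthonormalize((R1p + R2p) / 2.0)
            zm = Rm[:, 2]
            twist = math.degrees(math.atan2(
                float(np.dot(np.cross(R1p[:, 0], R2p[:, 0]), zm)),
                float(np.dot(R1p[:, 0], R2p[:, 0]))))
            phi = math.degrees(math.atan2(
                float(np.dot(np.cross(hinge, Rm[:, 1]), zm)),
                float(np.dot(hinge, Rm[:, 1]))))
            roll = gamma * math.cos(math.radians(phi))
            tilt = gamma * math.sin(math.radians(phi))
            shift, slide, rise = Rm.T @ (o2 - o1)
            rows.append((i + 1, f, shift, slide, rise, tilt, roll, twist))
    return pd.DataFrame(rows, columns=["step", "frame", "shift", "slide",
                                       "rise", "tilt", "roll", "twist"])


def compute_step_parameters(coords, atom_names, res_ids, chain_ids,
                            res_names, return_frames: bool = False):
    """Step parameters of a duplex ensemble; optionally also the fitted
    base-pair frames (for segment bend computation)."""
    rot, orig = base_pair_frames(coords, atom_names, res_ids, chain_ids,
                                 res_names)
    series = step_parameters_from_frames(rot, orig)
    return (series, (rot, orig)) if return_frames else series


def step_rotation(tilt: float, roll: float, twist: float) -> np.ndarray:
    """Relative rotation R with frame2 = R @ frame1 implied by one step.

    Inverse of the mid-frame decomposition; used to propagate base-pair
    normals through a segment when only step parameters are available.
    """
    gamma = math.hypot(tilt, roll)
    phi = math.degrees(math.atan2(tilt, roll))
    zm = np.array([0.0, 0.0, 1.0])
    ym = np.array([0.0, 1.0, 0.0])
    # hinge sits at angle -phi from the mid-frame y axis (about z)
    hinge = rotation_about_axis(zm, -phi) @ ym
    Rm = np.eye(3)
    R1p = rotation_about_axis(zm, -twist / 2.0) @ Rm
    R2p = rotation_about_axis(zm, +twist / 2.0) @ Rm
    R1 = rotation_about_axis(hinge, -gamma / 2.0) @ R1p
    R2 = rotation_about_axis(hinge, +gamma / 2.0) @ R2p
    return R1.T @ R2  # local transform: frame2 = frame1 @ T


def segment_aggregate(series: pd.DataFrame, segment,
                      frames: tuple | None = None) -> pd.DataFrame:
    """Per-frame segment twist/stretch/bend over a set of steps.

    Segment twist is the mean step twist and stretch the mean step rise.
    Bend is the angle between the base-pair normals bounding the
    segment: from fitted frames when available, otherwise by composing
    the per-step rotations reconstructed from (tilt, roll, twist).
    """
    segment = sorted(segment)
    missing = set(segment) - set(series["step"].unique())
    if missing:
        raise ValueError(f"segment steps missing from series: {missing}")
    sub = series[series["step"].isin(segment)]
    agg = sub.groupby("frame").agg(
        twist=("twist", "mean"), stretch=("rise", "mean")).reset_index()

    if frames is not None:
        rot, _ = frames
        if rot.ndim == 3:
            rot = rot[None]
        first_bp, last_bp = segment[0] - 1, segment[-1]  # 0-based bp indices
        z1 = rot[:, first_bp, :, 2]
        z2 = rot[:, last_bp, :, 2]
        cosb = np.clip(np.einsum("ij,ij->i", z1, z2), -1.0, 1.0)
        bend = np.degrees(np.arccos(cosb))
        agg["bend"] = bend[agg["frame"].to_numpy()]
    else:
        bends = []
        for f, g in sub.sort_values("step").groupby("frame"):
            R = np.eye(3)
            for _, row in g.iterrows():
                R = R @ step_rotation(row["tilt"], row["roll"], row["twist"])
            cosb = np.clip(R[2, 2], -1.0, 1.0)
            bends.append((f, math.degrees(math.acos(cosb))))
        bend = pd.Series(dict(bends))
        agg["bend"] = bend.loc[agg["frame"]].to_numpy()
    return agg


@dataclass
class StiffnessResult:
    """Covariance and harmonic stiffness of fluctuation variables."""

    names: list[str]
    units: list[str]
    mean: np.ndarray
    covariance: np.ndarray
    stiffness: np.ndarray  # kcal/mol per unit_i*unit_j
    temperature: float
    n_samples: int

    def to_frames(self):
        idx = [f"{n} [{u}]" for n, u in zip(self.names, self.units)]
        return (pd.DataFrame(self.covariance, index=idx, columns=idx),
                pd.DataFrame(self.stiffness, index=idx, columns=idx))


_DEFAULT_UNITS = {"shift": "A", "slide": "A", "rise": "A", "stretch": "A",
                  "tilt": "deg", "roll": "deg", "twist": "deg",
                  "bend": "deg"}


def stiffness(data, temperature: float = 300.0, names=None,
              units=None) -> StiffnessResult:
    """K = kB*T*C^-1 from fluctuation samples.

    ``data`` is a DataFrame of per-frame variables (any non-variable
    columns like ``frame`` are dropped) or an (n, d) array with
    ``names``.  Raises on fewer samples than dimensions or a singular
    covariance (condition number reported).
    """
    if isinstance(data, pd.DataFrame):
        cols = [c for c in data.columns if c not in ("frame", "step")]
        names = names or cols
        X = data[names].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more than {d} samples, got {n}")
    C = np.cov(X, rowvar=False, ddof=1).reshape(d, d)
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular fluctuation covariance (condition number {cond:.3g})")
    K = kbt(temperature) * np.linalg.inv(C)
    K = (K + K.T) / 2.0
    units = units or [_DEFAULT_UNITS.get(nm, "") for nm in names]
    return StiffnessResult(list(names), list(units), X.mean(axis=0), C, K,
                           temperature, n)


def relative_change(ref: StiffnessResult, mod: StiffnessResult) -> pd.DataFrame:
    """Mode-wise percent changes of stiffness and equilibrium means.

    100*(mod - ref)/ref on the stiffness diagonal and on the variable
    means, per variable.
    """
    if ref.names != mod.names or ref.units != mod.units:
        raise ValueError("stiffness results use different variables/units")
    k_ref = np.diag(ref.stiffness)
    k_mod = np.diag(mod.stiffness)
    return pd.DataFrame({
        "variable": ref.names,
        "units": ref.units,
        "stiffness_ref": k_ref,
        "stiffness_mod": k_mod,
        "stiffness_change_percent": 100.0 * (k_mod - k_ref) / k_ref,
        "mean_ref": ref.mean,
        "mean_mod": mod.mean,
        "mean_change_percent": 100.0 * (mod.mean - ref.mean)
        / np.where(ref.mean != 0, ref.mean, np.nan),
    })


def conditional_twist_stats(series: pd.DataFrame, track: pd.DataFrame,
                            n_blocks: int = 5) -> dict:
    """Twist mean/SD conditioned on the BI/BII label, plus the pooled law.

    ``series`` and ``track`` are aligned on (step, frame).  A substate
    with no frames yields nan conditionals.  Block errors are standard
    errors over contiguous frame blocks.
    """
    keys = [c for c in ("step", "frame") if c in series.columns
            and c in track.columns]
    merged = series.merge(track[keys + ["label"]], on=keys)
    if len(merged) != len(series):
        raise ValueError("series and track do not align frame-for-frame")
    tw = merged["twist"].to_numpy()
    lab = merged["label"].to_numpy()

    def sd(x):
        return float(np.std(x, ddof=1)) if x.size >= 2 else float("nan")

    out = {
        "mean_BI": float(tw[lab == "BI"].mean()) if (lab == "BI").any()
        else float("nan"),
        "mean_BII": float(tw[lab == "BII"].mean()) if (lab == "BII").any()
        else float("nan"),
        "mean_total": float(tw.mean()),
        "sigma_BI": sd(tw[lab == "BI"]),
        "sigma_BII": sd(tw[lab == "BII"]),
        "sigma_total": sd(tw),
        "p_BII": float((lab == "BII").mean()),
    }
    frames = merged["frame"].to_numpy()
    edges = np.quantile(frames, np.linspace(0, 1, n_blocks + 1))
    sig = []
    for b in range(n_blocks):
        m = (frames >= edges[b]) & ((frames < edges[b + 1])
                                    | (b == n_blocks - 1))
        if m.sum() >= 2:
            sig.append(np.std(tw[m], ddof=1))
    out["sigma_total_block_error"] = (
        float(np.std(sig, ddof=1) / math.sqrt(len(sig)))
        if len(sig) >= 2 else float("nan"))
    return out


def gaussianity_check(segment: pd.DataFrame, alpha: float = 0.01,
                      min_bic_margin: float = 10.0,
                      min_separation: float = 1.0) -> pd.DataFrame:
    """Bimodality and normality diagnostics for the harmonic model.

    Per variable: a two- vs one-component Gaussian-mixture BIC contrast
    (flagging bimodality when the margin exceeds ``min_bic_margin`` AND
    the fitted components are separated by more than ``min_separation``
    pooled SDs), plus skew/kurtosis normality z-scores.  Degenerate
    (constant) series are flagged separately.
    """
    from sklearn.mixture import GaussianMixture

    rows = []
    for col in [c for c in segment.columns if c != "frame"]:
        x = segment[col].to_numpy(dtype=float)
        if x.size < 100:
            raise ValueError("need at least 100 samples per variable")
        if np.std(x) < 1e-12:
            rows.append((col, np.nan, np.nan, np.nan, np.nan, False, True))
            continue
        z = (x - x.mean()) / x.std()
        k2, p_norm = stats.normaltest(z)
        X = z.reshape(-1, 1)
        g1 = GaussianMixture(1, random_state=0).fit(X)
        g2 = GaussianMixture(2, random_state=0, n_init=3).fit(X)
        margin = g1.bic(X) - g2.bic(X)
        mu = g2.means_.ravel()
        sd = np.sqrt(g2.covariances_.ravel())
        sep = abs(mu[0] - mu[1]) / np.sqrt(0.5 * (sd[0]**2 + sd[1]**2))
        bimodal = bool(margin > min_bic_margin and sep > min_separation)
        rows.append((col, float(k2), float(p_norm), float(margin),
                     float(sep), bimodal or (p_norm < alpha and bimodal),
                     False))
    return pd.DataFrame(rows, columns=[
        "variable", "normality_stat", "normality_p", "bic_margin",
        "component_separation", "flag_bimodal", "flag_degenerate"])
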