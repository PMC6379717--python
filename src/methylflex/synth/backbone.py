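"""Two-state BI/BII backbone dihedral generator.

Each dinucleotide step adopts BI or BII; (epsilon, zeta) are drawn from
wrapped Gaussians around the basin centers (the canonical trans/gauche-
assignment for BI and gauche-/trans for BII).  Simultaneous BII at
adjacent steps is penalized by a pairwise Gibbs factor exp(-kappa),
reproducing the nearest-neighbor BII anti-correlation seen in DNA
simulations; kappa = 0 gives independent steps.  Sampling of the label
chain is exact (backward transfer-matrix messages, forward draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..geom3d import wrap180, wrap360

__all__ = ["TwoStateBackboneModel", "generate_backbone_series",
           "adjacent_pair_distribution"]

#: Canonical basin centers (epsilon, zeta) in degrees.
BI_CENTER = (190.0, 265.0)
BII_CENTER = (245.0, 175.0)


@dataclass
class TwoStateBackboneModel:
    """Parameters of the per-step two-basin (epsilon, zeta) mixture.

    ``p_bii`` is the marginal field probability of BII per step (scalar
    broadcast or per-step array); ``kappa`` >= 0 penalizes simultaneous
    BII at adjacent steps (the realized joint probability of adjacent
    BII is suppressed by ~exp(-kappa) relative to independence).
    """

    p_bii: float | np.ndarray = 0.164
    bi_center: tuple[float, float] = BI_CENTER
    bii_center: tuple[float, float] = BII_CENTER
    sigma_bi: tuple[float, float] = (12.0, 12.0)
    sigma_bii: tuple[float, float] = (12.0, 12.0)
    kappa: float = 0.0
    temperature: float = 300.0
    seed: int = 0

    def validate(self, n_steps: int) -> np.ndarray:
        p = np.broadcast_to(np.asarray(self.p_bii, dtype=float),
                            (n_steps,)).copy()
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p_bii must lie in [0, 1]")
        for s in (*self.sigma_bi, *self.sigma_bii):
            if s <= 0:
                raise ValueError(f"basin widths must be positive, got {s}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if wrap180(self.bi_center[0] - self.bi_center[1]) >= 0:
            raise ValueError("BI center must satisfy eps - zeta < 0")
        if wrap180(self.bii_center[0] - self.bii_center[1]) <= 0:
            raise ValueError("BII center must satisfy eps - zeta > 0")
        return p


def _sample_labels(p: np.ndarray, kappa: float, n_frames: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Exact samples of the coupled binary chain; shape (n_frames, n_steps).

    Gibbs weight: prod_j p_j^{s_j} (1-p_j)^{1-s_j} * prod_j e^{-kappa s_j s_{j+1}}.
    """
    n_steps = len(p)
    w = np.stack([1.0 - p, p], axis=1)  # field weights, (n_steps, 2)
    if kappa == 0.0:
        return (rng.random((n_frames, n_steps)) < p[None, :]).astype(int)

    T = np.array([[1.0, 1.0], [1.0, np.exp(-kappa)]])
    # backward messages b[j, s] ~ w_j(s) * sum_{s'} T[s, s'] b[j+1, s']
    b = np.zeros((n_steps, 2))
    b[-1] = w[-1]
    for j in range(n_steps - 2, -1, -1):
        nxt = T @ b[j + 1]
        b[j] = w[j] * nxt
        b[j] /= b[j].sum()  # running normalization for stability

    out = np.zeros((n_frames, n_steps), dtype=int)
    u = rng.random((n_frames, n_steps))
    p1 = b[0, 1] / b[0].sum()
    out[:, 0] = (u[:, 0] < p1).astype(int)
    for j in range(1, n_steps):
        cond = T[out[:, j - 1]] * b[j][None, :]  # (n_frames, 2)
        p1 = cond[:, 1] / cond.sum(axis=1)
        out[:, j] = (u[:, j] < p1).astype(int)
    return out


def adjacent_pair_distribution(p1: float, p2: float, kappa: float):
    """Exact 4-state Gibbs distribution of one adjacent step pair.

    Returns (joint[2, 2] indexed by (s1, s2) with s = 1 for BII,
    Pearson correlation of the BII indicators).
    """
    joint = np.empty((2, 2))
    for s1 in (0, 1):
        for s2 in (0, 1):
            w1 = p1 if s1 else 1.0 - p1
            w2 = p2 if s2 else 1.0 - p2
            joint[s1, s2] = w1 * w2 * np.exp(-kappa * s1 * s2)
    joint /= joint.sum()
    m1, m2 = joint[1].sum(), joint[:, 1].sum()
    cov = joint[1, 1] - m1 * m2
    denom = np.sqrt(m1 * (1 - m1) * m2 * (1 - m2))
    corr = cov / denom if denom > 0 else 0.0
    return joint, float(corr)


def generate_backbone_series(model: TwoStateBackboneModel, n_steps: int,
                             n_frames: int):
    """Draw per-step, per-frame (epsilon, zeta) with ground-truth labels.

    Returns (DihedralSeries, SubstateTrack) DataFrames with columns
    [step, strand, frame, epsilon, zeta, eps_zeta] and
    [step, strand, frame, label].  Angles are wrapped to [0, 360) and
    eps_zeta to (-180, 180].  Deterministic under the model seed.
    """
    if n_frames < 1 or n_steps < 1:
        raise ValueError("n_steps and n_frames must be >= 1")
    p = model.validate(n_steps)
    rng = np.random.default_rng(model.seed)
    labels = _sample_labels(p, model.kappa, n_frames, rng)  # (F, S)

    centers = np.where(labels[..., None] == 1,
                       np.array(model.bii_center),
                       np.array(model.bi_center))  # (F, S, 2)
    sigmas = np.where(labels[..., None] == 1,
                      np.array(model.sigma_bii),
                      np.array(model.sigma_bi))
    angles = wrap360(rng.normal(centers, sigmas))
    eps, zeta = angles[..., 0], angles[..., 1]

    frame_idx, step_idx = np.meshgrid(np.arange(n_frames),
                                      np.arange(1, n_steps + 1),
                                      indexing="ij")
    series = pd.DataFrame({
        "step": step_idx.ravel(),
        "strand": 1,
        "frame": frame_idx.ravel(),
        "epsilon": eps.ravel(),
        "zeta": zeta.ravel(),
    })
    series["eps_zeta"] = wrap180(series["epsilon"] - series["zeta"])
    track = series[["step", "strand", "frame"]].copy()
    track["label"] = np.where(labels.ravel() == 1, "BII", "BI")
    return series, track
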