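"""Substate-conditional helical-parameter generator.

The six rigid-body step parameters (shift, slide, rise, tilt, roll,
twist) are drawn from a joint Gaussian; twist is replaced by a
substate-conditional Gaussian selected by a BI/BII label track, which
reproduces the mechanism by which a broader BI twist distribution makes
the cumulative distribution (and hence the apparent twist stiffness)
depend on the BI/BII population balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..constants import kbt

__all__ = ["HelicalMixtureModel", "generate_helical_series",
           "sample_from_stiffness", "STEP_PARAMETER_NAMES"]

STEP_PARAMETER_NAMES = ["shift", "slide", "rise", "tilt", "roll", "twist"]


def _default_cov() -> np.ndarray:
    sd = np.array([0.5, 0.7, 0.3, 3.5, 6.0, 7.2])
    return np.diag(sd ** 2)


@dataclass
class HelicalMixtureModel:
    """Joint Gaussian for the six step parameters + conditional twist law.

    Twist means/SDs are per substate (deg); ``mean`` and ``cov`` cover
    (shift, slide, rise, tilt, roll, twist) in (A, A, A, deg, deg, deg).
    """

    twist_mean_bi: float = 36.0
    twist_mean_bii: float = 36.0
    twist_sigma_bi: float = 7.2
    twist_sigma_bii: float = 6.2
    mean: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 3.38, 0.0, 0.0, 36.0]))
    cov: np.ndarray = field(default_factory=_default_cov)
    seed: int = 0

    def validate(self) -> None:
        if self.twist_sigma_bi <= 0 or self.twist_sigma_bii <= 0:
            raise ValueError("twist sigmas must be positive")
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (6, 6) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be a symmetric 6x6 matrix")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() <= 0:
            raise ValueError(
                f"covariance must be positive definite (min eig {eig.min():g})")


def generate_helical_series(model: HelicalMixtureModel,
                            track: pd.DataFrame) -> pd.DataFrame:
    """Step-parameter draws following a SubstateTrack frame-for-frame.

    Returns a StepParameterSeries DataFrame with columns
    [step, frame, shift, slide, rise, tilt, roll, twist]; the twist of a
    record labeled BI/BII follows the respective conditional Gaussian.
    Deterministic under the model seed.
    """
    model.validate()
    required = {"step", "frame", "label"}
    if not required.issubset(track.columns):
        raise ValueError(f"track must carry columns {sorted(required)}")
    rng = np.random.default_rng(model.seed)
    n = len(track)
    draws = rng.multivariate_normal(model.mean, model.cov, size=n,
                                    method="cholesky")
    is_bii = (track["label"].to_numpy() == "BII")
    mu = np.where(is_bii, model.twist_mean_bii, model.twist_mean_bi)
    sd = np.where(is_bii, model.twist_sigma_bii, model.twist_sigma_bi)
    draws[:, 5] = rng.normal(mu, sd)
    out = pd.DataFrame(draws, columns=STEP_PARAMETER_NAMES)
    out.insert(0, "frame", track["frame"].to_numpy())
    out.insert(0, "step", track["step"].to_numpy())
    return out


def sample_from_stiffness(K: np.ndarray, temperature: float, n: int,
                          seed: int, means=None,
                          names=("twist", "stretch", "bend")) -> pd.DataFrame:
    """Gaussian fluctuation samples whose ground-truth stiffness is K.

    Draws from the covariance C = kB*T*K^-1 implied by the harmonic
    model, so a stiffness estimate on the samples can be checked against
    the generating matrix.  Returns a frame-indexed DataFrame with the
    named columns.
    """
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("stiffness matrix must be symmetric")
    cov = kbt(temperature) * np.linalg.inv(K)
    mean = np.zeros(K.shape[0]) if means is None else np.asarray(means, float)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    out = pd.DataFrame(draws, columns=list(names))
    out.insert(0, "frame", np.arange(n))
    return out
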