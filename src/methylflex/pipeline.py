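"""End-to-end comparative runs: reference vs modified condition.

Every headline quantity of the methyl-masking methodology is a
difference between two conditions (e.g. all interactions present vs
methyl-sugar vdW masked).  A run therefore generates or loads an
ensemble per condition, pushes both through the backbone, geometry and
mechanics stages, and emits a comparative report whose every number is
traceable to a stored CSV artifact.  All randomness derives from a
single run seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .backbone import (basin_free_energy_difference, classify_substates,
                       delta_g_bii, free_energy_profile, population_stats,
                       transition_stats)
from .mechanics import conditional_twist_stats, relative_change, stiffness
from .synth.backbone import TwoStateBackboneModel, generate_backbone_series
from .synth.helical import HelicalMixtureModel, generate_helical_series

__all__ = ["ConditionSpec", "AnalysisConfig", "RunReport", "run", "compare"]


@dataclass
class ConditionSpec:
    """Generator parameterization of one simulated condition."""

    name: str
    p_bii: float = 0.164
    kappa: float = 0.0
    twist_sigma_bi: float = 7.2
    twist_sigma_bii: float = 6.2
    twist_mean_bi: float = 36.0
    twist_mean_bii: float = 36.0


@dataclass
class AnalysisConfig:
    """Configuration of a comparative synthetic run."""

    reference: ConditionSpec = field(
        default_factory=lambda: ConditionSpec("reference"))
    modified: ConditionSpec = field(
        default_factory=lambda: ConditionSpec("modified", p_bii=0.45))
    n_steps: int = 4
    n_frames: int = 20000
    segment: tuple[int, ...] = (1, 2, 3, 4)
    temperature: float = 300.0
    bin_width: float = 5.0
    n_blocks: int = 5
    seed: int = 0
    output_dir: str = "results/run"
    mask_prmtop: str | None = None  # optional topology to mask alongside
    mask_partner: str = "sugar-c2"

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for key in ("reference", "modified"):
            if key in d and isinstance(d[key], dict):
                d[key] = ConditionSpec(**d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if self.n_steps < 1 or self.n_frames < 2:
            raise ValueError("need n_steps >= 1 and n_frames >= 2")
        if not set(self.segment) <= set(range(1, self.n_steps + 1)):
            raise ValueError("segment steps outside 1..n_steps")
        if self.mask_prmtop is not None and not Path(self.mask_prmtop).exists():
            raise FileNotFoundError(
                f"mask_prmtop does not exist: {self.mask_prmtop}")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Comparative results plus provenance; numbers mirror stored CSVs."""

    conditions: dict
    comparison: dict
    provenance: dict

    def to_json(self, indent=2) -> str:
        return json.dumps({"conditions": self.conditions,
                           "comparison": self.comparison,
                           "provenance": self.provenance},
                          indent=indent, default=float)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _condition_seed(run_seed: int, index: int) -> int:
    # deterministic per-condition seed, kept below 2**31
    return int(np.random.SeedSequence([run_seed, index]).generate_state(1)[0]
               % (2**31 - 1))


def _analyze_condition(spec: ConditionSpec, cfg: AnalysisConfig,
                       seed: int, outdir: Path, log: list[str]) -> dict:
    cdir = outdir / spec.name
    cdir.mkdir(parents=True, exist_ok=True)

    model = TwoStateBackboneModel(p_bii=spec.p_bii, kappa=spec.kappa,
                                  temperature=cfg.temperature, seed=seed)
    series, track = generate_backbone_series(model, cfg.n_steps, cfg.n_frames)
    log.append(f"[{spec.name}] generated {len(series)} dihedral records "
               f"({cfg.n_steps} steps x {cfg.n_frames} frames)")

    labels = classify_substates(series)
    pops = population_stats(labels, segment=cfg.segment,
                            n_blocks=cfg.n_blocks)
    trans = transition_stats(labels)
    seg = series[series["step"].isin(cfg.segment)]
    profile = free_energy_profile(seg["eps_zeta"].to_numpy(),
                                  bin_width=cfg.bin_width,
                                  temperature=cfg.temperature,
                                  frames=seg["frame"].to_numpy(),
                                  n_blocks=cfg.n_blocks)

    helical = HelicalMixtureModel(
        twist_mean_bi=spec.twist_mean_bi, twist_mean_bii=spec.twist_mean_bii,
        twist_sigma_bi=spec.twist_sigma_bi,
        twist_sigma_bii=spec.twist_sigma_bii, seed=seed + 1)
    steps = generate_helical_series(helical, track)
    twist_stats = conditional_twist_stats(steps, track,
                                          n_blocks=cfg.n_blocks)
    seg_steps = steps[steps["step"].isin(cfg.segment)]
    seg_series = seg_steps.groupby("frame").agg(
        twist=("twist", "mean"), stretch=("rise", "mean"),
        bend=("roll", "mean")).reset_index()
    stiff = stiffness(seg_series[["twist", "stretch", "bend"]],
                      temperature=cfg.temperature)

    series.to_csv(cdir / "dihedrals.csv", index=False)
    labels.to_csv(cdir / "substates.csv", index=False)
    trans.to_csv(cdir / "transitions.csv", index=False)
    profile.to_frame().to_csv(cdir / "free_energy_profile.csv", index=False)
    steps.to_csv(cdir / "step_parameters.csv", index=False)
    seg_series.to_csv(cdir / "segment_series.csv", index=False)
    cov_df, k_df = stiff.to_frames()
    cov_df.to_csv(cdir / "covariance.csv")
    k_df.to_csv(cdir / "stiffness.csv")
    log.append(f"[{spec.name}] P(BI) = {pops['p_bi_percent']:.2f}% ; "
               f"sigma_total(twist) = {twist_stats['sigma_total']:.3f} deg")

    return {
        "seed": seed,
        "populations": pops,
        "delta_g_bii_kcal_mol": delta_g_bii(profile),
        "twist_stats": twist_stats,
        "stiffness_diag": dict(zip(stiff.names,
                                   np.diag(stiff.stiffness))),
        "_profile": profile,
        "_stiffness": stiff,
    }


def run(config: AnalysisConfig) -> RunReport:
    """Execute the full comparative pipeline; deterministic under the seed."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    if config.mask_prmtop is not None:
        from .masking import MaskSpec, apply_mask, balanced_redistribution
        from .prmtop import diff_topologies, read_prmtop, write_prmtop

        top = read_prmtop(Path(config.mask_prmtop).read_text())
        mspec = MaskSpec(partner=config.mask_partner, zero_charges=True)
        mspec.redistribution = balanced_redistribution(top, mspec)
        masked = apply_mask(top, mspec, log)
        (outdir / "masked.prmtop").write_text(write_prmtop(masked))
        diff = diff_topologies(top, masked)
        (outdir / "mask_diff.txt").write_text(diff.summary())
        log.append(f"masked topology written; "
                   f"{len(diff.changed_sections())} sections changed")

    results = {}
    profiles = {}
    stiffs = {}
    for i, spec in enumerate((config.reference, config.modified)):
        seed = _condition_seed(config.seed, i)
        res = _analyze_condition(spec, config, seed, outdir, log)
        profiles[spec.name] = res.pop("_profile")
        stiffs[spec.name] = res.pop("_stiffness")
        results[spec.name] = res

    ddg = basin_free_energy_difference(profiles[config.reference.name],
                                       profiles[config.modified.name])
    rel = relative_change(stiffs[config.reference.name],
                          stiffs[config.modified.name])
    rel.to_csv(outdir / "relative_changes.csv", index=False)
    comparison = {
        "delta_p_bi_points": (
            results[config.modified.name]["populations"]["p_bi_percent"]
            - results[config.reference.name]["populations"]["p_bi_percent"]),
        "delta_delta_g_kcal_mol": ddg["delta_delta_g"],
        "stiffness_change_percent": dict(zip(
            rel["variable"], rel["stiffness_change_percent"])),
    }
    report = RunReport(
        conditions=results, comparison=comparison,
        provenance={"seed": config.seed, "config_digest": config.digest(),
                    "version": __version__,
                    "config": asdict(config)},
    )
    report.save(outdir / "report.json")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return report


def compare(report_a: RunReport | dict, report_b: RunReport | dict,
            condition: str | None = None) -> pd.DataFrame:
    """Tabulate population, Delta-Delta-G and stiffness deltas of two runs.

    Compares the named condition (default: first) of each report; raises
    when the two reports analysed different variable sets.
    """
    def unpack(r):
        d = r if isinstance(r, dict) else json.loads(r.to_json())
        name = condition or next(iter(d["conditions"]))
        if name not in d["conditions"]:
            raise KeyError(f"condition {name!r} absent from report")
        return d["conditions"][name]

    a, b = unpack(report_a), unpack(report_b)
    if set(a["stiffness_diag"]) != set(b["stiffness_diag"]):
        raise ValueError("reports use different stiffness variable sets")
    rows = [("p_bi_percent", a["populations"]["p_bi_percent"],
             b["populations"]["p_bi_percent"])]
    rows.append(("delta_g_bii_kcal_mol", a["delta_g_bii_kcal_mol"],
                 b["delta_g_bii_kcal_mol"]))
    for var in a["stiffness_diag"]:
        rows.append((f"stiffness_{var}", a["stiffness_diag"][var],
                     b["stiffness_diag"][var]))
    df = pd.DataFrame(rows, columns=["quantity", "run_a", "run_b"])
    df["delta"] = df["run_b"] - df["run_a"]
    df["relative_percent"] = 100.0 * df["delta"] / df["run_a"].where(
        df["run_a"] != 0)
    return df
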