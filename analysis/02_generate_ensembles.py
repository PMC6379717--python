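#!/usr/bin/env python
"""Generate the synthetic study ensembles for every sequence case.

Each 15-mer case is represented by its central-segment BI population
(the generator's field probability); the masked condition emulates the
removal of methyl-sugar clashes by a raised BII population.  A
nearest-neighbor coupling kappa = 1 reproduces the BII anti-correlation
of adjacent steps.  Writes per-case dihedral/substate/step-parameter
CSVs to results/ensembles/.
"""

from pathlib import Path

import pandas as pd

from methylflex.synth.backbone import (TwoStateBackboneModel,
                                       generate_backbone_series)
from methylflex.synth.helical import (HelicalMixtureModel,
                                      generate_helical_series)

OUT = Path(__file__).resolve().parent.parent / "results" / "ensembles"

#: Central-segment P(BI) percentages parameterizing each studied case.
CASES = {
    "AT": 83.6, "AU": 75.5, "CG": 73.4, "CstarG": 78.8,
    "AA": 88.3, "CT": 77.2, "GT": 76.4,
}
#: Emulated BII stabilization when methyl-sugar clashes are removed
#: (~2 kcal/mol on the ApT basin -> strongly raised BII population).
MASKED_P_BII = 0.45

N_STEPS = 4       # central segment, steps 6-9 of the 15-mer
N_FRAMES = 20000
KAPPA = 1.0
SEED = 20260921


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    summaries = []
    for i, (case, p_bi) in enumerate(CASES.items()):
        for cond, p_bii in (("reference", 1 - p_bi / 100.0),
                            ("masked", MASKED_P_BII)):
            seed = SEED + 10 * i + (0 if cond == "reference" else 1)
            model = TwoStateBackboneModel(p_bii=p_bii, kappa=KAPPA,
                                          seed=seed)
            series, track = generate_backbone_series(model, N_STEPS,
                                                     N_FRAMES)
            helical = HelicalMixtureModel(seed=seed + 5)
            steps = generate_helical_series(helical, track)
            d = OUT / case / cond
            d.mkdir(parents=True, exist_ok=True)
            series.to_csv(d / "dihedrals.csv", index=False)
            track.to_csv(d / "substates.csv", index=False)
            steps.to_csv(d / "step_parameters.csv", index=False)
            summaries.append({
                "case": case, "condition": cond, "p_bii_field": p_bii,
                "n_steps": N_STEPS, "n_frames": N_FRAMES, "kappa": KAPPA,
                "seed": seed,
            })
    pd.DataFrame(summaries).to_csv(OUT / "manifest.csv", index=False)
    print(f"generated {len(summaries)} ensembles "
          f"({N_STEPS} steps x {N_FRAMES} frames each) under {OUT}")


if __name__ == "__main__":
    main()
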