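#!/usr/bin/env python
"""Build fixture topologies and apply the three methyl-masking variants.

For the solvated ApT dinucleotide fixture, the methyl group's pairwise
vdW interactions are masked against (a) all water, (b) the 5'-neighbor
sugar C2' group and (c) the 5'-neighbor base, with methyl charges
removed and redistributed.  Writes the masked prmtops and an editing
footprint table to results/topologies/.
"""

from pathlib import Path

import pandas as pd

from methylflex.masking import (MaskSpec, apply_mask,
                                balanced_redistribution)
from methylflex.prmtop import diff_topologies, read_prmtop, write_prmtop
from methylflex.synth.fixtures import make_prmtop_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "topologies"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    top = read_prmtop(make_prmtop_fixture("ta-solvated"))
    (OUT / "reference.prmtop").write_text(write_prmtop(top))
    rows = []
    for partner in ("water", "sugar-c2", "base"):
        spec = MaskSpec(partner=partner, zero_charges=True)
        spec.redistribution = balanced_redistribution(top, spec)
        log: list[str] = []
        masked = apply_mask(top, spec, log)
        name = f"masked_{partner.replace('-', '_')}.prmtop"
        (OUT / name).write_text(write_prmtop(masked))
        diff = diff_topologies(top, masked)
        rows.append({
            "partner": partner,
            "charge_entries_changed": diff.n_changed("CHARGE"),
            "lj_types_before": top.ntypes,
            "lj_types_after": masked.ntypes,
            "total_charge_before_e": top.total_charge,
            "total_charge_after_e": masked.total_charge,
        })
        print(f"[{partner}] " + " | ".join(log))
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "masking_footprint.csv", index=False)
    print("\nEditing footprint (total charge conserved in every variant):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
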