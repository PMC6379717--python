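# methylflex

Tools for studying how the C5-methyl group of thymine (and of
5-methylcytosine, the epigenetic DNA mark) couples to the DNA backbone
fine structure and to duplex flexibility — by *selectively masking* the
methyl group's non-bonded interactions in Amber force-field topologies
and analyzing the resulting conformational statistics.

The package is aimed at molecular-modelling practitioners who run
comparative MD studies of DNA methylation: it provides the topology
surgery, the backbone/geometry/mechanics analyses, and a synthetic-data
generator that emulates the statistical structure of such trajectories
so that every stage is testable without running MD.

## What it computes

**Backbone substates.** A dinucleotide step adopts BI or BII depending
on the ε (C4′–C3′–O3′–P) and ζ (C3′–O3′–P–O5′) torsions:

    BI:  ε − ζ < 0        BII:  ε − ζ > 0

Populations are pooled over a central segment, and free-energy profiles
along ε − ζ follow from Boltzmann inversion of the sampled histogram,

    F(x) = −k_B T · ln p(x),

anchored at the occupied minimum, with block-averaged errors.  Basin
free energies give ΔG(BI→BII) = −k_B T ln(P_BII/P_BI) and, between two
conditions, ΔΔG.

**Topology masking.** Methyl charges (C7, H71–H73) are removed and
redistributed onto adjacent base atoms (total charge conserved to
10⁻⁶ e), and the pairwise 12-6 Lennard-Jones terms between the methyl
group and a partner group — all water, the 5′-neighbor sugar C2′/H2′/H2′′,
or the 5′-neighbor base — are set to exactly zero by atom-type
splitting, leaving every other pair numerically untouched.

**Geometry coupling.** Sugar pseudorotation phases
(Altona–Sundaralingam; C3′-endo ≈ 18°, C2′-endo ≈ 162°), weak
C–H···O hydrogen bonds (H6/H8 donors to O3′/O5′), methyl-to-C2′
distances, and normalized 2-D density maps against ε − ζ.

**Harmonic mechanics.** Base-pair step parameters (shift, slide, rise,
tilt, roll, twist) by the mid-frame construction, segment-level
twist/stretch/bend, and the stiffness matrix

    K = k_B T · C⁻¹

from the fluctuation covariance C, with mode-wise relative changes
between a reference and a masked condition and Gaussianity diagnostics
guarding the harmonic premise.

**Synthetic data.** A two-basin wrapped-Gaussian (ε, ζ) generator with
per-step BII probabilities, a pairwise Gibbs penalty exp(−κ) on
adjacent simultaneous BII (the nearest-neighbor anti-correlation), a
substate-conditional twist mixture (BI broader than BII), an idealized
all-atom B-DNA duplex builder, and self-consistent prmtop fixtures.

## Worked example

```python
from methylflex.prmtop import read_prmtop
from methylflex.masking import MaskSpec, apply_mask, balanced_redistribution
from methylflex.synth.fixtures import make_prmtop_fixture
from methylflex.synth.backbone import TwoStateBackboneModel, generate_backbone_series
from methylflex.backbone import (classify_substates, population_stats,
                                 free_energy_profile, delta_g_bii)

top = read_prmtop(make_prmtop_fixture("ta-solvated"))
spec = MaskSpec.sugar_c2(zero_charges=True)
spec.redistribution = balanced_redistribution(top, spec)
masked = apply_mask(top, spec)
print(f"total charge: {top.total_charge:+.6f} e -> {masked.total_charge:+.6f} e")

model = TwoStateBackboneModel(p_bii=0.164, seed=1)
series, _ = generate_backbone_series(model, n_steps=4, n_frames=50_000)
pops = population_stats(classify_substates(series), n_blocks=5)
prof = free_energy_profile(series["eps_zeta"].to_numpy(), bin_width=5.0,
                           temperature=300.0)
print(f"P(BI) = {pops['p_bi_percent']:.2f} +/- {pops['error_percent']:.2f} %")
print(f"dG(BI->BII) = {delta_g_bii(prof):.3f} kcal/mol")
```

prints

```
total charge: -1.000000 e -> -1.000000 e
P(BI) = 83.65 +/- 0.06 %
dG(BI->BII) = 0.973 kcal/mol
```

i.e. masking conserves the molecular charge exactly, and a generator
configured with a 16.4% BII field probability yields an 83.65 ± 0.06%
BI population whose basin free-energy cost, +0.973 kcal/mol, matches
the closed form −k_B T ln(16.4/83.6) = 0.971 kcal/mol at 300 K.

## Analysis pipeline

The numbered drivers under `analysis/` run the full comparative study
on synthetic ensembles and write tables under `results/`:

1. `01_mask_topologies.py` — the three masking variants and their
   editing footprint,
2. `02_generate_ensembles.py` — per-case reference/masked ensembles,
3. `03_backbone_substates.py` — populations, profiles, ΔΔG,
4. `04_geometry_coupling.py` — pucker coupling, H-bonds, methyl
   distances,
5. `05_helical_stiffness.py` — conditional twist widths, stiffness,
   relative changes,
6. `06_compare_conditions.py` — end-to-end two-condition run with
   report traceability.

The same flow is scriptable via the `methylflex` CLI
(`generate`, `mask`, `analyze`, `compare`, `report`); see
`methylflex --help`.

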