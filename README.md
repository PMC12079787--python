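# bondbreak

Automated generation of nonequilibrium molecular conformers by forced,
stepwise bond breaking — the data-generation workflow behind reactive
machine-learning interatomic potentials for small organic molecules.

Training data for reactive potentials must contain the stretched, partially
dissociated geometries that occur along reaction pathways, yet equilibrium
datasets and transition-state searches barely sample them. `bondbreak`
produces such geometries systematically: for every chemically unique bond of
a molecule it walks a staged elongation schedule, relaxing and thermalizing
the rest of the molecule at each step, and labels the sampled conformers
with finite-temperature occupation quantities that quantify the emerging
radical character.

## What it does

For a bond of equilibrium length *l*₀, the default schedule stretches to
2·*l*₀ in 10 steps and on to 3·*l*₀ in 5 more (per-step increment
(*n*ₑ − 1)·*l*₀/*n*steps within each stage). At each target distance:

* the two bond atoms are displaced symmetrically along the bond axis and
  then held at fixed positions;
* the remaining atoms are relaxed (constrained L-BFGS-B) and the relaxed
  frame saved;
* a 1 ps NVT Langevin trajectory (0.5 fs timestep, snapshot every 10 fs)
  runs from the relaxed frame, and a greedy farthest-point ("minimax")
  selection keeps the 10 most diverse of its 100 snapshots.

A bond therefore yields 15 + 150 = 165 conformers. Bonds are deduplicated
beforehand by an environment hash (per-shell sums of 5-integer atom
descriptors over the radius-3 neighborhood), so methane contributes one
trajectory, not four.

Labels use the Fermi-smearing convention: spin-orbital occupations follow
the Fermi–Dirac distribution at electronic temperatures of 0, 1000 and
5000 K, and the fractional-orbital-density number

N_FOD = Σ_{ε<E_F} (1 − fᵢ) + Σ_{ε≥E_F} fᵢ

measures radical/multireference character (≈ 0 for a gapped closed shell,
2 for a homolytically dissociated bond). Calculators are pluggable through
an energy/forces/dipole/orbital-energies contract; a bundled analytic toy
force field plus mock spectrum model exercises everything without DFT.

## Worked example

Stretch ethane's C–C bond with the toy calculator:

```python
from bondbreak import (
    SamplerConfig, embed_geometry, parse_molecule, run_bond_trajectory,
    label_geometry,
)
from bondbreak.datasetio import records_from_trajectory, write_dataset
from bondbreak.toy_models import ToyForceField

ethane = parse_molecule("CC", "ethane")
geometry = embed_geometry(ethane, seed=0)
calc = ToyForceField(ethane, reference_bond=(0, 1))

result = run_bond_trajectory(ethane, geometry, (0, 1), calc, SamplerConfig(rng_seed=0))
print(f"conformers: {result.n_conformers} "
      f"({len(result.opt_geometries)} opt + {len(result.md_geometries)} md)")

for step in (0, 7, 14):
    frame = result.opt_geometries[step]
    label = label_geometry(frame, calc)
    print(f"step {step:2d}: r(C-C) = {frame.distance(0, 1):.3f} A, "
          f"N_FOD(5000 K) = {label.n_fod_by_temperature[5000.0]:.3f}")

manifest = write_dataset(records_from_trajectory(result), "ethane_cc")
print(manifest)
```

prints

```
conformers: 165 (15 opt + 150 md)
step  0: r(C-C) = 1.663 A, N_FOD(5000 K) = 0.010
step  7: r(C-C) = 2.722 A, N_FOD(5000 K) = 1.826
step 14: r(C-C) = 4.536 A, N_FOD(5000 K) = 2.000
{'total': 165, 'opt': 15, 'md': 150, 'embed': 0, 'discarded': 0,
 'length_unit': 'Angstrom', 'energy_unit': 'eV'}
```

The accounting shows one full per-bond run (15 relaxed frames, 150 diverse
MD frames); N_FOD climbs from ~0 at mild stretch to 2.0 once the bond is
fully broken — the toy spectrum's HOMO–LUMO gap closes and the two frontier
electrons smear equally over the degenerate manifold, the signature of a
separated biradical. The dataset lands in `ethane_cc/` as an HDF5 container,
an extended-XYZ file with per-frame provenance, and the printed manifest.

The same pipeline is scriptable from the shell:

```
bondbreak prepare --input molecules.csv --max-heavy 7 --elements H,C,N,O --seed 0
bondbreak bonds   --input molecules.csv --radius 3 --out bonds.tsv
bondbreak sample  --input molecules.csv --calculator toy --out dataset/ --seed 0
bondbreak export  --input dataset/ --format extxyz --out dataset.extxyz
bondbreak evaluate --triples triples.csv
```

`bondbreak evaluate` computes reaction energetics (P-R reaction energy,
TS-R barrier height, TS-P) from reactant/transition-state/product energy
triples; the `evaluate` module also provides bond-dissociation energies
(Σ fragment energies − reactant energy) and grouped MAE reports.

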