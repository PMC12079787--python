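# Methods

## The sampling model

`bondbreak` generates highly nonequilibrium molecular conformers by forcing
individual bonds to break. Reaction profiles sampled from equilibrium MD or
transition-state searches rarely visit the stretched, partially dissociated
geometries that reactive interatomic potentials must learn; artificially
elongating one bond at a time, while letting the rest of the molecule relax
and thermalize, visits exactly that region of configuration space at a
predictable cost.

For a selected bond with equilibrium length *l*₀ the workflow walks a staged
schedule of absolute target distances. With stage list
`[(n₁, s₁), (n₂, s₂), …]` each stage stretches the bond from the previous
endpoint to *n*ᵢ·*l*₀ in *s*ᵢ equal increments, i.e. a per-step increment of
(*n*ᵢ − *n*ᵢ₋₁)·*l*₀/*s*ᵢ. The default `[(2.0, 10), (3.0, 5)]` reaches twice
the equilibrium length after step 10 and three times after step 15,
concentrating samples in the 1–2 bond-length window where rearrangements and
radical formation concentrate. Stage endpoints are landed exactly (the last
increment is assigned, not accumulated), so `targets[-1]/l0` equals the final
multiplier with no floating-point drift.

At each step:

1. **Elongate** — both bond atoms are displaced by ±(target − d)/2 along the
   bond axis. The symmetric split preserves the fragment midpoint and avoids
   net drift; all other atoms are untouched (bit-identical).
2. **Constrained optimization** — all atoms except the two bond atoms are
   relaxed (L-BFGS-B over the free coordinates only, so the constraint is
   exact by construction). Convergence means max per-atom |force| on free
   atoms ≤ `opt_fmax` (default 0.05 eV/Å, max 500 iterations). The relaxed
   frame is saved.
3. **Constrained MD** — NVT dynamics from the relaxed frame with the bond
   atoms pinned: BAOAB Langevin splitting at 300 K with friction 0.01 fs⁻¹
   (plain velocity Verlet when the thermostat is disabled), dt = 0.5 fs for
   1 ps, a snapshot every 10 fs (100 frames). Velocities are
   Maxwell–Boltzmann at the MD temperature with fixed atoms zeroed, drawn
   from a seeded generator.
4. **Diversity cap** — up to `snapshot_cap` (default 10) frames are kept per
   MD segment by greedy farthest-point selection.

The next step continues from the relaxed geometry of the current step
(`continue_from="opt"`, the deterministic default; the final MD frame can be
used instead). With defaults and no calculator failures a bond yields
15 optimization + 150 MD = 165 conformers.

The MD temperature and thermostat are exposed rather than hard-coded because
they are tuning choices, not part of the method's identity; Langevin at
300 K is a standard NVT default. Both bond atoms are held at fixed Cartesian
positions during optimization and MD — the strictest reading of "fixed
bond" — with a distance-only constraint mode (`constraint_mode="distance"`,
SLSQP equality constraint) behind a flag for users who want the bond free to
translate and rotate.

## Bond deduplication

Chemically equivalent bonds (the four C–H bonds of methane) should be
sampled once. Each atom gets a 5-integer descriptor — atomic number, bonded
hydrogens, neighbor count, total valence, aromatic flag — and a bond is
keyed by its two endpoints' radius-3 neighborhood descriptors added
together. Two representation choices matter:

* The five components are kept as a tuple, never collapsed to one scalar, so
  distinct component values cannot alias through addition.
* The neighborhood sums are kept **per shell** (topological distance 0, 1,
  2, 3) rather than collapsed across shells. On molecules of graph diameter
  ≤ 3 every atom's collapsed radius-3 sum equals the whole-molecule total,
  which would merge ethane's C–C and C–H bonds into one class; the
  shell-resolved key keeps them apart while remaining symmetric in the two
  atoms and invariant under relabeling.

The hash is deliberately weaker than canonical graph labeling: bonds in the
same automorphism orbit always share a key (tested against a brute-force
automorphism oracle), but distinct orbits may merge. That direction of error
only costs a little sampling redundancy removal, never correctness.
Deduplication can run per molecule or across a whole input set.

## Snapshot diversity

The descriptor of a frame is its sorted vector of all pairwise interatomic
distances — invariant under rigid motions and atom relabeling, and cheap at
these molecule sizes. Selection is greedy farthest-point ("minimax")
sampling in Euclidean descriptor space: seed with the earliest frame, then
repeatedly add the frame whose minimum distance to the selected set is
largest, breaking ties toward the smaller index. The greedy rule guarantees,
at every addition, that no remaining candidate has a larger minimum distance
(asserted as a property test); exact max–min subset selection is NP-hard and
not attempted.

## Finite-temperature occupations and N_FOD

Stretching a bond homolytically creates biradical character that closed-shell
labels cannot represent and per-geometry open-shell treatments cannot
automate. The workflow's labeling convention is Fermi smearing: all levels
are spin orbitals with occupancy in [0, 1], and occupations follow the
Fermi–Dirac distribution f(ε) = 1/(1 + exp((ε − E_F)/k_B T_el)) with the
Fermi level solved by bisection until Σfᵢ matches the electron count to
1e-10 (overflow-safe via the logistic function).

Conventions at the edges:

* **T_el = 0** — occupations are a step function. When a gap separates the
  highest filled from the lowest empty level, E_F is placed mid-gap (the
  same place the T > 0 bisection converges to); levels degenerate at the
  Fermi cut share the remaining electrons equally. Putting E_F *at* the
  HOMO instead would make a gapped closed-shell spectrum carry a spurious
  N_FOD of 1.
* **Fully filled / empty spectra** — E_F sits above (below) every level.

The fractional-orbital-density number is the occupation-space sum

    N_FOD = Σ_{εᵢ < E_F} (1 − fᵢ) + Σ_{εᵢ ≥ E_F} fᵢ,

the reduction of the spatial FOD integral for orthonormal orbitals
(real-space grids are out of scope). Levels within 1e-9 energy units of E_F
count as "not below", which makes the dissociated-biradical limit — a
degenerate frontier manifold at E_F sharing two electrons — evaluate to
exactly 2. Limits: N_FOD → 0 for any gapped spectrum as T_el → 0, and all
fᵢ → n/N as T_el → ∞.

The recommended smearing temperature follows the empirical linear rule
T_el/K = 5000 + 20000·a_x in the Fock-exchange fraction a_x of the
functional; a pure GGA-type functional gets 5000 K. Labels default to
electronic temperatures of 0, 1000 and 5000 K. Evaluations that fail are
discarded from the labeled set rather than imputed — the same policy the
sampler applies to failed optimizations, where the step is counted in
`discarded_count` and the loop continues from the stretched geometry.

## Toy models

Real labeling requires DFT; the bundled fixtures stand in with the right
*shapes* at negligible cost, so the whole pipeline is exercisable and
testable end to end.

**ToyForceField** — harmonic bonds (rest lengths near typical embedded
values, e.g. C–H 1.09 Å, C–C 1.53 Å, contracted 13 % per unit of bond order
above one; stiffness 15 eV/Å² for X–H, 25 eV/Å² for heavy pairs), harmonic
angles (109.47° at saturated centers, 120° at unsaturated ones, 3 eV/rad²),
and exponential repulsion (1 eV amplitude, 0.4 Å decay) between atoms at
graph distance ≥ 3. Forces are the analytic gradient, verified against
central finite differences to 1e-4. The X–H stiffness is kept on the soft
side of physical so the fastest oscillation period (~14 fs) is comfortably
resolved at dt = 0.5 fs, keeping the velocity-Verlet shadow-energy
fluctuation well under 1 % of the thermal kinetic energy. The rest lengths
approximating embedded geometry keep constraint forces modest at the first
elongation step. The potential is deliberately **non-reactive**: the term
list is frozen at construction, so hydrogen transfers, radical quenching and
other rearrangements that the real workflow captures are out of the toy's
(and the test suite's) scope. A `fail_predicate` hook injects evaluation
failures to exercise the discard path.

**ToySpectrumModel** — a mock spin-orbital ladder whose HOMO–LUMO gap decays
as g(r) = g₀·exp(−(r − r₀)/w) (g₀ = 8 eV, w = 0.3 Å) in the length r of a
designated reference bond: continuous, strictly decreasing. At rest the
spectrum is gapped and N_FOD(5000 K) ≈ 0; at three times the rest length the
four frontier spin levels are effectively degenerate at E_F with two
electrons and N_FOD → 2, emulating homolytic biradical formation. N_FOD at
fixed temperature is non-decreasing in r, which drives the end-to-end
sampler + labeling tests.

The fixture suite is deterministic per seed and covers the worked species
(methane, ethane, 2,2-dimethylbutane, 1-aminoethanol, ethanamine, ethanimine,
benzene) plus randomly assembled H/C/N/O molecules with at most seven heavy
atoms. Because ethanamine itself has no C=N bond, the imine species is
included alongside it so double-bond stretching is representable.

What passing tests show — and what they do not: the workflow accounting,
constraint exactness, determinism and occupation analysis are validated
exactly; the chemistry of real bond breaking (rearrangements, charge
transfer, actual radical energetics) is not, because the toy potential
cannot express it. Conclusions about real data require plugging in a real
calculator behind the same contract.

## Molecule preparation

Input is SMILES (single strings or `identifier,smiles` tables). Hydrogens
are always made explicit — the workflow stretches C–H bonds, so the bond
enumeration must see them. The default admission filter keeps neutral
closed-shell molecules of H, C, N and O with at most seven heavy atoms;
charged or radical inputs are parseable behind a flag. Embedding is a
contract (one low-energy conformer, deterministic per seed, bonded distances
in [0.7, 2.0] Å); the default implementation is RDKit ETKDGv3 with a fixed
random seed and a single thread, followed by a best-effort MMFF/UFF cleanup.
Molecules with stereocenters are embedded as-is, without stereoisomer
enumeration. One conformer per molecule: conformational ensembles are the
MD stage's job.

## Dataset layout

Records persist to an HDF5 container grouped molecule → bond → step →
frame, with a global order attribute, plus a flat extended-XYZ export whose
per-frame comment line carries the provenance as key=value pairs, and a JSON
manifest with per-origin counts. Units on disk: Å for coordinates, a
declared energy unit (default eV) in the file metadata. Coordinates and
label quantities are stored as float64, so round trips are exact in
practice (declared: 1e-8 Å, 1e-10 energy). Malformed or truncated inputs
are reported with the offending record/frame index.

## Problem sizes

The test suite and the acceptance script run the complete default workflow
(15 steps × 1 ps MD at 0.5 fs) on a single ethane C–C bond — about 30,000
force evaluations, 15–25 s on one CPU — and shrunk configurations
(2 steps × 50 fs) where only mechanics, not accounting, is under test.
Property tests over random spectra use up to 1000 draws. These sizes are
chosen so the whole suite runs in about half a minute while still covering
one full-scale per-bond run end to end.

## Known limitations

* The toy calculator cannot produce rearrangements, so discard paths are
  tested by fault injection rather than by genuine non-convergence.
* The bond hash may merge distinct automorphism orbits (by design); the
  per-shell key makes this rare for molecules in scope but not impossible.
* The Fermi solver assumes a discrete, finite spin-orbital spectrum; no
  degeneracy weights or k-point sums.
* Single molecules only: no periodic systems, no intermolecular sampling,
  no transition-state search.
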