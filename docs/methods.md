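# Methods

## Model

The package simulates mixtures of three coarse-grained molecule kinds in
a periodic L_x × L_y × L_z box (L_x = L_y; slab interfaces form
perpendicular to z, the long axis):

* **colloid** — one hard sphere, radius R_col (a globular macromolecule);
* **polymer** — N_mono hard beads of radius R_mono on a freely jointed
  chain (a disordered macromolecule);
* **tadpole** — one head bead (R_head = R_col) grafted to a tail chain of
  N_tail beads (R_tail = R_mono): a protein with one globular domain and
  one intrinsically disordered region.  The head is bonded to tail
  bead 0; with N_tail = N_mono a tadpole is exactly a colloid fused to a
  polymer.

All interactions are purely repulsive, so every allowed configuration has
the same (zero) energy and phase behaviour is decided by entropy alone:
polymers gain conformational entropy when colloids cluster (depletion
flocculation), which can drive liquid–liquid phase separation and gives
tadpoles their surfactant character (head prefers the colloid-rich
phase, tail the polymer-rich phase).

Pair interactions are hard-sphere, U(r) = ∞ for r < R_i + R_j (strict
inequality — contact is allowed; the boundary is a set of measure zero
but the convention is fixed for testability).  Bonds are hard square
wells permitting R_i + R_j ≤ r < R_i + R_j + 3 R_tail.

### Units and parameters

Lengths are in ℓ (= 12.5 nm when mapped to the nuclear environment),
energies in ε = k_BT, and time in τ, defined as the time a tail-sized
bead takes to diffuse its own size.  That definition absorbs the solvent
viscosity: Stokes–Einstein becomes D_i = R_tail³/(6 R_i) ℓ²/τ, so
D_tail = R_tail²/6 exactly and larger beads diffuse more slowly as 1/R.

| parameter | default | meaning |
|---|---|---|
| R_col = R_head | 0.44 ℓ | large-bead radius |
| R_mono = R_tail | 0.0908 ℓ | small-bead radius |
| N_mono | 30 | beads per polymer |
| N_tail | 15–30 | beads per tadpole tail |
| δt | 0.4 τ | MC time increment |
| u_W | 1 ε | WCA energy scale (soft mode) |
| k_F | 7.822 / 2.558 ε/ℓ² | FENE constant, tail–tail / head–tail |
| T | 300 K | SI conversion temperature |

These sizes give an isolated 30-bead chain a size ratio
q = R_g/R_col ≈ 2.3 (the protein limit q > 1), the ratio of human RNA
polymerase II's disordered C-terminal domain to its globular core; the
package's own long-run protocol (`tadsim.protocols.measure_q`, eight
independent 1.2 × 10⁶-sweep chains) measures q = 2.22 ± 0.02.  The
per-axis trial-step scale obeys sqrt(2 D_i δt) < R_tail for every
species (0.033 ℓ for small beads, 0.015 ℓ for large), keeping hard-mode
acceptance high and the dynamics quasi-Brownian.

## Dynamic Monte Carlo

Each sweep advances time by δt: every mobile bead, visited in a fresh
random permutation (a fixed order would introduce drift artifacts),
attempts one displacement drawn per axis from Normal(0, 2 D_i δt) and
accepted with probability min[1, exp(−ΔU)].  In hard mode this reduces
to accepting iff the moved bead's final overlap/bond energy is zero;
ΔU evaluation short-circuits on the first violation.  Moves are
single-bead only — cluster moves would scramble the dynamic
interpretation of δt.  Positions are stored wrapped into [0, L); all
pair geometry uses the minimum-image convention.

Hard-mode overlap checks use a linked cell list (cell edge ≥ the largest
interaction distance) updated in place on accepted moves; boxes thinner
than three cells in any dimension fall back to an O(N²) scan.  Soft mode
keeps per-bead Verlet lists built with a 0.8 ℓ skin over the per-pair
WCA cutoffs and rebuilt whenever accumulated displacements could bridge
half the skin; bridging half the skin within one sweep would require a
>10 σ step, so stale-list errors are negligible.  The rebuild uses a
multi-shell cell search (cells of edge ~cutoff/2, ±2 shells) because the
thin boxes used here do not fit three cutoff-sized cells transversely.

Seeding: a run is reproducible from (initial configuration, RunParams)
alone; per-chunk kernel seeds are derived from the run seed via a
PCG64 stream, and kernels use numba's seeded RNG.

## Initialization

Random sequential addition jams near φ_col ≈ 0.3, so dense starting
states are built in two stages.  Molecules are
placed at random — chains grown bead by bead with bond lengths inside
the hard window — tolerating overlaps, then an athermal push-off
resolves them: every overlapping pair is nudged apart along its centre
line, bonds are re-projected into their windows, and the bead radii ramp
up in stages (0.6, 0.8, 0.9, 1.0 of full size).  The result is verified
to have exactly zero hard energy; failure to converge raises an error
naming the residual violation count.  The "slab" layout pre-segregates
colloids (low z) from polymers/tadpoles (high z) to shortcut interface
formation, with the colloid slab sized for a plausible dense-phase
packing.

## Soft mode and interfacial tension

Hard systems have no defined forces, so tensions are measured in a
softened variant: WCA repulsion
U_W = 4 u_W (s⁻¹² − s⁻⁶ + ¼) for s = r/R_W < 2^(1/6), R_W = R_i + R_j,
plus FENE bonds U_F = −½ k_F R_F² ln(1 − (r/R_F)²) with
R_F = R_i + R_j + 4 R_tail.  The FENE constants above make the soft mean
bond lengths match the hard square-well means (hard closed form
⟨r⟩ = (3/4)(b⁴−a⁴)/(b³−a³) ≈ 0.3545 ℓ tail–tail; the soft means follow
from 1-D quadrature of r² exp(−U) and agree within a few percent — the
matching was evidently done per-pair, which is what the quadrature
check encodes).  WCA evaluation at r → 0 returns +∞ in Metropolis
context (guaranteed rejection) and raises in force evaluations; FENE
over-extension is a move-rejection signal, not a crash, except in
explicit force/virial calls where it names the offending bond.

The pressure tensor is the box-integrated virial
P_αβ = (N k_BT δ_αβ + Σ_pairs f_ij,α r_ij,β)/V (WCA over all pairs in
range, bonded or not; FENE along bonds), and the tension of a
two-interface slab is the Kirkwood–Buff integral evaluated in closed
form from the global anisotropy,

    γ_snap = (L_z/2) (P_zz − (P_xx + P_yy)/2),

the ½ accounting for the two interfaces a periodic slab necessarily
contains; the sign convention (σ = −P) makes γ of a stable interface
positive.  No z-resolved (Irving–Kirkwood) profile is needed because
only the integral enters.  Scaled and SI forms use the interfacial-width
estimate δ = 2 R_col (1 + q) = 2.904 ℓ = 36.3 nm and
k_BT/ℓ² = 26.51 μN m⁻¹ at 300 K; errors propagate linearly.

**Statistics.**  The instantaneous anisotropy of a steep WCA system
fluctuates enormously (σ(γ_snap) ≈ 7 ε/ℓ² for ~1500 beads in a
4 × 4 × 6.75 box) and carries a slow component tied to interface
configuration changes, so successive snapshots are far from independent.
`measure_tension` therefore averages independent runs and quotes the
standard error over run means — the honest error — rather than the
naive per-snapshot SEM.

**Finite-size caveat.**  Two interfaces of width δ = 2.9 ℓ need
L_z ≳ 2δ plus bulk on both sides.  In a quarter-volume box
(4 × 4 × 6.75, counts scaled by ¼ from the 374 + 188 reference system)
the interfaces overlap completely and the measured tension is
statistically zero (−0.25 ± 0.43 ε/ℓ² pooled over three independent
20 000-sweep runs) even though the density contrast survives.  The
package's reduced-scale tension studies therefore use boxes with
L_z ≥ 12 ℓ; desk-scale results are ordering-level checks, not
quantitative reproductions of the full-size (6 × 6 × 12,
200-snapshot) values.

## Analysis

**Profiles.**  φ(z) per species uses an exact sphere–slab partition:
each bead contributes to a bin the exact volume of its sphere's
intersection with that z-slab (cyclically wrapped).  This makes volume
conservation between profile and global composition exact and keeps
profiles smooth although a colloid diameter (0.88 ℓ) spans several of
the default 0.5 ℓ bins.  Solvent fraction is φ_s = 1 − Σ_species φ.

**Interfaces and alignment.**  The interface locator smooths the
reference-species profile (3-bin boxcar), estimates the two plateau
levels as the 10th/90th percentiles, and takes the midpoint crossings
bounding the longest above-midpoint run (after a 3-bin morphological
closing/opening to bridge noise); the crossing with φ ascending in +z
is "first" by convention.  Colloids are the reference species wherever
present (they exist in every studied two-phase system); tadpoles
otherwise.  Snapshot-to-snapshot alignment maximizes the circular
cross-correlation of reference profiles — far more robust for noisy
single-snapshot profiles than aligning on per-snapshot interface
detections — then the stack is placed so the ascending interface of the
mean sits at L_z/4.

**Bulk compositions and tie lines.**  Per phase, φ is averaged over bins
farther than a margin (default δ = 2.904 ℓ) from both interfaces;
phases thinner than 2 × margin raise an explicit error.  Tie lines
average coexisting compositions over independent runs, re-pairing
phases by descending colloid φ; exported errors are 2 × SEM (the
plotting convention for phase-diagram error diamonds).

**Radius of gyration.**  Chains are unwrapped along their bond
connectivity before computing R_g (equal bead weights; a broken-bond
step > 2× the bond window raises a topology error).  For tadpoles both
tail-only (default) and head-inclusive variants exist; for pure
polymers the distinction is moot, and q = R_g/R_col reported by the
package uses the tail-only convention.

**State classification.**  `classify_state` labels a trajectory
macrophase (interface detection and bulk extraction succeed), mixed
(profiles flat within noise; plateau contrast < 0.2), or microphase
(otherwise — e.g. micelles or bicontinuous structures), and always
returns the diagnostics behind the label, including connected-cluster
statistics of the large beads (contact distance + 0.1 ℓ tolerance).

**Equilibration.**  The equilibration criterion is a documented
heuristic of this package: split the stored snapshots into halves; pass
iff interface detection agrees between halves and, for two-phase
states, the per-species bulk compositions of the halves agree within
twice the combined SEM.  It reports every number behind the verdict.

## Reduced problem sizes

The package's own study sizes are chosen to keep the standard analyses
on a single core: single-chain q uses 10 independent runs of 3 × 10⁵
sweeps (R_g relaxation is a few × 10³ sweeps, so samples every 1.5 × 10³
sweeps are nearly independent); reduced-scale tension studies use
quarter- to half-volume slabs as described above with snapshots every
~10² sweeps.  Full-size phase-diagram and Table-scale tension runs
(6 000 beads, ≥ 7 replicates, 200 independent snapshots at 3 × 10⁴ τ
spacing) use the same code paths unchanged — only counts, box and sweep
budgets differ.

## What the synthetic generators do and do not emulate

`synthetic_two_slab` produces two-slab configurations with prescribed
interior compositions, uniform placement and optional transverse jitter;
it has sharp (not δ-wide) interfaces, no inter-particle correlations and
no excluded volume, so it validates the geometry/bookkeeping of the
profile → align → bulk → tie-line pipeline (parameter recovery within
2 × SEM), not the physics of interface formation.  Fixtures
(`uniform_mix`, `two_phase_slab`, …) are deterministic lattice/helix
constructions with exactly uniform per-bin densities, giving the
analysis stack machine-precision oracles.  Passing these tests shows
the measurement chain is unbiased on known inputs; it does not by
itself validate equilibrium sampling — that is what the
free-diffusion, caged-bead uniformity, bond-histogram and
Boltzmann-quadrature engine tests are for.

## Known limitations

* No hydrodynamic interactions beyond Stokes–Einstein diffusivities; no
  attractive potentials, electrostatics or explicit solvent.
* Dynamic MC time is physical only in the quasi-static limit; the
  Metropolis filter slightly distorts short-time dynamics at φ ≈ 0.3.
* The Kirkwood–Buff estimator at desk scales resolves orderings and
  signs, not the full-size tension values; quantitative reproduction
  needs the full 6 × 6 × 12 geometry with ~200 independent snapshots.
* The equilibration criterion is a stand-in heuristic, deliberately
  conservative and fully reported.
* Monodisperse radii and single-tail tadpoles only ("pearl necklace"
  morphologies with globular domains at both ends are out of scope).
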