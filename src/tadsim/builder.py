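"""Initial configurations and deterministic test fixtures.

Initialization places molecules at random (chains grown bead by bead),
tolerating overlaps, then removes them with an athermal push-off: pairs
are nudged apart down the overlap gradient and bonds re-projected into
their hard window until the hard energy is exactly zero.  Random
sequential addition alone jams at the densities this model is run at
(colloid volume fractions around 0.3), hence the two-stage scheme with a
radius ramp.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels
from .composition import CompositionSpec, composition_volume_fractions
from .snapshot import Snapshot, SystemTopology, build_system_topology

__all__ = [
    "initialize_configuration",
    "make_fixture",
    "synthetic_two_slab",
    "FIXTURE_NAMES",
]

#: radius ramp stages for the push-off (fraction of full radii)
_RAMP = (0.6, 0.8, 0.9, 1.0)


class InitializationError(RuntimeError):
    pass


def _grow_molecule(mol, rng, box, z_range=None):
    """Random positions for one molecule; bonds drawn inside their window."""
    n = mol.n_beads
    pos = np.empty((n, 3))
    lo = np.zeros(3)
    hi = np.asarray(box, dtype=float)
    if z_range is not None:
        lo[2], hi[2] = z_range
    pos[0] = lo + rng.random(3) * (hi - lo)
    for a, b in mol.bonds:
        r_min = mol.bead_radii[a] + mol.bead_radii[b]
        # stay comfortably inside the window [r_min, r_min + 3 R_tail)
        r = r_min * 1.02 + 0.6 * rng.random() * r_min
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        pos[b] = pos[a] + r * v
    return pos % np.asarray(box)


def _resolve_overlaps(pos, topo: SystemTopology, box, max_sweeps=4000):
    r_min, r_max = topo.bond_windows()
    bonds = topo.bonds if topo.n_bonds else np.empty((0, 2), dtype=np.int64)
    for scale in _RAMP:
        bad = _kernels.pushoff_sweeps(
            pos, topo.radii, np.asarray(box, dtype=float), bonds,
            r_min, r_max, scale, max_sweeps, 1.0,
        )
    if bad:
        raise InitializationError(
            f"push-off failed to resolve all hard constraints; "
            f"{bad} violations remain"
        )
    return pos


def initialize_configuration(
    spec: CompositionSpec,
    seed: int = 0,
    layout: str = "mixed",
    max_sweeps: int = 4000,
) -> Snapshot:
    """Build a zero-hard-energy starting Snapshot for a composition.

    ``layout="mixed"`` scatters all molecules uniformly; ``layout="slab"``
    pre-segregates colloids (low z) from polymers (high z) to shortcut
    interface formation, with tadpoles placed in the polymer-side region.
    Deterministic for fixed (spec, seed, layout).
    """
    if layout not in ("mixed", "slab"):
        raise ValueError(f"unknown layout {layout!r}")
    composition_volume_fractions(spec)  # feasibility check
    topo = build_system_topology(spec)
    rng = np.random.default_rng(seed)
    box = np.asarray(spec.box, dtype=float)

    z_col = z_rest = None
    if layout == "slab":
        phi = composition_volume_fractions(spec)
        # colloid slab sized for a plausible dense-phase packing
        frac = min(0.8, max(0.2, (phi["col"] + 0.5 * phi["tad"]) / 0.40))
        z_col = (0.0, frac * box[2])
        z_rest = (frac * box[2], box[2])

    pos = np.empty((topo.n_beads, 3))
    offset = 0
    for mol in topo.molecules:
        if layout == "slab":
            big = mol.kind == "colloid"
            z_range = z_col if big else z_rest
        else:
            z_range = None
        pos[offset:offset + mol.n_beads] = _grow_molecule(mol, rng, box, z_range)
        offset += mol.n_beads

    _resolve_overlaps(pos, topo, box, max_sweeps=max_sweeps)
    return Snapshot(box=box, positions=pos, topology=topo, time=0.0)


def hard_energy_is_zero(snap: Snapshot) -> bool:
    """Full O(N^2) validation that all hard constraints are satisfied."""
    n_over = _kernels.count_hard_overlaps(snap.positions, snap.radii, snap.box)
    topo = snap.topology
    if topo.n_bonds:
        r_min, r_max = topo.bond_windows()
        n_over += _kernels.count_bond_violations(
            snap.positions, snap.box, topo.bonds, r_min, r_max)
    return n_over == 0


# ---------------------------------------------------------------------------
# deterministic fixtures

FIXTURE_NAMES = ("dimer_z", "single_tadpole", "uniform_mix", "two_phase_slab")


def make_fixture(name: str, N_tail: int = 30) -> Snapshot:
    """Deterministic, seed-independent configurations used in tests.

    - ``dimer_z``: two bonded tail beads at separation 0.30 along z.
    - ``single_tadpole``: one tadpole, tail extended along z.
    - ``uniform_mix``: colloids and polymers on a homogeneous lattice.
    - ``two_phase_slab``: colloid slab (z < L_z/2) against a polymer slab,
      a sharp planar boundary in a 4 x 4 x 27 box.
    """
    if name == "dimer_z":
        spec = CompositionSpec(N_col=0, N_poly=1, N_tad=0, N_mono=2,
                               box=(4.0, 4.0, 4.0))
        topo = build_system_topology(spec)
        pos = np.array([[2.0, 2.0, 1.85], [2.0, 2.0, 2.15]])
        return Snapshot(box=spec.box, positions=pos, topology=topo)

    if name == "single_tadpole":
        spec = CompositionSpec(N_col=0, N_poly=0, N_tad=1, N_tail=N_tail,
                               box=(8.0, 8.0, 16.0))
        topo = build_system_topology(spec)
        pos = np.empty((topo.n_beads, 3))
        pos[:, 0] = 4.0
        pos[:, 1] = 4.0
        pos[0, 2] = 2.0
        z = 2.0 + topo.radii[0] + topo.radii[1] + 0.02
        for k in range(1, topo.n_beads):
            pos[k, 2] = z
            z += 0.30
        return Snapshot(box=spec.box, positions=pos, topology=topo)

    if name == "uniform_mix":
        return _lattice_mix()

    if name == "two_phase_slab":
        return _two_phase_slab()

    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


def _lattice_mix() -> Snapshot:
    """Homogeneous colloid + polymer arrangement (uniform z-density).

    Colloids sit on a helix: uniformly spaced in z with the transverse
    position cycling through a 4 x 4 grid of cell centres, so every z-bin
    holds the same colloid volume.  Straight polymer chains run along z
    on the grid corners with starts uniformly staggered in z, tiling the
    box periodically.  All hard constraints are satisfied.
    """
    box = (4.0, 4.0, 16.0)
    spec = CompositionSpec(N_col=64, N_poly=32, N_tad=0, N_mono=8, box=box)
    topo = build_system_topology(spec)
    pos = np.empty((topo.n_beads, 3))
    for k in range(64):
        ix, iy = k % 4, (k // 4) % 4
        pos[k] = (ix + 0.5, iy + 0.5, (k + 0.5) * 16.0 / 64.0)
    off = 64
    for c in range(32):
        ix, iy = c % 4, (c // 4) % 4
        z0 = (c + 0.5) * 16.0 / 32.0
        for b in range(8):
            pos[off] = (float(ix), float(iy), z0 + 0.30 * b)
            off += 1
    return Snapshot(box=np.asarray(box), positions=pos % np.asarray(box),
                    topology=topo)


def _two_phase_slab() -> Snapshot:
    """Sharp colloid/polymer slab pair in a 4 x 4 x 27 box.

    Colloids fill z < 13.5 on a helix with exact 0.0625 z-spacing (eight
    centres per 0.5 bin), polymers fill 14 <= z < 26.5 as straight
    10-bead chains whose beads tile a global 0.25 z-grid, so both bulk
    phases have exactly uniform density away from the boundary.  This is
    the known-composition oracle for profile / alignment /
    bulk-composition code.
    """
    box = (4.0, 4.0, 27.0)
    n_col = 216                    # z-spacing 13.5/216 = 0.0625
    n_cols_xy = 8                  # polymer columns per side, spacing 0.5
    n_chain_per_col = 5            # 5 chains x 10 beads tile 50 slots of 0.25
    n_poly = n_cols_xy * n_cols_xy * n_chain_per_col
    spec = CompositionSpec(N_col=n_col, N_poly=n_poly, N_tad=0, N_mono=10,
                           box=box)
    topo = build_system_topology(spec)
    pos = np.empty((topo.n_beads, 3))
    for k in range(n_col):
        ix, iy = k % 4, (k // 4) % 4
        pos[k] = (ix + 0.5, iy + 0.5, (k + 0.5) * 13.5 / n_col)
    off = n_col
    for ix in range(n_cols_xy):
        for iy in range(n_cols_xy):
            for c in range(n_chain_per_col):
                z0 = 14.0 + 0.125 + 10 * 0.25 * c
                for b in range(10):
                    pos[off] = (0.25 + ix * 0.5, 0.25 + iy * 0.5,
                                z0 + 0.25 * b)
                    off += 1
    return Snapshot(box=np.asarray(box), positions=pos % np.asarray(box),
                    topology=topo)


def synthetic_two_slab(
    phi_col_rich: tuple[float, float],
    phi_poly_rich: tuple[float, float],
    seed: int = 0,
    box: tuple[float, float, float] = (4.0, 4.0, 27.0),
    slab_fraction: float = 0.5,
    n_snapshots: int = 1,
    jitter: float = 0.05,
) -> list[Snapshot]:
    """Generate snapshots with two slabs of prescribed composition.

    ``phi_col_rich`` and ``phi_poly_rich`` give the target (phi_col,
    phi_poly) of the two phases.  Beads are placed uniformly at random
    inside their slab, keeping a margin off the boundary (overlaps are
    permitted — these snapshots feed the analysis stack, not the engine).
    Returns ``(snapshots, truth)`` where ``truth`` holds the realized
    interior volume fractions of each phase after molecule-count
    rounding — the ground truth for parameter-recovery tests.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    v_col = 4.0 / 3.0 * math.pi * 0.44**3
    v_mono = 4.0 / 3.0 * math.pi * 0.0908**3
    A = box[0] * box[1]
    z_split = slab_fraction * box[2]
    n_mono = 8
    margin = 0.45          # keeps bead centres off the slab boundary
    chain_span = 0.30 * n_mono

    counts = []
    for (phic, phip), (z_lo, z_hi) in ((phi_col_rich, (0.0, z_split)),
                                       (phi_poly_rich, (z_split, box[2]))):
        L_col = z_hi - z_lo - 2 * margin
        L_poly = z_hi - z_lo - 2 * margin - chain_span
        counts.append((int(round(phic * A * L_col / v_col)),
                       int(round(phip * A * L_poly / (n_mono * v_mono))),
                       L_col, L_poly))
    (ca, pa, LcA, LpA), (cb, pb, LcB, LpB) = counts
    truth = {
        "rich": {"col": ca * v_col / (A * LcA),
                 "poly": pa * n_mono * v_mono / (A * LpA)},
        "dilute": {"col": cb * v_col / (A * LcB),
                   "poly": pb * n_mono * v_mono / (A * LpB)},
    }
    spec = CompositionSpec(N_col=ca + cb, N_poly=pa + pb, N_tad=0,
                           N_mono=n_mono, box=tuple(box))
    topo = build_system_topology(spec)

    snaps = []
    for _ in range(n_snapshots):
        pos = np.empty((topo.n_beads, 3))
        k = 0
        for count, z_lo, z_hi in ((ca, 0.0, z_split), (cb, z_split, box[2])):
            for _ in range(count):
                pos[k, :2] = rng.random(2) * box[:2]
                pos[k, 2] = z_lo + margin + rng.random() * (z_hi - z_lo - 2 * margin)
                k += 1
        for count, z_lo, z_hi in ((pa, 0.0, z_split), (pb, z_split, box[2])):
            for _ in range(count):
                x, y = rng.random(2) * box[:2]
                z0 = z_lo + margin + rng.random() * (z_hi - z_lo - 2 * margin - chain_span)
                for b in range(n_mono):
                    pos[k] = (x + jitter * rng.normal(),
                              y + jitter * rng.normal(), z0 + 0.30 * b)
                    k += 1
        snaps.append(Snapshot(box=box.copy(), positions=pos % box, topology=topo))
    return snaps, truth
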