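"""Dynamic Monte Carlo propagation.

One sweep proposes one Gaussian Brownian displacement per mobile bead
(fresh random visiting order each sweep), applies the Metropolis test,
and advances time by dt.  Trial steps are drawn per axis from
Normal(0, 2 D_i dt) with the Stokes-Einstein D_i of each bead, so
accepted trajectories approximate Brownian dynamics.  In hard mode the
Metropolis test reduces to "accept iff the moved bead's final hard
energy is zero"; soft mode uses the WCA/FENE energies.
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import SoftParams
from .potentials import diffusivity
from .snapshot import Snapshot, SystemTopology, Trajectory
from .topology import SPECIES_LABELS

__all__ = ["RunParams", "propose_displacement", "metropolis_accept",
           "sweep", "neighbor_search", "run"]

_SEED_MOD = 2**31 - 1

#: Verlet-list skin [l] for soft mode; bridging half the skin within one
#: sweep would take a >10 sigma step, so stale-list errors are negligible,
#: and the rebuild cadence balances list size against rebuild cost
_VERLET_SKIN = 0.8


@dataclass(frozen=True)
class RunParams:
    """Propagation controls (times in tau)."""

    dt: float = 0.4
    n_steps: int = 1000
    sample_interval: int = 100
    snapshot_spacing_time: float = 3.0e4
    seed: int = 0
    mode: str = "hard"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.mode not in ("hard", "soft"):
            raise ValueError("mode must be 'hard' or 'soft'")
        if self.n_steps < 0 or self.sample_interval < 1:
            raise ValueError("invalid step counts")

    def validate_step_constraint(self, radii: np.ndarray, R_tail: float) -> None:
        """Require sqrt(2 D_i dt) < R_tail for every species present."""
        D = np.asarray([diffusivity(r, R_tail) for r in np.unique(radii)])
        rms = np.sqrt(2.0 * D * self.dt)
        if np.any(rms >= R_tail):
            raise ValueError(
                f"time step dt={self.dt} violates sqrt(2 D dt) < R_tail "
                f"(max rms per-axis step {rms.max():.4f} >= {R_tail})"
            )


def propose_displacement(D_i: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Brownian trial displacement: each axis ~ Normal(0, 2 D_i dt)."""
    if D_i <= 0 or dt <= 0:
        raise ValueError("D_i and dt must be positive")
    return rng.normal(0.0, math.sqrt(2.0 * D_i * dt), size=3)


def metropolis_accept(delta_U: float, rng: np.random.Generator) -> bool:
    """Accept with probability min[1, exp(-dU / k_B T)] (energies in eps)."""
    if delta_U <= 0.0:
        return True
    if math.isinf(delta_U):
        return False
    return rng.random() < math.exp(-delta_U)


def _step_sigmas(topo: SystemTopology, dt: float) -> np.ndarray:
    R_tail = topo.species_params.R_tail
    return np.sqrt(2.0 * diffusivity(topo.radii, R_tail) * dt)


def _interaction_cutoff(topo: SystemTopology, mode: str) -> float:
    r_max = 2.0 * float(topo.radii.max())
    if mode == "soft":
        r_max *= _kernels.WCA_CUT
    if topo.n_bonds:
        _, bond_hi = topo.bond_windows()
        r_max = max(r_max, float(bond_hi.max()))
        if mode == "soft":
            _, R_F = topo.soft_bond_params()
            r_max = max(r_max, float(R_F.max()))
    return r_max


def _cells_usable(box: np.ndarray, cutoff: float) -> bool:
    nx, ny, nz = _kernels.cell_grid_shape(np.asarray(box, float), cutoff)
    return min(nx, ny, nz) >= 3


def neighbor_search(snapshot: Snapshot, cutoff: float) -> np.ndarray:
    """Candidate interacting pairs (i < j) within cutoff (minimum image).

    Uses a linked cell list with cell edge >= cutoff; boxes thinner than
    three cells in any dimension fall back to the O(N^2) scan.  The
    result is a superset of all true pairs within the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = snapshot.positions
    box = np.asarray(snapshot.box, dtype=float)
    if pos.shape[0] == 0:
        return np.empty((0, 2), dtype=np.int64)
    if _cells_usable(box, cutoff):
        nx, ny, nz = _kernels.cell_grid_shape(box, cutoff)
        return _kernels.cell_pairs(pos, box, cutoff, nx, ny, nz)
    return _kernels.brute_pairs(pos, box, cutoff)


def _run_sweeps(snap: Snapshot, params: RunParams, n_sweeps: int,
                kernel_seed: int, mobile: np.ndarray,
                soft: SoftParams | None = None) -> np.ndarray:
    """Advance ``snap`` in place by ``n_sweeps`` sweeps; return accepts."""
    topo = snap.topology
    box = np.asarray(snap.box, dtype=float)
    sigma = _step_sigmas(topo, params.dt)
    adj = topo.bond_adjacency()
    cutoff = _interaction_cutoff(topo, params.mode)
    use_cells = _cells_usable(box, cutoff)

    if params.mode == "hard":
        _, r_max = topo.bond_windows()
        adj_rmax2 = np.zeros_like(adj, dtype=np.float64)
        bond_hi = {}
        for b, (i, j) in enumerate(topo.bonds):
            bond_hi[(i, j)] = bond_hi[(j, i)] = r_max[b] ** 2
        for i in range(topo.n_beads):
            for a in range(2):
                j = adj[i, a]
                if j >= 0:
                    adj_rmax2[i, a] = bond_hi[(i, j)]
        accepts = _kernels.run_hard(
            snap.positions, topo.radii, box, adj, adj_rmax2, mobile, sigma,
            n_sweeps, kernel_seed, use_cells, cutoff)
    else:
        soft = soft or SoftParams(species=topo.species_params)
        k_F, R_F = topo.soft_bond_params(soft)
        adj_kF = np.zeros_like(adj, dtype=np.float64)
        adj_RF2 = np.zeros_like(adj, dtype=np.float64)
        bond_p = {}
        for b, (i, j) in enumerate(topo.bonds):
            bond_p[(i, j)] = bond_p[(j, i)] = (k_F[b], R_F[b] ** 2)
        for i in range(topo.n_beads):
            for a in range(2):
                j = adj[i, a]
                if j >= 0:
                    adj_kF[i, a], adj_RF2[i, a] = bond_p[(i, j)]
        accepts = _kernels.run_soft(
            snap.positions, topo.radii, box, adj, adj_kF, adj_RF2, mobile,
            sigma, soft.u_W, n_sweeps, kernel_seed, _VERLET_SKIN)
    snap.time += n_sweeps * params.dt
    snap.mode = params.mode
    return accepts


def sweep(snapshot: Snapshot, params: RunParams,
          rng: np.random.Generator, n_sweeps: int = 1,
          mobile: np.ndarray | None = None,
          soft: SoftParams | None = None) -> Snapshot:
    """Advance a copy of ``snapshot`` by ``n_sweeps`` sweeps of dt each."""
    out = snapshot.copy()
    if mobile is None:
        mobile = np.ones(out.n_beads, dtype=np.bool_)
    kernel_seed = int(rng.integers(_SEED_MOD))
    _run_sweeps(out, params, n_sweeps, kernel_seed, mobile, soft)
    return out


def run(initial: Snapshot, params: RunParams,
        mobile: np.ndarray | None = None,
        soft: SoftParams | None = None,
        store_initial: bool = False,
        log=None) -> Trajectory:
    """Propagate ``initial`` for ``params.n_steps`` sweeps, storing a
    snapshot every ``params.sample_interval`` sweeps.

    Deterministic for fixed (initial, params): per-chunk kernel seeds are
    drawn from a generator seeded with ``params.seed``.  The trajectory
    metadata records the seed, acceptance rate per species and wall time.
    """
    params.validate_step_constraint(initial.radii,
                                    initial.topology.species_params.R_tail)
    snap = initial.copy()
    topo = snap.topology
    if mobile is None:
        mobile = np.ones(snap.n_beads, dtype=np.bool_)
    mobile = np.asarray(mobile, dtype=np.bool_)
    rng = np.random.default_rng(params.seed)

    frames: list[Snapshot] = [snap.copy()] if store_initial else []
    accepts = np.zeros(snap.n_beads, dtype=np.int64)
    t0 = _time.perf_counter()
    n_done = 0
    while n_done < params.n_steps:
        chunk = min(params.sample_interval, params.n_steps - n_done)
        kernel_seed = int(rng.integers(_SEED_MOD))
        accepts += _run_sweeps(snap, params, chunk, kernel_seed, mobile, soft)
        n_done += chunk
        frames.append(snap.copy())
        if log is not None:
            log(f"sweep {n_done}/{params.n_steps} t={snap.time:.1f} tau")
    wall = _time.perf_counter() - t0

    acc_rate = {}
    n_mobile_sweeps = max(n_done, 1)
    for code, label in SPECIES_LABELS.items():
        sel = (topo.species == code) & mobile
        if sel.any():
            acc_rate[label] = float(accepts[sel].sum()) / (sel.sum() * n_mobile_sweeps)
    meta = {
        "seed": params.seed,
        "mode": params.mode,
        "dt": params.dt,
        "n_steps": params.n_steps,
        "sample_interval": params.sample_interval,
        "acceptance_rate": acc_rate,
        "wall_time_s": wall,
    }
    return Trajectory(frames=frames, topology=topo, meta=meta)
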