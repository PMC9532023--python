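"""High-level study protocols built on the engine and analysis stack.

These encode the standard numerical experiments of the tadpole model:
the single-chain size ratio q = R_g / R_col, and the interfacial-tension
measurement on softened slab systems (including the series fusing
colloid + polymer pairs into tadpoles at fixed large- and small-particle
totals).
"""

from __future__ import annotations

import math

import numpy as np

from .analysis import radius_of_gyration
from .builder import initialize_configuration
from .composition import CompositionSpec, fuse_composition
from .engine import RunParams, run
from .soft import TensionResult, gamma_per_snapshot
from .units import UnitSystem

__all__ = ["measure_q", "measure_tension", "tension_fusion_series"]

_SEED_MOD = 2**31 - 1


def measure_q(
    seed: int = 0,
    n_seeds: int = 8,
    n_sweeps: int = 1_200_000,
    burn_in: int = 200_000,
    sample_every: int = 4_000,
    N_mono: int = 30,
    box_edge: float = 16.0,
    dt: float = 0.4,
):
    """Size ratio q = R_g / R_col of an isolated hard bead chain.

    Runs ``n_seeds`` independent single-chain simulations, samples R_g
    every ``sample_every`` sweeps after ``burn_in``, and pools the
    samples.  R_g carries a slow mode of order 10^4-10^5 sweeps on top
    of the few-thousand-sweep local relaxation, so the burn-in must
    cover the swelling of the compactly grown initial chain and run
    lengths must be long enough that run-to-run means agree; the
    defaults give q to about +/- 0.02.  Returns a
    :class:`~tadsim.analysis.GyrationResult` whose quoted error is the
    SEM over independent run means.
    """
    if burn_in >= n_sweeps:
        raise ValueError("burn_in must be shorter than n_sweeps")
    rng = np.random.default_rng(seed)
    spec = CompositionSpec(N_col=0, N_poly=1, N_tad=0, N_mono=N_mono,
                           box=(box_edge, box_edge, box_edge))
    run_means = []
    all_rg2 = []
    for _ in range(n_seeds):
        s = initialize_configuration(spec, seed=int(rng.integers(_SEED_MOD)))
        params = RunParams(dt=dt, n_steps=n_sweeps, sample_interval=sample_every,
                           seed=int(rng.integers(_SEED_MOD)))
        traj = run(s, params)
        frames = [f for f in traj.frames if f.time > burn_in * dt]
        res = radius_of_gyration(frames, kind="polymer")
        # pool squared radii for the overall mean
        for f in frames:
            r = radius_of_gyration(f, kind="polymer")
            all_rg2.append(r.R_g**2)
        run_means.append(res.R_g)
    rg = math.sqrt(float(np.mean(all_rg2)))
    sem_runs = float(np.std(run_means, ddof=1) / math.sqrt(len(run_means))) \
        if len(run_means) > 1 else 0.0
    from .analysis import GyrationResult

    R_col = spec.species_params().R_col
    return GyrationResult(R_g=rg, R_g_err=sem_runs, q=rg / R_col,
                          q_err=sem_runs / R_col,
                          n_samples=len(all_rg2))


def measure_tension(
    spec: CompositionSpec,
    seed: int = 0,
    layout: str = "slab",
    equil_sweeps: int = 6_000,
    n_snapshots: int = 150,
    snapshot_spacing: int = 90,
    n_runs: int = 2,
    dt: float = 0.4,
    units: UnitSystem | None = None,
    delta: float | None = None,
) -> TensionResult:
    """Kirkwood-Buff tension of a softened system, averaged over
    ``n_runs`` independent runs.

    Each run builds a fresh configuration (slab layout for two-interface
    systems), equilibrates in soft mode, then samples the pressure
    anisotropy.  The quoted error is the SEM over per-run means when
    ``n_runs`` > 1 (run means are independent, unlike successive
    snapshots), else the autocorrelation-naive SEM over snapshots.
    """
    rng = np.random.default_rng(seed)
    run_means = []
    all_g = []
    n = 0
    for _ in range(n_runs):
        s = initialize_configuration(spec, seed=int(rng.integers(_SEED_MOD)),
                                     layout=layout)
        p_eq = RunParams(dt=dt, n_steps=equil_sweeps,
                         sample_interval=equil_sweeps, seed=int(rng.integers(_SEED_MOD)),
                         mode="soft")
        s = run(s, p_eq).frames[-1]
        p_s = RunParams(dt=dt, n_steps=n_snapshots * snapshot_spacing,
                        sample_interval=snapshot_spacing,
                        seed=int(rng.integers(_SEED_MOD)), mode="soft")
        traj = run(s, p_s)
        g = np.array([gamma_per_snapshot(f) for f in traj.frames])
        all_g.extend(g.tolist())
        run_means.append(float(g.mean()))
        n += len(g)
    gamma = float(np.mean(run_means))
    if n_runs > 1:
        err = float(np.std(run_means, ddof=1) / math.sqrt(n_runs))
    else:
        g = np.asarray(all_g)
        err = float(g.std(ddof=1) / math.sqrt(len(g)))
    from .soft import _make_result

    return _make_result(gamma, err, units, delta, n)


def tension_fusion_series(
    base: CompositionSpec,
    n_tad_values,
    seed: int = 0,
    **kwargs,
) -> dict[int, TensionResult]:
    """Tension for a series of systems fusing polymers + colloids into
    tadpoles at fixed totals of large particles and small beads."""
    out = {}
    for i, k in enumerate(n_tad_values):
        spec = fuse_composition(base, k)
        out[k] = measure_tension(spec, seed=seed + 1000 * i, **kwargs)
    return out
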