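"""Dynamic Monte Carlo engine: proposal statistics, Metropolis rule,
free diffusion, detailed balance and neighbor search."""

import math

import numpy as np
import pytest
from scipy import stats

import tadsim as ts
from tadsim import (CompositionSpec, RunParams, diffusivity, metropolis_accept,
                    neighbor_search, propose_displacement, run)
from tadsim.builder import hard_energy_is_zero, initialize_configuration, make_fixture
from tadsim.snapshot import Snapshot, build_system_topology

R_SMALL = 0.0908
R_BIG = 0.44


class TestProposeDisplacement:
    def test_moments(self):
        rng = np.random.default_rng(0)
        D = diffusivity(R_SMALL)
        dt = 0.4
        draws = np.array([propose_displacement(D, dt, rng)
                          for _ in range(30_000)])
        target_var = 2 * D * dt
        assert target_var == pytest.approx(1.099e-3, abs=2e-6)
        se_mean = math.sqrt(target_var / len(draws))
        assert np.all(np.abs(draws.mean(axis=0)) < 4 * se_mean)
        rel_se_var = math.sqrt(2 / len(draws))
        assert draws.var(axis=0) == pytest.approx(target_var,
                                                  rel=5 * rel_se_var)

    def test_rms_step_below_tail_radius(self):
        # the proposal-scale constraint of the dynamic interpretation
        for R in (R_SMALL, R_BIG):
            assert math.sqrt(2 * diffusivity(R) * 0.4) < R_SMALL
        assert math.sqrt(2 * diffusivity(R_SMALL) * 0.4) == pytest.approx(
            0.0331, abs=2e-4)

    def test_step_constraint_validation(self):
        params = RunParams(dt=3000.0)
        with pytest.raises(ValueError, match="R_tail"):
            params.validate_step_constraint(np.array([R_SMALL]), R_SMALL)


class TestMetropolis:
    def test_zero_delta_always_accepts(self):
        rng = np.random.default_rng(1)
        assert all(metropolis_accept(0.0, rng) for _ in range(100))

    def test_infinite_delta_always_rejects(self):
        rng = np.random.default_rng(2)
        assert not any(metropolis_accept(math.inf, rng) for _ in range(100))

    def test_unit_delta_accepts_at_exp_minus_one(self):
        rng = np.random.default_rng(3)
        n = 200_000
        acc = sum(metropolis_accept(1.0, rng) for _ in range(n)) / n
        p = math.exp(-1)
        assert abs(acc - p) < 4 * math.sqrt(p * (1 - p) / n)


def _single_bead_snapshot(R, box=(8.0, 8.0, 8.0)):
    if R == R_BIG:
        spec = CompositionSpec(N_col=1, N_poly=0, N_tad=0, box=box)
    else:
        spec = CompositionSpec(N_col=0, N_poly=1, N_tad=0, N_mono=1, box=box)
    topo = build_system_topology(spec)
    pos = np.array([[4.0, 4.0, 4.0]])
    return Snapshot(box=np.asarray(box), positions=pos, topology=topo)


class TestFreeDiffusion:
    @pytest.mark.parametrize("R", [R_SMALL, R_BIG])
    def test_msd_matches_6Dt_within_3_sigma(self, R):
        """MSD of a free bead over disjoint windows recovers D_i."""
        snap = _single_bead_snapshot(R)
        dt = 0.4
        window = 50
        n_windows = 80
        params = RunParams(dt=dt, n_steps=window * n_windows,
                           sample_interval=window, seed=hash(R) % 1000)
        traj = run(snap, params, store_initial=True)
        assert traj.meta["acceptance_rate"]["col" if R == R_BIG else "mono"] == 1.0
        pos = np.array([f.positions[0] for f in traj.frames])
        # unwrap per window via minimum image (steps are << box)
        deltas = np.diff(pos, axis=0)
        deltas -= snap.box * np.round(deltas / snap.box)
        sq = (deltas**2).sum(axis=1)
        t = window * dt
        D = diffusivity(R)
        expected = 6 * D * t
        # |delta|^2 is a sum of three scaled chi-square(1): sd = 2Dt sqrt(6)
        sem = 2 * D * t * math.sqrt(6) / math.sqrt(n_windows)
        assert abs(sq.mean() - expected) < 3 * sem


class TestHardModeSampling:
    def test_caged_bead_never_moves_but_time_advances(self):
        """A bead whose entire neighbourhood is excluded volume cannot
        accept any move; the clock still runs."""
        spec = CompositionSpec(N_col=6, N_poly=1, N_tad=0, N_mono=1,
                               box=(4.0, 4.0, 4.0), max_packing=1.0)
        topo = build_system_topology(spec)
        c = 2.0
        pos = np.array([
            [c + 0.53, c, c], [c - 0.53, c, c],
            [c, c + 0.53, c], [c, c - 0.53, c],
            [c, c, c + 0.53], [c, c, c - 0.53],
            [c, c, c],
        ])
        snap = Snapshot(box=np.array([4.0, 4.0, 4.0]), positions=pos,
                        topology=topo)
        mobile = np.zeros(7, dtype=bool)
        mobile[6] = True
        params = RunParams(dt=0.4, n_steps=500, sample_interval=500, seed=9)
        traj = run(snap, params, mobile=mobile)
        assert np.array_equal(traj.frames[-1].positions[6], pos[6])
        assert traj.frames[-1].time == pytest.approx(200.0)

    def test_uniform_sampling_in_free_volume(self):
        """Long-run positions of one hard bead around a fixed obstacle are
        uniform over the accessible volume (chi-square against a Monte
        Carlo estimate of the free volume per cell) — a detailed-balance
        check of the hard-mode accept rule."""
        L = 1.2
        spec = CompositionSpec(N_col=1, N_poly=1, N_tad=0, N_mono=1,
                               box=(L, L, L), max_packing=1.0)
        topo = build_system_topology(spec)
        pos = np.array([[L / 2, L / 2, L / 2], [0.05, 0.05, 0.05]])
        snap = Snapshot(box=np.array([L, L, L]), positions=pos, topology=topo)
        mobile = np.array([False, True])
        params = RunParams(dt=0.4, n_steps=160_000, sample_interval=400,
                           seed=13)
        traj = run(snap, params, mobile=mobile)
        samples = np.array([f.positions[1] for f in traj.frames])

        # oracle: rejection-sampled free volume on a 3x3x3 grid
        rng = np.random.default_rng(99)
        pts = rng.random((400_000, 3)) * L
        d = pts - L / 2
        free = (d**2).sum(axis=1) > (R_BIG + R_SMALL) ** 2
        cells_or = (np.floor(pts[free] / (L / 3)).astype(int) * [9, 3, 1]).sum(axis=1)
        cells_obs = (np.floor(samples / (L / 3)).astype(int) * [9, 3, 1]).sum(axis=1)
        expected = np.bincount(cells_or, minlength=27).astype(float)
        observed = np.bincount(cells_obs, minlength=27).astype(float)
        keep = expected / expected.sum() * len(samples) >= 5
        exp = expected[keep] / expected[keep].sum() * observed[keep].sum()
        chi2 = ((observed[keep] - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_bonded_dimer_samples_r_squared_measure(self, hard_dimer_samples):
        """Hard dimer bond lengths follow p(r) ~ r^2 on [0.1816, 0.4540)."""
        r = hard_dimer_samples
        a, b = 0.1816, 0.4540
        assert r.min() >= a and r.max() < b

        cdf = lambda x: (np.clip(x, a, b) ** 3 - a**3) / (b**3 - a**3)
        # thin to ~independent samples for the KS test
        thin = r[::5]
        p = stats.kstest(thin, cdf).pvalue
        assert p > 0.01
        mean_exact = 0.75 * (b**4 - a**4) / (b**3 - a**3)
        assert r.mean() == pytest.approx(mean_exact, abs=4 * r.std() / math.sqrt(len(thin)))

    def test_trajectory_keeps_zero_hard_energy(self):
        spec = CompositionSpec(N_col=25, N_poly=4, N_tad=2, N_mono=8,
                               N_tail=8, box=(4, 4, 6))
        snap = initialize_configuration(spec, seed=21)
        params = RunParams(dt=0.4, n_steps=200, sample_interval=40, seed=22)
        traj = run(snap, params)
        assert all(hard_energy_is_zero(f) for f in traj.frames)

    def test_run_is_deterministic(self):
        spec = CompositionSpec(N_col=10, N_poly=2, N_tad=0, N_mono=5,
                               box=(4, 4, 6))
        snap = initialize_configuration(spec, seed=31)
        params = RunParams(dt=0.4, n_steps=100, sample_interval=25, seed=32)
        a = run(snap, params)
        b = run(snap, params)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.positions, fb.positions)

    def test_micelle_scale_system_smoke(self):
        """Dense tadpole + colloid composition runs to completion."""
        spec = CompositionSpec(N_col=112, N_tad=56, N_poly=0, N_tail=30,
                               box=(4, 4, 8), max_packing=0.6)
        snap = initialize_configuration(spec, seed=41)
        traj = run(snap, RunParams(dt=0.4, n_steps=20, sample_interval=10,
                                   seed=42))
        assert len(traj) == 2
        assert hard_energy_is_zero(traj.frames[-1])


def _numpy_pairs(pos, box, cutoff):
    """Independent O(N^2) oracle for pairs within cutoff."""
    n = len(pos)
    d = pos[:, None, :] - pos[None, :, :]
    d -= box * np.round(d / box)
    dist = np.sqrt((d**2).sum(axis=2))
    ii, jj = np.where((dist <= cutoff) & (np.arange(n)[:, None] < np.arange(n)))
    return set(zip(ii.tolist(), jj.tolist()))


class TestNeighborSearch:
    def test_cell_list_matches_brute_force_on_random_snapshots(self):
        """Cell-list pair sets are supersets of (here: equal to) the exact
        pair sets on 100 randomized boxes, including thin-box fallbacks."""
        rng = np.random.default_rng(55)
        for trial in range(100):
            L = rng.uniform(2.0, 8.0)
            Lz = rng.uniform(2.0, 12.0)
            box = np.array([L, L, Lz])
            v_col = 4 / 3 * np.pi * 0.44**3
            n_max = int(0.35 * box.prod() / v_col)
            n = int(rng.integers(2, max(3, min(60, n_max))))
            cutoff = float(rng.uniform(0.3, 1.3))
            spec = CompositionSpec(N_col=n, N_poly=0, N_tad=0,
                                   box=tuple(box), max_packing=1.0)
            topo = build_system_topology(spec)
            pos = rng.random((n, 3)) * box
            snap = Snapshot(box=box, positions=pos, topology=topo)
            pairs = neighbor_search(snap, cutoff)
            got = set((min(i, j), max(i, j)) for i, j in pairs)
            want = _numpy_pairs(pos, box, cutoff)
            assert want <= got, f"trial {trial}: missing pairs {want - got}"

    def test_pair_across_periodic_boundary(self):
        spec = CompositionSpec(N_col=2, N_poly=0, N_tad=0, box=(6, 6, 6))
        topo = build_system_topology(spec)
        pos = np.array([[3.0, 3.0, 0.04], [3.0, 3.0, 5.94]])
        snap = Snapshot(box=np.array([6.0, 6.0, 6.0]), positions=pos,
                        topology=topo)
        pairs = neighbor_search(snap, 0.2)
        assert len(pairs) == 1

    def test_empty_box(self):
        spec = CompositionSpec(N_col=0, N_poly=0, N_tad=0, box=(6, 6, 6))
        topo = build_system_topology(spec)
        snap = Snapshot(box=np.array([6.0, 6.0, 6.0]),
                        positions=np.empty((0, 3)), topology=topo)
        assert len(neighbor_search(snap, 1.0)) == 0
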