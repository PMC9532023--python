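"""Profiles, interface alignment, tie lines, gyration radii and phase
classification."""

import math

import numpy as np
import pytest

import tadsim as ts
from tadsim import (CompositionSpec, RunParams, run, radius_of_gyration,
                    tie_line, volume_fraction_profile)
from tadsim.analysis import (InsufficientBulkError, MixedStateError, Profile,
                             bulk_compositions, classify_state,
                             detect_and_align, detect_interfaces,
                             equilibration_check)
from tadsim.builder import (initialize_configuration, make_fixture,
                            synthetic_two_slab)
from tadsim.snapshot import Snapshot, build_system_topology


class TestVolumeFractionProfile:
    def test_volume_conservation_is_exact(self, two_phase_slab):
        """Sum over bins of phi * bin volume equals the global species
        volume exactly (sphere-slab partition property)."""
        prof = volume_fraction_profile(two_phase_slab, n_bins=54)
        box = two_phase_slab.box
        bin_vol = box[0] * box[1] * prof.bin_width
        V = float(np.prod(box))
        for s in ("col", "poly", "tad"):
            assert prof.phi[s].sum() * bin_vol == pytest.approx(
                prof.phi_global[s] * V, rel=1e-12)

    def test_uniform_fixture_flat_profiles(self, uniform_mix):
        prof = volume_fraction_profile(uniform_mix, n_bins=32)
        for s in ("col", "poly"):
            ratio = prof.ratio(s)
            assert np.allclose(ratio, 1.0, atol=1e-9)

    def test_two_phase_slab_steps(self, two_phase_slab):
        prof = volume_fraction_profile(two_phase_slab, n_bins=54)
        # colloid-rich below 13.5, polymer-rich above (the bins touching
        # z = 0 and z = 27 exchange wrapped sphere volume cyclically)
        z = prof.z_bins
        assert prof.phi["col"][(z > 1) & (z < 12)].min() > 0.3
        assert prof.phi["col"][(z > 15) & (z < 26)].max() < 1e-12
        assert prof.phi["poly"][(z > 16) & (z < 24)].min() > 0.04
        assert prof.phi["poly"][z < 12].max() < 1e-12

    def test_single_colloid_in_wide_bin(self):
        spec = CompositionSpec(N_col=1, N_poly=0, N_tad=0, box=(4, 4, 8))
        topo = build_system_topology(spec)
        snap = Snapshot(box=np.array([4.0, 4.0, 8.0]),
                        positions=np.array([[2.0, 2.0, 3.0]]), topology=topo)
        prof = volume_fraction_profile(snap, n_bins=4)  # 2-wide bins
        vols = prof.phi["col"] * 4 * 4 * 2.0
        v_sphere = 4 / 3 * math.pi * 0.44**3
        assert vols[1] == pytest.approx(v_sphere, rel=1e-12)
        assert vols[[0, 2, 3]] == pytest.approx([0, 0, 0], abs=1e-15)

    def test_absent_species_ratio_is_none(self, two_phase_slab):
        prof = volume_fraction_profile(two_phase_slab)
        assert prof.ratio("tad") is None

    def test_requires_enough_bins(self, two_phase_slab):
        with pytest.raises(ValueError):
            volume_fraction_profile(two_phase_slab, n_bins=3)


def _tanh_profile(z0, width=1.0, n_bins=54, Lz=27.0, lo=0.02, hi=0.42):
    """Synthetic colloid profile with interfaces at z0 and z0 + Lz/2."""
    z = (np.arange(n_bins) + 0.5) * (Lz / n_bins)
    d1 = (z - z0 + Lz / 2) % Lz - Lz / 2
    d2 = (z - z0 - Lz / 2 + Lz / 2) % Lz - Lz / 2
    y = lo + (hi - lo) * 0.5 * (np.tanh(d1 / width) - np.tanh(d2 / width))
    y = np.clip(y, lo, hi)
    phi = {"col": y, "poly": 0.05 * (1 - (y - lo) / (hi - lo)), "tad": np.zeros(n_bins)}
    return Profile(z_bins=z, phi=phi,
                   phi_global={k: float(v.mean()) for k, v in phi.items()},
                   n_snapshots=1, box=np.array([4.0, 4.0, Lz]))


class TestInterfaceDetection:
    def test_constructed_tanh_interface_found_within_one_bin(self):
        for z0 in (3.2, 13.9, 24.5):
            prof = _tanh_profile(z0)
            z_up, z_down = detect_interfaces(prof)
            bin_w = prof.bin_width
            assert min(abs(z_up - z0), 27 - abs(z_up - z0)) < 1.5 * bin_w
            expect_down = (z0 + 13.5) % 27
            assert min(abs(z_down - expect_down),
                       27 - abs(z_down - expect_down)) < 1.5 * bin_w

    def test_flat_profile_raises_mixed(self, uniform_mix):
        prof = volume_fraction_profile(uniform_mix)
        with pytest.raises(MixedStateError):
            detect_interfaces(prof)

    def test_alignment_recovers_random_offsets(self, two_phase_slab):
        """Cyclically shifted copies of one slab align back onto each
        other: the aligned mean equals the aligned original."""
        base = two_phase_slab
        rng = np.random.default_rng(4)
        shifted = []
        for _ in range(5):
            s = base.copy()
            dz = rng.uniform(0, 27)
            s.positions[:, 2] = (s.positions[:, 2] + dz) % 27
            shifted.append(s)
        mean_prof, positions = detect_and_align(shifted, n_bins=54)
        ref_prof, _ = detect_and_align([base], n_bins=54)
        # aligned mean equals the aligned original except where sub-bin
        # rounding of the shift moves the sharp step by one bin
        mismatch = np.abs(mean_prof.phi["col"] - ref_prof.phi["col"]) > 0.02
        assert mismatch.sum() <= 6
        # interface positions recovered modulo the box
        spread = (positions - positions[0]) % 27
        assert len(positions) == 5

    def test_alignment_is_idempotent(self, two_phase_slab):
        prof1, _ = detect_and_align([two_phase_slab], n_bins=54)
        prof2, _ = detect_and_align([prof1], n_bins=54)
        for s in ("col", "poly"):
            assert np.allclose(prof1.phi[s], prof2.phi[s], atol=1e-12)

    def test_mixed_system_alignment_fails(self, uniform_mix):
        with pytest.raises(MixedStateError):
            detect_and_align([uniform_mix])


class TestBulkCompositions:
    def test_recovers_constructed_slab_compositions(self, two_phase_slab):
        prof, _ = detect_and_align([two_phase_slab], n_bins=54)
        rich, dilute = bulk_compositions(prof)
        # constructed densities: 8 colloids per 0.5-bin; 128 tail beads/bin
        v_col = 4 / 3 * math.pi * 0.44**3
        v_mono = 4 / 3 * math.pi * 0.0908**3
        assert rich["col"] == pytest.approx(8 * v_col / 8.0, rel=1e-6)
        assert rich["poly"] == pytest.approx(0.0, abs=1e-12)
        assert dilute["poly"] == pytest.approx(128 * v_mono / 8.0, rel=1e-6)
        assert dilute["col"] == pytest.approx(0.0, abs=1e-12)
        assert rich["s"] == pytest.approx(1 - rich["col"], rel=1e-9)

    def test_phase_order_follows_colloid_content(self, two_phase_slab):
        prof, _ = detect_and_align([two_phase_slab], n_bins=54)
        rich, dilute = bulk_compositions(prof)
        assert rich["col"] > dilute["col"]

    def test_thin_phase_raises(self):
        prof = _tanh_profile(5.0, n_bins=54, Lz=27.0)
        with pytest.raises(InsufficientBulkError):
            bulk_compositions(prof, margin=7.0)

    def test_pure_solvent_region(self):
        prof = _tanh_profile(5.0)
        prof.phi["poly"][:] = 0.0
        _, dilute = bulk_compositions(prof)
        assert dilute["s"] == pytest.approx(1 - dilute["col"])


class TestTieLine:
    def comp(self, col, poly, tad=0.0):
        s = 1 - col - poly - tad
        return {"col": col, "poly": poly, "tad": tad, "s": s}

    def test_identical_runs_zero_error(self):
        pair = (self.comp(0.4, 0.005), self.comp(0.05, 0.05))
        tl = tie_line([pair] * 7)
        assert tl.n_runs == 7
        assert tl.phase_A["col"] == pytest.approx(0.4)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in tl.phase_A_err.values())

    def test_sem_matches_closed_form(self):
        rng = np.random.default_rng(8)
        cols = 0.4 + 0.02 * rng.standard_normal(9)
        runs = [(self.comp(c, 0.005), self.comp(0.05, 0.05)) for c in cols]
        tl = tie_line(runs)
        assert tl.phase_A["col"] == pytest.approx(cols.mean())
        assert tl.phase_A_err["col"] == pytest.approx(
            cols.std(ddof=1) / 3, rel=1e-12)
        assert tl.export()["phase_A_err_2sem"]["col"] == pytest.approx(
            2 * tl.phase_A_err["col"])

    def test_swapped_phases_repaired(self):
        a, b = self.comp(0.4, 0.005), self.comp(0.05, 0.05)
        tl = tie_line([(a, b), (b, a), (a, b)])
        assert tl.phase_A["col"] == pytest.approx(0.4)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in tl.phase_A_err.values())

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            tie_line([(self.comp(0.4, 0.005), self.comp(0.05, 0.05))])

    def test_parameter_recovery_from_synthetic_two_slab(self):
        """Tie-line endpoints recover the synthetic generator's
        compositions within 2 x SEM."""
        target_rich = (0.30, 0.004)
        target_dilute = (0.02, 0.045)
        comps = []
        for seed in range(6):
            snaps, truth = synthetic_two_slab(target_rich, target_dilute,
                                              seed=seed, n_snapshots=4)
            prof, _ = detect_and_align(snaps, n_bins=54)
            # margin > placement margin + chain span, so only the flat
            # interior plateau of the generator is sampled
            comps.append(bulk_compositions(prof, margin=3.2))
        tl = tie_line(comps)
        for key, phase, err in (("rich", tl.phase_A, tl.phase_A_err),
                                ("dilute", tl.phase_B, tl.phase_B_err)):
            for s in ("col", "poly"):
                tol = max(2 * err[s], 0.004)
                assert phase[s] == pytest.approx(truth[key][s], abs=tol), \
                    f"{key}/{s}"


class TestRadiusOfGyration:
    def test_single_bead_zero(self):
        spec = CompositionSpec(N_col=0, N_poly=1, N_tad=0, N_mono=1,
                               box=(4, 4, 4))
        topo = build_system_topology(spec)
        snap = Snapshot(box=np.full(3, 4.0),
                        positions=np.array([[1.0, 1.0, 1.0]]), topology=topo)
        res = radius_of_gyration(snap, kind="polymer")
        assert res.R_g == 0.0

    def test_three_collinear_beads_closed_form(self):
        spec = CompositionSpec(N_col=0, N_poly=1, N_tad=0, N_mono=3,
                               box=(8, 8, 8))
        topo = build_system_topology(spec)
        b = 0.3
        pos = np.array([[4, 4, 4 - b], [4, 4, 4], [4, 4, 4 + b]], dtype=float)
        snap = Snapshot(box=np.full(3, 8.0), positions=pos, topology=topo)
        res = radius_of_gyration(snap, kind="polymer")
        assert res.R_g**2 == pytest.approx(2 * b**2 / 3, rel=1e-12)

    def test_unwrap_across_boundary(self):
        spec = CompositionSpec(N_col=0, N_poly=1, N_tad=0, N_mono=3,
                               box=(8, 8, 8))
        topo = build_system_topology(spec)
        b = 0.3
        pos = np.array([[4, 4, 7.9], [4, 4, 7.9 + b], [4, 4, 7.9 + 2 * b]])
        pos = pos % 8.0
        snap = Snapshot(box=np.full(3, 8.0), positions=pos, topology=topo)
        res = radius_of_gyration(snap, kind="polymer")
        assert res.R_g**2 == pytest.approx(2 * b**2 / 3, rel=1e-12)

    def test_gyration_grows_with_tail_length(self):
        """q(N_tail = 15) < q(N_tail = 30) for isolated chains."""
        qs = {}
        for n in (15, 30):
            spec = CompositionSpec(N_col=0, N_poly=1, N_tad=0, N_mono=n,
                                   box=(16, 16, 16))
            snap = initialize_configuration(spec, seed=n)
            traj = run(snap, RunParams(dt=0.4, n_steps=30_000,
                                       sample_interval=500, seed=n + 1))
            qs[n] = radius_of_gyration(traj.frames[10:], kind="polymer").q
        assert qs[15] < qs[30]

    def test_tadpole_tail_only_vs_with_head(self):
        snap = make_fixture("single_tadpole", N_tail=30)
        tail = radius_of_gyration(snap, kind="tadpole", tail_only=True)
        full = radius_of_gyration(snap, kind="tadpole", tail_only=False)
        assert tail.R_g != full.R_g
        assert tail.n_samples == full.n_samples == 1


class TestClassifyState:
    def test_two_phase_slab_is_macrophase(self, two_phase_slab):
        label, diag = classify_state([two_phase_slab])
        assert label == "macrophase"
        assert "bulk_compositions" in diag

    def test_uniform_mix_is_mixed(self, uniform_mix):
        label, diag = classify_state([uniform_mix])
        assert label == "mixed"
        assert diag["contrast"] < 0.2

    def test_compact_cluster_is_microphase(self):
        """A dense colloid ball in a thin box: structured profile but no
        two-plateau slab -> microphase."""
        rng = np.random.default_rng(12)
        spec = CompositionSpec(N_col=60, N_poly=0, N_tad=0, box=(8, 8, 8),
                               max_packing=1.0)
        topo = build_system_topology(spec)
        # overlapping-free packed ball around the centre
        pts = []
        grid = np.arange(-2, 3) * 0.9
        for x in grid:
            for y in grid:
                for z in grid:
                    if x * x + y * y + z * z <= 2.0**2:
                        pts.append((4 + x, 4 + y, 4 + z))
        pts = np.asarray(pts)[:60]
        spec = CompositionSpec(N_col=len(pts), N_poly=0, N_tad=0,
                               box=(8, 8, 8), max_packing=1.0)
        topo = build_system_topology(spec)
        snap = Snapshot(box=np.full(3, 8.0), positions=pts, topology=topo)
        label, diag = classify_state([snap])
        assert label == "microphase"
        assert diag["largest_cluster_fraction"] > 0.9


class TestEquilibrationCheck:
    def test_identical_snapshots_pass(self, two_phase_slab):
        frames = [two_phase_slab.copy() for _ in range(6)]
        passed, diag = equilibration_check(frames)
        assert passed

    def test_drifting_slab_fails(self, two_phase_slab):
        """A slab whose colloid phase steadily dilates between snapshots
        exceeds the 2 x SEM agreement between halves."""
        frames = []
        base = two_phase_slab
        for k in range(8):
            s = base.copy()
            # progressively stretch the colloid slab in z (dilute it)
            zc = s.positions[:, 2]
            col = s.species == 0
            s.positions[col, 2] = zc[col] * (1.0 + 0.04 * k)
            s.positions[:, 2] %= 27.0
            frames.append(s)
        passed, diag = equilibration_check(frames)
        assert not passed

    def test_too_few_snapshots(self, two_phase_slab):
        with pytest.raises(ValueError):
            equilibration_check([two_phase_slab] * 3)
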