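"""Trajectory analysis: volume-fraction profiles, interface detection and
alignment, bulk-phase compositions and tie lines, radius of gyration, and
phase-state classification.

Profiles use an exact sphere-slab partition: each bead contributes to a
z-bin the exact volume of the intersection of its sphere with that bin,
so per-species volume is conserved between the profile and the global
composition to machine precision, and profiles are smooth even though a
colloid diameter (0.88 l) spans several bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .snapshot import Snapshot, Trajectory
from .soft import default_interface_width
from .topology import SPECIES_COL, SPECIES_HEAD, SPECIES_MONO, SPECIES_TAIL

__all__ = [
    "Profile", "TieLine", "GyrationResult",
    "volume_fraction_profile", "detect_interfaces", "detect_and_align",
    "bulk_compositions", "tie_line", "radius_of_gyration",
    "classify_state", "equilibration_check",
    "MixedStateError", "InsufficientBulkError",
]

PHI_SPECIES = ("col", "poly", "tad")


class MixedStateError(RuntimeError):
    """Interface detection failed: no distinct plateaus.  The system is
    mixed or microphase-separated; use :func:`classify_state`."""


class InsufficientBulkError(RuntimeError):
    """A phase is too thin to contain bulk bins beyond the margin."""


# ---------------------------------------------------------------------------
# profiles


def _species_group(snapshot: Snapshot) -> dict[str, np.ndarray]:
    sp = snapshot.species
    return {
        "col": sp == SPECIES_COL,
        "poly": sp == SPECIES_MONO,
        "tad": (sp == SPECIES_HEAD) | (sp == SPECIES_TAIL),
    }


def _sphere_slab_volumes(z: np.ndarray, R: np.ndarray, edges: np.ndarray,
                         Lz: float) -> np.ndarray:
    """(n_beads, n_bins) exact sphere volume inside each z-slab.

    Periodic in z: a sphere straddling the box boundary contributes
    cyclically.  Row sums equal 4/3 pi R^3 exactly.
    """

    def below(h):
        # sphere volume below plane z = h, per bead (cap from the bottom)
        hh = np.clip(h[None, :] - (z - R)[:, None], 0.0,
                     (2.0 * R)[:, None])
        return math.pi / 3.0 * hh**2 * (3.0 * R[:, None] - hh)

    out = np.zeros((z.shape[0], edges.shape[0] - 1))
    for shift in (-Lz, 0.0, Lz):
        zs = z + shift
        caps = math.pi / 3.0 * np.clip(
            edges[None, :] - (zs - R)[:, None], 0.0, (2.0 * R)[:, None]
        ) ** 2 * (3.0 * R[:, None]
                  - np.clip(edges[None, :] - (zs - R)[:, None], 0.0,
                            (2.0 * R)[:, None]))
        out += caps[:, 1:] - caps[:, :-1]
    return out


@dataclass
class Profile:
    """z-binned per-species volume fractions, averaged over snapshots."""

    z_bins: np.ndarray                     # bin centres
    phi: dict[str, np.ndarray]             # species -> phi per bin
    phi_global: dict[str, float]
    n_snapshots: int
    box: np.ndarray
    reference: str = "col"

    @property
    def bin_width(self) -> float:
        return float(self.z_bins[1] - self.z_bins[0])

    @property
    def n_bins(self) -> int:
        return self.z_bins.shape[0]

    def phi_solvent(self) -> np.ndarray:
        return 1.0 - sum(self.phi[s] for s in PHI_SPECIES)

    def ratio(self, species: str) -> np.ndarray:
        """phi(z) scaled by its global value; None if globally absent."""
        if self.phi_global[species] == 0.0:
            return None
        return self.phi[species] / self.phi_global[species]

    def rolled(self, shift_bins: int) -> "Profile":
        return Profile(
            z_bins=self.z_bins,
            phi={s: np.roll(v, shift_bins) for s, v in self.phi.items()},
            phi_global=dict(self.phi_global),
            n_snapshots=self.n_snapshots,
            box=self.box, reference=self.reference,
        )


def volume_fraction_profile(
    snapshots: Trajectory | list[Snapshot] | Snapshot,
    n_bins: int | None = None,
) -> Profile:
    """Per-species volume-fraction profile phi(z).

    Averages plainly over the given snapshots (align first with
    :func:`detect_and_align` when interfaces drift between snapshots).
    The default bin width is 0.5 l (n_bins = 2 L_z).
    """
    if isinstance(snapshots, Snapshot):
        snapshots = [snapshots]
    frames = list(snapshots)
    if not frames:
        raise ValueError("need at least one snapshot")
    box = np.asarray(frames[0].box, float)
    Lz = float(box[2])
    if n_bins is None:
        n_bins = max(4, int(round(2 * Lz)))
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    edges = np.linspace(0.0, Lz, n_bins + 1)
    A = box[0] * box[1]
    bin_vol = A * (edges[1] - edges[0])

    groups = _species_group(frames[0])
    acc = {s: np.zeros(n_bins) for s in PHI_SPECIES}
    for snap in frames:
        vols = _sphere_slab_volumes(snap.positions[:, 2], snap.radii, edges, Lz)
        for s, mask in groups.items():
            if mask.any():
                acc[s] += vols[mask].sum(axis=0)
    phi = {s: acc[s] / (len(frames) * bin_vol) for s in PHI_SPECIES}
    V = float(np.prod(box))
    phi_global = {s: float(acc[s].sum() / (len(frames) * V)) for s in PHI_SPECIES}
    return Profile(
        z_bins=0.5 * (edges[:-1] + edges[1:]), phi=phi,
        phi_global=phi_global, n_snapshots=len(frames), box=box,
    )


# ---------------------------------------------------------------------------
# interface detection and alignment

#: minimum plateau contrast (max-min)/(max+min) for a profile to count as
#: structured rather than flat-within-noise
CONTRAST_THRESHOLD = 0.2


def _smooth_circular(y: np.ndarray, width: int = 3) -> np.ndarray:
    kernel = np.ones(width) / width
    pad = width // 2
    yp = np.concatenate([y[-pad:], y, y[:pad]])
    return np.convolve(yp, kernel, mode="valid")


def detect_interfaces(profile: Profile, reference: str | None = None):
    """Locate the two interfaces of a two-phase slab profile.

    The interface position is where the boxcar-smoothed (3-bin) reference
    species profile crosses the midpoint of its two bulk plateau levels.
    Returns ``(z_ascending, z_descending)``: the crossing with the
    reference phi rising in +z is "first" by convention.

    Raises
    ------
    MixedStateError
        If the profile is flat within noise or has no clean pair of
        midpoint crossings (mixed or microphase state).
    """
    from scipy.ndimage import binary_closing, binary_opening

    reference = reference or profile.reference
    y = profile.phi[reference]
    if y.max() <= 0:
        raise MixedStateError(f"reference species {reference!r} absent")
    ys = _smooth_circular(y)
    # plateau levels from percentiles (robust to single-bin noise spikes)
    lo, hi = (float(v) for v in np.percentile(ys, [10, 90]))
    contrast = (hi - lo) / (hi + lo) if hi + lo > 0 else 0.0
    if contrast < CONTRAST_THRESHOLD:
        raise MixedStateError(
            f"profile flat within noise (contrast {contrast:.3f}); "
            "use classify_state")
    mid = 0.5 * (lo + hi)
    n = ys.shape[0]
    dz = profile.bin_width
    high = ys > mid
    # bridge noise-induced gaps / islands shorter than 3 bins (circularly,
    # via wrap padding)
    struct = np.ones(3, dtype=bool)
    pad = 4
    wrapped = np.concatenate([high[-pad:], high, high[:pad]])
    wrapped = binary_closing(wrapped, structure=struct)
    wrapped = binary_opening(wrapped, structure=struct)
    high = wrapped[pad:-pad]
    if high.all() or not high.any():
        raise MixedStateError("no midpoint crossing; not a two-phase slab")
    # longest circular run of above-midpoint bins = the reference-rich slab
    best = None
    for k in range(n):
        if high[k] and not high[(k - 1) % n]:
            length = 0
            j = k
            while high[j % n] and length < n:
                length += 1
                j += 1
            if best is None or length > best[1]:
                best = (k, length)
    start, length = best
    end = (start + length - 1) % n

    def _cross(k_lo, k_hi):
        a, b = ys[k_lo], ys[k_hi]
        frac = 0.5 if b == a else min(1.0, max(0.0, (mid - a) / (b - a)))
        return (profile.z_bins[k_lo] + frac * dz) % float(profile.box[2])

    z_up = _cross((start - 1) % n, start)
    z_down = _cross(end, (end + 1) % n)
    return z_up, z_down


def detect_and_align(
    snapshots_or_profiles,
    n_bins: int | None = None,
    reference: str = "col",
    z_ref: float | None = None,
):
    """Align snapshots (or per-snapshot profiles) on their interfaces.

    Each snapshot is profiled individually and cyclically translated onto
    the first profile by maximizing the circular cross-correlation of the
    reference-species profile (robust against single-snapshot noise);
    the stack is then translated as a whole so the ascending interface
    of the aligned mean sits at ``z_ref`` (default L_z/4).  Returns the
    aligned snapshot-averaged :class:`Profile` and the per-snapshot
    ascending-interface positions.

    Raises
    ------
    MixedStateError
        If the aligned mean profile has no detectable pair of interfaces
        (mixed or microphase system) — use :func:`classify_state`.
    """
    items = list(snapshots_or_profiles)
    if not items:
        raise ValueError("nothing to align")
    if isinstance(items[0], Snapshot):
        profiles = [volume_fraction_profile(s, n_bins) for s in items]
    else:
        profiles = items
    p0 = profiles[0]
    Lz = float(p0.box[2])
    if z_ref is None:
        z_ref = 0.25 * Lz
    dz = p0.bin_width
    n = p0.n_bins

    ref_y = p0.phi[reference]
    shifts = []
    aligned_phi = {s: np.zeros(n) for s in PHI_SPECIES}
    for p in profiles:
        y = p.phi[reference]
        corr = np.real(np.fft.ifft(np.fft.fft(ref_y) * np.conj(np.fft.fft(y))))
        shift = int(np.argmax(corr))  # roll(y, shift) best matches ref_y
        shifts.append(shift)
        rolled = p.rolled(shift)
        for s in PHI_SPECIES:
            aligned_phi[s] += rolled.phi[s]
    m = len(profiles)
    mean_profile = Profile(
        z_bins=p0.z_bins,
        phi={s: v / m for s, v in aligned_phi.items()},
        phi_global={s: float(np.mean([p.phi_global[s] for p in profiles]))
                    for s in PHI_SPECIES},
        n_snapshots=sum(p.n_snapshots for p in profiles),
        box=p0.box, reference=reference,
    )
    # place the ascending interface of the mean at z_ref
    z_up, _ = detect_interfaces(mean_profile, reference)
    global_shift = int(round((z_ref - z_up) / dz))
    mean_profile = mean_profile.rolled(global_shift)
    positions = ((z_up - (np.asarray(shifts) + 0) * dz) % Lz)
    return mean_profile, positions


# ---------------------------------------------------------------------------
# bulk compositions and tie lines


def _circular_distance(z, z0, Lz):
    d = np.abs((z - z0 + 0.5 * Lz) % Lz - 0.5 * Lz)
    return d


def bulk_compositions(
    profile: Profile,
    margin: float | None = None,
    reference: str | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Mean phi per species in each bulk phase of an aligned profile.

    Bins closer than ``margin`` (default: the interfacial width estimate
    delta = 2 R_col (1 + q) = 2.904 l) to either interface are excluded.
    Returns ``(colloid_rich, dilute)`` composition dicts including the
    solvent fraction phi_s.
    """
    if margin is None:
        margin = default_interface_width()
    z_up, z_down = detect_interfaces(profile, reference)
    Lz = float(profile.box[2])
    z = profile.z_bins
    far = (_circular_distance(z, z_up, Lz) > margin) & \
          (_circular_distance(z, z_down, Lz) > margin)
    # the reference-rich phase runs from the ascending to the descending
    # interface in +z (circularly)
    inside = ((z - z_up) % Lz) < ((z_down - z_up) % Lz)
    phases = []
    for mask in (far & inside, far & ~inside):
        if not mask.any():
            raise InsufficientBulkError(
                f"phase thinner than 2 x margin ({margin:.3g} l); "
                "no bulk bins remain")
        comp = {s: float(profile.phi[s][mask].mean()) for s in PHI_SPECIES}
        comp["s"] = 1.0 - sum(comp[s] for s in PHI_SPECIES)
        comp["n_bins"] = int(mask.sum())
        phases.append(comp)
    return phases[0], phases[1]


@dataclass
class TieLine:
    """Tie-line end points: per-phase mean compositions with errors.

    ``err`` fields are one standard error of the mean; ``export()``
    doubles them (the 2 x SEM plotting convention).
    """

    phase_A: dict[str, float]
    phase_A_err: dict[str, float]
    phase_B: dict[str, float]
    phase_B_err: dict[str, float]
    n_runs: int

    def export(self) -> dict:
        return {
            "phase_A": self.phase_A,
            "phase_A_err_2sem": {k: 2 * v for k, v in self.phase_A_err.items()},
            "phase_B": self.phase_B,
            "phase_B_err_2sem": {k: 2 * v for k, v in self.phase_B_err.items()},
            "n_runs": self.n_runs,
        }


def tie_line(per_run_compositions) -> TieLine:
    """Average per-run coexisting compositions into a tie line.

    ``per_run_compositions`` is a sequence of (phase_1, phase_2) dicts,
    one pair per independent run.  Pairs are re-ordered by descending
    colloid phi before averaging, so runs that happened to label their
    phases oppositely are re-paired consistently.
    """
    runs = list(per_run_compositions)
    if len(runs) < 2:
        raise ValueError("need >= 2 independent runs for a standard error")
    keys = ("col", "poly", "tad", "s")
    A, B = [], []
    for a, b in runs:
        if a["col"] < b["col"]:
            a, b = b, a
        A.append([a[k] for k in keys])
        B.append([b[k] for k in keys])
    A = np.asarray(A)
    B = np.asarray(B)
    n = len(runs)

    def stats(M):
        mean = {k: float(m) for k, m in zip(keys, M.mean(axis=0))}
        sem = {k: float(s) for k, s in
               zip(keys, M.std(axis=0, ddof=1) / math.sqrt(n))}
        return mean, sem

    mA, eA = stats(A)
    mB, eB = stats(B)
    return TieLine(phase_A=mA, phase_A_err=eA, phase_B=mB, phase_B_err=eB,
                   n_runs=n)


# ---------------------------------------------------------------------------
# radius of gyration


@dataclass
class GyrationResult:
    """Chain radius of gyration and the size ratio q = R_g / R_col."""

    R_g: float
    R_g_err: float
    q: float
    q_err: float
    n_samples: int
    tail_only: bool = True


def _unwrap_chain(snapshot: Snapshot, bead_idx: np.ndarray) -> np.ndarray:
    """Unwrap a bonded chain (beads in chain order) across the box."""
    pos = snapshot.positions[bead_idx]
    out = pos.copy()
    for k in range(1, len(bead_idx)):
        d = snapshot.minimum_image(pos[k] - pos[k - 1])
        out[k] = out[k - 1] + d
    return out


def radius_of_gyration(
    trajectory: Trajectory | list[Snapshot] | Snapshot,
    kind: str = "polymer",
    molecule_ids=None,
    tail_only: bool = True,
    R_col: float | None = None,
    max_bond_stretch: float = 2.0,
) -> GyrationResult:
    """R_g of the selected chains, averaged over molecules and snapshots.

    Chains are unwrapped across the periodic boundaries along their bond
    connectivity before computing R_g^2 (equal bead weights).  For
    tadpoles the default measures the tail only; ``tail_only=False``
    includes the head bead.  q is R_g / R_col with the system's colloid
    radius.

    Raises
    ------
    ValueError
        If a bond's minimum-image length exceeds ``max_bond_stretch``
        times the hard window maximum (a broken topology).
    """
    if isinstance(trajectory, Snapshot):
        frames = [trajectory]
        topo = trajectory.topology
    elif isinstance(trajectory, Trajectory):
        frames = list(trajectory.frames)
        topo = trajectory.topology
    else:
        frames = list(trajectory)
        topo = frames[0].topology
    params = topo.species_params
    if R_col is None:
        R_col = params.R_col

    wanted = []
    for m, mol in enumerate(topo.molecules):
        if molecule_ids is not None:
            if m in molecule_ids:
                wanted.append(m)
        elif mol.kind == kind:
            wanted.append(m)
    if not wanted:
        raise ValueError(f"no molecules selected (kind={kind!r})")

    window_max = (2 * params.R_col + 3 * params.R_tail) * max_bond_stretch
    samples = []
    for snap in frames:
        for m in wanted:
            sel = np.flatnonzero(topo.molecule_id == m)
            sel = sel[np.argsort(topo.bead_index[sel])]
            if topo.molecules[m].kind == "tadpole" and tail_only:
                chain = sel  # unwrap with the head, then drop it
            else:
                chain = sel
            un = _unwrap_chain(snap, chain)
            steps = np.linalg.norm(np.diff(un, axis=0), axis=1)
            if steps.size and steps.max() > window_max:
                raise ValueError(
                    f"broken bond in molecule {m}: step {steps.max():.3f} l")
            if topo.molecules[m].kind == "tadpole" and tail_only:
                un = un[1:]
            if len(un) == 1:
                samples.append(0.0)
                continue
            com = un.mean(axis=0)
            samples.append(float(np.mean(np.sum((un - com) ** 2, axis=1))))
    rg2 = np.asarray(samples)
    rg = math.sqrt(rg2.mean())
    if len(samples) > 1:
        # delta-method error on sqrt of the mean
        sem2 = rg2.std(ddof=1) / math.sqrt(len(samples))
        err = 0.5 * sem2 / rg if rg > 0 else 0.0
    else:
        err = 0.0
    return GyrationResult(R_g=rg, R_g_err=err, q=rg / R_col, q_err=err / R_col,
                          n_samples=len(samples), tail_only=tail_only)


# ---------------------------------------------------------------------------
# state classification and equilibration


def _large_bead_clusters(snapshot: Snapshot, tol: float = 0.1):
    """Connected clusters of large beads (contact distance + tol)."""
    big = np.flatnonzero(snapshot.radii > 0.25)
    if big.size == 0:
        return 0, 0.0
    pos = snapshot.positions[big]
    R = snapshot.radii[big]
    box = snapshot.box
    n = big.size
    rows, cols = [], []
    for i in range(n):
        dr = pos[i + 1:] - pos[i]
        dr -= box * np.round(dr / box)
        d = np.linalg.norm(dr, axis=1)
        touch = np.flatnonzero(d < R[i] + R[i + 1:] + tol)
        rows.extend([i] * touch.size)
        cols.extend((touch + i + 1).tolist())
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    largest = np.bincount(labels).max() / n
    return n_comp, float(largest)


def classify_state(
    snapshots: Trajectory | list[Snapshot],
    n_bins: int | None = None,
    reference: str = "col",
    margin: float | None = None,
):
    """Label a trajectory as ``mixed``, ``macrophase`` or ``microphase``.

    Macrophase: interface detection and bulk extraction succeed (two
    stable interfaces with distinct plateaus).  Mixed: profiles flat
    within noise.  Microphase: neither — plateau detection fails while
    the large beads are neither one slab nor dispersed.  Returns
    ``(label, diagnostics)``.
    """
    frames = list(snapshots)
    diag: dict = {}
    if reference == "col":
        # fall back to the tadpole profile when no colloids are present
        probe = volume_fraction_profile(frames[-1], n_bins)
        if probe.phi_global["col"] == 0.0:
            reference = "tad"
    try:
        profile, positions = detect_and_align(frames, n_bins, reference)
        diag["interface_positions"] = positions
        phase_a, phase_b = bulk_compositions(profile, margin, reference)
        diag["bulk_compositions"] = (phase_a, phase_b)
        diag["plateau_contrast"] = float(
            abs(phase_a[reference if reference in PHI_SPECIES else "col"]
                - phase_b[reference if reference in PHI_SPECIES else "col"]))
        return "macrophase", diag
    except (MixedStateError, InsufficientBulkError) as exc:
        diag["profile_failure"] = str(exc)

    mean_profile = volume_fraction_profile(frames, n_bins)
    y = mean_profile.ratio(reference)
    if y is not None:
        ys = _smooth_circular(y)
        contrast = float((ys.max() - ys.min()) / (ys.max() + ys.min()))
    else:
        contrast = 0.0
    diag["contrast"] = contrast
    n_clusters, largest = _large_bead_clusters(frames[-1])
    diag["n_large_clusters"] = n_clusters
    diag["largest_cluster_fraction"] = largest
    if contrast < CONTRAST_THRESHOLD:
        return "mixed", diag
    return "microphase", diag


def equilibration_check(
    trajectory: Trajectory | list[Snapshot],
    n_bins: int | None = None,
    reference: str = "col",
    margin: float | None = None,
):
    """Heuristic equilibration verdict from the stored snapshots.

    Splits the snapshots into halves and passes iff (a) interface
    detection agrees between the halves (both two-phase or both not) and
    (b) when two-phase, the per-species bulk compositions of the halves
    agree within twice the combined standard error of the mean.  Returns
    ``(passed, diagnostics)`` with the numbers behind the verdict.
    """
    frames = list(trajectory)
    if len(frames) < 4:
        raise ValueError("need at least 4 snapshots to compare halves")
    half = len(frames) // 2
    halves = (frames[:half], frames[half:])

    def half_stats(snaps):
        comps = []
        for s in snaps:
            try:
                prof, _ = detect_and_align([s], n_bins, reference)
                a, b = bulk_compositions(prof, margin, reference)
                comps.append((a, b))
            except (MixedStateError, InsufficientBulkError):
                comps.append(None)
        return comps

    stats = [half_stats(h) for h in halves]
    counts = [sum(c is not None for c in st) for st in stats]
    diag = {"n_snapshots": len(frames),
            "two_phase_snapshots_per_half": counts}
    two_phase = [c > len(st) / 2 for c, st in zip(counts, stats)]
    if two_phase[0] != two_phase[1]:
        diag["reason"] = "interface count changed between halves"
        return False, diag
    if not two_phase[0]:
        diag["reason"] = "no stable interfaces in either half"
        return True, diag

    keys = ("col", "poly", "tad", "s")
    passed = True
    deltas = {}
    for phase in (0, 1):
        for k in keys:
            vals = [np.asarray([c[phase][k] for c in st if c is not None])
                    for st in stats]
            m = [v.mean() for v in vals]
            sem = [v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else 0.0
                   for v in vals]
            combined = math.hypot(sem[0], sem[1])
            delta = abs(m[0] - m[1])
            deltas[f"phase{phase}_{k}"] = (delta, 2.0 * combined)
            if delta > 2.0 * combined + 1e-12:
                passed = False
    diag["half_differences_vs_2sem"] = deltas
    return passed, diag
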