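"""Softened-system observables: forces, pressure tensor and interfacial
tension via the Kirkwood-Buff route.

The tension of a slab system with two planar interfaces perpendicular to
z is the z-integral of the normal-tangential pressure anisotropy,

    gamma = (L_z / 2) * < P_zz - (P_xx + P_yy) / 2 >,

evaluated from the box-integrated virial (the ideal-gas terms cancel in
the anisotropy; the 1/2 accounts for the two interfaces the periodic
slab necessarily contains).  The sign convention makes gamma positive
for a stable interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import SoftParams
from .snapshot import Snapshot, Trajectory
from .units import UnitSystem

__all__ = [
    "TensionResult",
    "total_soft_energy_forces",
    "pressure_tensor",
    "kirkwood_buff_gamma",
    "scale_and_convert",
    "default_interface_width",
]


def default_interface_width(R_col: float = 0.44, q: float = 2.3) -> float:
    """Estimated interfacial width delta = 2 R_col (1 + q), in code units.

    With the model defaults this is 2.904 l = 36.3 nm.
    """
    return 2.0 * R_col * (1.0 + q)


@dataclass(frozen=True)
class TensionResult:
    """Interfacial tension in code, scaled and SI forms.

    ``gamma_scaled = gamma_code * delta^2`` (delta in l; k_B T = 1 in
    code units) and ``gamma_SI = gamma_code * (eps/l^2 in uN/m)``; the
    errors propagate linearly through both scalings.
    """

    gamma_code: float
    gamma_code_err: float
    gamma_scaled: float
    gamma_scaled_err: float
    gamma_SI: float
    gamma_SI_err: float
    delta_code: float
    delta_nm: float
    n_snapshots: int


def _soft_arrays(snapshot: Snapshot, soft: SoftParams | None):
    topo = snapshot.topology
    soft = soft or SoftParams(species=topo.species_params)
    if topo.n_bonds:
        k_F, R_F = topo.soft_bond_params(soft)
        bonds = topo.bonds
    else:
        bonds = np.empty((0, 2), dtype=np.int64)
        k_F = np.empty(0)
        R_F = np.empty(0)
    return soft, bonds, k_F, R_F


def total_soft_energy_forces(
    snapshot: Snapshot, soft: SoftParams | None = None
) -> tuple[float, np.ndarray]:
    """Total WCA + FENE energy [eps] and per-bead net forces [eps/l].

    WCA repulsion acts between every pair within its cutoff (bonded or
    not); FENE acts along bonds.  Forces obey Newton's third law
    pairwise, so the returned array sums to zero.

    Raises
    ------
    ValueError
        If any bond is stretched to r >= R_F (infinite energy).
    """
    soft, bonds, k_F, R_F = _soft_arrays(snapshot, soft)
    energy, forces, _ = _kernels.soft_forces_virial(
        snapshot.positions, snapshot.radii, np.asarray(snapshot.box, float),
        bonds, k_F, R_F, soft.u_W)
    if math.isinf(energy):
        bad = _overextended_bonds(snapshot, bonds, R_F)
        raise ValueError(f"bond(s) at or beyond full FENE extension: {bad}")
    return energy, forces


def _overextended_bonds(snapshot, bonds, R_F):
    out = []
    for b in range(bonds.shape[0]):
        dr = snapshot.minimum_image(
            snapshot.positions[bonds[b, 0]] - snapshot.positions[bonds[b, 1]])
        if np.linalg.norm(dr) >= R_F[b]:
            out.append(tuple(int(x) for x in bonds[b]))
    return out


def pressure_tensor(snapshot: Snapshot, soft: SoftParams | None = None) -> np.ndarray:
    """Virial pressure tensor [eps/l^3].

    P_ab = (N k_B T delta_ab + sum_pairs f_ij,a r_ij,b) / V with
    minimum-image pair separations; symmetric up to round-off.
    """
    soft, bonds, k_F, R_F = _soft_arrays(snapshot, soft)
    box = np.asarray(snapshot.box, float)
    energy, _, virial = _kernels.soft_forces_virial(
        snapshot.positions, snapshot.radii, box, bonds, k_F, R_F, soft.u_W)
    if math.isinf(energy):
        bad = _overextended_bonds(snapshot, bonds, R_F)
        raise ValueError(f"bond(s) at or beyond full FENE extension: {bad}")
    V = float(np.prod(box))
    N = snapshot.n_beads
    return (N * np.eye(3) + virial) / V


def gamma_per_snapshot(snapshot: Snapshot, soft: SoftParams | None = None) -> float:
    """Instantaneous gamma_snap = (L_z/2) (P_zz - (P_xx + P_yy)/2)."""
    P = pressure_tensor(snapshot, soft)
    Lz = float(snapshot.box[2])
    return 0.5 * Lz * (P[2, 2] - 0.5 * (P[0, 0] + P[1, 1]))


def kirkwood_buff_gamma(
    trajectory: Trajectory | list[Snapshot],
    units: UnitSystem | None = None,
    delta: float | None = None,
    soft: SoftParams | None = None,
) -> TensionResult:
    """Interfacial tension of a two-interface slab trajectory.

    Averages the per-snapshot anisotropy integral over the trajectory;
    the quoted error is the standard error of the mean over snapshots.

    Parameters
    ----------
    delta :
        Interface width used for the dimensionless scaling, in code
        units; defaults to 2 R_col (1 + q) = 2.904 l.
    """
    frames = list(trajectory)
    if len(frames) < 2:
        raise ValueError("need at least 2 snapshots to estimate an error")
    box = np.asarray(frames[0].box, float)
    if box[2] < max(box[0], box[1]):
        import warnings

        warnings.warn("box is not slab-shaped (L_z is not the long axis); "
                      "Kirkwood-Buff assumes interfaces perpendicular to z",
                      stacklevel=2)
    gammas = np.array([gamma_per_snapshot(f, soft) for f in frames])
    g = float(gammas.mean())
    err = float(gammas.std(ddof=1) / math.sqrt(len(gammas)))
    return _make_result(g, err, units, delta, len(frames))


def _make_result(g, err, units, delta, n):
    units = units or UnitSystem()
    if delta is None:
        delta = default_interface_width()
    if delta <= 0:
        raise ValueError("delta must be positive")
    scaled, si = scale_and_convert(g, units, delta)
    return TensionResult(
        gamma_code=g, gamma_code_err=err,
        gamma_scaled=scaled, gamma_scaled_err=err * delta**2,
        gamma_SI=si, gamma_SI_err=err * units.tension_unit_uN_per_m,
        delta_code=delta, delta_nm=units.length_to_nm(delta),
        n_snapshots=n,
    )


def scale_and_convert(
    gamma_code: float, units: UnitSystem | None = None, delta: float | None = None
) -> tuple[float, float]:
    """Scale a code-unit tension to (gamma delta^2 / k_B T, gamma in uN/m).

    ``delta`` defaults to 2 R_col (1 + q) = 2.904 l (36.3 nm); the SI
    conversion uses k_B T / l^2 at the unit system's temperature.
    """
    units = units or UnitSystem()
    if delta is None:
        delta = default_interface_width()
    if delta <= 0:
        raise ValueError("delta must be positive")
    return gamma_code * delta**2, units.tension_to_SI(gamma_code)
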