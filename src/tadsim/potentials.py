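"""Pair and bond potentials, forces, and Stokes-Einstein diffusivities.

Hard potentials take only the values {0, +inf}; the soft (WCA/FENE) mode
has well-defined forces used for the virial pressure tensor.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "hard_pair_energy",
    "hard_bond_energy",
    "wca_energy_force",
    "fene_energy_force",
    "diffusivity",
]

_WCA_CUT = 2.0 ** (1.0 / 6.0)
#: Below this separation (in units of R_W) the WCA force evaluation is
#: treated as divergent; the energy is +inf so Metropolis always rejects.
_WCA_R_FLOOR = 1e-9


def hard_pair_energy(r: float, R_i: float, R_j: float) -> float:
    """Hard-sphere excluded volume: +inf for r < R_i + R_j, else 0.

    The inequality is strict: exact contact (r = R_i + R_j) is allowed.
    """
    if r < 0:
        raise ValueError("separation r must be non-negative")
    if R_i <= 0 or R_j <= 0:
        raise ValueError("radii must be positive")
    return math.inf if r < R_i + R_j else 0.0


def hard_bond_energy(r: float, R_i: float, R_j: float, R_tail: float = 0.0908) -> float:
    """Hard square-well bond: 0 for r < R_i + R_j + 3 R_tail, else +inf.

    Acts alongside :func:`hard_pair_energy`, so the allowed window for a
    bonded pair is R_i + R_j <= r < R_i + R_j + 3 R_tail.
    """
    if r < 0:
        raise ValueError("separation r must be non-negative")
    if R_i <= 0 or R_j <= 0 or R_tail <= 0:
        raise ValueError("radii must be positive")
    return 0.0 if r < R_i + R_j + 3.0 * R_tail else math.inf


def wca_energy_force(
    r: float, R_i: float, R_j: float, u_W: float = 1.0
) -> tuple[float, float]:
    """Weeks-Chandler-Andersen repulsion between beads i and j.

    With s = r / R_W and R_W = R_i + R_j:

        U(s) = 4 u_W (s^-12 - s^-6 + 1/4)   for s < 2^(1/6), else 0.

    Returns ``(energy, force_magnitude)`` where the force is -dU/dr,
    repulsive (>= 0) and exactly zero at and beyond the cutoff.

    Raises
    ------
    ZeroDivisionError
        If r is zero (or numerically indistinguishable from it); in a
        Metropolis energy evaluation callers should map this to +inf.
    """
    if r < 0:
        raise ValueError("separation r must be non-negative")
    R_W = R_i + R_j
    if r < _WCA_R_FLOOR * R_W:
        raise ZeroDivisionError("WCA evaluation at r ~ 0 diverges")
    s = r / R_W
    if s >= _WCA_CUT:
        return 0.0, 0.0
    inv6 = s**-6
    energy = 4.0 * u_W * (inv6 * inv6 - inv6 + 0.25)
    # -dU/dr = (4 u_W / R_W) (12 s^-13 - 6 s^-7)
    force = 4.0 * u_W * (12.0 * inv6 * inv6 - 6.0 * inv6) / r
    return energy, force


def fene_energy_force(r: float, k_F: float, R_F: float) -> tuple[float, float]:
    """Finitely extensible nonlinear elastic bond.

        U(r) = -1/2 k_F R_F^2 ln(1 - (r/R_F)^2)   for r < R_F, else +inf.

    Returns ``(energy, force_magnitude)``; the force magnitude is
    k_F r / (1 - (r/R_F)^2), directed back toward r = 0.  At r >= R_F the
    energy is +inf and the force is +inf — a Metropolis move-rejection
    signal, not an exception.
    """
    if r < 0:
        raise ValueError("separation r must be non-negative")
    if k_F <= 0 or R_F <= 0:
        raise ValueError("k_F and R_F must be positive")
    x2 = (r / R_F) ** 2
    if x2 >= 1.0:
        return math.inf, math.inf
    energy = -0.5 * k_F * R_F**2 * math.log1p(-x2)
    force = k_F * r / (1.0 - x2)
    return energy, force


def diffusivity(R_i: float, R_tail: float = 0.0908) -> float:
    """Stokes-Einstein diffusivity in code units l^2/tau.

    With tau defined as the time for a tail bead to diffuse its own size,
    D_i = R_tail^3 / (6 R_i); in particular D_tail = R_tail^2 / 6 so that
    <r^2> = 6 D_tail tau = R_tail^2 exactly.
    """
    R_i = np.asarray(R_i, dtype=float) if np.ndim(R_i) else float(R_i)
    if np.any(np.asarray(R_i) <= 0) or R_tail <= 0:
        raise ValueError("radii must be positive")
    return R_tail**3 / (6.0 * R_i)
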