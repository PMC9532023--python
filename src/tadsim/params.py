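"""Model parameters: bead sizes, chain lengths and softened-potential constants.

The defaults reproduce the reference parameter set of the tadpole model
(all lengths in code units l, energies in eps = k_B T):

==================  ========  =======================================
parameter           default   meaning
==================  ========  =======================================
R_col = R_head      0.44      colloid / tadpole-head radius
R_mono = R_tail     0.0908    polymer / tadpole-tail bead radius
N_mono              30        beads per polymer
N_tail              15 or 30  beads per tadpole tail
dt                  0.4 tau   Monte Carlo time increment
u_W                 1 eps     WCA energy scale (soft mode)
k_F (tail-tail)     7.822     FENE spring constant, eps/l^2
k_F (head-tail)     2.558     FENE spring constant, eps/l^2
==================  ========  =======================================

Soft-mode length scales are derived per bonded/interacting pair:
R_W = R_i + R_j (WCA) and R_F = R_i + R_j + 4 R_tail (FENE maximum
extension).  The hard bond window is [R_i + R_j, R_i + R_j + 3 R_tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Versioned table of model defaults (code units).
PARAMETER_TABLE_VERSION = "1.0"
PARAMETER_TABLE = {
    "length_unit_nm": 12.5,
    "R_col": 0.44,
    "R_head": 0.44,
    "R_mono": 0.0908,
    "R_tail": 0.0908,
    "N_mono": 30,
    "dt": 0.4,
    "u_W": 1.0,
    "k_F_tail": 7.822,
    "k_F_head": 2.558,
    "q_reference": 2.3,  # R_g / R_col for a 30-bead chain
}


@dataclass(frozen=True)
class SpeciesParams:
    """Bead radii and chain lengths for the three molecule kinds.

    The model simplification ``R_head = R_col`` and ``R_tail = R_mono``
    is applied unless the fields are overridden explicitly.
    """

    R_col: float = 0.44
    R_head: float | None = None
    R_mono: float = 0.0908
    R_tail: float | None = None
    N_mono: int = 30
    N_tail: int = 30

    def __post_init__(self) -> None:
        if self.R_head is None:
            object.__setattr__(self, "R_head", self.R_col)
        if self.R_tail is None:
            object.__setattr__(self, "R_tail", self.R_mono)
        for name in ("R_col", "R_head", "R_mono", "R_tail"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.N_mono < 1 or self.N_tail < 1:
            raise ValueError("chain lengths must be >= 1")

    def hard_bond_window(self, R_i: float, R_j: float) -> tuple[float, float]:
        """Allowed separation window [r_min, r_max) for a hard bond."""
        return (R_i + R_j, R_i + R_j + 3.0 * self.R_tail)


@dataclass(frozen=True)
class SoftParams:
    """WCA/FENE constants for the softened (tension-measurement) mode."""

    u_W: float = 1.0
    k_F_tail: float = 7.822
    k_F_head: float = 2.558
    species: SpeciesParams = field(default_factory=SpeciesParams)

    def __post_init__(self) -> None:
        if self.u_W <= 0:
            raise ValueError("u_W must be positive")
        if self.k_F_tail <= 0 or self.k_F_head <= 0:
            raise ValueError("FENE spring constants must be positive")

    def R_W(self, R_i: float, R_j: float) -> float:
        return R_i + R_j

    def R_F(self, R_i: float, R_j: float) -> float:
        return R_i + R_j + 4.0 * self.species.R_tail
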