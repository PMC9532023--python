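"""System compositions and the polymer + colloid -> tadpole transform."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .params import SpeciesParams


@dataclass(frozen=True)
class CompositionSpec:
    """Counts, chain lengths and box of one simulated system.

    The box is periodic with L_x = L_y and the long axis along z (slab
    geometries put their interfaces perpendicular to z).  ``max_packing``
    is a feasibility ceiling on the total bead volume fraction; dense
    micelle-forming systems may need it raised above the 0.45 default.
    """

    N_col: int
    N_poly: int
    N_tad: int
    box: tuple[float, float, float]
    N_mono: int = 30
    N_tail: int = 30
    max_packing: float = 0.45

    def __post_init__(self) -> None:
        if min(self.N_col, self.N_poly, self.N_tad) < 0:
            raise ValueError("molecule counts must be non-negative")
        if self.N_mono < 1 or self.N_tail < 1:
            raise ValueError("chain lengths must be >= 1")
        Lx, Ly, Lz = self.box
        if min(Lx, Ly, Lz) <= 0:
            raise ValueError("box dimensions must be positive")
        if not math.isclose(Lx, Ly):
            raise ValueError("box must have L_x = L_y")
        phi = self.total_bead_volume() / self.volume
        if phi >= self.max_packing:
            raise ValueError(
                f"infeasible composition: total bead volume fraction {phi:.3f} "
                f">= packing ceiling {self.max_packing}"
            )

    @property
    def volume(self) -> float:
        Lx, Ly, Lz = self.box
        return Lx * Ly * Lz

    def species_params(self) -> SpeciesParams:
        return SpeciesParams(N_mono=self.N_mono, N_tail=self.N_tail)

    def total_bead_volume(self, params: SpeciesParams | None = None) -> float:
        params = params or self.species_params()
        v_big = 4.0 / 3.0 * math.pi * params.R_col**3
        v_small = 4.0 / 3.0 * math.pi * params.R_mono**3
        return (
            self.N_col * v_big
            + self.N_poly * self.N_mono * v_small
            + self.N_tad * (v_big + self.N_tail * v_small)
        )


def fuse_composition(base: CompositionSpec, k: int) -> CompositionSpec:
    """Fuse ``k`` (colloid, polymer) pairs into ``k`` tadpoles.

    Keeps the total number of large particles (colloids + tadpole heads)
    and of small beads (polymer + tail beads, when N_tail = N_mono)
    constant; box and chain lengths are unchanged.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > base.N_col or k > base.N_poly:
        raise ValueError(
            f"cannot fuse {k} pairs from (N_col={base.N_col}, N_poly={base.N_poly})"
        )
    if base.N_tail != base.N_mono:
        raise ValueError("fuse_composition requires N_tail = N_mono")
    return replace(base, N_col=base.N_col - k, N_poly=base.N_poly - k,
                   N_tad=base.N_tad + k)


def composition_volume_fractions(spec: CompositionSpec) -> dict[str, float]:
    """Per-species volume fractions phi and the implicit-solvent remainder.

    Each species' volume is the summed volume of the individual beads of
    its molecules (a tadpole counts its head plus all tail beads);
    phi_s = 1 - phi_col - phi_tad - phi_poly is the solvent fraction.
    """
    params = spec.species_params()
    v_big = 4.0 / 3.0 * math.pi * params.R_col**3
    v_small = 4.0 / 3.0 * math.pi * params.R_mono**3
    V = spec.volume
    phi = {
        "col": spec.N_col * v_big / V,
        "poly": spec.N_poly * spec.N_mono * v_small / V,
        "tad": spec.N_tad * (v_big + spec.N_tail * v_small) / V,
    }
    phi["s"] = 1.0 - phi["col"] - phi["poly"] - phi["tad"]
    if phi["s"] < 0:
        raise ValueError("infeasible composition: solvent volume fraction < 0")
    return phi
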