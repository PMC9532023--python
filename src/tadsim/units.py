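"""Code units and their SI mapping.

All simulation quantities are carried in code units:

* length  ``l``   — one code length unit, 12.5 nm by default,
* energy  ``eps`` — the thermal energy ``k_B T`` (so energies are in units
  of k_B T and the Metropolis test needs no temperature factor),
* time    ``tau`` — the time a tail-sized bead takes to diffuse its own
  size, which fixes every diffusivity as ``D_i = R_tail^3 / (6 R_i)`` in
  ``l^2/tau`` without an explicit solvent viscosity.

SI conversion happens only at output (tensions in uN/m, lengths in nm).
"""

from __future__ import annotations

from dataclasses import dataclass

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between code units (l, tau, eps) and SI.

    Parameters
    ----------
    length_unit_nm :
        Physical size of one code length unit, in nanometres.
    temperature_K :
        Absolute temperature used when converting energies to SI.
    """

    length_unit_nm: float = 12.5
    temperature_K: float = 300.0

    def __post_init__(self) -> None:
        if self.length_unit_nm <= 0:
            raise ValueError("length_unit_nm must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")

    @property
    def energy_unit_J(self) -> float:
        """One eps = k_B T in joules."""
        return BOLTZMANN_J_PER_K * self.temperature_K

    @property
    def tension_unit_uN_per_m(self) -> float:
        """One eps/l^2 expressed in micronewtons per metre.

        At 300 K and l = 12.5 nm this is 26.51 uN/m.
        """
        length_m = self.length_unit_nm * 1e-9
        return self.energy_unit_J / length_m**2 * 1e6

    def length_to_nm(self, x: float) -> float:
        return x * self.length_unit_nm

    def tension_to_SI(self, gamma_code: float) -> float:
        """Convert a tension from eps/l^2 to uN/m."""
        return gamma_code * self.tension_unit_uN_per_m
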