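"""Molecule topologies: colloids, polymers and tadpoles.

A colloid is a single large bead.  A polymer is a linear chain of
``N_mono`` small beads.  A tadpole is one large "head" bead (the globular
domain) bonded to a chain of ``N_tail`` small "tail" beads (the
intrinsically disordered region); the head is grafted to tail bead 0, so
a tadpole with N_tail = N_mono is exactly a colloid fused to a polymer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import SpeciesParams

#: integer species codes used in snapshots
SPECIES_COL = 0
SPECIES_HEAD = 1
SPECIES_MONO = 2
SPECIES_TAIL = 3
SPECIES_LABELS = {SPECIES_COL: "col", SPECIES_HEAD: "head",
                  SPECIES_MONO: "mono", SPECIES_TAIL: "tail"}
SPECIES_CODES = {v: k for k, v in SPECIES_LABELS.items()}

MOLECULE_KINDS = ("colloid", "polymer", "tadpole")


@dataclass(frozen=True)
class MoleculeTopology:
    """Bead radii, species labels and chain bonds of one molecule."""

    kind: str
    bead_radii: tuple[float, ...]
    bead_species: tuple[int, ...]
    bonds: tuple[tuple[int, int], ...] = field(default=())

    @property
    def n_beads(self) -> int:
        return len(self.bead_radii)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


def build_topology(kind: str, params: SpeciesParams | None = None) -> MoleculeTopology:
    """Construct the topology of a single molecule of the given kind.

    Parameters
    ----------
    kind :
        One of ``"colloid"``, ``"polymer"``, ``"tadpole"``.
    params :
        Bead radii and chain lengths; model defaults when omitted.
    """
    params = params or SpeciesParams()
    if kind == "colloid":
        return MoleculeTopology(
            kind="colloid",
            bead_radii=(params.R_col,),
            bead_species=(SPECIES_COL,),
            bonds=(),
        )
    if kind == "polymer":
        n = params.N_mono
        return MoleculeTopology(
            kind="polymer",
            bead_radii=(params.R_mono,) * n,
            bead_species=(SPECIES_MONO,) * n,
            bonds=tuple((i, i + 1) for i in range(n - 1)),
        )
    if kind == "tadpole":
        n = params.N_tail
        # bead 0 is the head; tail beads are 1..n, head grafted to tail bead 0
        return MoleculeTopology(
            kind="tadpole",
            bead_radii=(params.R_head,) + (params.R_tail,) * n,
            bead_species=(SPECIES_HEAD,) + (SPECIES_TAIL,) * n,
            bonds=tuple((i, i + 1) for i in range(n)),
        )
    raise ValueError(f"unknown molecule kind {kind!r}; expected one of {MOLECULE_KINDS}")
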