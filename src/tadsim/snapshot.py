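"""In-memory containers: system topology, snapshots and trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .composition import CompositionSpec
from .params import SoftParams, SpeciesParams
from .topology import (
    SPECIES_HEAD,
    SPECIES_TAIL,
    MoleculeTopology,
    build_topology,
)

#: bond kinds
BOND_TAIL = 0  # between two small beads (polymer or tail chain)
BOND_HEAD = 1  # between a tadpole head and its first tail bead


@dataclass(frozen=True)
class SystemTopology:
    """Flattened per-bead and per-bond arrays for a whole system.

    Beads are ordered molecule by molecule; ``molecule_id`` and
    ``bead_index`` recover the per-molecule structure.  ``bond_adjacency``
    lists, for every bead, the indices of its bonded partners (padded
    with -1; chain connectivity means at most two partners per bead).
    """

    molecules: tuple[MoleculeTopology, ...]
    radii: np.ndarray          # (N,)
    species: np.ndarray        # (N,) int codes
    molecule_id: np.ndarray    # (N,)
    bead_index: np.ndarray     # (N,) position within the molecule
    bonds: np.ndarray          # (M, 2) global bead indices
    bond_kind: np.ndarray      # (M,) BOND_TAIL or BOND_HEAD
    species_params: SpeciesParams = field(default_factory=SpeciesParams)

    @property
    def n_beads(self) -> int:
        return self.radii.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bonds.shape[0]

    def bond_windows(self) -> tuple[np.ndarray, np.ndarray]:
        """Hard-bond windows [r_min, r_max) per bond."""
        Ri = self.radii[self.bonds[:, 0]]
        Rj = self.radii[self.bonds[:, 1]]
        r_min = Ri + Rj
        r_max = Ri + Rj + 3.0 * self.species_params.R_tail
        return r_min, r_max

    def soft_bond_params(self, soft: SoftParams | None = None) -> tuple[np.ndarray, np.ndarray]:
        """FENE (k_F, R_F) per bond."""
        soft = soft or SoftParams(species=self.species_params)
        Ri = self.radii[self.bonds[:, 0]]
        Rj = self.radii[self.bonds[:, 1]]
        k_F = np.where(self.bond_kind == BOND_HEAD, soft.k_F_head, soft.k_F_tail)
        R_F = Ri + Rj + 4.0 * soft.species.R_tail
        return k_F, R_F

    def bond_adjacency(self) -> np.ndarray:
        """(N, 2) bonded-partner indices, padded with -1."""
        adj = np.full((self.n_beads, 2), -1, dtype=np.int64)
        count = np.zeros(self.n_beads, dtype=np.int64)
        for a, b in self.bonds:
            adj[a, count[a]] = b
            count[a] += 1
            adj[b, count[b]] = a
            count[b] += 1
        return adj


def build_system_topology(spec: CompositionSpec) -> SystemTopology:
    """Expand a composition into flat per-bead arrays.

    Molecule order is colloids, then polymers, then tadpoles.
    """
    params = spec.species_params()
    mols: list[MoleculeTopology] = []
    mols += [build_topology("colloid", params)] * spec.N_col
    mols += [build_topology("polymer", params)] * spec.N_poly
    mols += [build_topology("tadpole", params)] * spec.N_tad

    radii, species, mol_id, bead_idx = [], [], [], []
    bonds, bond_kind = [], []
    offset = 0
    for m, mol in enumerate(mols):
        radii.extend(mol.bead_radii)
        species.extend(mol.bead_species)
        mol_id.extend([m] * mol.n_beads)
        bead_idx.extend(range(mol.n_beads))
        for a, b in mol.bonds:
            bonds.append((offset + a, offset + b))
            ka = mol.bead_species[a] == SPECIES_HEAD or mol.bead_species[b] == SPECIES_HEAD
            bond_kind.append(BOND_HEAD if ka else BOND_TAIL)
        offset += mol.n_beads

    return SystemTopology(
        molecules=tuple(mols),
        radii=np.asarray(radii, dtype=np.float64),
        species=np.asarray(species, dtype=np.int64),
        molecule_id=np.asarray(mol_id, dtype=np.int64),
        bead_index=np.asarray(bead_idx, dtype=np.int64),
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_kind=np.asarray(bond_kind, dtype=np.int64),
        species_params=params,
    )


@dataclass
class Snapshot:
    """One configuration: periodic box, wrapped positions and metadata."""

    box: np.ndarray            # (3,)
    positions: np.ndarray      # (N, 3), wrapped into [0, L)
    topology: SystemTopology
    time: float = 0.0
    mode: str = "hard"

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.shape != (self.topology.n_beads, 3):
            raise ValueError("positions shape does not match topology")

    @property
    def radii(self) -> np.ndarray:
        return self.topology.radii

    @property
    def species(self) -> np.ndarray:
        return self.topology.species

    @property
    def molecule_id(self) -> np.ndarray:
        return self.topology.molecule_id

    @property
    def n_beads(self) -> int:
        return self.topology.n_beads

    def copy(self) -> "Snapshot":
        return replace(self, positions=self.positions.copy(),
                       box=self.box.copy())

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        return dr - self.box * np.round(dr / self.box)


@dataclass
class Trajectory:
    """Time-ordered snapshots sharing one topology, plus run metadata."""

    frames: list[Snapshot]
    topology: SystemTopology
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.time for f in self.frames])
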