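"""Trajectory, topology and config I/O.

Snapshots are stored as extended XYZ (one frame per snapshot; per-atom
columns ``species x y z radius molecule_id bead_index``; the comment
line carries the box, time and mode).  XYZ has no bond concept, so the
bond list travels in a JSON topology sidecar, one record per molecule.
Round trips are lossless at the stored precision (positions are written
with 17 significant digits, i.e. full float64).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import yaml

from .composition import CompositionSpec
from .engine import RunParams
from .params import PARAMETER_TABLE
from .snapshot import Snapshot, SystemTopology, Trajectory, build_system_topology
from .topology import SPECIES_CODES, SPECIES_LABELS, MoleculeTopology
from .units import UnitSystem

__all__ = ["write_trajectory", "read_trajectory", "write_topology",
           "read_topology", "load_config", "TrajectoryFormatError"]

TOPOLOGY_FORMAT_VERSION = "1"


class TrajectoryFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# topology sidecar


def write_topology(topo: SystemTopology, path) -> None:
    doc = {
        "format": "tadsim-topology",
        "version": TOPOLOGY_FORMAT_VERSION,
        "species_params": {
            "R_col": topo.species_params.R_col,
            "R_mono": topo.species_params.R_mono,
            "N_mono": topo.species_params.N_mono,
            "N_tail": topo.species_params.N_tail,
        },
        "molecules": [
            {"kind": m.kind, "n_beads": m.n_beads,
             "bonds": [list(b) for b in m.bonds]}
            for m in topo.molecules
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_topology(path) -> SystemTopology:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "tadsim-topology":
        raise TrajectoryFormatError(f"{path}: not a tadsim topology document")
    sp = doc["species_params"]
    from .params import SpeciesParams
    from .topology import SPECIES_COL, SPECIES_HEAD, SPECIES_MONO, SPECIES_TAIL

    params = SpeciesParams(R_col=sp["R_col"], R_mono=sp["R_mono"],
                           N_mono=sp["N_mono"], N_tail=sp["N_tail"])
    mols = []
    for rec in doc["molecules"]:
        kind, n = rec["kind"], rec["n_beads"]
        if kind == "colloid":
            radii, species = (params.R_col,), (SPECIES_COL,)
        elif kind == "polymer":
            radii = (params.R_mono,) * n
            species = (SPECIES_MONO,) * n
        else:
            radii = (params.R_head,) + (params.R_tail,) * (n - 1)
            species = (SPECIES_HEAD,) + (SPECIES_TAIL,) * (n - 1)
        mols.append(MoleculeTopology(
            kind=kind, bead_radii=radii, bead_species=species,
            bonds=tuple(tuple(b) for b in rec["bonds"])))

    radii_l, species_l, mol_id, bead_idx = [], [], [], []
    bonds, bond_kind = [], []
    offset = 0
    for m, mol in enumerate(mols):
        radii_l.extend(mol.bead_radii)
        species_l.extend(mol.bead_species)
        mol_id.extend([m] * mol.n_beads)
        bead_idx.extend(range(mol.n_beads))
        for a, b in mol.bonds:
            bonds.append((offset + a, offset + b))
            head = (mol.bead_species[a] == SPECIES_HEAD
                    or mol.bead_species[b] == SPECIES_HEAD)
            bond_kind.append(1 if head else 0)
        offset += mol.n_beads
    return SystemTopology(
        molecules=tuple(mols),
        radii=np.asarray(radii_l, dtype=float),
        species=np.asarray(species_l, dtype=np.int64),
        molecule_id=np.asarray(mol_id, dtype=np.int64),
        bead_index=np.asarray(bead_idx, dtype=np.int64),
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_kind=np.asarray(bond_kind, dtype=np.int64),
        species_params=params,
    )


# ---------------------------------------------------------------------------
# extended XYZ trajectory

_PROPS = "species:S:1:pos:R:3:radius:R:1:molecule_id:I:1:bead_index:I:1"


def write_trajectory(traj: Trajectory, path, topology_path=None,
                     meta_path=None) -> None:
    """Write frames as extended XYZ; optionally topology/metadata sidecars."""
    path = Path(path)
    with path.open("w") as fh:
        for frame in traj.frames:
            fh.write(f"{frame.n_beads}\n")
            Lx, Ly, Lz = (float(v) for v in frame.box)
            fh.write(
                f'Lattice="{Lx!r} 0 0 0 {Ly!r} 0 0 0 {Lz!r}" '
                f"Properties={_PROPS} Time={float(frame.time)!r} "
                f"mode={frame.mode}\n"
            )
            topo = frame.topology
            for i in range(frame.n_beads):
                x, y, z = (float(v) for v in frame.positions[i])
                fh.write(
                    f"{SPECIES_LABELS[int(topo.species[i])]} {x!r} {y!r} {z!r} "
                    f"{float(topo.radii[i])!r} {int(topo.molecule_id[i])} "
                    f"{int(topo.bead_index[i])}\n"
                )
    if topology_path is not None:
        write_topology(traj.topology, topology_path)
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(traj.meta, default=str))


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([-\w.+]+)")
_MODE_RE = re.compile(r"mode=(\w+)")


def read_trajectory(path, topology: SystemTopology | None = None) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`.

    If ``topology`` is given (e.g. from :func:`read_topology`) its bond
    list is attached; otherwise a bond-less topology is reconstructed
    from the per-atom columns.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise TrajectoryFormatError(f"{path}: empty trajectory file")
    frames = []
    k = 0
    frame_no = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}: frame {frame_no}, line {k + 1}: "
                f"expected atom count, got {lines[k]!r}") from exc
        if k + 2 + n > len(lines):
            raise TrajectoryFormatError(
                f"{path}: frame {frame_no} truncated "
                f"(expected {n} atoms)")
        comment = lines[k + 1]
        m = _LATTICE_RE.search(comment)
        if not m:
            raise TrajectoryFormatError(
                f"{path}: frame {frame_no}, line {k + 2}: missing Lattice")
        lat = [float(v) for v in m.group(1).split()]
        box = np.array([lat[0], lat[4], lat[8]])
        tm = _TIME_RE.search(comment)
        time = float(tm.group(1)) if tm else 0.0
        md = _MODE_RE.search(comment)
        mode = md.group(1) if md else "hard"

        species, pos, radii, mol_id, bead_idx = [], [], [], [], []
        for a in range(n):
            parts = lines[k + 2 + a].split()
            if len(parts) < 7:
                raise TrajectoryFormatError(
                    f"{path}: frame {frame_no}, line {k + 3 + a}: "
                    f"expected 7 columns, got {len(parts)}")
            species.append(SPECIES_CODES[parts[0]])
            pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
            radii.append(float(parts[4]))
            mol_id.append(int(parts[5]))
            bead_idx.append(int(parts[6]))
        frames.append((box, np.asarray(pos), np.asarray(species),
                       np.asarray(radii, dtype=float),
                       np.asarray(mol_id), np.asarray(bead_idx), time, mode))
        k += 2 + n
        frame_no += 1

    if topology is None:
        topology = _topology_from_columns(*frames[0][2:6])
    snaps = [Snapshot(box=b, positions=p, topology=topology, time=t, mode=mo)
             for (b, p, _, _, _, _, t, mo) in frames]
    snaps.sort(key=lambda s: s.time)
    return Trajectory(frames=snaps, topology=topology, meta={"source": str(path)})


def _topology_from_columns(species, radii, mol_id, bead_idx) -> SystemTopology:
    from .params import SpeciesParams
    from .snapshot import SystemTopology as ST
    from .topology import SPECIES_HEAD, SPECIES_COL

    mols = []
    bonds = []
    bond_kind = []
    for m in np.unique(mol_id):
        sel = np.flatnonzero(mol_id == m)
        sel = sel[np.argsort(bead_idx[sel])]
        sp = species[sel]
        if sp[0] == SPECIES_COL:
            kind = "colloid"
        elif sp[0] == SPECIES_HEAD:
            kind = "tadpole"
        else:
            kind = "polymer"
        local_bonds = tuple((i, i + 1) for i in range(len(sel) - 1))
        mols.append(MoleculeTopology(
            kind=kind, bead_radii=tuple(radii[sel]),
            bead_species=tuple(int(s) for s in sp), bonds=local_bonds))
        for a, b in local_bonds:
            bonds.append((sel[a], sel[b]))
            bond_kind.append(1 if (sp[a] == SPECIES_HEAD or sp[b] == SPECIES_HEAD)
                             else 0)
    n_tail = max((m.n_beads - 1 for m in mols if m.kind == "tadpole"),
                 default=30)
    n_mono = max((m.n_beads for m in mols if m.kind == "polymer"),
                 default=30)
    params = SpeciesParams(N_mono=n_mono, N_tail=n_tail)
    return ST(
        molecules=tuple(mols),
        radii=np.asarray(radii, dtype=float),
        species=np.asarray(species, dtype=np.int64),
        molecule_id=np.asarray(mol_id, dtype=np.int64),
        bead_index=np.asarray(bead_idx, dtype=np.int64),
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_kind=np.asarray(bond_kind, dtype=np.int64),
        species_params=params,
    )


# ---------------------------------------------------------------------------
# run configuration

_COMPOSITION_KEYS = {"N_col", "N_poly", "N_tad", "N_mono", "N_tail", "box",
                     "max_packing"}
_RUN_KEYS = {"dt", "n_steps", "sample_interval", "snapshot_spacing_time",
             "seed", "mode"}
_UNIT_KEYS = {"length_unit_nm", "temperature_K"}
_VALID_KEYS = _COMPOSITION_KEYS | _RUN_KEYS | _UNIT_KEYS | {"layout"}


def load_config(path) -> tuple[CompositionSpec, RunParams, UnitSystem]:
    """Load a YAML run configuration.

    Unspecified keys take the model defaults (R_col = 0.44,
    R_mono = 0.0908, N_mono = 30, dt = 0.4 tau, l = 12.5 nm ...); the
    step-size constraint sqrt(2 D dt) < R_tail is validated before any
    simulation.  Unknown keys are an error.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _VALID_KEYS
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys {sorted(unknown)}; "
            f"valid keys: {sorted(_VALID_KEYS)}")
    comp_kwargs = {k: raw[k] for k in _COMPOSITION_KEYS if k in raw}
    comp_kwargs.setdefault("N_col", 0)
    comp_kwargs.setdefault("N_poly", 0)
    comp_kwargs.setdefault("N_tad", 0)
    comp_kwargs.setdefault("N_mono", PARAMETER_TABLE["N_mono"])
    comp_kwargs.setdefault("box", (4.0, 4.0, 27.0))
    comp_kwargs["box"] = tuple(float(v) for v in comp_kwargs["box"])
    spec = CompositionSpec(**comp_kwargs)

    run_kwargs = {k: raw[k] for k in _RUN_KEYS if k in raw}
    run_kwargs.setdefault("dt", PARAMETER_TABLE["dt"])
    params = RunParams(**run_kwargs)

    unit_kwargs = {k: raw[k] for k in _UNIT_KEYS if k in raw}
    units = UnitSystem(**unit_kwargs)

    topo = build_system_topology(spec)
    if topo.n_beads:
        params.validate_step_constraint(topo.radii, topo.species_params.R_tail)
    else:
        params.validate_step_constraint(
            np.array([spec.species_params().R_tail]),
            spec.species_params().R_tail)
    return spec, params, units
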