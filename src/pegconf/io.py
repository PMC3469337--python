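"""Reading and writing conformers and trajectories.

PDB is the interchange format (single-model for one conformer,
multi-model for a trajectory), handled through biotite's structure I/O.
PEG atoms are residue ``PEG`` with group labels encoded in the atom
names: carbons ``C1..``, CH2 hydrogens ``H1..`` (group CH), ether
oxygens ``O1..`` (group O), terminal hydroxyl oxygens/hydrogens
``OT1/OT2`` and ``HT1/HT2`` (group OH).  Waters are ``HOH`` HETATM
records with atom names O, H1, H2.

XYZ frame series are also supported (element + coordinates only); the
comment line of each frame carries ``peg_atoms=<count> t=<ps>`` so
waters can be separated on reading.  A sidecar ``<name>.meta.txt`` with
``key = value`` pairs records generation parameters (seed, snapshot
interval) next to every trajectory written.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .builder import Conformer
from .sampling import Trajectory
from .topology import PEGTopology, build_topology


# ----------------------------------------------------------------------
# atom naming

def _peg_atom_names(topology: PEGTopology) -> list[str]:
    names = []
    counters = {"C": 0, "O": 0, "H": 0, "OT": 0, "HT": 0}
    for atom in topology.atoms:
        if atom.group == "OH":
            key = "OT" if atom.element == "O" else "HT"
        else:
            key = atom.element
        counters[key] += 1
        names.append(f"{key}{counters[key]}")
    return names


def _conformer_to_atom_array(conformer: Conformer) -> bst.AtomArray:
    topo = conformer.topology
    n_water_atoms = 3 * conformer.n_waters
    n = topo.n_atoms + n_water_atoms
    arr = bst.AtomArray(n)
    arr.coord[: topo.n_atoms] = conformer.coords
    arr.chain_id[:] = "A"
    arr.res_id[: topo.n_atoms] = 1
    arr.res_name[: topo.n_atoms] = "PEG"
    arr.element[: topo.n_atoms] = [a.element for a in topo.atoms]
    arr.atom_name[: topo.n_atoms] = _peg_atom_names(topo)
    arr.hetero[: topo.n_atoms] = True  # PEG is a heterogen, not a polymer residue
    if conformer.n_waters:
        arr.coord[topo.n_atoms :] = conformer.waters.reshape(-1, 3)
        for w in range(conformer.n_waters):
            s = topo.n_atoms + 3 * w
            arr.res_id[s : s + 3] = 2 + w
            arr.res_name[s : s + 3] = "HOH"
            arr.element[s : s + 3] = ["O", "H", "H"]
            arr.atom_name[s : s + 3] = ["O", "H1", "H2"]
            arr.hetero[s : s + 3] = True
    return arr


def _atom_array_to_conformer(arr: bst.AtomArray) -> Conformer:
    peg_mask = arr.res_name == "PEG"
    n_peg = int(peg_mask.sum())
    if (n_peg - 3) % 7 != 0 or n_peg < 10:
        raise ValueError(
            f"{n_peg} PEG atoms does not match 7n+3 for any subunit count n"
        )
    topo = build_topology((n_peg - 3) // 7)
    elements = arr.element[peg_mask]
    expected = [a.element for a in topo.atoms]
    if list(elements) != expected:
        raise ValueError("PEG atom ordering in file does not match the chain layout")
    water_mask = arr.res_name == "HOH"
    n_water_atoms = int(water_mask.sum())
    if n_water_atoms % 3 != 0:
        raise ValueError("water records are not complete O,H1,H2 triples")
    waters = (
        arr.coord[water_mask].reshape(-1, 3, 3) if n_water_atoms else None
    )
    return Conformer(topo, np.array(arr.coord[peg_mask], dtype=float), waters)


# ----------------------------------------------------------------------
# PDB

def write_pdb(path: str | Path, conformer: Conformer) -> None:
    """Write a single conformer (plus waters) as a single-model PDB."""
    pdb = PDBFile()
    pdb.set_structure(_conformer_to_atom_array(conformer))
    pdb.write(str(path))


def read_pdb(path: str | Path) -> Conformer:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    try:
        arr = PDBFile.read(str(path)).get_structure(model=1)
    except Exception as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    return _atom_array_to_conformer(arr)


def write_trajectory_pdb(path: str | Path, trajectory: Trajectory) -> None:
    """Write a trajectory as a multi-model PDB plus a metadata sidecar."""
    arrays = [_conformer_to_atom_array(c) for c in trajectory.snapshots]
    counts = {a.array_length() for a in arrays}
    if len(counts) > 1:
        raise ValueError(
            "snapshots differ in atom count (uneven water counts); "
            "multi-model PDB requires a constant atom set"
        )
    stack = bst.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    _write_sidecar(path, trajectory)


def read_trajectory_pdb(path: str | Path) -> Trajectory:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    try:
        stack = PDBFile.read(str(path)).get_structure()
    except Exception as exc:
        raise ValueError(f"malformed multi-model PDB {path}: {exc}") from exc
    snapshots = [_atom_array_to_conformer(stack[i]) for i in range(stack.stack_depth())]
    meta = _read_sidecar(path)
    interval = float(meta.get("snapshot_interval_ps", 5.0))
    seed = int(meta["seed"]) if "seed" in meta else None
    times = interval * np.arange(len(snapshots))
    return Trajectory(snapshots[0].topology, snapshots, times, seed=seed)


# ----------------------------------------------------------------------
# XYZ frame series

def write_trajectory_xyz(path: str | Path, trajectory: Trajectory) -> None:
    topo = trajectory.topology
    elements = [a.element for a in topo.atoms]
    lines: list[str] = []
    for conf, t in zip(trajectory.snapshots, trajectory.times):
        n_total = topo.n_atoms + 3 * conf.n_waters
        lines.append(str(n_total))
        lines.append(f"peg_atoms={topo.n_atoms} t={t:.3f}")
        for el, xyz in zip(elements, conf.coords):
            lines.append(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
        if conf.n_waters:
            for w in conf.waters:
                for el, xyz in zip(("O", "H", "H"), w):
                    lines.append(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
    _write_sidecar(path, trajectory)


def read_trajectory_xyz(path: str | Path) -> Trajectory:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"XYZ file not found: {path}")
    lines = path.read_text().splitlines()
    frames: list[tuple[int, float, np.ndarray]] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_total = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}")
        if i + 2 + n_total > len(lines):
            raise ValueError(
                f"{path}:{i + 1}: truncated frame — header promises {n_total} atoms"
            )
        comment = lines[i + 1]
        n_peg = n_total
        t = 0.0
        for token in comment.split():
            if token.startswith("peg_atoms="):
                n_peg = int(token.split("=", 1)[1])
            elif token.startswith("t="):
                t = float(token.split("=", 1)[1])
        coords = np.empty((n_total, 3))
        for k in range(n_total):
            lineno = i + 2 + k
            parts = lines[lineno].split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno + 1}: expected 'element x y z', got {lines[lineno]!r}"
                )
            coords[k] = [float(v) for v in parts[1:]]
        frames.append((n_peg, t, coords))
        i += 2 + n_total
    if not frames:
        raise ValueError(f"{path}: no frames found")

    n_peg = frames[0][0]
    if (n_peg - 3) % 7 != 0:
        raise ValueError(f"{path}: {n_peg} PEG atoms does not match 7n+3")
    topo = build_topology((n_peg - 3) // 7)
    snapshots = []
    times = []
    for n_p, t, coords in frames:
        if n_p != n_peg:
            raise ValueError(f"{path}: inconsistent PEG atom counts across frames")
        n_water_atoms = len(coords) - n_peg
        if n_water_atoms % 3 != 0:
            raise ValueError(f"{path}: water atoms are not complete triples")
        waters = coords[n_peg:].reshape(-1, 3, 3) if n_water_atoms else None
        snapshots.append(Conformer(topo, coords[:n_peg], waters))
        times.append(t)
    times = np.asarray(times)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = 5.0 * np.arange(len(snapshots))
    meta = _read_sidecar(path)
    seed = int(meta["seed"]) if "seed" in meta else None
    return Trajectory(topo, snapshots, times, seed=seed)


# ----------------------------------------------------------------------
# sidecar metadata

def _sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.txt")


def _write_sidecar(path: str | Path, trajectory: Trajectory) -> None:
    meta = {
        "n_subunits": trajectory.topology.n_subunits,
        "n_snapshots": trajectory.n_snapshots,
        "snapshot_interval_ps": (
            float(trajectory.times[1] - trajectory.times[0])
            if len(trajectory.times) > 1
            else 5.0
        ),
    }
    if trajectory.seed is not None:
        meta["seed"] = trajectory.seed
    _sidecar_path(path).write_text(
        "\n".join(f"{k} = {v}" for k, v in meta.items()) + "\n"
    )


def _read_sidecar(path: str | Path) -> dict[str, str]:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return {}
    meta = {}
    for line in sidecar.read_text().splitlines():
        if "=" in line:
            k, _, v = line.partition("=")
            meta[k.strip()] = v.strip()
    return meta
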