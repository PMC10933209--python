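"""Trajectory containers, readers/writers and frame selection.

The analysis layer works on a light :class:`Trajectory` container: an
ordered list of :class:`Frame` snapshots (coordinates + periodic cell)
plus one :class:`MoleculeMap` assigning every atom to a solute molecule
or marking it as solvent.  Standard coordinate formats (PDB multi-MODEL,
DCD and everything else MDAnalysis can read) are loaded through
MDAnalysis; XYZ files — including the extended flavour with a
``Lattice="..."`` comment line, which is what the bundled simulator
emits — are handled natively so the periodic cell survives the
round-trip.

Molecule grouping comes from topology residues (one selected residue =
one molecule) or, for formats without residue records, from a
plain-text sidecar map with columns ``atom_index  molecule_id
element`` where ``molecule_id = -1`` marks solvent atoms.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .box import BoxSpec

__all__ = [
    "Frame",
    "MoleculeMap",
    "Trajectory",
    "TrajectoryReadError",
    "SelectionError",
    "read_trajectory",
    "read_molecule_map",
    "write_molecule_map",
    "write_xyz",
    "read_xyz",
    "select_equispaced_frames",
    "equispaced_indices",
]


class TrajectoryReadError(IOError):
    """A coordinate file could not be read (names the offending frame)."""


class SelectionError(ValueError):
    """A solute selection matched no atoms/molecules."""


@dataclass(frozen=True)
class Frame:
    """One trajectory snapshot.

    Attributes
    ----------
    index : int
        Ordinal position in the source trajectory.
    time : float
        Time in picoseconds.
    coords : (n_atoms, 3) float array
        Cartesian coordinates, angstrom.
    box : BoxSpec
        Periodic cell for this frame.
    """

    index: int
    time: float
    coords: np.ndarray
    box: BoxSpec

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n_atoms, 3), got {coords.shape}")
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class MoleculeMap:
    """Per-atom molecule assignment.

    ``molecule_id[i] >= 0`` gives the 0-based solute molecule of atom
    ``i``; ``-1`` marks solvent/ion atoms excluded from clustering.
    Solute molecule ids must be contiguous ``0..n_molecules-1``.
    """

    molecule_id: np.ndarray
    elements: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        mol_id = np.asarray(self.molecule_id, dtype=int)
        solute = mol_id[mol_id >= 0]
        if solute.size == 0:
            raise SelectionError("molecule map contains no solute atoms")
        ids = np.unique(solute)
        if not np.array_equal(ids, np.arange(ids.size)):
            raise ValueError(
                "solute molecule ids must be contiguous starting at 0; "
                f"got {ids.tolist()[:10]}..."
            )
        object.__setattr__(self, "molecule_id", mol_id)
        if self.elements and len(self.elements) != mol_id.size:
            raise ValueError("elements length must match molecule_id length")

    @property
    def n_atoms(self) -> int:
        return int(self.molecule_id.size)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_id.max()) + 1

    @property
    def solute_mask(self) -> np.ndarray:
        """Boolean mask over atoms, ``True`` for solute."""
        return self.molecule_id >= 0

    def heavy_mask(self) -> np.ndarray:
        """Mask of non-hydrogen atoms (all-True when elements unknown)."""
        if not self.elements:
            return np.ones(self.n_atoms, dtype=bool)
        return np.array([e.upper() not in ("H", "D") for e in self.elements])


@dataclass
class Trajectory:
    """Ordered frames sharing one molecule map, plus provenance."""

    frames: list[Frame]
    molecule_map: MoleculeMap
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n_atoms = self.molecule_map.n_atoms
        for fr in self.frames:
            if fr.n_atoms != n_atoms:
                raise ValueError(
                    f"frame {fr.index} has {fr.n_atoms} atoms, "
                    f"molecule map has {n_atoms}"
                )
        times = [fr.time for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    @property
    def n_molecules(self) -> int:
        return self.molecule_map.n_molecules


# ----------------------------------------------------------------------
# frame selection
# ----------------------------------------------------------------------

def equispaced_indices(n_available: int, n_wanted: int) -> list[int]:
    """Indices of ``n_wanted`` equispaced frames from ``n_available``.

    Always includes the first and last frame when ``n_wanted >= 2``:
    index ``i`` maps to ``floor(i * (F - 1) / (n - 1))``.  If fewer
    frames exist than requested, all are returned.
    """
    if n_wanted < 1:
        raise ValueError("must select at least one frame")
    if n_available < 1:
        raise ValueError("trajectory is empty")
    if n_available <= n_wanted:
        return list(range(n_available))
    if n_wanted == 1:
        return [0]
    return [i * (n_available - 1) // (n_wanted - 1) for i in range(n_wanted)]


def select_equispaced_frames(traj: Trajectory, n: int) -> Trajectory:
    """Sub-sample ``n`` equispaced frames (first and last included).

    Mirrors the standard analysis practice of measuring population
    distributions on a fixed number of equispaced snapshots (5000 for a
    production run) regardless of trajectory length.  When the
    trajectory holds fewer than ``n`` frames, all frames are returned
    and the shortfall is recorded in provenance.
    """
    idx = equispaced_indices(len(traj), n)
    prov = dict(traj.provenance)
    prov["n_frames_requested"] = n
    prov["n_frames_selected"] = len(idx)
    if len(idx) < n:
        prov["frame_shortfall"] = True
    return Trajectory(
        frames=[traj.frames[i] for i in idx],
        molecule_map=traj.molecule_map,
        provenance=prov,
    )


# ----------------------------------------------------------------------
# molecule-map sidecar
# ----------------------------------------------------------------------

def write_molecule_map(path: str | Path, mol_map: MoleculeMap) -> None:
    """Write the plain-text sidecar (atom_index, molecule_id, element)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# atom_index\tmolecule_id\telement\n")
        elements = mol_map.elements or ("X",) * mol_map.n_atoms
        for i, (mid, el) in enumerate(zip(mol_map.molecule_id, elements)):
            fh.write(f"{i}\t{int(mid)}\t{el}\n")


def read_molecule_map(path: str | Path) -> MoleculeMap:
    """Read the sidecar written by :func:`write_molecule_map`."""
    ids: list[int] = []
    elements: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed molecule-map line: {line!r}")
            ids.append(int(parts[1]))
            elements.append(parts[2] if len(parts) > 2 else "X")
    return MoleculeMap(np.array(ids, dtype=int), tuple(elements))


# ----------------------------------------------------------------------
# XYZ (extended, with optional Lattice= comment)
# ----------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([-\d.eE+]+)")


def write_xyz(path: str | Path, traj: Trajectory) -> None:
    """Write an extended-XYZ trajectory with a Lattice comment per frame."""
    elements = traj.molecule_map.elements or ("X",) * traj.molecule_map.n_atoms
    with Path(path).open("w") as fh:
        for fr in traj.frames:
            fh.write(f"{fr.n_atoms}\n")
            lat = " ".join(f"{x:.6f}" for x in fr.box.vectors.ravel())
            fh.write(f'Lattice="{lat}" Time={fr.time:.6f}\n')
            for el, xyz in zip(elements, fr.coords):
                fh.write(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def read_xyz(
    path: str | Path,
    molecule_map: MoleculeMap | None = None,
    default_box: BoxSpec | None = None,
    save_interval_ps: float = 20.0,
) -> Trajectory:
    """Read a (possibly extended) XYZ trajectory.

    Frames without a ``Lattice`` comment use ``default_box``; frames
    without a ``Time`` comment default to ``index * save_interval_ps``.
    Without a molecule map, every atom becomes its own single-atom
    solute molecule.
    """
    path = Path(path)
    frames: list[Frame] = []
    elements: list[str] = []
    with path.open() as fh:
        lines = fh.readlines()
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryReadError(
                f"{path}: frame {frame_idx}: bad atom-count line {pos + 1}"
            )
        if pos + 2 + n_atoms > len(lines):
            raise TrajectoryReadError(
                f"{path}: frame {frame_idx} truncated mid-record"
            )
        comment = lines[pos + 1]
        m = _LATTICE_RE.search(comment)
        if m:
            box = BoxSpec(np.array(m.group(1).split(), float).reshape(3, 3))
        elif default_box is not None:
            box = default_box
        else:
            raise TrajectoryReadError(
                f"{path}: frame {frame_idx}: no Lattice comment and no default box"
            )
        t = _TIME_RE.search(comment)
        time = float(t.group(1)) if t else frame_idx * save_interval_ps
        coords = np.empty((n_atoms, 3))
        frame_elements: list[str] = []
        for i in range(n_atoms):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise TrajectoryReadError(
                    f"{path}: frame {frame_idx} truncated mid-record "
                    f"(atom {i} of {n_atoms})"
                )
            frame_elements.append(parts[0])
            try:
                coords[i] = [float(x) for x in parts[1:4]]
            except ValueError:
                raise TrajectoryReadError(
                    f"{path}: frame {frame_idx}: bad coordinate at atom {i}"
                )
        if not elements:
            elements = frame_elements
        frames.append(Frame(frame_idx, time, coords, box))
        pos += 2 + n_atoms
        frame_idx += 1
    if not frames:
        raise TrajectoryReadError(f"{path}: no frames found")
    if molecule_map is None:
        molecule_map = MoleculeMap(
            np.arange(frames[0].n_atoms), tuple(elements)
        )
    return Trajectory(
        frames, molecule_map, provenance={"source": str(path), "format": "xyz"}
    )


# ----------------------------------------------------------------------
# general reader (MDAnalysis-backed for PDB/DCD/...)
# ----------------------------------------------------------------------

def read_trajectory(
    coord_path: str | Path,
    topology: str | Path | None = None,
    solute_selection: str | None = None,
    map_path: str | Path | None = None,
    save_interval_ps: float = 20.0,
    default_box: BoxSpec | None = None,
) -> Trajectory:
    """Read a trajectory and attach its molecule map.

    Parameters
    ----------
    coord_path
        Coordinate file (PDB multi-MODEL, DCD, XYZ, ...).
    topology
        Topology file for coordinate-only formats (e.g. PDB for a DCD).
    solute_selection
        MDAnalysis selection string for the solute; each selected
        residue becomes one molecule.  Ignored when ``map_path`` is
        given.
    map_path
        Plain-text molecule-map sidecar (fallback for formats without
        residue records, e.g. XYZ).
    save_interval_ps
        Frame spacing used when the format carries no time information.
    default_box
        Periodic cell used for frames that carry none.
    """
    coord_path = Path(coord_path)
    if not coord_path.exists():
        raise TrajectoryReadError(f"no such file: {coord_path}")

    mol_map = read_molecule_map(map_path) if map_path else None

    if coord_path.suffix.lower() == ".xyz":
        return read_xyz(
            coord_path,
            molecule_map=mol_map,
            default_box=default_box,
            save_interval_ps=save_interval_ps,
        )

    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if topology is not None:
                universe = mda.Universe(str(topology), str(coord_path))
            else:
                universe = mda.Universe(str(coord_path))
    except Exception as exc:  # noqa: BLE001 - library raises many types
        raise TrajectoryReadError(f"cannot read {coord_path}: {exc}") from exc

    if mol_map is None:
        if solute_selection is None:
            solute = universe.atoms
        else:
            solute = universe.select_atoms(solute_selection)
            if len(solute) == 0:
                raise SelectionError(
                    f"selection {solute_selection!r} matches no atoms"
                )
        mol_ids = np.full(len(universe.atoms), -1, dtype=int)
        for mid, residue in enumerate(solute.residues):
            mol_ids[residue.atoms.ix] = mid
        try:
            elements = tuple(
                str(e) for e in universe.atoms.elements
            )
        except (AttributeError, mda.exceptions.NoDataError):
            elements = tuple(
                str(n)[0] for n in getattr(universe.atoms, "names", [])
            ) or ()
        mol_map = MoleculeMap(mol_ids, elements)

    frames: list[Frame] = []
    try:
        for i, ts in enumerate(universe.trajectory):
            if ts.dimensions is not None and ts.dimensions[:3].min() > 0:
                box = BoxSpec.from_parameters(*ts.dimensions)
            elif default_box is not None:
                box = default_box
            else:
                raise TrajectoryReadError(
                    f"{coord_path}: frame {i} has no box and no default given"
                )
            time = float(ts.time) if ts.time and ts.time > 0 else i * save_interval_ps
            if frames and time <= frames[-1].time:
                time = frames[-1].time + save_interval_ps
            frames.append(Frame(i, time, ts.positions.astype(float).copy(), box))
    except TrajectoryReadError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise TrajectoryReadError(
            f"{coord_path}: frame {len(frames)} unreadable or truncated: {exc}"
        ) from exc

    return Trajectory(
        frames,
        mol_map,
        provenance={
            "source": str(coord_path),
            "topology": str(topology) if topology else None,
            "selection": solute_selection,
        },
    )
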