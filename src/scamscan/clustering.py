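"""Contact detection and connected-component cluster counting.

Two solute molecules belong to the same cluster when any pair of their
atoms — heavy or hydrogen — lies within a distance cutoff under the
minimum-image convention (3.0 A is the calibrated default for
atomistic systems: smaller cutoffs miss nearest-neighbour contacts,
cutoffs beyond 5-6 A merge non-interacting molecules).  Cluster
membership is the transitive closure of these pairwise contacts, so
the per-frame cluster count ``N_c`` is the number of connected
components of the intermolecular contact graph: ``N_c = 1`` is one big
aggregate, ``N_c = N_mol`` is full dispersion.

Contact search is available in two interchangeable flavours: a
vectorised minimum-image all-pairs scan (``brute``), and a grid-based
neighbour search (``cell_list``) delegated to
:func:`MDAnalysis.lib.distances.capped_distance`, valid while the
cutoff stays below half the smallest box extent.  Components are
extracted by union-find with path compression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .box import BoxSpec, minimum_image_displacement
from .trajectory_io import Frame, MoleculeMap, Trajectory, select_equispaced_frames

__all__ = [
    "ContactGraph",
    "ClusterLabels",
    "NcRecord",
    "NcSeries",
    "UnionFind",
    "find_contacts",
    "connected_components",
    "cluster_frame",
    "cluster_trajectory",
    "DEFAULT_CUTOFF",
    "DEFAULT_N_FRAMES",
]

#: Calibrated intermolecular atom-atom contact cutoff, angstrom.
DEFAULT_CUTOFF = 3.0
#: Number of equispaced frames analysed per trajectory.
DEFAULT_N_FRAMES = 5000


@dataclass(frozen=True)
class ContactGraph:
    """Undirected intermolecular contact graph for one frame."""

    frame_index: int
    n_molecules: int
    edges: frozenset[tuple[int, int]]
    cutoff: float

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-edge on molecule {i}")
            if not (0 <= i < self.n_molecules and 0 <= j < self.n_molecules):
                raise ValueError(f"edge ({i}, {j}) outside molecule range")


@dataclass(frozen=True)
class ClusterLabels:
    """Per-molecule component labels for one frame."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)

    @property
    def sizes(self) -> np.ndarray:
        """Cluster sizes, descending."""
        _, counts = np.unique(self.labels, return_counts=True)
        return np.sort(counts)[::-1]


@dataclass(frozen=True)
class NcRecord:
    frame_index: int
    time_ps: float
    n_clusters: int
    largest_cluster_size: int


@dataclass(frozen=True)
class NcSeries:
    """Per-frame cluster counts for one trajectory."""

    records: tuple[NcRecord, ...]
    n_molecules: int
    cutoff: float = DEFAULT_CUTOFF
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for rec in self.records:
            if not 1 <= rec.n_clusters <= self.n_molecules:
                raise ValueError(
                    f"frame {rec.frame_index}: N_c = {rec.n_clusters} outside "
                    f"[1, {self.n_molecules}]"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def nc(self) -> np.ndarray:
        return np.array([r.n_clusters for r in self.records], dtype=int)

    def to_frame(self):
        """As a pandas DataFrame (frame_index, time_ps, n_clusters, largest_cluster_size)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "frame_index": [r.frame_index for r in self.records],
                "time_ps": [r.time_ps for r in self.records],
                "n_clusters": [r.n_clusters for r in self.records],
                "largest_cluster_size": [
                    r.largest_cluster_size for r in self.records
                ],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_molecules: int, cutoff: float = DEFAULT_CUTOFF):
        import pandas as pd

        df = pd.read_csv(path)
        records = tuple(
            NcRecord(
                int(r.frame_index),
                float(r.time_ps),
                int(r.n_clusters),
                int(r.largest_cluster_size),
            )
            for r in df.itertuples()
        )
        return cls(records, n_molecules=n_molecules, cutoff=cutoff)


class UnionFind:
    """Disjoint-set forest with path compression and union by size."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]


# ----------------------------------------------------------------------
# contact detection
# ----------------------------------------------------------------------

def _solute_atoms(
    frame: Frame, mol_map: MoleculeMap, contact_atoms: str
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates and molecule ids of the atoms entering the contact test."""
    mask = mol_map.solute_mask.copy()
    if contact_atoms == "heavy":
        mask &= mol_map.heavy_mask()
    elif contact_atoms != "all":
        raise ValueError(f"contact_atoms must be 'all' or 'heavy', got {contact_atoms!r}")
    if not mask.any():
        raise ValueError("no atoms left after applying solute/heavy masks")
    return frame.coords[mask], mol_map.molecule_id[mask]


def _edges_brute(
    coords: np.ndarray, mol_ids: np.ndarray, box: BoxSpec, cutoff: float
) -> set[tuple[int, int]]:
    """All-pairs minimum-image contact scan (chunked to bound memory)."""
    n = len(coords)
    edges: set[tuple[int, int]] = set()
    chunk = max(1, int(2e6) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        # displacement of every atom pair (block x all), minimum image
        disp = minimum_image_displacement(
            box,
            np.repeat(coords[start:stop], n, axis=0),
            np.tile(coords, (stop - start, 1)),
        )
        dist2 = np.einsum("ij,ij->i", disp, disp).reshape(stop - start, n)
        ii, jj = np.nonzero(dist2 <= cutoff * cutoff)
        for a, b in zip(ii + start, jj):
            mi, mj = int(mol_ids[a]), int(mol_ids[b])
            if mi != mj:
                edges.add((min(mi, mj), max(mi, mj)))
    return edges


def _perpendicular_widths(box: BoxSpec) -> np.ndarray:
    """Perpendicular width of the cell along each lattice direction.

    ``w_a = V / |b x c|`` etc.; a fractional slab of thickness ``1/n``
    along axis *a* is ``w_a / n`` angstrom thick, which is what bounds
    how far a neighbour can sit in fractional-cell units.
    """
    v = box.vectors
    volume = box.volume
    return np.array(
        [
            volume / np.linalg.norm(np.cross(v[1], v[2])),
            volume / np.linalg.norm(np.cross(v[2], v[0])),
            volume / np.linalg.norm(np.cross(v[0], v[1])),
        ]
    )


def _candidate_pairs_cell_list(
    coords: np.ndarray, box: BoxSpec, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate atom pairs (a < b) from a fractional-space cell list.

    Atoms are binned on a grid of n_k fractional cells per axis with
    n_k <= w_k / cutoff (w_k the perpendicular cell width), so every
    pair within ``cutoff`` falls in the same or an adjacent (periodic)
    grid cell.  Distances are not computed here; the caller screens
    candidates with the minimum-image metric.
    """
    widths = _perpendicular_widths(box)
    n_cells = np.maximum(np.floor(widths / cutoff).astype(int), 1)
    if (n_cells < 3).any():
        raise ValueError(
            f"cutoff {cutoff} A is too large for a cell list in this box "
            f"(perpendicular widths {np.round(widths, 1)} A); use method='brute'"
        )
    frac = coords @ box._inverse
    frac -= np.floor(frac)
    cell_of = tuple(
        np.minimum((frac[:, k] * n_cells[k]).astype(int), n_cells[k] - 1)
        for k in range(3)
    )
    occupied: dict[tuple[int, int, int], list[int]] = {}
    for atom, key in enumerate(zip(*cell_of)):
        occupied.setdefault(key, []).append(atom)

    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    left: list[np.ndarray] = []
    right: list[np.ndarray] = []
    for (cx, cy, cz), atoms in occupied.items():
        home = np.asarray(atoms)
        for ox, oy, oz in offsets:
            key = (
                (cx + ox) % n_cells[0],
                (cy + oy) % n_cells[1],
                (cz + oz) % n_cells[2],
            )
            other = occupied.get(key)
            if other is None:
                continue
            other = np.asarray(other)
            la, lb = np.meshgrid(home, other, indexing="ij")
            keep = la < lb  # each unordered pair once
            if keep.any():
                left.append(la[keep])
                right.append(lb[keep])
    if not left:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(left), np.concatenate(right)


def _edges_cell_list(
    coords: np.ndarray, mol_ids: np.ndarray, box: BoxSpec, cutoff: float
) -> set[tuple[int, int]]:
    """Cell-list contact scan: grid candidates + minimum-image screen."""
    if cutoff >= 0.5 * float(np.min(_perpendicular_widths(box))):
        raise ValueError(
            f"cutoff {cutoff} A is >= half the smallest perpendicular box "
            f"width; use method='brute'"
        )
    ia, ib = _candidate_pairs_cell_list(coords, box, cutoff)
    edges: set[tuple[int, int]] = set()
    if ia.size == 0:
        return edges
    disp = minimum_image_displacement(box, coords[ia], coords[ib])
    dist2 = np.einsum("ij,ij->i", disp, disp)
    for a, b in zip(ia[dist2 <= cutoff * cutoff], ib[dist2 <= cutoff * cutoff]):
        mi, mj = int(mol_ids[a]), int(mol_ids[b])
        if mi != mj:
            edges.add((min(mi, mj), max(mi, mj)))
    return edges


def find_contacts(
    frame: Frame,
    mol_map: MoleculeMap,
    cutoff: float = DEFAULT_CUTOFF,
    method: str = "cell_list",
    contact_atoms: str = "all",
    min_contacts: int = 1,
) -> ContactGraph:
    """Build the intermolecular contact graph for one frame.

    An edge joins molecules *i* and *j* when at least ``min_contacts``
    of their atom pairs lie within ``cutoff`` (inclusive) under the
    minimum-image convention.  The default single qualifying atom pair
    is the topology-agnostic criterion used for cluster analysis of
    small-molecule aggregation; ``contact_atoms='heavy'`` restricts the
    test to non-hydrogen atoms.

    Parameters
    ----------
    method
        ``'cell_list'`` (grid neighbour search; requires
        ``cutoff < min(box)/2``) or ``'brute'`` (all pairs; always valid).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords, mol_ids = _solute_atoms(frame, mol_map, contact_atoms)
    if min_contacts == 1:
        if method == "brute":
            edges = _edges_brute(coords, mol_ids, frame.box, cutoff)
        elif method == "cell_list":
            edges = _edges_cell_list(coords, mol_ids, frame.box, cutoff)
        else:
            raise ValueError(f"method must be 'brute' or 'cell_list', got {method!r}")
    else:
        edges = _edges_min_contacts(
            coords, mol_ids, frame.box, cutoff, method, min_contacts
        )
    return ContactGraph(
        frame_index=frame.index,
        n_molecules=mol_map.n_molecules,
        edges=frozenset(edges),
        cutoff=cutoff,
    )


def _edges_min_contacts(
    coords: np.ndarray,
    mol_ids: np.ndarray,
    box: BoxSpec,
    cutoff: float,
    method: str,
    min_contacts: int,
) -> set[tuple[int, int]]:
    """Count qualifying atom pairs per molecule pair, keep those >= min_contacts."""
    from collections import Counter

    counts: Counter[tuple[int, int]] = Counter()
    if method == "cell_list":
        from MDAnalysis.lib.distances import capped_distance

        if cutoff >= 0.5 * float(np.min(box.lengths)):
            raise ValueError("cutoff too large for cell_list; use method='brute'")
        pairs = capped_distance(
            coords.astype(np.float64),
            coords.astype(np.float64),
            max_cutoff=cutoff,
            box=box.to_mdanalysis(),
            return_distances=False,
        )
        for a, b in pairs:
            mi, mj = int(mol_ids[a]), int(mol_ids[b])
            if mi < mj:  # each unordered atom pair appears twice in self-search
                counts[(mi, mj)] += 1
    else:
        n = len(coords)
        for a in range(n):
            disp = minimum_image_displacement(
                box, np.broadcast_to(coords[a], (n - a - 1, 3)), coords[a + 1 :]
            )
            dist2 = np.einsum("ij,ij->i", np.atleast_2d(disp), np.atleast_2d(disp))
            for off in np.nonzero(dist2 <= cutoff * cutoff)[0]:
                b = a + 1 + int(off)
                mi, mj = int(mol_ids[a]), int(mol_ids[b])
                if mi != mj:
                    counts[(min(mi, mj), max(mi, mj))] += 1
    return {pair for pair, c in counts.items() if c >= min_contacts}


# ----------------------------------------------------------------------
# components
# ----------------------------------------------------------------------

def connected_components(graph: ContactGraph, n_molecules: int | None = None) -> ClusterLabels:
    """Cluster labels as connected components of the contact graph.

    Isolated molecules form singleton clusters, so a fully dispersed
    frame yields ``N_c = N_mol``.  Labels are canonicalised to the
    smallest molecule id in each component.
    """
    n = n_molecules if n_molecules is not None else graph.n_molecules
    if graph.edges and max(max(e) for e in graph.edges) >= n:
        raise ValueError("graph contains molecule ids >= n_molecules")
    uf = UnionFind(n)
    for i, j in graph.edges:
        uf.union(i, j)
    roots = np.array([uf.find(i) for i in range(n)], dtype=int)
    # canonical label: smallest member id of each component
    canonical: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        labels[i] = canonical.setdefault(int(r), i)
    return ClusterLabels(labels)


def cluster_frame(
    frame: Frame,
    mol_map: MoleculeMap,
    cutoff: float = DEFAULT_CUTOFF,
    method: str = "cell_list",
    contact_atoms: str = "all",
) -> ClusterLabels:
    """Contacts + components for a single frame."""
    graph = find_contacts(frame, mol_map, cutoff=cutoff, method=method,
                          contact_atoms=contact_atoms)
    return connected_components(graph)


def cluster_trajectory(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    n_frames: int = DEFAULT_N_FRAMES,
    method: str = "cell_list",
    contact_atoms: str = "all",
) -> NcSeries:
    """Per-frame cluster counts on ``n_frames`` equispaced snapshots.

    Returns the ``N_c`` time series from which population profiles and
    the fC_5 aggregation metric are computed.
    """
    sub = select_equispaced_frames(traj, n_frames)
    records = []
    for fr in sub:
        labels = cluster_frame(
            fr, sub.molecule_map, cutoff=cutoff, method=method,
            contact_atoms=contact_atoms,
        )
        records.append(
            NcRecord(
                frame_index=fr.index,
                time_ps=fr.time,
                n_clusters=labels.n_clusters,
                largest_cluster_size=int(labels.sizes[0]),
            )
        )
    return NcSeries(
        records=tuple(records),
        n_molecules=sub.n_molecules,
        cutoff=cutoff,
        meta={"contact_atoms": contact_atoms, "method": method,
              **sub.provenance},
    )
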