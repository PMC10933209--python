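"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the library's own geometry/graph code paths:
minimum images come from explicit enumeration of the 27 neighbouring
periodic images of wrapped points, and connected components from a
depth-first search over an adjacency list (cross-checked elsewhere
against networkx).
"""

from __future__ import annotations

import itertools

import numpy as np


def wrap_fractional(vectors: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Wrap points into the primary cell via fractional coordinates."""
    inv = np.linalg.inv(vectors)
    frac = np.atleast_2d(points) @ inv
    frac -= np.floor(frac)
    return frac @ vectors


def brute_min_image_distance(vectors: np.ndarray, a, b) -> float:
    """Min distance over the 27 periodic images of wrapped points."""
    a = wrap_fractional(vectors, np.asarray(a, float))[0]
    b = wrap_fractional(vectors, np.asarray(b, float))[0]
    best = np.inf
    for i, j, k in itertools.product((-1, 0, 1), repeat=3):
        shift = i * vectors[0] + j * vectors[1] + k * vectors[2]
        best = min(best, float(np.linalg.norm(b + shift - a)))
    return best


def brute_contact_edges(
    vectors: np.ndarray, coords: np.ndarray, mol_ids: np.ndarray, cutoff: float
) -> set[tuple[int, int]]:
    """All-pairs 27-image contact edges between distinct molecules."""
    wrapped = wrap_fractional(vectors, coords)
    shifts = np.array(
        [i * vectors[0] + j * vectors[1] + k * vectors[2]
         for i, j, k in itertools.product((-1, 0, 1), repeat=3)]
    )
    # images of every atom: (n, 27, 3)
    images = wrapped[:, None, :] + shifts[None, :, :]
    edges: set[tuple[int, int]] = set()
    n = len(wrapped)
    for a in range(n):
        diff = images[a + 1 :, :, :] - wrapped[a][None, None, :]  # (m, 27, 3)
        dmin = np.sqrt(np.einsum("mkc,mkc->mk", diff, diff).min(axis=1))
        for off in np.nonzero(dmin <= cutoff)[0]:
            b = a + 1 + int(off)
            mi, mj = int(mol_ids[a]), int(mol_ids[b])
            if mi != mj:
                edges.add((min(mi, mj), max(mi, mj)))
    return edges


def dfs_components(n: int, edges) -> list[int]:
    """Component labels (smallest member id) by iterative DFS."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    labels = [-1] * n
    for start in range(n):
        if labels[start] != -1:
            continue
        stack = [start]
        while stack:
            node = stack.pop()
            if labels[node] != -1:
                continue
            labels[node] = start
            stack.extend(adj[node])
    return labels


def random_frame(rng: np.random.Generator, truncated_octahedron: bool = False):
    """A random synthetic frame: molecules as Gaussian atom blobs in a box.

    Returns (vectors, coords, mol_ids).  Molecule centres are uniform in
    the cell; atoms scatter 1.5 A around their centre so intermolecular
    contacts occur at realistic rates for cutoffs of 2-6 A.
    """
    n_mol = int(rng.integers(5, 51))
    length = float(rng.uniform(30.0, 60.0))
    if truncated_octahedron:
        from scamscan.box import BoxSpec

        vectors = BoxSpec.truncated_octahedron(length).vectors
    else:
        vectors = np.eye(3) * length
    centers_frac = rng.random((n_mol, 3))
    centers = centers_frac @ vectors
    coords, mol_ids = [], []
    for m in range(n_mol):
        n_atoms = int(rng.integers(1, 41))
        coords.append(centers[m] + rng.normal(scale=1.5, size=(n_atoms, 3)))
        mol_ids.extend([m] * n_atoms)
    return vectors, np.concatenate(coords), np.array(mol_ids, dtype=int)
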