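import numpy as np
import pytest

from _oracles import brute_contact_edges, dfs_components, random_frame
from conftest import single_bead_trajectory
from scamscan.box import BoxSpec
from scamscan.clustering import (
    ContactGraph,
    NcSeries,
    NcRecord,
    UnionFind,
    cluster_trajectory,
    connected_components,
    find_contacts,
)
from scamscan.trajectory_io import Frame, MoleculeMap


def frame_of(points, box, elements=None):
    n = len(points)
    mol_map = MoleculeMap(np.arange(n), tuple(elements or ["C"] * n))
    return Frame(0, 0.0, np.asarray(points, float), box), mol_map


class TestFindContacts:
    def test_pair_within_cutoff_has_edge(self, cubic_box):
        frame, mol_map = frame_of([[10, 10, 10], [10, 10, 12.9]], cubic_box)
        graph = find_contacts(frame, mol_map, cutoff=3.0)
        assert graph.edges == frozenset({(0, 1)})

    def test_pair_just_beyond_cutoff_no_edge(self, cubic_box):
        frame, mol_map = frame_of([[10, 10, 10], [10, 10, 13.01]], cubic_box)
        assert not find_contacts(frame, mol_map, cutoff=3.0).edges

    def test_cutoff_boundary_is_inclusive(self, cubic_box):
        frame, mol_map = frame_of([[10, 10, 10], [10, 10, 13.0]], cubic_box)
        assert find_contacts(frame, mol_map, cutoff=3.0).edges

    def test_contact_across_periodic_boundary(self):
        box = BoxSpec.cubic(20.0)
        frame, mol_map = frame_of([[0.5, 5, 5], [19.5, 5, 5]], box)
        assert find_contacts(frame, mol_map, cutoff=1.5).edges == frozenset({(0, 1)})

    def test_heavy_only_ignores_hydrogen_contacts(self, cubic_box):
        # molecules touch only through an H atom
        points = [[10, 10, 10], [10, 10, 12.0], [10, 10, 30], [10, 10, 13.5]]
        mol_map = MoleculeMap(np.array([0, 0, 1, 1]), ("C", "H", "C", "C"))
        frame = Frame(0, 0.0, np.asarray(points, float), cubic_box)
        assert find_contacts(frame, mol_map, cutoff=3.0, contact_atoms="all").edges
        assert not find_contacts(frame, mol_map, cutoff=3.0, contact_atoms="heavy").edges

    def test_cell_list_rejects_huge_cutoff(self, cubic_box):
        frame, mol_map = frame_of([[1, 1, 1], [5, 5, 5]], cubic_box)
        with pytest.raises(ValueError, match="brute"):
            find_contacts(frame, mol_map, cutoff=31.0, method="cell_list")
        # brute still works
        find_contacts(frame, mol_map, cutoff=31.0, method="brute")

    def test_min_contacts_requires_multiple_pairs(self, cubic_box):
        # two two-atom molecules sharing exactly one close atom pair
        points = [[10, 10, 10], [10, 10, 5], [10, 10, 12], [10, 10, 40]]
        mol_map = MoleculeMap(np.array([0, 0, 1, 1]), ("C",) * 4)
        frame = Frame(0, 0.0, np.asarray(points, float), cubic_box)
        assert find_contacts(frame, mol_map, cutoff=3.0, min_contacts=1).edges
        assert not find_contacts(frame, mol_map, cutoff=3.0, min_contacts=2).edges

    @pytest.mark.parametrize("octa", [False, True], ids=["cubic", "truncated_octahedron"])
    def test_brute_equals_cell_list_random_frames(self, rng, octa):
        for _ in range(15):
            vectors, coords, mol_ids = random_frame(rng, truncated_octahedron=octa)
            box = BoxSpec(vectors)
            mol_map = MoleculeMap(mol_ids, tuple(["C"] * len(mol_ids)))
            frame = Frame(0, 0.0, coords, box)
            cutoff = float(rng.uniform(2.0, 6.0))
            brute = find_contacts(frame, mol_map, cutoff=cutoff, method="brute")
            cell = find_contacts(frame, mol_map, cutoff=cutoff, method="cell_list")
            assert brute.edges == cell.edges

    def test_matches_mdanalysis_kdtree_search(self, rng):
        # independent library route (periodic KD-tree) on a cubic cell
        from MDAnalysis.lib.distances import capped_distance

        vectors, coords, mol_ids = random_frame(rng)
        box = BoxSpec(vectors)
        mol_map = MoleculeMap(mol_ids, tuple(["C"] * len(mol_ids)))
        ours = find_contacts(Frame(0, 0.0, coords, box), mol_map, cutoff=4.0)
        pairs = capped_distance(
            coords, coords, max_cutoff=4.0, box=box.to_mdanalysis(),
            return_distances=False, method="pkdtree",
        )
        ref = {
            (min(mol_ids[a], mol_ids[b]), max(mol_ids[a], mol_ids[b]))
            for a, b in pairs
            if mol_ids[a] != mol_ids[b]
        }
        assert ours.edges == frozenset(ref)

    def test_translation_by_lattice_vector_preserves_graph(self, rng):
        vectors, coords, mol_ids = random_frame(rng, truncated_octahedron=True)
        box = BoxSpec(vectors)
        mol_map = MoleculeMap(mol_ids, tuple(["C"] * len(mol_ids)))
        g0 = find_contacts(Frame(0, 0.0, coords, box), mol_map, cutoff=4.0)
        shifted = coords + 2 * vectors[0] - vectors[2]
        g1 = find_contacts(Frame(0, 0.0, shifted, box), mol_map, cutoff=4.0)
        assert g0.edges == g1.edges

    def test_nc_non_increasing_in_cutoff(self, rng):
        vectors, coords, mol_ids = random_frame(rng)
        box = BoxSpec(vectors)
        mol_map = MoleculeMap(mol_ids, tuple(["C"] * len(mol_ids)))
        frame = Frame(0, 0.0, coords, box)
        previous = None
        for cutoff in (2.0, 3.0, 4.0, 5.0, 6.0):
            graph = find_contacts(frame, mol_map, cutoff=cutoff)
            nc = connected_components(graph).n_clusters
            if previous is not None:
                assert nc <= previous
            previous = nc


class TestConnectedComponents:
    def test_no_edges_gives_all_singletons(self):
        graph = ContactGraph(0, 11, frozenset(), 3.0)
        labels = connected_components(graph)
        assert labels.n_clusters == 11
        assert list(labels.sizes) == [1] * 11

    def test_chain_of_three(self):
        graph = ContactGraph(0, 11, frozenset({(0, 1), (1, 2)}), 3.0)
        labels = connected_components(graph)
        assert labels.n_clusters == 9
        assert list(labels.sizes) == [3] + [1] * 8

    def test_random_graphs_match_dfs_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 30))
            n_edges = int(rng.integers(0, 2 * n))
            edges = set()
            for _ in range(n_edges):
                i, j = rng.integers(0, n, size=2)
                if i != j:
                    edges.add((min(i, j), max(i, j)))
            graph = ContactGraph(0, n, frozenset((int(a), int(b)) for a, b in edges), 3.0)
            ours = connected_components(graph)
            oracle = dfs_components(n, edges)
            assert list(ours.labels) == oracle

    def test_matches_networkx(self, rng):
        import networkx as nx

        for _ in range(50):
            n = int(rng.integers(2, 25))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1 << 31)))
            edges = frozenset((min(u, v), max(u, v)) for u, v in g.edges)
            ours = connected_components(ContactGraph(0, n, edges, 3.0))
            assert ours.n_clusters == nx.number_connected_components(g)

    def test_rejects_out_of_range_ids(self):
        graph = ContactGraph(0, 5, frozenset({(0, 4)}), 3.0)
        with pytest.raises(ValueError):
            connected_components(graph, n_molecules=3)

    def test_union_find_idempotent_unions(self):
        uf = UnionFind(4)
        uf.union(0, 1)
        uf.union(0, 1)
        uf.union(2, 3)
        assert uf.find(1) == uf.find(0)
        assert uf.find(2) == uf.find(3)
        assert uf.find(0) != uf.find(2)


class TestClusterTrajectory:
    def test_fused_blob_every_frame(self, cubic_box):
        blob = 30.0 + np.arange(12)[:, None] * [0.0, 0.0, 1.0]
        traj = single_bead_trajectory([blob, blob, blob], cubic_box)
        series = cluster_trajectory(traj, cutoff=1.5, n_frames=3)
        assert all(r.n_clusters == 1 for r in series.records)
        assert all(r.largest_cluster_size == 12 for r in series.records)

    def test_dispersed_every_frame(self, dispersed_frame, cubic_box):
        traj = single_bead_trajectory(
            [dispersed_frame.coords, dispersed_frame.coords + 0.5], cubic_box
        )
        series = cluster_trajectory(traj, cutoff=3.0, n_frames=2)
        assert all(r.n_clusters == 12 for r in series.records)

    def test_alternating_fused_dispersed(self, dispersed_frame, cubic_box):
        blob = 30.0 + np.arange(12)[:, None] * [0.0, 0.0, 1.0]
        frames = [blob, dispersed_frame.coords, blob + 0.3, dispersed_frame.coords + 0.3]
        traj = single_bead_trajectory(frames, cubic_box)
        series = cluster_trajectory(traj, cutoff=1.5, n_frames=4)
        assert [r.n_clusters for r in series.records] == [1, 12, 1, 12]

    def test_series_roundtrips_through_csv(self, tmp_path, dispersed_frame, cubic_box):
        traj = single_bead_trajectory(
            [dispersed_frame.coords, dispersed_frame.coords + 1.0], cubic_box
        )
        series = cluster_trajectory(traj, cutoff=3.0, n_frames=2)
        path = tmp_path / "nc.csv"
        series.to_csv(path)
        back = NcSeries.from_csv(path, n_molecules=12)
        assert back.records == series.records


def test_nc_series_validates_range():
    with pytest.raises(ValueError):
        NcSeries((NcRecord(0, 0.0, 13, 1),), n_molecules=12)
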