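import numpy as np
import pytest

from scamscan.box import BoxSpec
from scamscan.trajectory_io import (
    Frame,
    MoleculeMap,
    SelectionError,
    Trajectory,
    TrajectoryReadError,
    equispaced_indices,
    read_molecule_map,
    read_trajectory,
    read_xyz,
    select_equispaced_frames,
    write_molecule_map,
    write_xyz,
)


def toy_trajectory(n_frames=3, n_mol=12, box=None, jitter=0.0, rng=None):
    box = box or BoxSpec.cubic(60.0)
    base = np.linspace(5, 55, n_mol)[:, None] * [1.0, 0.0, 0.0] + [0.0, 30.0, 30.0]
    frames = []
    for i in range(n_frames):
        coords = base + (rng.normal(scale=jitter, size=base.shape) if jitter else 0.0)
        frames.append(Frame(i, 20.0 * i, coords, box))
    mol_map = MoleculeMap(np.arange(n_mol), tuple(["C"] * n_mol))
    return Trajectory(frames, mol_map)


class TestXYZRoundTrip:
    def test_three_frame_single_bead_counts(self, tmp_path):
        traj = toy_trajectory()
        path = tmp_path / "t.xyz"
        write_xyz(path, traj)
        back = read_trajectory(path)
        assert len(back) == 3
        assert back.n_molecules == 12

    def test_coordinates_survive_to_format_precision(self, tmp_path, rng):
        traj = toy_trajectory(jitter=2.0, rng=rng)
        path = tmp_path / "t.xyz"
        write_xyz(path, traj)
        back = read_xyz(path)
        for orig, rt in zip(traj.frames, back.frames):
            assert np.abs(orig.coords - rt.coords).max() <= 1e-3
            assert np.allclose(orig.box.vectors, rt.box.vectors, atol=1e-3)
            assert rt.time == pytest.approx(orig.time)

    def test_truncated_second_frame_names_frame(self, tmp_path):
        traj = toy_trajectory(n_frames=3, n_mol=4)
        path = tmp_path / "t.xyz"
        write_xyz(path, traj)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[: 6 + 2 + 2]) + "\n")  # cut frame 1 mid-record
        with pytest.raises(TrajectoryReadError, match="frame 1"):
            read_xyz(path)

    def test_missing_file(self):
        with pytest.raises(TrajectoryReadError, match="no such file"):
            read_trajectory("/nonexistent/path.xyz")


class TestMoleculeMap:
    def test_sidecar_round_trip(self, tmp_path):
        mol_map = MoleculeMap(np.array([0, 0, 1, -1, 2]), ("C", "H", "N", "O", "C"))
        path = tmp_path / "m.map.tsv"
        write_molecule_map(path, mol_map)
        back = read_molecule_map(path)
        assert np.array_equal(back.molecule_id, mol_map.molecule_id)
        assert back.elements == mol_map.elements

    def test_non_contiguous_ids_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            MoleculeMap(np.array([0, 2, 2]))

    def test_all_solvent_rejected(self):
        with pytest.raises(SelectionError):
            MoleculeMap(np.array([-1, -1]))

    def test_heavy_mask_flags_hydrogens(self):
        mol_map = MoleculeMap(np.array([0, 0, 1]), ("C", "H", "N"))
        assert list(mol_map.heavy_mask()) == [True, False, True]


class TestPDBReading:
    def _write_pdb(self, path, n_solute=11, n_water=5):
        lines = []
        serial = 1
        for model in (1, 2):
            lines.append(f"MODEL     {model}")
            for res in range(n_solute):
                x = 5.0 * res + model
                lines.append(
                    f"ATOM  {serial:>5} {'C1':<4}"
                    f" LIG A{res + 1:>4}    "
                    f"{x:8.3f}{10.0:8.3f}{10.0:8.3f}  1.00  0.00           C"
                )
                serial += 1
            for res in range(n_water):
                x = 5.0 * res
                lines.append(
                    f"ATOM  {serial:>5} {'O':<4}"
                    f" WAT A{n_solute + res + 1:>4}    "
                    f"{x:8.3f}{40.0:8.3f}{40.0:8.3f}  1.00  0.00           O"
                )
                serial += 1
            lines.append("ENDMDL")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")

    def test_selection_masks_solute_molecules(self, tmp_path):
        path = tmp_path / "s.pdb"
        self._write_pdb(path)
        traj = read_trajectory(
            path, solute_selection="resname LIG", default_box=BoxSpec.cubic(60.0)
        )
        assert len(traj) == 2
        assert traj.n_molecules == 11
        # waters retained but masked out
        assert traj.molecule_map.n_atoms == 16
        assert traj.molecule_map.solute_mask.sum() == 11

    def test_empty_selection_raises(self, tmp_path):
        path = tmp_path / "s.pdb"
        self._write_pdb(path)
        with pytest.raises(SelectionError):
            read_trajectory(
                path, solute_selection="resname XXX", default_box=BoxSpec.cubic(60.0)
            )


class TestEquispacedSelection:
    def test_5000_from_50000(self):
        idx = equispaced_indices(50_000, 5000)
        assert len(idx) == 5000
        assert idx[0] == 0 and idx[-1] == 49_999
        strides = {b - a for a, b in zip(idx, idx[1:])}
        assert strides <= {10, 11}  # nominally every 10th frame

    def test_identity_when_counts_match(self):
        traj = toy_trajectory(n_frames=3)
        sub = select_equispaced_frames(traj, 3)
        assert [f.index for f in sub.frames] == [0, 1, 2]

    def test_endpoints_f5_n2(self):
        traj = toy_trajectory(n_frames=5)
        sub = select_equispaced_frames(traj, 2)
        assert [f.index for f in sub.frames] == [0, 4]

    def test_shortfall_recorded_in_provenance(self):
        traj = toy_trajectory(n_frames=3)
        sub = select_equispaced_frames(traj, 10)
        assert len(sub) == 3
        assert sub.provenance["frame_shortfall"] is True

    @pytest.mark.parametrize("n_avail,n_want", [(7, 2), (100, 7), (5000, 5000), (9, 4)])
    def test_first_and_last_always_included(self, n_avail, n_want):
        idx = equispaced_indices(n_avail, n_want)
        assert idx[0] == 0
        assert idx[-1] == n_avail - 1
        assert idx == sorted(set(idx))

    def test_empty_request_rejected(self):
        with pytest.raises(ValueError):
            equispaced_indices(10, 0)


def test_trajectory_rejects_non_increasing_times():
    box = BoxSpec.cubic(10.0)
    mol_map = MoleculeMap(np.array([0]))
    frames = [
        Frame(0, 0.0, np.zeros((1, 3)), box),
        Frame(1, 0.0, np.zeros((1, 3)), box),
    ]
    with pytest.raises(ValueError, match="strictly increasing"):
        Trajectory(frames, mol_map)
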