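import numpy as np
import pytest

from scamscan.box import BoxSpec
from scamscan.clustering import NcRecord, NcSeries
from scamscan.trajectory_io import Frame, MoleculeMap, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def cubic_box():
    return BoxSpec.cubic(60.0)


def make_series(nc_values, n_molecules=11, cutoff=3.0):
    """NcSeries from a plain list of per-frame cluster counts."""
    records = tuple(
        NcRecord(i, 20.0 * i, int(nc), n_molecules - int(nc) + 1)
        for i, nc in enumerate(nc_values)
    )
    return NcSeries(records, n_molecules=n_molecules, cutoff=cutoff)


def single_bead_trajectory(positions_per_frame, box, times=None):
    """Trajectory of single-atom molecules from a list of (n, 3) arrays."""
    n = len(positions_per_frame[0])
    mol_map = MoleculeMap(np.arange(n), tuple(["C"] * n))
    frames = [
        Frame(i, times[i] if times else 20.0 * i, np.asarray(p, float), box)
        for i, p in enumerate(positions_per_frame)
    ]
    return Trajectory(frames, mol_map)


@pytest.fixture
def dispersed_frame(cubic_box):
    """12 single-bead molecules on a loose grid, all far apart."""
    pts = np.array(
        [[10.0 + 20 * i, 10.0 + 20 * j, 15.0 + 30 * k]
         for i in range(2) for j in range(3) for k in range(2)]
    )
    return single_bead_trajectory([pts], cubic_box).frames[0]
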