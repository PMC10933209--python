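"""Overdamped Langevin (Brownian) dynamics of sticky spheres.

A desk-scale surrogate for solvated molecular dynamics of self-
associating solutes: N single-bead (optionally rigid-trimer) molecules
diffuse in a periodic box under a truncated-and-shifted Lennard-Jones
pair potential.  The well depth ``epsilon`` (in units of kT) is the
single knob controlling aggregation propensity, playing the role that
solute hydrophobicity plays in explicit solvent — ``epsilon = 0``
leaves only the repulsive core (a dispersed, near-ideal suspension)
while a few kT of attraction drives spontaneous aggregation into a few
large clusters, reproducing both limiting population-profile regimes
on demand.

The pair potential follows the Weeks-Chandler-Andersen splitting: the
repulsive core (r < 2^(1/6) sigma) always acts with at least unit
strength so that beads remain impenetrable even at ``epsilon = 0``,
while the attractive branch is the truncated-and-shifted LJ tail
scaled by ``epsilon`` (cutoff 2.5 sigma); for ``epsilon >= 1`` this
reduces to the plain LJ potential of well depth epsilon.  The force is
continuous everywhere.

Positions advance by the position-Langevin (overdamped) update

    x <- x + (F / gamma) dt + N(0, sqrt(2 kT dt / gamma))

with minimum-image pair forces and wrapped output coordinates.
Internally the integrator works in reduced units (sigma = 1, kT = 1,
gamma = 1, so the time unit is tau = sigma^2 gamma / kT); coordinates
are scaled to angstrom on output via the bead diameter.  Runs are
bitwise reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .box import BoxSpec, wrap_coordinates
from .trajectory_io import Frame, MoleculeMap, Trajectory, write_molecule_map, write_xyz

__all__ = [
    "SimConfig",
    "PlacementError",
    "InstabilityError",
    "place_molecules",
    "simulate",
    "recommended_contact_cutoff",
]


class PlacementError(RuntimeError):
    """Could not place molecules at the requested density/separation."""


class InstabilityError(RuntimeError):
    """Integration step moved a bead further than sigma/2."""


@dataclass(frozen=True)
class SimConfig:
    """Sticky-sphere simulation parameters.

    Defaults reproduce the solute-count regime of a small-molecule
    aggregation study (about a dozen solutes in a periodic cell) at a
    density where both dispersed and aggregated end states are
    reachable within a short run.

    Attributes
    ----------
    n_molecules : int
        Number of solute molecules (default 12).
    beads_per_molecule : int
        1 (point particle) or 3 (rigid linear trimer, bead centres
        sigma/2 apart, for exercising heavy-vs-all-atom contact modes).
    sigma : float
        Bead diameter, angstrom.  Sets the length scale of the LJ core.
    epsilon : float
        LJ well depth in units of kT.  0 disables attraction.
    box_length : float
        Cubic box edge, angstrom.
    temperature : float
        Nominal temperature in kelvin (bookkeeping only: energies are
        expressed in kT, so dynamics depend on epsilon alone).
    dt : float
        Timestep in reduced time units tau = sigma^2 gamma / kT.
    n_steps : int
        Number of integration steps.
    save_interval : int
        Steps between saved frames.
    friction : float
        Reduced friction coefficient gamma (1.0 leaves D = 1).
    seed : int
        RNG seed; identical seeds give identical trajectories.
    min_separation : float
        Minimum pairwise minimum-image distance at placement, angstrom.
    save_interval_ps : float
        Nominal picoseconds per saved frame in the emitted trajectory
        (cosmetic time axis for downstream tooling).
    """

    n_molecules: int = 12
    beads_per_molecule: int = 1
    sigma: float = 10.0
    epsilon: float = 0.0
    box_length: float = 60.0
    temperature: float = 300.0
    dt: float = 1e-4
    n_steps: int = 200_000
    save_interval: int = 200
    friction: float = 1.0
    seed: int = 0
    min_separation: float = 10.0
    save_interval_ps: float = 20.0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.sigma <= 0 or self.box_length <= 0:
            raise ValueError("sigma and box_length must be positive")
        if self.beads_per_molecule not in (1, 3):
            raise ValueError("beads_per_molecule must be 1 or 3")
        if self.n_molecules < 1 or self.n_steps < 1 or self.save_interval < 1:
            raise ValueError("counts must be positive")
        # crude feasibility check: bead cores must fit in the box
        n_beads = self.n_molecules * self.beads_per_molecule
        if n_beads * self.sigma**3 > 0.5 * self.box_length**3:
            raise ValueError(
                "density too high: N * sigma^3 must be well below the box volume"
            )

    @property
    def box(self) -> BoxSpec:
        return BoxSpec.cubic(self.box_length)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            data = yaml.safe_load(Path(source).read_text())
        else:
            data = yaml.safe_load(source)
        return cls(**data)


def recommended_contact_cutoff(config: SimConfig) -> float:
    """Contact cutoff (angstrom) suited to bead systems: 1.5 sigma.

    For Lennard-Jones particles the first coordination shell extends to
    the first minimum of g(r) near 1.5 sigma, the conventional bonding
    criterion in colloidal cluster analysis.  (The 3.0 A atomistic
    default probes atom-atom surface contacts and is not meaningful for
    smooth beads whose centres sit ~2^(1/6) sigma apart when bound.)
    """
    return 1.5 * config.sigma


def place_molecules(
    n: int, box: BoxSpec, min_sep: float, seed: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Random sequential insertion of ``n`` points with a separation floor.

    Draws uniform positions in the cell, rejecting any candidate whose
    minimum-image distance to an accepted point is below ``min_sep``.
    Deterministic for a given seed.  Raises :class:`PlacementError`
    after 10^4 consecutive rejections (density infeasible).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    rejections = 0
    inv = np.linalg.inv(box.vectors)
    while len(placed) < n:
        frac = rng.random(3)
        cand = frac @ box.vectors
        ok = True
        if placed:
            from .box import minimum_image_displacement

            disp = minimum_image_displacement(
                box, np.array(placed), np.broadcast_to(cand, (len(placed), 3))
            )
            if np.min(np.einsum("ij,ij->i", np.atleast_2d(disp), np.atleast_2d(disp))) < min_sep**2:
                ok = False
        if ok:
            placed.append(cand)
            rejections = 0
        else:
            rejections += 1
            if rejections >= 10_000:
                raise PlacementError(
                    f"placed {len(placed)}/{n} molecules before 10^4 consecutive "
                    f"rejections; reduce density or min_separation"
                )
    _ = inv  # fractional basis kept for clarity
    return np.array(placed)


def _lj_forces(pos: np.ndarray, box_len: float, epsilon: float, rcut: float,
               mol_ids: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Truncated-and-shifted LJ forces in reduced units (sigma = kT = 1).

    Intramolecular bead pairs (same ``mol_ids`` entry) are excluded: a
    rigid molecule's internal geometry is not subject to pair forces.
    Returns (forces, max_force_magnitude).  Minimum image for the cubic
    cell is plain coordinate rounding.
    """
    n = len(pos)
    d = pos[:, None, :] - pos[None, :, :]
    d -= box_len * np.round(d / box_len)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    np.fill_diagonal(r2, np.inf)
    if mol_ids is not None:
        r2[mol_ids[:, None] == mol_ids[None, :]] = np.inf
    mask = r2 < rcut * rcut
    inv_r2 = np.where(mask, 1.0 / np.maximum(r2, 1e-12), 0.0)
    inv_r6 = inv_r2**3
    # dU/dr term: F_vec = 24 eps_eff (2 r^-12 - r^-6) / r^2 * d_vec
    # epsilon = 0 keeps the repulsive (WCA-like) core with unit strength.
    eps_eff = np.where(r2 < 2 ** (1 / 3), max(epsilon, 1.0), epsilon)
    fmag = 24.0 * eps_eff * (2.0 * inv_r6 * inv_r6 - inv_r6) * inv_r2
    forces = np.einsum("ij,ijk->ik", fmag, d)
    max_step_force = float(np.abs(fmag[mask] * np.sqrt(r2[mask])).max()) if mask.any() else 0.0
    return forces, max_step_force


def simulate(config: SimConfig) -> Trajectory:
    """Run overdamped Langevin dynamics and return the trajectory.

    Beads start from a well-dispersed random placement (the surrogate
    for a high-temperature mixing phase) and evolve under the update
    ``x <- x + (F/gamma) dt + sqrt(2 kT dt / gamma) * xi``.  Frames are
    emitted every ``save_interval`` steps with coordinates wrapped into
    the primary cell.  A step that would move any bead further than
    sigma/2 aborts with :class:`InstabilityError` (reduce ``dt``).
    """
    rng = np.random.default_rng(config.seed)
    L = config.box_length / config.sigma  # box edge, reduced units
    rcut = 2.5
    n_beads = config.n_molecules * config.beads_per_molecule

    centers = place_molecules(
        config.n_molecules,
        BoxSpec.cubic(L),
        config.min_separation / config.sigma,
        config.seed,
        rng=rng,
    )
    if config.beads_per_molecule == 1:
        pos = centers
        mol_ids = np.arange(config.n_molecules)
    else:
        # rigid linear trimer along a random axis, beads sigma/2 apart
        axes = rng.normal(size=(config.n_molecules, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        offsets = np.array([-0.5, 0.0, 0.5])
        pos = (centers[:, None, :] + offsets[None, :, None] * axes[:, None, :]).reshape(-1, 3)
        mol_ids = np.repeat(np.arange(config.n_molecules), 3)

    noise_scale = np.sqrt(2.0 * config.dt / config.friction)
    mobility = config.dt / config.friction
    max_disp = 0.5  # sigma/2 in reduced units

    frames: list[Frame] = []
    out_box = config.box
    frame_count = 0

    def _emit(step: int) -> None:
        nonlocal frame_count
        wrapped = wrap_coordinates(out_box, pos * config.sigma)
        frames.append(
            Frame(
                index=frame_count,
                time=frame_count * config.save_interval_ps,
                coords=wrapped,
                box=out_box,
            )
        )
        frame_count += 1

    _emit(0)
    for step in range(1, config.n_steps + 1):
        if config.beads_per_molecule == 1:
            forces, _ = _lj_forces(pos, L, config.epsilon, rcut)
            step_vec = mobility * forces + noise_scale * rng.standard_normal(
                (n_beads, 3)
            )
            disp_max = float(np.abs(step_vec).max())
            if disp_max > max_disp:
                raise InstabilityError(
                    f"step {step}: displacement {disp_max:.2f} sigma exceeds "
                    f"sigma/2; reduce dt (currently {config.dt})"
                )
            pos = pos + step_vec
        else:
            # rigid molecules: translate each trimer by its net force +
            # one shared noise kick (rotational diffusion neglected)
            forces, _ = _lj_forces(pos, L, config.epsilon, rcut, mol_ids=mol_ids)
            net = np.zeros((config.n_molecules, 3))
            np.add.at(net, mol_ids, forces)
            step_vec = (
                mobility * net / config.beads_per_molecule
                + noise_scale
                * rng.standard_normal((config.n_molecules, 3))
                / np.sqrt(config.beads_per_molecule)
            )
            disp_max = float(np.abs(step_vec).max())
            if disp_max > max_disp:
                raise InstabilityError(
                    f"step {step}: displacement {disp_max:.2f} sigma exceeds "
                    f"sigma/2; reduce dt (currently {config.dt})"
                )
            pos = pos + step_vec[mol_ids]
        if step % config.save_interval == 0:
            _emit(step)

    mol_map = MoleculeMap(mol_ids, tuple(["C"] * n_beads))
    return Trajectory(
        frames,
        mol_map,
        provenance={
            "generator": "scamscan.simulate",
            "seed": config.seed,
            "epsilon_kT": config.epsilon,
            "sigma_A": config.sigma,
            "n_steps": config.n_steps,
        },
    )


def write_simulation(traj: Trajectory, out_prefix: str | Path) -> dict[str, Path]:
    """Write XYZ + molecule-map sidecar; returns the emitted paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    xyz = out_prefix.parent / (out_prefix.name + ".xyz")
    sidecar = out_prefix.parent / (out_prefix.name + ".map.tsv")
    write_xyz(xyz, traj)
    write_molecule_map(sidecar, traj.molecule_map)
    return {"xyz": xyz, "map": sidecar}
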