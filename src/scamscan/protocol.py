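"""Simulation-protocol and system-composition artefacts.

Encodes the reference MD protocol for solvated small-molecule
aggregation runs — minimisation, a 0->500 K mixing heat-up, a
500->300 K cool-down (20 ps NVT each), 2 ns of NPT equilibration at
300 K / 1 atm, and a 1 microsecond production run saving coordinates
every 20 ps, all with a 2 fs timestep, hydrogen-bond constraints, a
10 A non-bonded cutoff and Langevin friction 1.0 ps^-1 — as checkable
emitted text (AMBER-style ``mdin`` namelists) without executing any
dynamics.

The composition calculator turns a periodic cell plus assay-buffer
recipe (solute count, DMSO volume fraction, NaCl molarity) into the
integer molecule/ion counts a system builder needs, and verifies the
solute concentration lands in the intended millimolar regime.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = [
    "Stage",
    "ProtocolSpec",
    "CompositionSpec",
    "Composition",
    "default_protocol",
    "emit_input_files",
    "parse_mdin",
    "composition",
    "AVOGADRO",
    "DMSO_MOLAR_VOLUME",
]

#: Avogadro constant, 1/mol.
AVOGADRO = 6.022_140_76e23

#: Molar volume of liquid DMSO at 25 C, cm^3/mol (density 1.1004 g/cm^3,
#: M = 78.13 g/mol).  Configurable in :func:`composition`.
DMSO_MOLAR_VOLUME = 71.3

_ENSEMBLES = ("minimisation", "NVT", "NPT")


@dataclass(frozen=True)
class Stage:
    """One protocol stage (restart-chained to its predecessor)."""

    name: str
    ensemble: str
    temperature_initial: float  # K
    temperature_final: float  # K
    duration_ps: float
    timestep_fs: float = 2.0
    cutoff_angstrom: float = 10.0
    friction_per_ps: float = 1.0
    pressure_atm: float | None = None  # NPT only
    constrain_h_bonds: bool = True
    save_interval_ps: float | None = None

    def __post_init__(self) -> None:
        if self.ensemble not in _ENSEMBLES:
            raise ValueError(f"ensemble must be one of {_ENSEMBLES}")
        if self.duration_ps <= 0:
            raise ValueError(f"stage {self.name!r}: duration must be positive")
        if self.ensemble != "minimisation" and self.timestep_fs <= 0:
            raise ValueError(f"stage {self.name!r}: timestep must be positive")
        if self.ensemble == "NPT" and self.pressure_atm is None:
            raise ValueError(f"stage {self.name!r}: NPT requires a pressure")

    @property
    def n_steps(self) -> int:
        """Exact integer step count duration/timestep (dynamics stages)."""
        if self.ensemble == "minimisation":
            return int(self.duration_ps)  # interpreted as minimisation cycles
        steps = self.duration_ps * 1000.0 / self.timestep_fs
        rounded = round(steps)
        if abs(steps - rounded) > 1e-6:
            raise ValueError(
                f"stage {self.name!r}: duration {self.duration_ps} ps is not an "
                f"integer number of {self.timestep_fs} fs steps"
            )
        return int(rounded)

    @property
    def save_stride(self) -> int | None:
        """Steps between saved frames, if this stage saves coordinates."""
        if self.save_interval_ps is None:
            return None
        return round(self.save_interval_ps * 1000.0 / self.timestep_fs)


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered stages of one simulation protocol."""

    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("protocol needs at least one stage")
        names = [s.name for s in self.stages]
        if len(set(names)) != len(names):
            raise ValueError("stage names must be unique")

    def stage(self, name: str) -> Stage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)


def default_protocol() -> ProtocolSpec:
    """The reference five-stage aggregation-MD protocol.

    minimisation -> NVT heat 0->500 K (20 ps, to disperse the solutes)
    -> NVT cool 500->300 K (20 ps) -> NPT 300 K / 1 atm (2 ns) ->
    production 1 us at 300 K saving every 20 ps.  All dynamics stages
    use dt = 2 fs with hydrogen constraints, a 10 A non-bonded cutoff
    and Langevin friction 1.0 ps^-1.
    """
    common = dict(timestep_fs=2.0, cutoff_angstrom=10.0, friction_per_ps=1.0)
    return ProtocolSpec(
        stages=(
            Stage(
                name="min",
                ensemble="minimisation",
                temperature_initial=0.0,
                temperature_final=0.0,
                duration_ps=2000,  # minimisation cycles, see emitted comment
                **common,
            ),
            Stage(
                name="heat",
                ensemble="NVT",
                temperature_initial=0.0,
                temperature_final=500.0,
                duration_ps=20.0,
                **common,
            ),
            Stage(
                name="cool",
                ensemble="NVT",
                temperature_initial=500.0,
                temperature_final=300.0,
                duration_ps=20.0,
                **common,
            ),
            Stage(
                name="equil",
                ensemble="NPT",
                temperature_initial=300.0,
                temperature_final=300.0,
                duration_ps=2000.0,
                pressure_atm=1.0,
                **common,
            ),
            Stage(
                name="prod",
                ensemble="NPT",
                temperature_initial=300.0,
                temperature_final=300.0,
                duration_ps=1_000_000.0,  # 1 microsecond
                pressure_atm=1.0,
                save_interval_ps=20.0,
                **common,
            ),
        )
    )


# ----------------------------------------------------------------------
# mdin emission
# ----------------------------------------------------------------------

_DIALECTS = ("amber_mdin",)


def _mdin_lines(stage: Stage) -> list[str]:
    """Sorted key = value namelist body for one stage."""
    kv: dict[str, str] = {}
    if stage.ensemble == "minimisation":
        kv["imin"] = "1"
        kv["maxcyc"] = str(stage.n_steps)
        kv["ncyc"] = str(stage.n_steps // 4)
    else:
        kv["imin"] = "0"
        kv["nstlim"] = str(stage.n_steps)
        kv["dt"] = f"{stage.timestep_fs / 1000.0:.6f}"
        kv["tempi"] = f"{stage.temperature_initial:.1f}"
        kv["temp0"] = f"{stage.temperature_final:.1f}"
        kv["gamma_ln"] = f"{stage.friction_per_ps:.1f}"
        kv["ntt"] = "3"  # Langevin thermostat
        kv["ntb"] = "2" if stage.ensemble == "NPT" else "1"
        if stage.ensemble == "NPT":
            kv["ntp"] = "1"
            kv["pres0"] = f"{stage.pressure_atm:.1f}"
    kv["cut"] = f"{stage.cutoff_angstrom:.1f}"
    if stage.constrain_h_bonds and stage.ensemble != "minimisation":
        kv["ntc"] = "2"
        kv["ntf"] = "2"
    if stage.save_stride is not None:
        kv["ntwx"] = str(stage.save_stride)
    lines = [f"{stage.name}: {stage.ensemble} stage", " &cntrl"]
    for key in sorted(kv):
        lines.append(f"  {key} = {kv[key]},")
    lines.append(" /")
    if stage.ensemble == "minimisation":
        lines.append("! minimisation cycle counts unspecified-in-source; defaults emitted")
    if stage.ensemble == "NPT":
        lines.append("! pressure-coupling scheme implementation-default (isotropic)")
    lines.append("")
    return lines


def emit_input_files(
    spec: ProtocolSpec, out_dir: str | Path, dialect: str = "amber_mdin"
) -> list[Path]:
    """Write one input text file per stage; byte-stable across runs.

    Keys are sorted and numbers formatted with fixed precision so
    re-emission is byte-identical.
    """
    if dialect not in _DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; supported dialects: {list(_DIALECTS)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, stage in enumerate(spec.stages, start=1):
        path = out_dir / f"{i:02d}_{stage.name}.mdin"
        path.write_text("\n".join(_mdin_lines(stage)))
        paths.append(path)
    return paths


def parse_mdin(path: str | Path) -> dict[str, str]:
    """Parse an emitted mdin file back to its key/value dict."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if "=" in line and not line.startswith(("!", "&", "/")):
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip().rstrip(",")
    return kv


def roundtrip_stage(stage: Stage, path: str | Path) -> bool:
    """Check an emitted file encodes the same physics as ``stage``."""
    kv = parse_mdin(path)
    if stage.ensemble == "minimisation":
        return kv.get("imin") == "1" and int(kv["maxcyc"]) == stage.n_steps
    checks = [
        int(kv["nstlim"]) == stage.n_steps,
        math.isclose(float(kv["dt"]) * 1000.0, stage.timestep_fs, rel_tol=1e-6),
        math.isclose(float(kv["temp0"]), stage.temperature_final),
        math.isclose(float(kv["cut"]), stage.cutoff_angstrom),
        math.isclose(float(kv["gamma_ln"]), stage.friction_per_ps),
    ]
    if stage.save_stride is not None:
        checks.append(int(kv["ntwx"]) == stage.save_stride)
    if stage.ensemble == "NPT":
        checks.append(math.isclose(float(kv["pres0"]), stage.pressure_atm))
    return all(checks)


# ----------------------------------------------------------------------
# composition
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionSpec:
    """Assay-buffer recipe for one simulation cell."""

    box_volume_A3: float
    n_solute: int = 11
    dmso_volume_fraction: float = 0.05
    nacl_mM: float = 50.0

    def __post_init__(self) -> None:
        if self.box_volume_A3 <= 0:
            raise ValueError("box volume must be positive")
        if not 0.0 <= self.dmso_volume_fraction <= 1.0:
            raise ValueError("DMSO volume fraction must lie in [0, 1]")
        if self.n_solute < 0 or self.nacl_mM < 0:
            raise ValueError("counts and concentrations must be non-negative")


@dataclass(frozen=True)
class Composition:
    """Derived composition: concentrations and integer counts."""

    solute_molarity: float  # mol/L
    ion_pairs: int
    dmso_molecules: int
    spec: CompositionSpec = field(compare=False, default=None)

    @property
    def solute_mM(self) -> float:
        return self.solute_molarity * 1e3

    def to_dict(self) -> dict:
        return {
            "solute_molarity_mM": self.solute_mM,
            "nacl_ion_pairs": self.ion_pairs,
            "dmso_molecules": self.dmso_molecules,
            **(asdict(self.spec) if self.spec else {}),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def composition(
    spec: CompositionSpec, dmso_molar_volume: float = DMSO_MOLAR_VOLUME
) -> Composition:
    """Integer molecule/ion counts for a buffer recipe in a given cell.

    * solute molarity = n_solute / (N_A * V)
    * NaCl ion pairs  = round(c * N_A * V)      (banker's rounding)
    * DMSO molecules  = round(f_vv * V / v_DMSO), with the per-molecule
      volume v_DMSO from the molar volume (default 71.3 cm^3/mol).

    Eleven solutes in the ~4.49e6 A^3 truncated-octahedron cell give
    ~4 mM — the intended millimolar regime, well above micromolar
    critical aggregation concentrations.
    """
    volume_L = spec.box_volume_A3 * 1e-27  # 1 A^3 = 1e-27 L
    solute_molarity = spec.n_solute / (AVOGADRO * volume_L)
    ion_pairs = round(spec.nacl_mM * 1e-3 * AVOGADRO * volume_L)
    v_dmso_A3 = dmso_molar_volume / AVOGADRO * 1e24  # cm^3 -> A^3
    dmso_molecules = round(spec.dmso_volume_fraction * spec.box_volume_A3 / v_dmso_A3)
    return Composition(
        solute_molarity=solute_molarity,
        ion_pairs=int(ion_pairs),
        dmso_molecules=int(dmso_molecules),
        spec=spec,
    )
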