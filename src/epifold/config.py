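"""Run configuration: one YAML-serialisable bundle of all parameter blocks.

Defaults equal the model's published operating point wherever one exists
(bond length 3.8 A, stiffness 11 k_B*T0/A^2, Morse range 2.1 1/A, core
strength 2 k_B*T0, T0 = 302.15 K, monomer mass 1.66e-22 g, friction
10 1/ps, step 0.01 ps, 127 replicas, quenches at 218.2 K and 134.3 K,
~10^4 shell points, 1 A activity tolerance, lambda = -0.2).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .docking import DEFAULT_SHELL_POINTS, DEFAULT_SWEEP_STEP
from .dynamics import ThermostatParams
from .energetics import PotentialParams
from .folding import DEFAULT_N_REPLICAS

__all__ = ["ScheduleConfig", "DockingConfig", "ScanConfig", "RunConfig"]


@dataclass(frozen=True)
class ScheduleConfig:
    """Folding-schedule block; t_fold derived from the variant at run time."""

    variant: str = "sqrt_exponent"
    dt_f: float = 10.0
    cap: float | None = None
    T_fold: float = 302.15
    T1: float = 218.2
    T2: float = 134.3
    T_f_factor: float = 1.25


@dataclass(frozen=True)
class DockingConfig:
    sweep: float = DEFAULT_SWEEP_STEP
    n_shell_points: int = DEFAULT_SHELL_POINTS
    tolerance: float = 1.0


@dataclass(frozen=True)
class ScanConfig:
    n_pairs: int = 100
    lam: float = -0.2
    sig_mult: float = 3.0
    error_mode: str = "quadrature"


@dataclass(frozen=True)
class RunConfig:
    potentials: PotentialParams = field(default_factory=PotentialParams)
    thermostat: ThermostatParams = field(default_factory=ThermostatParams)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    docking: DockingConfig = field(default_factory=DockingConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    n_replicas: int = DEFAULT_N_REPLICAS
    lindemann_c: float = 0.25
    base_seed: int = 0
    out_dir: str = "epifold_out"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            potentials=PotentialParams(**d.get("potentials", {})),
            thermostat=ThermostatParams(**d.get("thermostat", {})),
            schedule=ScheduleConfig(**d.get("schedule", {})),
            docking=DockingConfig(**d.get("docking", {})),
            scan=ScanConfig(**d.get("scan", {})),
            n_replicas=d.get("n_replicas", DEFAULT_N_REPLICAS),
            lindemann_c=d.get("lindemann_c", 0.25),
            base_seed=d.get("base_seed", 0),
            out_dir=d.get("out_dir", "epifold_out"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """Short digest embedded in reports for provenance."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
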