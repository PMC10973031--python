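"""Model parameters, physical-unit mapping and characteristic scales.

The model couples a conserved phase field ``phi`` (labelling the two cell
types, +-1 in pure regions), a polarity vector ``p`` along which cells
self-propel, and an incompressible friction-damped Stokes flow ``v``.
Cell-type-specific coefficients (self-propulsion ``alpha``, viscosity
``nu``) are linearly interpolated between the pure-phase values via
``(1 + phi)/2`` weights.

Simulation units map to physical units through ``time_unit`` (minutes per
simulation time unit) and ``length_unit`` (micrometres per simulation
length unit); the default mapping is 10 min and 10 um, so one unit of
simulation velocity is 1 um/min.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelParams", "reference_params", "characteristic_scales", "to_physical"]

_POSITIVE = (
    "a",
    "K_phi",
    "a_p",
    "K_p",
    "M",
    "Gamma",
    "xi",
    "nu_A",
    "nu_B",
    "dt",
    "L",
    "time_unit",
    "length_unit",
)


@dataclass(frozen=True)
class ModelParams:
    """Coefficients of the binary active-polar mixture model.

    Defaults are the reference parameter set: cell type A self-propels
    twice as strongly and is half as viscous as type B, giving intrinsic
    migration speeds ``alpha/xi`` of 1.0 and 0.5 um/min.
    """

    a: float = 0.1          # phase double-well strength
    K_phi: float = 0.05     # phase gradient stiffness
    a_p: float = 0.1        # polar double-well strength
    K_p: float = 1.0        # polar alignment stiffness
    M: float = 10.0         # phase mobility
    Gamma: float = 5.0      # polarity relaxation rate
    kappa: float = 0.7      # flow-alignment parameter (dimensionless)
    alpha_A: float = 1.0    # self-propulsion, cell type A
    alpha_B: float = 0.5    # self-propulsion, cell type B
    nu_A: float = 5.0       # viscosity, cell type A
    nu_B: float = 10.0      # viscosity, cell type B
    xi: float = 1.0         # substrate friction
    p0: float = 1.0         # polar magnitude set-point
    time_unit: float = 10.0    # minutes per simulation time unit
    length_unit: float = 10.0  # micrometres per simulation length unit
    L: float = 50.0         # square domain side (simulation units)
    dt: float = 1.0e-2      # time step
    seed: int = 0

    def __post_init__(self):
        for name in _POSITIVE:
            val = getattr(self, name)
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"parameter {name!r} must be positive and finite")
        for name in ("alpha_A", "alpha_B"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"parameter {name!r} must be non-negative")
        if not np.isfinite(self.kappa):
            raise ValueError("kappa must be finite")

    # -- derived scales -------------------------------------------------
    @property
    def interface_width(self) -> float:
        """Phase interface width sqrt(K_phi / 2a) in simulation units."""
        return float(np.sqrt(self.K_phi / (2.0 * self.a)))

    @property
    def nu_mean(self) -> float:
        return 0.5 * (self.nu_A + self.nu_B)

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("parameter file must hold a flat mapping")
        return cls.from_dict(data)


def reference_params(**overrides) -> ModelParams:
    """The reference parameter preset (see module docstring for the units)."""
    return ModelParams(**overrides)


_UNIT_KINDS = ("length", "time", "velocity", "dimensionless")


def to_physical(value, kind: str, params: ModelParams):
    """Convert a simulation-units quantity to physical units.

    ``length`` -> um, ``time`` -> min, ``velocity`` -> um/min,
    ``dimensionless`` -> unchanged.
    """
    if kind == "length":
        return value * params.length_unit
    if kind == "time":
        return value * params.time_unit
    if kind == "velocity":
        return value * params.length_unit / params.time_unit
    if kind == "dimensionless":
        return value
    raise ValueError(f"unknown unit kind {kind!r}; expected one of {_UNIT_KINDS}")


def characteristic_scales(params: ModelParams) -> dict:
    """Closed-form characteristic scales of the model, in physical units.

    Returns intrinsic migration speeds ``alpha/xi`` (um/min), the phase
    interface width sqrt(K_phi/2a) (um), the phase relaxation time
    ``(M a)^-1`` and the polarity formation time ``(a_p Gamma)^-1`` (min),
    and the polar and velocity correlation lengths sqrt(K_p/2a_p),
    sqrt(nu/xi) (um).
    """
    return {
        "speed_A_um_per_min": to_physical(params.alpha_A / params.xi, "velocity", params),
        "speed_B_um_per_min": to_physical(params.alpha_B / params.xi, "velocity", params),
        "speed_ratio": params.alpha_A / params.alpha_B,
        "interface_width_um": to_physical(params.interface_width, "length", params),
        "phase_relaxation_min": to_physical(1.0 / (params.M * params.a), "time", params),
        "polarity_time_min": to_physical(1.0 / (params.a_p * params.Gamma), "time", params),
        "polar_correlation_um": to_physical(
            np.sqrt(params.K_p / (2.0 * params.a_p)), "length", params
        ),
        "velocity_correlation_um": to_physical(
            np.sqrt(params.nu_mean / params.xi), "length", params
        ),
    }
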