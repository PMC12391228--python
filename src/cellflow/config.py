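"""Run configuration: calibrated defaults, YAML loading, validation.

Every material parameter defaults to its calibrated value: membrane
persistence length p = 0.00141, membrane viscosity gamma = 4, cell
area/volume constraint constants 10,000 / 15,000 (nucleus 5,000 /
15,000), spring maximum lengths 3 (cell) and 1.2 (nucleus), equilibrium
length 0.5, bending stiffnesses 65 (cell) and 250 (nucleus),
nuclear-cytoplasmic ratio 0.29; cytoskeleton stiffness k_s = 120 with
the 5x nucleus rule (k_s_nuc = 600), damper k_v = 10 on both networks,
bond densities rho = 0.8, topology M2 with w = 5.

Loading an empty file therefore reproduces the calibrated model; any
override is applied on top, unknown keys are rejected by name, and the
nucleus spring stiffness follows the 5x rule automatically unless
explicitly overridden.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields

import yaml

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "MembraneSection", "CytoskeletonSection", "UnitsSection",
           "DpdSection", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Malformed configuration: unknown key, bad type, or bad value."""


@dataclass
class MembraneSection:
    persistence_length: float = 0.00141
    gamma: float = 4.0
    k_A: float = 10_000.0
    k_V: float = 15_000.0
    l_max: float = 3.0
    l_0: float = 0.5
    bending_stiffness: float = 65.0
    theta_0: float = 0.0

    def validate(self, path: str) -> None:
        if not (0 < self.l_0 < self.l_max):
            raise ConfigError(f"{path}: require 0 < l_0 < l_max")
        for name in ("persistence_length", "gamma", "k_A", "k_V",
                     "bending_stiffness"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{path}.{name}: must be non-negative")
        if self.persistence_length <= 0:
            raise ConfigError(f"{path}.persistence_length: must be positive")


def _nucleus_membrane_defaults() -> MembraneSection:
    return MembraneSection(k_A=5_000.0, l_max=1.2, bending_stiffness=250.0)


@dataclass
class CytoskeletonSection:
    k_s_cyt: float = 120.0
    k_s_nuc: float | None = None  # defaults to 5 * k_s_cyt
    k_v_cyt: float = 10.0
    k_v_nuc: float | None = None  # defaults to k_v_cyt
    rho_cyt: float = 0.8
    rho_nucl: float = 0.8
    topology: str = "M2"
    w: int = 5
    strain_based: bool = True

    def validate(self, path: str) -> None:
        if self.rho_cyt <= 0 or self.rho_nucl <= 0:
            raise ConfigError(f"{path}: bond densities must be positive")
        if self.k_s_cyt < 0 or self.k_v_cyt < 0:
            raise ConfigError(f"{path}: stiffness/viscosity must be non-negative")
        if self.topology not in ("M1", "M2"):
            raise ConfigError(f"{path}.topology: must be 'M1' or 'M2'")
        if self.w < 1:
            raise ConfigError(f"{path}.w: must be >= 1")

    def resolve(self) -> None:
        """Apply the 5x nucleus stiffness rule and shared damper default."""
        if self.k_s_nuc is None:
            self.k_s_nuc = 5.0 * self.k_s_cyt
        if self.k_v_nuc is None:
            self.k_v_nuc = self.k_v_cyt


@dataclass
class DpdSection:
    kBT: float = 0.1
    r_c: float = 1.0
    gamma_D: float = 4.5
    s: float = 0.75
    a_scale: float = 25.0  # conservative coefficient, units kBT / r_c
    dt: float = 0.005
    number_density: float = 3.0
    lam: float = 0.5  # velocity-prediction weight in modified velocity-Verlet

    def validate(self, path: str) -> None:
        if self.r_c <= 0 or self.dt <= 0 or self.s <= 0:
            raise ConfigError(f"{path}: r_c, dt and s must be positive")
        if self.kBT < 0 or self.gamma_D < 0:
            raise ConfigError(f"{path}: kBT and gamma_D must be non-negative")


@dataclass
class UnitsSection:
    """Mapping from simulation units to physical units.

    Nominal identity defaults; a full-resolution study calibrates these
    against the physical pipette geometry and fluid viscosity.
    """

    length_um: float = 1.0  # micrometres per simulation length unit
    pressure_pa: float = 1.0  # pascal per simulation pressure unit
    time_s: float = 1.0  # seconds per simulation time unit

    def validate(self, path: str) -> None:
        if min(self.length_um, self.pressure_pa, self.time_s) <= 0:
            raise ConfigError(f"{path}: unit scales must be positive")


@dataclass
class RunConfig:
    cell_membrane: MembraneSection = field(default_factory=MembraneSection)
    nucleus_membrane: MembraneSection = field(
        default_factory=_nucleus_membrane_defaults
    )
    cytoskeleton: CytoskeletonSection = field(default_factory=CytoskeletonSection)
    dpd: DpdSection = field(default_factory=DpdSection)
    units: UnitsSection = field(default_factory=UnitsSection)
    nc_ratio: float = 0.29
    diameter_um: float = 16.0
    seed: int = 0
    resolution: str = "scaled"
    output_dir: str = "out"
    schema: int = 1

    def validate(self) -> None:
        self.cell_membrane.validate("cell_membrane")
        self.nucleus_membrane.validate("nucleus_membrane")
        self.cytoskeleton.validate("cytoskeleton")
        self.dpd.validate("dpd")
        self.units.validate("units")
        if not (0.0 < self.nc_ratio < 1.0):
            raise ConfigError("nc_ratio: must lie in (0, 1)")
        if self.diameter_um <= 0:
            raise ConfigError("diameter_um: must be positive")
        if self.resolution not in ("scaled", "full"):
            raise ConfigError("resolution: must be 'scaled' or 'full'")

    # -- model construction --------------------------------------------
    def membrane_params(self, which: str, a_0: float, v_0: float):
        from .membrane import MembraneParams

        sec = self.cell_membrane if which == "cell" else self.nucleus_membrane
        return MembraneParams(
            p=sec.persistence_length, l_max=sec.l_max, l_0=sec.l_0,
            k_b=sec.bending_stiffness, k_a=sec.k_A, k_vol=sec.k_V,
            a_0=a_0, v_0=v_0, gamma=sec.gamma, kbt=self.dpd.kBT,
            theta_0=sec.theta_0,
        )

    def build_cell(self, diameter_um: float | None = None):
        from .builder import build_cell
        from .cytoskeleton import TopologySpec

        cyt = self.cytoskeleton
        cyt.resolve()
        cell = build_cell(
            diameter_um or self.diameter_um,
            self.nc_ratio,
            topology=TopologySpec(
                variant=cyt.topology, w=cyt.w, rho=cyt.rho_cyt, seed=self.seed
            ),
            k_s=cyt.k_s_cyt,
            k_v_damp=cyt.k_v_cyt,
            rho_nucl=cyt.rho_nucl,
            target_edge_length=self.cell_membrane.l_0,
            length_scale_um=self.units.length_um,
            kbt=self.dpd.kBT,
        )
        # honor explicit nucleus overrides of the 5x / shared-damper rules
        cell.cytoskeleton.k_s[:] = cyt.k_s_cyt
        cell.cytoskeleton.k_v_damp[:] = cyt.k_v_cyt
        cell.nucleus_bonds.k_s[:] = cyt.k_s_nuc
        cell.nucleus_bonds.k_v_damp[:] = cyt.k_v_nuc
        cell.outer_params = self.membrane_params(
            "cell", cell.outer.area(), cell.outer.volume()
        )
        cell.nucleus_params = self.membrane_params(
            "nucleus", cell.nucleus.area(), cell.nucleus.volume()
        )
        return cell


def _apply(obj, data: dict, path: str) -> None:
    valid = {f.name: f for f in fields(obj)}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown configuration key: {path}{key}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _apply(current, value, f"{path}{key}.")
        else:
            if isinstance(value, dict):
                raise ConfigError(f"{path}{key}: scalar expected, got a mapping")
            if isinstance(current, bool) and not isinstance(value, bool):
                raise ConfigError(f"{path}{key}: boolean expected")
            if isinstance(current, (int, float)) and not isinstance(
                value, (int, float)
            ):
                raise ConfigError(f"{path}{key}: number expected, got {value!r}")
            setattr(obj, key, value)
            logger.info("config override %s%s = %r", path, key, value)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; defaults are the calibrated tables.

    An empty file yields all defaults.  Unknown keys raise
    :class:`ConfigError` naming the key; the 5x nucleus stiffness rule
    fires unless ``cytoskeleton.k_s_nuc`` is given explicitly.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    cfg = RunConfig()
    _apply(cfg, data, "")
    cfg.cytoskeleton.resolve()
    cfg.validate()
    logger.info("resolved configuration: %s", dataclasses.asdict(cfg))
    return cfg
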