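"""Physical parameter containers for the microbubble system.

All quantities are strict SI internally (m, s, Pa, kg). Convenience
constructors and the YAML config layer accept the field-customary units
(kPa, MHz, micrometres) and convert at the boundary; unit-annotated key
names (``pnp_kpa``, ``radius_um``) make the convention explicit in config
files.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "GasProperties",
    "MediumProperties",
    "ShellProperties",
    "AcousticDrive",
    "BubbleSystem",
    "RegimeThresholds",
    "load_config",
    "dump_config",
    "default_system",
    "default_drive",
    "config_hash",
]


@dataclass(frozen=True)
class GasProperties:
    """Gas-core properties.

    The default polytropic exponent 1.07 corresponds to quasi-adiabatic
    behaviour of perfluorobutane (C4F10) at these drive amplitudes; full
    thermal modelling is out of scope.
    """

    polytropic_exponent: float = 1.07
    vapor_pressure: float = 0.0  # Pa

    def __post_init__(self) -> None:
        if self.polytropic_exponent < 1.0:
            raise ValueError("polytropic_exponent must be >= 1")
        if self.vapor_pressure < 0.0:
            raise ValueError("vapor_pressure must be >= 0")


@dataclass(frozen=True)
class MediumProperties:
    """Bulk liquid surrounding the bubble (water-like buffer)."""

    density: float = 1000.0  # kg/m^3
    dynamic_viscosity: float = 1.0e-3  # Pa s
    sound_speed: float = 1500.0  # m/s
    ambient_pressure: float = 101325.0  # Pa
    water_surface_tension: float = 0.073  # N/m

    def __post_init__(self) -> None:
        for name in (
            "density",
            "dynamic_viscosity",
            "sound_speed",
            "ambient_pressure",
            "water_surface_tension",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ShellProperties:
    """Lipid monolayer shell: elastic modulus chi, dilatational surface
    viscosity kappa_s, and the surface tension of the shell at rest.

    The buckling radius is not an independent parameter here: it is derived
    from the resting radius so that the elastic branch of the surface-tension
    law evaluates to ``initial_surface_tension`` at rest (see
    :func:`sonokit.bubble_dynamics.surface_tension`).
    """

    elastic_modulus_chi: float  # N/m
    surface_viscosity_kappa_s: float  # kg/s
    initial_surface_tension: float = 0.02  # N/m

    def __post_init__(self) -> None:
        if self.elastic_modulus_chi <= 0.0:
            raise ValueError("elastic_modulus_chi must be > 0")
        if self.surface_viscosity_kappa_s < 0.0:
            raise ValueError("surface_viscosity_kappa_s must be >= 0")
        if self.initial_surface_tension < 0.0:
            raise ValueError("initial_surface_tension must be >= 0")

    def buckling_radius(self, resting_radius: float) -> float:
        """Radius below which the monolayer buckles and tension vanishes."""
        return resting_radius / math.sqrt(
            1.0 + self.initial_surface_tension / self.elastic_modulus_chi
        )

    def rupture_radius(self, resting_radius: float, water_surface_tension: float) -> float:
        """Radius above which the shell has ruptured and the interface
        behaves like a clean gas-water interface."""
        return self.buckling_radius(resting_radius) * math.sqrt(
            1.0 + water_surface_tension / self.elastic_modulus_chi
        )


@dataclass(frozen=True)
class AcousticDrive:
    """Sinusoidal insonation burst, rarefaction-first phase convention:
    p(t) = -PNP sin(2 pi f t) for the first ``n_cycles`` periods, 0 after."""

    center_frequency: float = 250e3  # Hz
    peak_negative_pressure: float = 0.0  # Pa
    n_cycles: int = 50
    envelope: str = "rectangular"  # rectangular | ramped

    def __post_init__(self) -> None:
        if self.center_frequency <= 0.0:
            raise ValueError("center_frequency must be > 0")
        if self.peak_negative_pressure < 0.0:
            raise ValueError("peak_negative_pressure must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.envelope not in ("rectangular", "ramped"):
            raise ValueError("envelope must be 'rectangular' or 'ramped'")

    @property
    def period(self) -> float:
        return 1.0 / self.center_frequency

    @property
    def duration(self) -> float:
        return self.n_cycles * self.period


@dataclass(frozen=True)
class BubbleSystem:
    """A bubble, its shell and gas core, and the surrounding medium.

    The equilibrium gas pressure follows from mechanical balance at rest:
    ``P_g0 = P_ambient + 2 sigma(R0)/R0 - P_vapor``.
    """

    resting_radius: float = 0.75e-6  # m (1.5 um diameter)
    gas: GasProperties = field(default_factory=GasProperties)
    medium: MediumProperties = field(default_factory=MediumProperties)
    shell: ShellProperties = field(
        default_factory=lambda: ShellProperties(
            elastic_modulus_chi=0.07, surface_viscosity_kappa_s=1.5e-9
        )
    )

    def __post_init__(self) -> None:
        if self.resting_radius <= 0.0:
            raise ValueError("resting_radius must be > 0")
        if self.shell.initial_surface_tension > self.medium.water_surface_tension:
            raise ValueError(
                "initial_surface_tension cannot exceed the clean-interface value"
            )

    @property
    def buckling_radius(self) -> float:
        return self.shell.buckling_radius(self.resting_radius)

    @property
    def rupture_radius(self) -> float:
        return self.shell.rupture_radius(
            self.resting_radius, self.medium.water_surface_tension
        )

    @property
    def equilibrium_gas_pressure(self) -> float:
        return (
            self.medium.ambient_pressure
            + 2.0 * self.shell.initial_surface_tension / self.resting_radius
            - self.gas.vapor_pressure
        )


@dataclass(frozen=True)
class RegimeThresholds:
    """Expansion-ratio bands used to classify the cavitation regime:
    below ``stable_lower`` oscillations are negligible, between the two
    thresholds cavitation is stable, above ``inertial_onset`` inertial."""

    stable_lower: float = 1.1
    inertial_onset: float = 3.5

    def __post_init__(self) -> None:
        if not (1.0 < self.stable_lower < self.inertial_onset):
            raise ValueError("require 1 < stable_lower < inertial_onset")


# ---------------------------------------------------------------------------
# YAML config layer


def _system_to_dict(system: BubbleSystem) -> dict:
    return {
        "bubble": {"resting_radius_um": system.resting_radius * 1e6},
        "gas": {
            "polytropic_exponent": system.gas.polytropic_exponent,
            "vapor_pressure_pa": system.gas.vapor_pressure,
        },
        "medium": {
            "density_kg_m3": system.medium.density,
            "dynamic_viscosity_pa_s": system.medium.dynamic_viscosity,
            "sound_speed_m_s": system.medium.sound_speed,
            "ambient_pressure_kpa": system.medium.ambient_pressure / 1e3,
            "water_surface_tension_n_m": system.medium.water_surface_tension,
        },
        "shell": {
            "elastic_modulus_chi_n_m": system.shell.elastic_modulus_chi,
            "surface_viscosity_kappa_s_kg_s": system.shell.surface_viscosity_kappa_s,
            "initial_surface_tension_n_m": system.shell.initial_surface_tension,
        },
    }


def _drive_to_dict(drive: AcousticDrive) -> dict:
    return {
        "drive": {
            "center_frequency_mhz": drive.center_frequency / 1e6,
            "pnp_kpa": drive.peak_negative_pressure / 1e3,
            "n_cycles": drive.n_cycles,
            "envelope": drive.envelope,
        }
    }


def dump_config(
    path: str | Path,
    system: BubbleSystem,
    drive: Optional[AcousticDrive] = None,
    thresholds: Optional[RegimeThresholds] = None,
) -> None:
    """Write a bubble/drive configuration to a YAML file."""
    data = _system_to_dict(system)
    data.update(_drive_to_dict(drive or AcousticDrive()))
    th = thresholds or RegimeThresholds()
    data["thresholds"] = {
        "stable_lower": th.stable_lower,
        "inertial_onset": th.inertial_onset,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _parse_config(data: dict) -> tuple[BubbleSystem, AcousticDrive, RegimeThresholds]:
    gas = data.get("gas", {})
    med = data.get("medium", {})
    sh = data.get("shell", {})
    bub = data.get("bubble", {})
    drv = data.get("drive", {})
    th = data.get("thresholds", {})
    system = BubbleSystem(
        resting_radius=bub.get("resting_radius_um", 0.75) * 1e-6,
        gas=GasProperties(
            polytropic_exponent=gas.get("polytropic_exponent", 1.07),
            vapor_pressure=gas.get("vapor_pressure_pa", 0.0),
        ),
        medium=MediumProperties(
            density=med.get("density_kg_m3", 1000.0),
            dynamic_viscosity=med.get("dynamic_viscosity_pa_s", 1.0e-3),
            sound_speed=med.get("sound_speed_m_s", 1500.0),
            ambient_pressure=med.get("ambient_pressure_kpa", 101.325) * 1e3,
            water_surface_tension=med.get("water_surface_tension_n_m", 0.073),
        ),
        shell=ShellProperties(
            elastic_modulus_chi=sh["elastic_modulus_chi_n_m"],
            surface_viscosity_kappa_s=sh["surface_viscosity_kappa_s_kg_s"],
            initial_surface_tension=sh.get("initial_surface_tension_n_m", 0.02),
        ),
    )
    drive = AcousticDrive(
        center_frequency=drv.get("center_frequency_mhz", 0.25) * 1e6,
        peak_negative_pressure=drv.get("pnp_kpa", 0.0) * 1e3,
        n_cycles=drv.get("n_cycles", 50),
        envelope=drv.get("envelope", "rectangular"),
    )
    thresholds = RegimeThresholds(
        stable_lower=th.get("stable_lower", 1.1),
        inertial_onset=th.get("inertial_onset", 3.5),
    )
    return system, drive, thresholds


def load_config(path: str | Path) -> tuple[BubbleSystem, AcousticDrive, RegimeThresholds]:
    """Load system, drive and thresholds from a YAML config file."""
    data = yaml.safe_load(Path(path).read_text())
    return _parse_config(data)


def _default_config_text() -> str:
    return (
        resources.files("sonokit.data").joinpath("default_bubble.yaml").read_text()
    )


def default_system() -> BubbleSystem:
    """The frozen default parameter set shipped with the package
    (``sonokit/data/default_bubble.yaml``)."""
    system, _, _ = _parse_config(yaml.safe_load(_default_config_text()))
    return system


def default_drive(peak_negative_pressure: float = 0.0) -> AcousticDrive:
    """Default drive (250 kHz, 50 cycles, rectangular) at the given PNP in Pa."""
    _, drive, _ = _parse_config(yaml.safe_load(_default_config_text()))
    return AcousticDrive(
        center_frequency=drive.center_frequency,
        peak_negative_pressure=peak_negative_pressure,
        n_cycles=drive.n_cycles,
        envelope=drive.envelope,
    )


def config_hash(system: BubbleSystem, drive: Optional[AcousticDrive] = None) -> str:
    """Short stable hash of a parameter set, for run logging."""
    payload = {"system": asdict(system)}
    if drive is not None:
        payload["drive"] = asdict(drive)
    text = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
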