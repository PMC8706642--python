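"""Structured configuration for the granulation simulator.

All quantities are SI internally (m, m3, s, kg, Pa.s, N/m).  The YAML
front-end accepts lengths in micrometres for the fields that end in
``_um`` and converts on load.

The default values describe a desk-scale high-shear wet granulation of a
bi-component blend (a hydrophobic API plus micro-crystalline cellulose)
with an aqueous binder: 1 kg powder charge, 0.6 liquid-to-solid ratio,
monodisperse 200 um spray drops, and the published optimized rate
constants.  The published rate constants are printed without units; each
carries a fixed per-mechanism unit convention here and is stored in SI
(see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Invalid or inconsistent configuration."""


@dataclass
class MaterialSet:
    """Physical constants of the two solids, the binder, and model cutoffs.

    ``f1`` is the API mass fraction of the formulation (the powder blend
    charged to the granulator).
    """

    rho_s1: float = 1030.0      # API true density, kg/m3 (ibuprofen)
    rho_s2: float = 1550.0      # excipient true density, kg/m3 (MCC)
    e_s1: float = 0.162         # API coefficient of restitution
    e_s2: float = 0.07          # excipient coefficient of restitution
    mu: float = 1.0e-3          # binder viscosity, Pa.s (water)
    sigma: float = 0.07         # binder surface tension, N/m
    rho_l: float = 1000.0       # binder density, kg/m3
    d_p: float = 25e-6          # API primary particle diameter, m
    d_p2: float = 75e-6         # excipient primary particle diameter, m
    f1: float = 0.5             # API mass fraction of the formulation
    phi_cp: float = 0.2         # critical-packing liquid volume fraction
    eps_min: float = 0.05       # minimum (fully consolidated) porosity
    h_a: float = 1.0e-6         # surface asperity height, m

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_cp < 1.0:
            raise ConfigError(f"phi_cp must lie in (0, 1), got {self.phi_cp}")
        for name in ("e_s1", "e_s2"):
            e = getattr(self, name)
            if not 0.0 <= e <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {e}")
        if not 0.0 < self.f1 < 1.0:
            raise ConfigError(f"f1 must lie in (0, 1), got {self.f1}")
        for name in ("rho_s1", "rho_s2", "rho_l", "mu", "sigma", "d_p", "d_p2", "h_a"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 < self.eps_min < 1.0:
            raise ConfigError(f"eps_min must lie in (0, 1), got {self.eps_min}")

    @property
    def f1_volume(self) -> float:
        """Blend API fraction on a solid-volume basis."""
        v1 = self.f1 / self.rho_s1
        v2 = (1.0 - self.f1) / self.rho_s2
        return v1 / (v1 + v2)


@dataclass
class ProcessConditions:
    """Operating conditions of the granulator."""

    q_spray: float = 1.5e-5     # volumetric binder spray rate, m3/s
    d_d: float = 200e-6         # spray drop diameter, m
    ls_ratio: float = 0.6       # liquid-to-solid mass ratio
    gamma: float = 1000.0       # characteristic shear rate, 1/s
    phi_p: float = 0.3          # particle volume fraction in the granulator
    t_end: float = 60.0         # total simulated time, s
    charge_mass: float = 1.0    # initial powder charge, kg
    f_bed: Optional[float] = None  # fixed spray fraction hitting powder; None = bed-mass fraction

    def __post_init__(self) -> None:
        if self.f_bed is not None and not 0.0 <= self.f_bed <= 1.0:
            raise ConfigError("f_bed must lie in [0, 1]")
        for name in ("q_spray", "d_d", "gamma", "t_end", "charge_mass"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.ls_ratio < 0:
            raise ConfigError("ls_ratio must be non-negative")
        if not 0.0 < self.phi_p < 1.0:
            raise ConfigError(f"phi_p must lie in (0, 1), got {self.phi_p}")

    @property
    def v_d(self) -> float:
        """Volume of a single spray drop, m3."""
        return math.pi / 6.0 * self.d_d ** 3

    def spray_duration(self, rho_l: float) -> float:
        """Time to deliver the full binder charge, s."""
        return self.ls_ratio * self.charge_mass / (rho_l * self.q_spray)

    def binder_volume(self, rho_l: float) -> float:
        """Total binder volume to be sprayed, m3."""
        return self.ls_ratio * self.charge_mass / rho_l

    def validate_against(self, materials: MaterialSet) -> None:
        if self.spray_duration(materials.rho_l) > self.t_end + 1e-12:
            raise ConfigError(
                "spray duration {:.3g} s exceeds t_end {:.3g} s".format(
                    self.spray_duration(materials.rho_l), self.t_end
                )
            )


@dataclass
class RateConstants:
    """Tunable kinetic constants (the six calibrated parameters).

    The literature prints these numerals without units; each constant is
    given a fixed per-mechanism unit convention here (beta0 1/s per pair
    count; k_con per cm; k_layer per mm^2 per s; k_sg cm/s) and stored in
    SI.  See docs/methods.md for the reasoning.
    """

    beta0: float = 4.34e-10     # aggregation rate prefactor, 1/s per pair count
    k_con: float = 0.167        # consolidation constant, 1/m (1.67e-3 cm^-1)
    k_layer: float = 2.01e-2    # layering constant, 1/(m2 s) (2.01e-8 mm^-2 s^-1)
    k_sg: float = 4.59e-13      # surface growth constant, m/s (4.59e-11 cm/s)

    def __post_init__(self) -> None:
        for name in ("beta0", "k_con", "k_layer", "k_sg"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class KernelOptions:
    """Configuration of the collision-efficiency kernel.

    ``ca_anchors`` are (API solid-volume fraction, capillary number) pairs
    through which the log-linear capillary-number regression passes; the
    capillary number scales the capillary work relative to the viscous
    (dissipative) work of the bridge.
    """

    ca_anchors: tuple = ((0.4, 1.0), (0.6, 3.0))
    efficiency_mode: str = "physical"   # "physical" | "unit" (beta* forced to 1)
    theta_prefactor: float = 5.0 * math.pi / 96.0

    def __post_init__(self) -> None:
        if self.efficiency_mode not in ("physical", "unit"):
            raise ConfigError(f"unknown efficiency_mode {self.efficiency_mode!r}")
        if len(self.ca_anchors) != 2:
            raise ConfigError("ca_anchors must hold exactly two (f, Ca) pairs")
        for f, ca in self.ca_anchors:
            if ca <= 0:
                raise ConfigError("capillary-number anchors must be positive")


@dataclass
class BreakageOptions:
    """Shear-driven binary breakage (default off)."""

    enabled: bool = False
    p_brk: float = 0.0          # rate prefactor, 1/m/... (K = p_brk * gamma * d^n)
    size_exponent: float = 1.0
    daughter_theta: float = 0.5  # volume fraction of the first daughter

    def __post_init__(self) -> None:
        if self.p_brk < 0:
            raise ConfigError("p_brk must be non-negative")
        if not 0.0 < self.daughter_theta < 1.0:
            raise ConfigError("daughter_theta must lie in (0, 1)")


@dataclass
class NucleationOptions:
    """Choice of the immersion-nucleation probability provider."""

    mode: str = "logistic"          # "constant" | "logistic" | "table"
    constant: float = 1.0
    anchors: tuple = ((0.5, 0.67), (0.6, 0.33))
    table: Optional[tuple] = None   # ((f1, P_im), ...) for linear interpolation

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "logistic", "table"):
            raise ConfigError(f"unknown nucleation mode {self.mode!r}")


@dataclass
class NumericsOptions:
    """Grid and time-stepping controls."""

    d_min: float = 31.5e-6      # smallest representative diameter, m
    d_max: float = 6000e-6      # largest representative diameter, m
    n_bins: int = 12            # bins per internal coordinate
    ratio_mode: str = "fit_span"  # "fit_span" | "fixed_ratio_4"
    dt_max: float = 0.1         # s
    dt_min: float = 1.0e-5      # s
    safety: float = 0.5         # CFL safety factor
    growth_limit: float = 0.2   # max relative coordinate drift per step
    record_interval: float = 1.0  # s between recorded snapshots
    pair_threshold: float = 1.0e-6  # cells below this fraction of N skip pairing

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ConfigError("n_bins must be at least 2")
        if self.ratio_mode not in ("fit_span", "fixed_ratio_4"):
            raise ConfigError(f"unknown ratio_mode {self.ratio_mode!r}")
        if not 0 < self.safety <= 1:
            raise ConfigError("safety must lie in (0, 1]")
        if self.d_min <= 0 or self.d_max <= self.d_min:
            raise ConfigError("require 0 < d_min < d_max")


@dataclass
class SimulationConfig:
    """Complete description of one simulation run."""

    materials: MaterialSet = field(default_factory=MaterialSet)
    process: ProcessConditions = field(default_factory=ProcessConditions)
    rates: RateConstants = field(default_factory=RateConstants)
    kernel: KernelOptions = field(default_factory=KernelOptions)
    breakage: BreakageOptions = field(default_factory=BreakageOptions)
    nucleation: NucleationOptions = field(default_factory=NucleationOptions)
    numerics: NumericsOptions = field(default_factory=NumericsOptions)

    def validate(self) -> "SimulationConfig":
        self.process.validate_against(self.materials)
        return self

    def replace(self, **groups) -> "SimulationConfig":
        """Return a deep copy with selected sub-group fields overridden.

        ``groups`` maps group name to a dict of field overrides, e.g.
        ``cfg.replace(rates={"beta0": 5e-10})``.
        """
        out = {}
        for name in ("materials", "process", "rates", "kernel", "breakage",
                     "nucleation", "numerics"):
            group = getattr(self, name)
            over = groups.pop(name, None)
            out[name] = dataclasses.replace(group, **over) if over else dataclasses.replace(group)
        if groups:
            raise ConfigError(f"unknown config groups {sorted(groups)}")
        return SimulationConfig(**out)


_UM_FIELDS = {"d_p", "d_p2", "h_a", "d_d", "d_min", "d_max"}
_GROUP_TYPES = {
    "materials": MaterialSet,
    "process": ProcessConditions,
    "rates": RateConstants,
    "kernel": KernelOptions,
    "breakage": BreakageOptions,
    "nucleation": NucleationOptions,
    "numerics": NumericsOptions,
}


def _coerce_group(cls, data: dict):
    kwargs = {}
    for key, value in data.items():
        if key.endswith("_um"):
            base = key[:-3]
            if base not in _UM_FIELDS:
                raise ConfigError(f"field {key!r} does not accept micrometres")
            kwargs[base] = float(value) * 1e-6
        else:
            if isinstance(value, list):
                value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    groups = {}
    for name, data in raw.items():
        if name not in _GROUP_TYPES:
            raise ConfigError(f"unknown config section {name!r}")
        groups[name] = _coerce_group(_GROUP_TYPES[name], data or {})
    return SimulationConfig(**groups).validate()


def dump_config(config: SimulationConfig, path) -> None:
    """Write a config back to YAML (SI units throughout)."""
    raw = {name: dataclasses.asdict(getattr(config, name)) for name in _GROUP_TYPES}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
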