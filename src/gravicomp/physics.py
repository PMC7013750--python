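"""Mechanical environment of a suspended cell in a 2D clinostat.

A fast 2D clinostat rotates a liquid-filled pipette about one horizontal
axis (here 60 rpm, i.e. omega = 2*pi rad/s, on a circle of radius 1.5 mm).
The medium undergoes solid-body rotation and a suspended cell essentially
co-rotates on its circle: at the particle scale the shear Reynolds number is
of order 1e-4 and the fractional particle/fluid spin lag is negligible, so
the spiralling inertial drift over a 5-minute run does not measurably
deviate from circular motion. This module computes, in SI units throughout,
the quantities that characterise what such a cell actually feels:

* the residual centrifugal acceleration (as a multiple of g),
* the weight force and its peak-to-peak variation in the rotating frame,
* the hydrostatic pressure cycle over one revolution,
* the maximum surface shear stress from Stokes sedimentation,
* the Coriolis force, the particle spin ratio and dimensionless numbers,
* the assembled per-revolution force/pressure cycle.

Cell density and medium viscosity are literature ranges, represented as
(low, high) pairs; single-valued operations default to the midpoint unless
an explicit value is passed (e.g. the upper density bound 1.12 g/mL
maximises the weight-variation figure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "ValueRange",
    "ParticleParams",
    "FluidParams",
    "RotorParams",
    "ForceCycle",
    "centrifugal_acceleration_g",
    "particle_mass",
    "weight_force",
    "weight_variation_peak_to_peak",
    "hydrostatic_pressure_cycle",
    "hydrostatic_pressure_mean",
    "hydrostatic_pressure_range",
    "stokes_terminal_velocity",
    "sedimentation_shear_stress",
    "particle_spin_ratio",
    "taylor_number",
    "shear_reynolds",
    "coriolis_force",
    "force_cycle",
    "physics_report",
    "STANDARD_GRAVITY",
]

STANDARD_GRAVITY = 9.81  # m/s^2


class ValueRange(NamedTuple):
    """A (low, high) literature range with midpoint default."""

    low: float
    high: float

    @property
    def mid(self) -> float:
        return 0.5 * (self.low + self.high)


@dataclass(frozen=True)
class ParticleParams:
    """Suspended cell modelled as a rigid sphere.

    Defaults are the Jurkat T-cell values: radius 5.75 um and density
    1.05-1.12 g/mL.
    """

    radius: float = 5.75e-6  # m
    density: ValueRange = ValueRange(1050.0, 1120.0)  # kg/m^3

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("particle radius must be positive")
        if self.density.low <= 0 or self.density.high < self.density.low:
            raise ValueError("invalid particle density range")


@dataclass(frozen=True)
class FluidParams:
    """Culture medium: density 1.00 g/mL, viscosity 1.09-1.14 mPa s."""

    density: float = 1000.0  # kg/m^3
    viscosity: ValueRange = ValueRange(1.09e-3, 1.14e-3)  # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("fluid density must be positive")
        if self.viscosity.low <= 0 or self.viscosity.high < self.viscosity.low:
            raise ValueError("invalid viscosity range")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity.mid / self.density  # m^2/s


@dataclass(frozen=True)
class RotorParams:
    """Rotation geometry. Clinostat defaults: R = 1.5 mm, omega = 2*pi rad/s."""

    radius: float = 1.5e-3  # m
    omega: float = 2.0 * math.pi  # rad/s
    g: float = STANDARD_GRAVITY  # m/s^2

    def __post_init__(self) -> None:
        if self.radius < 0 or self.omega < 0:
            raise ValueError("rotor radius and omega must be non-negative")

    @property
    def period(self) -> float:
        if self.omega == 0:
            raise ValueError("period undefined for omega = 0")
        return 2.0 * math.pi / self.omega


@dataclass(frozen=True)
class ForceCycle:
    """Sampled forces and pressure over one revolution (rotating frame).

    ``gravity`` holds the two in-plane components of the weight vector,
    which rotates at -omega in the co-rotating frame; ``centrifugal`` is the
    constant outward vector; ``pressure`` is hydrostatic pressure relative
    to the top of the circular path.
    """

    time: np.ndarray = field(repr=False)
    gravity: np.ndarray = field(repr=False)      # (n, 2), N
    centrifugal: np.ndarray = field(repr=False)  # (n, 2), N
    pressure: np.ndarray = field(repr=False)     # (n,), Pa
    mass: float = 0.0                            # kg
    period: float = 0.0                          # s


def centrifugal_acceleration_g(
    radius: float, omega: float, g: float = STANDARD_GRAVITY
) -> float:
    """Centrifugal acceleration omega^2 * R as a multiple of g."""
    if radius < 0 or omega < 0:
        raise ValueError("radius and omega must be non-negative")
    return omega**2 * radius / g


def particle_mass(particle: ParticleParams, density: float | None = None) -> float:
    """Sphere mass rho_c * (4/3) * pi * r^3 (midpoint density by default)."""
    rho = particle.density.mid if density is None else density
    return rho * (4.0 / 3.0) * math.pi * particle.radius**3


def weight_force(
    particle: ParticleParams,
    g: float = STANDARD_GRAVITY,
    density: float | None = None,
) -> float:
    """Weight F = m g of the particle, in newtons."""
    return particle_mass(particle, density) * g


def weight_variation_peak_to_peak(
    particle: ParticleParams,
    g: float = STANDARD_GRAVITY,
    density: float | None = None,
) -> float:
    """Peak-to-peak swing of the rotating-frame vertical weight component.

    Over one revolution the weight vector's component along any co-rotating
    axis oscillates between +mg and -mg, a swing of 2 m g. With the upper
    Jurkat density bound (1.12 g/mL) this evaluates to 17.5e-12 N.
    """
    return 2.0 * weight_force(particle, g, density)


def hydrostatic_pressure_cycle(
    rotor: RotorParams, fluid: FluidParams, phase: np.ndarray
) -> np.ndarray:
    """Hydrostatic pressure (Pa) at phase angles along the circular path.

    Pressure is referenced to the top of the path: p(theta) =
    rho_f * g * R * (1 - cos theta), theta = 0 at the top. The period mean
    is rho_f * g * R and the top-to-bottom range 2 * rho_f * g * R — with
    clinostat defaults 14.7 Pa and 29.4 Pa respectively.
    """
    theta = np.asarray(phase, dtype=float)
    return fluid.density * rotor.g * rotor.radius * (1.0 - np.cos(theta))


def hydrostatic_pressure_mean(rotor: RotorParams, fluid: FluidParams) -> float:
    """Closed-form period mean rho_f * g * R of the pressure cycle."""
    return fluid.density * rotor.g * rotor.radius


def hydrostatic_pressure_range(rotor: RotorParams, fluid: FluidParams) -> float:
    """Closed-form top-to-bottom pressure difference 2 * rho_f * g * R."""
    return 2.0 * fluid.density * rotor.g * rotor.radius


def stokes_terminal_velocity(
    particle: ParticleParams,
    fluid: FluidParams,
    acceleration: float = STANDARD_GRAVITY,
    density: float | None = None,
    viscosity: float | None = None,
) -> float:
    """Stokes terminal sedimentation velocity v = 2 r^2 (rho_c - rho_f) a / (9 mu)."""
    rho_c = particle.density.high if density is None else density
    mu = fluid.viscosity.mid if viscosity is None else viscosity
    if rho_c < fluid.density:
        raise ValueError("buoyant particle (rho_c < rho_f) is out of scope")
    return 2.0 * particle.radius**2 * (rho_c - fluid.density) * acceleration / (9.0 * mu)


def sedimentation_shear_stress(
    particle: ParticleParams,
    fluid: FluidParams,
    acceleration: float = STANDARD_GRAVITY,
    density: float | None = None,
    viscosity: float | None = None,
) -> float:
    """Maximum surface shear stress of a sphere sedimenting at Stokes speed.

    Computed as 3 mu v / (2 r) with v the Stokes terminal velocity; the
    viscosity cancels, leaving the closed form r (rho_c - rho_f) a / 3.
    With Jurkat parameters at 1 g this is 2.3 mPa. Uses the upper density
    bound by default (maximum stress), as for the weight variation.
    """
    mu = fluid.viscosity.mid if viscosity is None else viscosity
    v = stokes_terminal_velocity(particle, fluid, acceleration, density, mu)
    return 3.0 * mu * v / (2.0 * particle.radius)


def particle_spin_ratio(taylor: float) -> float:
    """Particle-to-fluid angular velocity ratio 1 - 0.3076 * Ta^(3/2).

    For the Taylor numbers of a cell-scale clinostat the ratio is
    indistinguishable from 1: the particle spins with the fluid.
    """
    if taylor < 0:
        raise ValueError("Taylor number must be non-negative")
    return 1.0 - 0.3076 * taylor**1.5


def taylor_number(
    particle: ParticleParams, rotor: RotorParams, fluid: FluidParams
) -> float:
    """Particle-scale rotational Taylor number, kinematic form r^2 omega / nu.

    Implemented as r^2 * omega * rho_f / mu, the dimensionless reading of
    the quantity (numerically identical to the shear Reynolds number for
    this flow); about 1.9e-4 for clinostat defaults.
    """
    return particle.radius**2 * rotor.omega * fluid.density / fluid.viscosity.mid


def shear_reynolds(
    particle: ParticleParams, rotor: RotorParams, fluid: FluidParams
) -> float:
    """Shear Reynolds number Re_s = r^2 omega / nu; order 1e-4 at defaults."""
    return particle.radius**2 * rotor.omega / fluid.kinematic_viscosity


def coriolis_force(
    mass: float, omega_vec: np.ndarray, velocity: np.ndarray
) -> np.ndarray:
    """Coriolis force -2 m (omega x v) on a particle in the rotating frame."""
    return -2.0 * mass * np.cross(np.asarray(omega_vec, float), np.asarray(velocity, float))


def force_cycle(
    particle: ParticleParams,
    fluid: FluidParams,
    rotor: RotorParams,
    n_steps: int = 360,
    density: float | None = None,
) -> ForceCycle:
    """Assemble the rotating-frame force/pressure description of one revolution.

    The weight vector rotates at -omega in the co-rotating frame (null
    average over a period); the centrifugal vector m omega^2 R points
    radially outward with constant magnitude; the pressure follows
    :func:`hydrostatic_pressure_cycle`. ``n_steps`` uniform samples cover
    [0, T) so periodic averages are exact to quadrature accuracy.
    """
    if n_steps < 4:
        raise ValueError("need at least 4 steps per revolution")
    m = particle_mass(particle, density)
    period = rotor.period
    t = np.arange(n_steps) / n_steps * period
    theta = rotor.omega * t
    # lab gravity (0, -g) seen from a frame rotating at +omega
    gravity = m * rotor.g * np.column_stack([-np.sin(theta), -np.cos(theta)])
    f_c = m * rotor.omega**2 * rotor.radius
    centrifugal = np.column_stack([np.full(n_steps, f_c), np.zeros(n_steps)])
    pressure = hydrostatic_pressure_cycle(rotor, fluid, theta)
    return ForceCycle(
        time=t,
        gravity=gravity,
        centrifugal=centrifugal,
        pressure=pressure,
        mass=m,
        period=period,
    )


def physics_report(
    particle: ParticleParams | None = None,
    fluid: FluidParams | None = None,
    rotor: RotorParams | None = None,
    n_steps: int = 360,
) -> dict:
    """All scalar quantities of the clinostat environment, with units."""
    particle = particle or ParticleParams()
    fluid = fluid or FluidParams()
    rotor = rotor or RotorParams()
    cycle = force_cycle(particle, fluid, rotor, n_steps)
    return {
        "centrifugal_acceleration_g": {
            "value": centrifugal_acceleration_g(rotor.radius, rotor.omega, rotor.g),
            "units": "xg",
        },
        "weight_force_N": {
            "value": weight_force(particle, rotor.g, particle.density.high),
            "units": "N",
        },
        "weight_variation_peak_to_peak_N": {
            "value": weight_variation_peak_to_peak(
                particle, rotor.g, particle.density.high
            ),
            "units": "N",
        },
        "hydrostatic_pressure_mean_Pa": {
            "value": float(cycle.pressure.mean()),
            "units": "Pa",
        },
        "hydrostatic_pressure_range_Pa": {
            "value": float(cycle.pressure.max() - cycle.pressure.min()),
            "units": "Pa",
        },
        "sedimentation_shear_stress_Pa": {
            "value": sedimentation_shear_stress(particle, fluid, rotor.g),
            "units": "Pa",
        },
        "shear_reynolds": {
            "value": shear_reynolds(particle, rotor, fluid),
            "units": "dimensionless",
        },
        "taylor_number": {
            "value": taylor_number(particle, rotor, fluid),
            "units": "dimensionless",
        },
        "particle_spin_ratio": {
            "value": particle_spin_ratio(taylor_number(particle, rotor, fluid)),
            "units": "dimensionless",
        },
    }
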