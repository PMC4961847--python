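"""Mass-transport diagnostics: is the assay reaction-limited?

The observed-rate analysis assumes surface binding, not analyte delivery,
controls the signal.  This module quantifies that assumption with the
standard microfluidic-biosensor scaling analysis:

* nanoparticle diffusivity from Stokes--Einstein,
  D = k_B T / (3 pi eta d_h);
* channel Peclet number Pe_H = Q / (D W_c) (convection vs diffusion over
  the channel height);
* shear Peclet number Pe_s = 6 (L/H)^2 Pe_H for a sensor of length L in a
  channel of height H;
* depletion-boundary-layer mass-transfer coefficient k_M = F D / L with
  F = 0.81 Pe_s^(1/3) for Pe_s > 1 (Leveque-type collection) and F = 1
  (full-collection limit) below;
* Damkoehler number Da = k_on b_m / k_M comparing the maximal surface
  reaction flux (site density b_m) with transport.

Verdict thresholds (order-of-magnitude conventions, cross-checked against
the two-compartment simulation oracle): Da < 0.1 reaction-limited,
0.1 <= Da < 1 transport-influenced, Da >= 1 transport-limited.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .simulate import L_PER_M3, KineticTruth

BOLTZMANN = 1.380649e-23  # J/K

VERDICT_REACTION = "reaction_limited"
VERDICT_INFLUENCED = "transport_influenced"
VERDICT_LIMITED = "transport_limited"

DA_REACTION_LIMIT = 0.1
DA_TRANSPORT_LIMIT = 1.0


class TransportError(ValueError):
    pass


@dataclass(frozen=True)
class TransportParams:
    """Particle and flow parameters.  Defaults: 46-nm particle in water at
    25 C, 1 uL/min channel flow."""

    hydrodynamic_diameter: float = 46e-9  # m
    temperature: float = 298.15  # K
    viscosity: float = 8.9e-4  # Pa s
    flow_rate: float = 1e-9 / 60.0  # m^3/s (1 uL/min)

    def __post_init__(self):
        for name in ("hydrodynamic_diameter", "temperature", "viscosity", "flow_rate"):
            if getattr(self, name) <= 0:
                raise TransportError(f"{name} must be positive")

    @property
    def diffusivity(self) -> float:
        return stokes_einstein(self)


@dataclass(frozen=True)
class ChannelGeometry:
    """Microchannel cross-section and sensor footprint."""

    width: float = 200e-6  # m
    height: float = 50e-6  # m
    sensor_length: float = 100e-6  # m

    def __post_init__(self):
        for name in ("width", "height", "sensor_length"):
            if getattr(self, name) <= 0:
                raise TransportError(f"{name} must be positive")

    @property
    def shallow(self) -> bool:
        return self.height <= self.width


@dataclass(frozen=True)
class SurfaceSiteDensity:
    """Areal density of active bait sites (mol/m^2).  No default: the bait
    surface density is assay-specific and must be supplied."""

    b_m: float

    def __post_init__(self):
        if self.b_m < 0:
            raise TransportError("b_m must be nonnegative")


@dataclass(frozen=True)
class RegimeReport:
    diffusivity: float  # m^2/s
    channel_peclet: float
    shear_peclet: float
    mass_transfer_coefficient: float  # m/s
    depletion_fraction: float
    damkohler: float
    verdict: str
    approximate: bool = False  # correlation outside its validity range

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def stokes_einstein(params: TransportParams) -> float:
    """Diffusivity D = k_B T / (3 pi eta d_h) of a spherical particle."""
    return BOLTZMANN * params.temperature / (
        3 * np.pi * params.viscosity * params.hydrodynamic_diameter
    )


def mass_transfer_coefficient(
    transport: TransportParams, geom: ChannelGeometry
) -> tuple[float, float, float, bool]:
    """k_M plus the Peclet numbers behind it.

    Returns (k_M, Pe_H, Pe_s, approximate).  ``approximate`` flags
    Pe_s < 1e-2 where the boundary-layer correlation has no validity.
    """
    d = stokes_einstein(transport)
    pe_h = transport.flow_rate / (d * geom.width)
    pe_s = 6.0 * (geom.sensor_length / geom.height) ** 2 * pe_h
    if pe_s > 1.0:
        f_coeff = 0.81 * pe_s ** (1.0 / 3.0)
    else:
        f_coeff = 1.0  # full-collection limit
    k_m = f_coeff * d / geom.sensor_length
    return k_m, pe_h, pe_s, pe_s < 1e-2


def damkohler(kon_bi: float, b_m: float, k_m: float) -> float:
    """Da = k_on b_m / k_M with k_on in M^-1 s^-1, b_m in mol/m^2, k_M in m/s."""
    if k_m <= 0:
        raise TransportError("mass-transfer coefficient must be positive")
    if kon_bi < 0 or b_m < 0:
        raise TransportError("kon_bi and b_m must be nonnegative")
    return (kon_bi / L_PER_M3) * b_m / k_m


def regime_report(
    transport: TransportParams,
    geom: ChannelGeometry,
    kin: KineticTruth | None,
    surface: SurfaceSiteDensity,
) -> RegimeReport:
    """Full transport diagnostic for one assay configuration.

    ``kin`` may be None for a kinetics-free report (Da = 0).  The
    depletion fraction estimates the share of incoming analyte flux
    captured by one sensor, k_on C b_m A_sensor / (Q C) with a square
    sensor footprint -- independent of C.
    """
    k_m, pe_h, pe_s, approx = mass_transfer_coefficient(transport, geom)
    kon = kin.kon_bi if kin is not None else 0.0
    da = damkohler(kon, surface.b_m, k_m)
    sensor_area = geom.sensor_length**2
    depletion = (kon / L_PER_M3) * surface.b_m * sensor_area / transport.flow_rate
    if da < DA_REACTION_LIMIT:
        verdict = VERDICT_REACTION
    elif da < DA_TRANSPORT_LIMIT:
        verdict = VERDICT_INFLUENCED
    else:
        verdict = VERDICT_LIMITED
    return RegimeReport(
        diffusivity=stokes_einstein(transport),
        channel_peclet=pe_h,
        shear_peclet=pe_s,
        mass_transfer_coefficient=k_m,
        depletion_fraction=depletion,
        damkohler=da,
        verdict=verdict,
        approximate=approx,
    )


def k_m_for_damkohler(kon_bi: float, b_m: float, da: float) -> float:
    """Mass-transfer coefficient giving a target Damkoehler number.

    Convenience inverse for two-compartment sweeps: k_M = k_on b_m / Da.
    """
    if da <= 0:
        raise TransportError("target Da must be positive")
    return (kon_bi / L_PER_M3) * b_m / da
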