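"""FRET efficiency, Förster-distance conversion and error propagation.

The true FRET efficiency of the interacting donor population follows from
the lifetime quenching, E = 1 - tau_F / tau_D, and the donor-acceptor
separation from the Förster relation E = 1 / (1 + (r / R0)^6), i.e.
r = R0 ((1 - E) / E)^(1/6). R0 is the Förster radius of the fluorophore
pair (57 Å for mTFP1/mVenus, taken as a configuration constant, not
computed from spectra). Uncertainties are propagated to first order
(delta method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FORSTER_RADIUS_ANGSTROM",
    "FRETResult",
    "fret_efficiency",
    "fret_distance",
    "efficiency_from_distance",
    "distance_sd_from_efficiency",
    "propagate_uncertainty",
]

FORSTER_RADIUS_ANGSTROM = 57.0


@dataclass(frozen=True)
class FRETResult:
    """FRET efficiency and donor-acceptor distance with propagated sds."""

    efficiency: float
    distance: float
    forster_radius: float
    efficiency_sd: float
    distance_sd: float


def fret_efficiency(tau_F: float, tau_D: float) -> float:
    """E = 1 - tau_F / tau_D for the FRET-quenched donor population.

    Requires 0 < tau_F <= tau_D (a FRET lifetime longer than the donor
    lifetime would imply a negative efficiency).
    """
    if not (tau_F > 0 and tau_D > 0 and math.isfinite(tau_F) and math.isfinite(tau_D)):
        raise ValueError("lifetimes must be positive and finite")
    if tau_F > tau_D:
        raise ValueError("tau_F > tau_D would imply negative FRET efficiency")
    return 1.0 - tau_F / tau_D


def fret_distance(E: float, R0: float = FORSTER_RADIUS_ANGSTROM) -> float:
    """Donor-acceptor distance r = R0 ((1 - E) / E)^(1/6), in R0's units.

    Strictly decreasing in E; E = 0.5 gives exactly R0. E in {0, 1} is
    rejected (distance unbounded / zero).
    """
    if not (0.0 < E < 1.0):
        raise ValueError("E must lie strictly inside (0, 1)")
    if R0 <= 0:
        raise ValueError("R0 must be > 0")
    return R0 * ((1.0 - E) / E) ** (1.0 / 6.0)


def efficiency_from_distance(r: float, R0: float = FORSTER_RADIUS_ANGSTROM) -> float:
    """Förster relation E = 1 / (1 + (r / R0)^6)."""
    if r <= 0 or R0 <= 0:
        raise ValueError("distances must be > 0")
    return 1.0 / (1.0 + (r / R0) ** 6)


def _dr_dE(E: float, R0: float) -> float:
    return -(R0 / 6.0) * ((1.0 - E) / E) ** (1.0 / 6.0) / (E * (1.0 - E))


def distance_sd_from_efficiency(
    E: float, E_sd: float, R0: float = FORSTER_RADIUS_ANGSTROM
) -> float:
    """First-order sd of the Förster distance given an efficiency spread.

    Useful when the efficiency spread is observed directly across cells;
    sd(r) = |dr/dE| sd(E), linear in sd(E).
    """
    if E_sd < 0:
        raise ValueError("E_sd must be >= 0")
    fret_distance(E, R0)  # validates E and R0
    return abs(_dr_dE(E, R0)) * E_sd


def propagate_uncertainty(
    tau_F: float,
    tau_D: float,
    tau_F_sd: float = 0.0,
    tau_D_sd: float = 0.0,
    R0: float = FORSTER_RADIUS_ANGSTROM,
) -> FRETResult:
    """Efficiency and distance with first-order (delta-method) sds.

    var(E) = (tau_F/tau_D^2)^2 var(tau_D) + (1/tau_D)^2 var(tau_F);
    sd(r) = |dr/dE| sd(E) with
    dr/dE = -(R0/6) ((1-E)/E)^(1/6) / (E (1-E)). Exact inputs (zero sds)
    give exact outputs.
    """
    if tau_F_sd < 0 or tau_D_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    E = fret_efficiency(tau_F, tau_D)
    e_var = (tau_F / tau_D**2) ** 2 * tau_D_sd**2 + (1.0 / tau_D) ** 2 * tau_F_sd**2
    e_sd = math.sqrt(e_var)
    r = fret_distance(E, R0)
    return FRETResult(
        efficiency=E,
        distance=r,
        forster_radius=R0,
        efficiency_sd=e_sd,
        distance_sd=abs(_dr_dE(E, R0)) * e_sd,
    )
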