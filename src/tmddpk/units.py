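"""Shared domain types and unit conversions.

Internal conventions used throughout the package:

* concentration — nmol/L (molar units; assay mass units are converted on
  the way in, reporting units on the way out),
* time — days,
* dose amounts — absolute mg per subject (per-kg inputs are resolved at
  regimen construction from the subject's body weight),
* volumes — mL, clearance — mL/day.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Route",
    "DrugProperties",
    "DEFAULT_DRUG",
    "DoseEvent",
    "Regimen",
    "mass_to_molar",
    "molar_to_mass",
    "ngml_to_molar",
    "molar_to_ngml",
    "build_regimen",
]


class Route(str, enum.Enum):
    """Administration route: IV bolus into the central compartment or
    first-order absorption from a subcutaneous depot."""

    IV = "IV"
    SC = "SC"


@dataclass(frozen=True)
class DrugProperties:
    """Identity and physical constants of the therapeutic protein.

    The default molecular weight is that of a full-length IgG2 antibody
    (~144 kDa), which sets the mass↔molar conversion factor.
    """

    name: str = "anti-a4b7-IgG2"
    molecular_weight: float = 144_000.0  # g/mol

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise ValueError("molecular_weight must be positive")


DEFAULT_DRUG = DrugProperties()


def _as_nonnegative(x, what: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{what} must be non-negative")
    return arr


def mass_to_molar(c_mass, drug: DrugProperties = DEFAULT_DRUG):
    """Convert a concentration from µg/mL to nmol/L.

    1 µg/mL = 1e-3 g/L, so c[nmol/L] = c[µg/mL] * 1e6 / MW[g/mol].
    Accepts scalars or arrays; negative input raises ``ValueError``.
    """
    c = _as_nonnegative(c_mass, "concentration")
    out = c * 1e6 / drug.molecular_weight
    return float(out) if np.isscalar(c_mass) else out


def molar_to_mass(c_molar, drug: DrugProperties = DEFAULT_DRUG):
    """Convert a concentration from nmol/L to µg/mL (inverse of
    :func:`mass_to_molar`)."""
    c = _as_nonnegative(c_molar, "concentration")
    out = c * drug.molecular_weight / 1e6
    return float(out) if np.isscalar(c_molar) else out


def ngml_to_molar(c_ngml, drug: DrugProperties = DEFAULT_DRUG):
    """Convert ng/mL (assay units, e.g. LLOQ values) to nmol/L."""
    c = _as_nonnegative(c_ngml, "concentration")
    out = c * 1e3 / drug.molecular_weight
    return float(out) if np.isscalar(c_ngml) else out


def molar_to_ngml(c_molar, drug: DrugProperties = DEFAULT_DRUG):
    """Convert nmol/L to ng/mL."""
    c = _as_nonnegative(c_molar, "concentration")
    out = c * drug.molecular_weight / 1e3
    return float(out) if np.isscalar(c_molar) else out


def mg_to_nmol(amount_mg: float, drug: DrugProperties = DEFAULT_DRUG) -> float:
    """Convert an absolute dose amount from mg to nmol."""
    if amount_mg < 0:
        raise ValueError("amount must be non-negative")
    return amount_mg * 1e6 / drug.molecular_weight


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: absolute amount in mg at ``time`` (days)."""

    time: float
    amount: float
    route: Route

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")
        object.__setattr__(self, "route", Route(self.route))


@dataclass(frozen=True)
class Regimen:
    """Ordered dose events plus an observation schedule for one subject."""

    doses: tuple[DoseEvent, ...]
    observation_times: tuple[float, ...]
    subject_body_weight: float

    def __post_init__(self) -> None:
        doses = tuple(self.doses)
        obs = tuple(float(t) for t in self.observation_times)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "observation_times", obs)
        if self.subject_body_weight <= 0:
            raise ValueError("body weight must be positive")
        times = [d.time for d in doses]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be non-decreasing")
        if any(t2 <= t1 for t1, t2 in zip(obs, obs[1:])):
            raise ValueError("observation times must be strictly increasing")
        if any(t < 0 for t in obs):
            raise ValueError("observation times must be >= 0")

    @property
    def total_dose(self) -> float:
        """Total administered amount in mg."""
        return float(sum(d.amount for d in self.doses))

    @property
    def dose_times(self) -> tuple[float, ...]:
        return tuple(d.time for d in self.doses)


def build_regimen(
    dose_mg_per_kg: float,
    body_weight: float,
    route: Route | str,
    n_doses: int = 1,
    interval: float | None = None,
    obs_grid: Sequence[float] = (),
) -> Regimen:
    """Construct a regimen from a per-kg dose level.

    Absolute amounts are ``dose_mg_per_kg * body_weight``; doses are placed
    at 0, interval, ..., (n_doses-1)*interval days.
    """
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    if n_doses < 1:
        raise ValueError("n_doses must be >= 1")
    if n_doses > 1 and (interval is None or interval <= 0):
        raise ValueError("interval must be positive for multiple doses")
    route = Route(route)
    amount = dose_mg_per_kg * body_weight
    step = interval if interval is not None else 0.0
    doses = tuple(
        DoseEvent(time=k * step, amount=amount, route=route) for k in range(n_doses)
    )
    return Regimen(
        doses=doses,
        observation_times=tuple(float(t) for t in obs_grid),
        subject_body_weight=body_weight,
    )
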