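"""Energy-balance bookkeeping with first-order uncertainty propagation.

Group-level quantities (daily food intake, fecal dry mass, fecal energy
density) enter as mean +/- combined standard uncertainty, all sources
treated as independent and Gaussian, and every derived quantity propagates
uncertainty by the first-order Taylor method:

    u(x +/- y) = sqrt(u_x^2 + u_y^2)
    u(x * y)   = sqrt((y u_x)^2 + (x u_y)^2)
    u(x / y)   = sqrt((u_x / y)^2 + (x u_y / y^2)^2)

Reporting convention: mean +/- 1.96 u (an approximate 95 % interval).

The bookkeeping itself:
    energy input      = daily food intake (g) * food energy density (kcal/g)
    energy excretion  = daily fecal dry mass (g) * fecal energy density
    energy extraction = input - excretion
    % extraction      = 100 * (input - excretion) / input

and the microbial contribution to fecal energy density is
cell density (cells/g) * cell dry mass (g/cell) * energy per g dry bacteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class UncertainValue:
    """A mean with its combined standard uncertainty (same units, >= 0)."""

    mean: float
    u: float = 0.0

    def __post_init__(self) -> None:
        if self.u < 0:
            raise ValueError("uncertainty must be non-negative")

    @property
    def interval95(self) -> tuple[float, float]:
        return (self.mean - 1.96 * self.u, self.mean + 1.96 * self.u)

    def __format__(self, spec: str) -> str:
        spec = spec or ".3g"
        return f"{self.mean:{spec}} ± {1.96 * self.u:{spec}}"


def from_samples(x) -> UncertainValue:
    """Group-level uncertain input: mean +/- standard error of the mean."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("no samples")
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return UncertainValue(float(np.mean(x)), sem)


def u_add(a: UncertainValue, b: UncertainValue, sign: int = 1) -> UncertainValue:
    """Sum or difference (sign=-1) of independent uncertain values."""
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    return UncertainValue(a.mean + sign * b.mean, float(np.hypot(a.u, b.u)))


def u_mul(a: UncertainValue, b: UncertainValue) -> UncertainValue:
    u = float(np.hypot(b.mean * a.u, a.mean * b.u))
    return UncertainValue(a.mean * b.mean, u)


def u_div(a: UncertainValue, b: UncertainValue) -> UncertainValue:
    if b.mean == 0:
        raise ZeroDivisionError("division by zero-mean uncertain value")
    u = float(np.hypot(a.u / b.mean, a.mean * b.u / b.mean**2))
    return UncertainValue(a.mean / b.mean, u)


@dataclass(frozen=True)
class BalanceConstants:
    """Energy densities and microbial parameters used in the bookkeeping."""

    food_energy_density: float = 3.94  # kcal per g chow
    cell_dry_mass: float = 2.26e-13  # g per bacterial cell
    bacterial_energy_density: float = 4.58  # kcal per g dry bacterial mass

    def __post_init__(self) -> None:
        for f in (self.food_energy_density, self.cell_dry_mass, self.bacterial_energy_density):
            if f <= 0:
                raise ValueError("balance constants must be positive")


DEFAULT_BALANCE = BalanceConstants()


@dataclass(frozen=True)
class EnergyBalance:
    input: UncertainValue
    excretion: UncertainValue
    extraction: UncertainValue
    percent_extraction: UncertainValue


def daily_energy_input(
    intake_g_per_day: UncertainValue, c: BalanceConstants = DEFAULT_BALANCE
) -> UncertainValue:
    """kcal/day ingested: food intake times the chow energy density."""
    return u_mul(intake_g_per_day, UncertainValue(c.food_energy_density, 0.0))


def daily_energy_excretion(
    fecal_dry_g_per_day: UncertainValue, fecal_energy_kcal_per_g: UncertainValue
) -> UncertainValue:
    """kcal/day excreted: dry fecal mass times bomb-calorimetry energy density."""
    return u_mul(fecal_dry_g_per_day, fecal_energy_kcal_per_g)


def balance(input: UncertainValue, excretion: UncertainValue) -> EnergyBalance:
    """Energy extraction and percent extraction with propagated uncertainty.

    Percent extraction f(x, y) = 100 (x - y) / x propagates with
    df/dx = 100 y / x^2 and df/dy = -100 / x.
    """
    if input.mean <= 0:
        raise ValueError("energy input must be positive")
    extraction = u_add(input, excretion, sign=-1)
    x, y = input.mean, excretion.mean
    pct = 100.0 * (x - y) / x
    u_pct = float(np.hypot(100.0 * y / x**2 * input.u, 100.0 / x * excretion.u))
    return EnergyBalance(
        input=input,
        excretion=excretion,
        extraction=extraction,
        percent_extraction=UncertainValue(pct, u_pct),
    )


def microbial_energy_density(
    cell_density_per_g: float, c: BalanceConstants = DEFAULT_BALANCE
) -> float:
    """Energy stored in fecal bacteria, kcal per g (linear in cell density).

    The published estimate applies a cell density measured per gram of
    cecal content to energy per gram of dry feces; the two denominators are
    not identical and the result should be read as an order-of-magnitude
    bound, which is flagged here once per call site.
    """
    if cell_density_per_g < 0:
        raise ValueError("cell density must be non-negative")
    warnings.warn(
        "cell density per g cecal content is applied to per-g-dry-feces "
        "energy; treat the result as approximate",
        UserWarning,
        stacklevel=2,
    )
    return cell_density_per_g * c.cell_dry_mass * c.bacterial_energy_density


def cecal_metabolite_pool(
    concentration: UncertainValue, cecal_mass_g: UncertainValue
) -> UncertainValue:
    """Total cecal amount = concentration (amount/g) x cecal mass (g)."""
    if concentration.mean < 0 or cecal_mass_g.mean < 0:
        raise ValueError("concentration and mass must be non-negative")
    return u_mul(concentration, cecal_mass_g)
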