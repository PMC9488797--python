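"""Gas exchange: Haldane-corrected VO2/VCO2, RER, Weir energy expenditure.

An open-circuit calorimeter extracts cage air at a known flow and measures
the O2 and CO2 volume-fraction differentials between the cage exhaust and a
reference (room-air) chamber.  Because the animal consumes more O2 volume
than it produces CO2 volume whenever RER < 1, inlet and outlet flows differ
slightly; the Haldane transformation recovers the inlet flow from
conservation of the inert gas (N2), which the animal neither consumes nor
produces.  Sign conventions: ``d_o2 = reference - cage`` (consumption
positive) and ``d_co2 = cage - reference`` (production positive), so both
differentials are non-negative after QC.

Energy expenditure uses Weir's abbreviated equation (no urinary-nitrogen
term, standard for metabolic cages): ``EE = 3.941*VO2 + 1.106*VCO2`` in
kcal with volumes in litres.  Air is assumed dry at the sensors (upstream
dehumidification); no humidity or STP correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class InvalidAtmosphereError(ValueError):
    """Implied cage gas fractions are outside (0,1) or the inert balance fails."""


@dataclass(frozen=True)
class GasConstants:
    """Weir coefficients (kcal per litre of gas) and reference-air fractions."""

    weir_o2: float = 3.941
    weir_co2: float = 1.106
    ref_o2: float = 0.2095
    ref_co2: float = 0.0004

    def __post_init__(self) -> None:
        if self.weir_o2 <= 0 or self.weir_co2 <= 0:
            raise ValueError("Weir coefficients must be positive")
        for f in (self.ref_o2, self.ref_co2):
            if not (0 < f < 1):
                raise ValueError("reference fractions must lie in (0,1)")


DEFAULT_CONSTANTS = GasConstants()


def haldane_volumes(
    d_o2, d_co2, flow_lpm, constants: GasConstants = DEFAULT_CONSTANTS
):
    """O2 consumption and CO2 production (L/min) from gas differentials.

    With outlet flow ``F_out = flow_lpm`` and cage (exhaust) fractions
    ``Fe_O2 = ref_o2 - d_o2`` and ``Fe_CO2 = ref_co2 + d_co2``, the inert
    (N2) balance ``F_in*(1 - ref_o2 - ref_co2) = F_out*(1 - Fe_O2 -
    Fe_CO2)`` fixes the inlet flow, and

        VO2  = F_in*ref_o2  - F_out*Fe_O2
        VCO2 = F_out*Fe_CO2 - F_in*ref_co2

    Accepts scalars or arrays.  Raises :class:`InvalidAtmosphereError` when
    an implied cage fraction leaves (0,1).
    """
    d_o2 = np.asarray(d_o2, dtype=float)
    d_co2 = np.asarray(d_co2, dtype=float)
    flow = np.asarray(flow_lpm, dtype=float)
    fe_o2 = constants.ref_o2 - d_o2
    fe_co2 = constants.ref_co2 + d_co2
    inert_in = 1.0 - constants.ref_o2 - constants.ref_co2
    inert_out = 1.0 - fe_o2 - fe_co2
    if np.any(fe_o2 <= 0) or np.any(fe_o2 >= 1) or np.any(fe_co2 < 0) or np.any(
        fe_co2 >= 1
    ):
        raise InvalidAtmosphereError("cage gas fractions outside (0,1)")
    if inert_in <= 0 or np.any(inert_out <= 0):
        raise InvalidAtmosphereError("non-positive inert-gas fraction")
    # algebraically identical to eliminating F_in, but expressed through the
    # measured differentials directly so near-zero exchange does not suffer
    # catastrophic cancellation between large flow terms
    w = constants.ref_o2 * fe_co2 - constants.ref_co2 * fe_o2
    vo2 = flow * (d_o2 - w) / inert_in
    vco2 = flow * (d_co2 - w) / inert_in
    if np.ndim(d_o2) == 0 and np.ndim(flow) == 0:
        return float(vo2), float(vco2)
    return vo2, vco2


def invert_haldane(
    vo2_lpm, vco2_lpm, flow_lpm, constants: GasConstants = DEFAULT_CONSTANTS
):
    """Gas differentials that reproduce given VO2/VCO2 under the Haldane model.

    Solves the linear two-gas system for the cage fractions; used by the
    synthetic generator so traces are emitted in raw sensor space and the
    forward computation is exercised nontrivially.
    """
    vo2 = np.asarray(vo2_lpm, dtype=float)
    vco2 = np.asarray(vco2_lpm, dtype=float)
    flow = np.asarray(flow_lpm, dtype=float)
    inert_in = 1.0 - constants.ref_o2 - constants.ref_co2
    a = constants.ref_o2 / inert_in
    b = constants.ref_co2 / inert_in
    # vo2/flow  = a - (a+1)*Fe_O2 - a*Fe_CO2
    # vco2/flow = -b + b*Fe_O2 + (1+b)*Fe_CO2
    rhs1 = vo2 / flow - a
    rhs2 = vco2 / flow + b
    det = -(a + 1.0) * (1.0 + b) + a * b
    fe_o2 = (rhs1 * (1.0 + b) - (-a) * rhs2) / det
    fe_co2 = ((-(a + 1.0)) * rhs2 - b * rhs1) / det
    d_o2 = constants.ref_o2 - fe_o2
    d_co2 = fe_co2 - constants.ref_co2
    if np.ndim(vo2) == 0 and np.ndim(flow) == 0:
        return float(d_o2), float(d_co2)
    return d_o2, d_co2


def rer(vo2_lpm, vco2_lpm):
    """Respiratory exchange ratio VCO2/VO2; NaN where VO2 is zero."""
    vo2 = np.asarray(vo2_lpm, dtype=float)
    vco2 = np.asarray(vco2_lpm, dtype=float)
    out = np.divide(vco2, vo2, out=np.full(np.broadcast(vo2, vco2).shape, np.nan), where=vo2 > 0)
    if out.ndim == 0:
        return float(out)
    return out


def weir_ee(
    vo2_lpm, vco2_lpm, constants: GasConstants = DEFAULT_CONSTANTS
):
    """Energy expenditure (kcal/min) from gas-exchange volumes."""
    vo2 = np.asarray(vo2_lpm, dtype=float)
    vco2 = np.asarray(vco2_lpm, dtype=float)
    out = constants.weir_o2 * vo2 + constants.weir_co2 * vco2
    if out.ndim == 0:
        return float(out)
    return out


def hydrogen_rate(d_h2_ppm, flow_lpm):
    """Hydrogen production rate as differential x flow (ppm * L/min)."""
    out = np.asarray(d_h2_ppm, dtype=float) * np.asarray(flow_lpm, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out


def add_exchange(
    frame: pd.DataFrame, constants: GasConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Attach vo2_lpm, vco2_lpm, rer, ee_kcal_min, h2_rate columns to a trace frame."""
    df = frame.copy()
    vo2, vco2 = haldane_volumes(
        df["d_o2"].to_numpy(), df["d_co2"].to_numpy(), df["flow_lpm"].to_numpy(), constants
    )
    df["vo2_lpm"] = vo2
    df["vco2_lpm"] = vco2
    df["rer"] = rer(vo2, vco2)
    df["ee_kcal_min"] = weir_ee(vo2, vco2, constants)
    df["h2_rate"] = hydrogen_rate(df["d_h2"].to_numpy(), df["flow_lpm"].to_numpy())
    return df
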