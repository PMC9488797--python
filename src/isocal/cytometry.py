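"""Bead-normalized absolute bacterial density from flow-cytometry counts.

Cecal content is homogenized in buffer, a small aliquot is stained and
spiked with counting beads of known concentration, and events are acquired
for a fixed time.  Because sample and beads pass the laser at the same
rate, the bacteria-per-bead ratio scales directly to concentration:

    cells/g = (bacterial events / bead events)
              * bead concentration (beads/uL) * mix volume (uL)   -> cells in mix
              / sample volume (uL) * homogenate volume (uL)       -> cells in homogenate
              / sample mass (g)                                   -> cells per g content

Counts are taken as already gated; germ-free samples define the blank and a
density whose counts are at blank level is flagged rather than reported as
a positive number.
"""

from __future__ import annotations

from dataclasses import dataclass


class AssayFailureError(ValueError):
    """No bead events: the spike or acquisition failed."""


@dataclass(frozen=True)
class CytometryAssay:
    """One bead-spiked acquisition of a cecal-content homogenate."""

    bacterial_events: int
    bead_events: int
    sample_mass_g: float
    bead_conc_per_ul: float = 4.55e3
    mix_volume_ul: float = 200.0
    sample_volume_ul: float = 2.0
    homogenate_volume_ul: float = 1000.0

    def __post_init__(self) -> None:
        if self.bacterial_events < 0 or self.bead_events < 0:
            raise ValueError("event counts must be non-negative")
        for name in (
            "sample_mass_g",
            "bead_conc_per_ul",
            "mix_volume_ul",
            "sample_volume_ul",
            "homogenate_volume_ul",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def density_from_events(a: CytometryAssay, blank_events: int = 0) -> dict:
    """Absolute bacterial density (cells per g of cecal content).

    ``blank_events`` is the bacterial-gate count of a germ-free negative
    control acquired identically; a sample within the blank level is
    reported with ``at_blank=True`` and its density should be read as not
    distinguishable from zero.
    """
    if a.bead_events == 0:
        raise AssayFailureError("zero bead events")
    cells_in_mix = (a.bacterial_events / a.bead_events) * a.bead_conc_per_ul * a.mix_volume_ul
    cells_in_homogenate = cells_in_mix / a.sample_volume_ul * a.homogenate_volume_ul
    density = cells_in_homogenate / a.sample_mass_g
    return {
        "cells_per_g": density,
        "at_blank": a.bacterial_events <= blank_events,
    }
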