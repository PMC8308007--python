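"""Microwave-digestion dilution back-calculation.

An ICP-SFMS run reports the concentration of the *analysed solution*
(µg·L⁻¹). Recovering the concentration in the original powder requires
undoing the sample-prep dilution chain:

    C_powder = C_solution × DF × V / W

with DF the pre-analysis dilution factor (5 by default), V the volume of
digest returned from the vessel (recorded in mL, converted to L here so
that µg·L⁻¹ × L / kg gives µg·kg⁻¹) and W the powder mass digested (kg).
``forward_reading`` is the algebraic inverse, used by the synthetic
generator to turn a chosen true powder concentration into the solution
concentration the instrument would see.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_DILUTION_FACTOR = 5.0
ML_PER_L = 1000.0


@dataclass(frozen=True)
class InstrumentReading:
    """One solution measurement plus the prep constants needed to undo dilution.

    c_inst: µg·L⁻¹ in the analysed solution. returned_volume: mL of digest.
    weighed_mass: kg of powder digested.
    """

    element: str
    c_inst: float
    returned_volume: float
    weighed_mass: float
    dilution_factor: float = DEFAULT_DILUTION_FACTOR

    def __post_init__(self) -> None:
        if self.c_inst < 0:
            raise ValueError(f"c_inst must be >= 0, got {self.c_inst}")
        if self.dilution_factor <= 0:
            raise ValueError(f"dilution_factor must be > 0, got {self.dilution_factor}")
        if self.returned_volume <= 0:
            raise ValueError(f"returned_volume must be > 0, got {self.returned_volume}")
        if self.weighed_mass <= 0:
            raise ValueError(f"weighed_mass must be > 0, got {self.weighed_mass}")


def back_calculate(r: InstrumentReading) -> float:
    """Powder concentration (µg·kg⁻¹) from a solution reading."""
    volume_l = r.returned_volume / ML_PER_L
    return r.c_inst * r.dilution_factor * volume_l / r.weighed_mass


def forward_reading(
    c_final: float,
    dilution_factor: float = DEFAULT_DILUTION_FACTOR,
    returned_volume: float = 10.0,
    weighed_mass: float = 0.0005,
) -> float:
    """Solution concentration (µg·L⁻¹) the instrument would report for a
    powder at ``c_final`` µg·kg⁻¹ — exact inverse of :func:`back_calculate`."""
    if c_final < 0:
        raise ValueError(f"c_final must be >= 0, got {c_final}")
    if dilution_factor <= 0 or returned_volume <= 0 or weighed_mass <= 0:
        raise ValueError("dilution_factor, returned_volume and weighed_mass must be > 0")
    volume_l = returned_volume / ML_PER_L
    return c_final * weighed_mass / (dilution_factor * volume_l)
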