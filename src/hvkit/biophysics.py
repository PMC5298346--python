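"""Closed-form electrochemistry shared by all pipeline stages.

Unit conventions, fixed package-wide:

* voltage       millivolts (mV)
* current       picoamperes (pA)
* conductance   nanosiemens (nS); note pA / mV == nS
* time          milliseconds (ms)
* concentration micromolar (µM) for Zn²⁺, mM elsewhere
* temperature   degrees Celsius at API boundaries, Kelvin internally

Sign conventions follow standard electrophysiology practice: outward
current is positive, and a proton-selective conductance carries current
``I = g * (V - E_H)`` where ``E_H`` is the proton Nernst potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "Cation",
    "SolutionConditions",
    "nernst_potential",
    "nernst_slope_per_pH_unit",
    "DEFAULT_TEMPERATURE_C",
    "GAS_CONSTANT",
    "FARADAY",
]

#: Molar gas constant, J mol^-1 K^-1 (CODATA 2018, exact).
GAS_CONSTANT = 8.31446261815324

#: Faraday constant, C mol^-1 (CODATA 2018, exact).
FARADAY = 96485.33212331001

_LN10 = math.log(10.0)

#: Recording temperature used throughout unless stated otherwise.
DEFAULT_TEMPERATURE_C = 21.0


class Cation(str, Enum):
    """Main monovalent cation of the recording solution."""

    TMA = "TMA"
    NA = "Na"
    K = "K"


@dataclass(frozen=True)
class SolutionConditions:
    """Experimental context of a recording: pH on both membrane faces,
    temperature, solution composition, and the liquid-junction offset.

    ``junction_potential_mV`` is the correction to be *subtracted* from
    command voltages before analysis (0 if unmeasured).
    """

    pH_o: float = 7.0
    pH_i: float = 7.0
    temperature_C: float = DEFAULT_TEMPERATURE_C
    main_cation: Cation = Cation.TMA
    zn_uM: float = 0.0
    junction_potential_mV: float = 0.0

    def __post_init__(self) -> None:
        if not (4.0 <= self.pH_o <= 10.5):
            raise ValueError(f"pH_o must be in [4.0, 10.5], got {self.pH_o}")
        if not (4.0 <= self.pH_i <= 10.5):
            raise ValueError(f"pH_i must be in [4.0, 10.5], got {self.pH_i}")
        if not (15.0 <= self.temperature_C <= 30.0):
            raise ValueError(
                f"temperature_C must be in [15, 30], got {self.temperature_C}"
            )
        if self.zn_uM < 0:
            raise ValueError(f"zn_uM must be >= 0, got {self.zn_uM}")
        if not isinstance(self.main_cation, Cation):
            object.__setattr__(self, "main_cation", Cation(self.main_cation))

    @property
    def delta_pH(self) -> float:
        """Transmembrane pH gradient, pH_o - pH_i."""
        return self.pH_o - self.pH_i

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15


def nernst_slope_per_pH_unit(temperature_C: float = DEFAULT_TEMPERATURE_C) -> float:
    """(RT/F)·ln(10) in mV — the reversal-potential change per unit pH
    gradient for a perfectly proton-selective conductance.

    58.4 mV at 21 °C (rounds to the textbook 58); 59.2 mV at 25 °C.
    """
    t_kelvin = temperature_C + 273.15
    return 1000.0 * GAS_CONSTANT * t_kelvin * _LN10 / FARADAY


def nernst_potential(conditions: SolutionConditions) -> float:
    """Proton Nernst potential E_H in mV.

    E_H = (RT/F)·ln10·(pH_i - pH_o): positive when pH_i > pH_o, so that
    protons flow inward at 0 mV and outward current is positive above E_H.
    """
    slope = nernst_slope_per_pH_unit(conditions.temperature_C)
    return slope * (conditions.pH_i - conditions.pH_o)
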