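"""Cross-family inference: ΔpH-gating slope, proton-selectivity statistics,
cation-substitution test, and the Zn²⁺ dose-response."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .biophysics import SolutionConditions, nernst_slope_per_pH_unit

__all__ = [
    "VariedSide",
    "GatingShiftResult",
    "SelectivityResult",
    "ZnResponse",
    "dpH_gating_slope",
    "selectivity_regression",
    "cation_substitution_test",
    "zn_dose_response",
]


class VariedSide(str, Enum):
    PH_O = "pH_o"
    PH_I = "pH_i"


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(x, y, 1)[0])


@dataclass
class GatingShiftResult:
    """Shift of the g-V position (voltage at 10% of g_max) per unit pH.

    ``slope_mV_per_pH`` is the signed pooled OLS slope over sub-saturation
    points; the headline figure is its magnitude with a direction flag
    (negative with increasing pH_o, positive with increasing pH_i).
    """

    series: Dict[str, List[Tuple[float, float]]]
    varied_side: VariedSide
    saturation_pH: float
    slope_mV_per_pH: float
    saturation_slope_mV_per_pH: Optional[float]
    per_cell_slopes: Dict[str, float] = field(default_factory=dict)

    @property
    def magnitude_mV_per_pH(self) -> float:
        return abs(self.slope_mV_per_pH)

    @property
    def shifts_negative_with_pH(self) -> bool:
        return self.slope_mV_per_pH < 0


def dpH_gating_slope(series, varied_side: VariedSide = VariedSide.PH_O,
                     saturation_pH: float = 8.0) -> GatingShiftResult:
    """OLS slope of V(10% g_max) versus pH, fitted separately below and
    above the saturation boundary.

    ``series`` is either a single list of (pH, v10) points or a mapping of
    cell/patch id -> list of points; per-cell slopes are preserved but the
    headline slope pools all sub-saturation points.
    """
    varied_side = VariedSide(varied_side)
    if isinstance(series, dict):
        cells = {str(k): [(float(p), float(v)) for p, v in pts]
                 for k, pts in series.items()}
    else:
        cells = {"cell0": [(float(p), float(v)) for p, v in series]}

    pooled = [pt for pts in cells.values() for pt in pts]
    below = [(p, v) for p, v in pooled if p <= saturation_pH]
    above = [(p, v) for p, v in pooled if p > saturation_pH]
    if len({p for p, _ in below}) < 2:
        raise ValueError("no sub-saturation points: need >= 2 with pH <= "
                         f"{saturation_pH}")
    bx = np.array([p for p, _ in below])
    by = np.array([v for _, v in below])
    slope = _ols_slope(bx, by)

    sat_slope = None
    if len({p for p, _ in above}) >= 2:
        ax = np.array([p for p, _ in above])
        ay = np.array([v for _, v in above])
        sat_slope = _ols_slope(ax, ay)

    per_cell = {}
    for cell, pts in cells.items():
        sub = [(p, v) for p, v in pts if p <= saturation_pH]
        if len({p for p, _ in sub}) >= 2:
            per_cell[cell] = _ols_slope(np.array([p for p, _ in sub]),
                                        np.array([v for _, v in sub]))

    return GatingShiftResult(series=cells, varied_side=varied_side,
                             saturation_pH=saturation_pH,
                             slope_mV_per_pH=slope,
                             saturation_slope_mV_per_pH=sat_slope,
                             per_cell_slopes=per_cell)


@dataclass
class SelectivityResult:
    """V_rev versus ΔpH compared against the Nernst line."""

    points: List[Tuple[float, float]]          # (pH_i - pH_o, vrev_mV)
    slope_mV_per_pH: float
    intercept_mV: float
    nernst_slope_mV_per_pH: float
    deviations_mV: List[float]                 # vrev - E_H per point
    rms_deviation_mV: float


def selectivity_regression(points: Sequence[Tuple[SolutionConditions, float]]
                           ) -> SelectivityResult:
    """Regression of measured reversal potentials on the pH gradient.

    Each point is (conditions, vrev_mV). Reports the fitted slope and the
    per-point and RMS deviations from the Nernst expectation at each
    point's own temperature. Raises on a singular design (one ΔpH)."""
    if len(points) < 2:
        raise ValueError("need >= 2 points for a selectivity regression")
    dph = np.array([c.pH_i - c.pH_o for c, _ in points])
    vrev = np.array([v for _, v in points])
    if len(set(np.round(dph, 12))) < 2:
        raise ValueError("singular design: only one distinct delta-pH value")
    fit = stats.linregress(dph, vrev)
    temps = [c.temperature_C for c, _ in points]
    nernst = nernst_slope_per_pH_unit(float(np.mean(temps)))
    devs = [v - nernst_slope_per_pH_unit(c.temperature_C) * (c.pH_i - c.pH_o)
            for c, v in points]
    rms = float(np.sqrt(np.mean(np.square(devs))))
    return SelectivityResult(points=list(zip(dph.tolist(), vrev.tolist())),
                             slope_mV_per_pH=float(fit.slope),
                             intercept_mV=float(fit.intercept),
                             nernst_slope_mV_per_pH=nernst,
                             deviations_mV=[float(d) for d in devs],
                             rms_deviation_mV=rms)


def cation_substitution_test(
        vrev_pairs: Sequence[Tuple[float, float, float]]) -> Tuple[float, float]:
    """Mean ± SEM change in V_rev upon bath-cation substitution.

    Each entry is (vrev_reference, vrev_substituted, junction_correction_mV);
    the correction is subtracted from the raw shift. SEM uses the n-1
    denominator in the standard deviation. Returns (mean_mV, sem_mV)."""
    if len(vrev_pairs) < 2:
        raise ValueError("need >= 2 substitution pairs")
    deltas = np.array([(vx - vt) - jc for vt, vx, jc in vrev_pairs])
    mean = float(np.mean(deltas))
    sem = float(np.std(deltas, ddof=1) / math.sqrt(len(deltas)))
    return mean, sem


@dataclass
class ZnResponse:
    concentrations_uM: List[float]
    fraction_remaining: List[float]
    percent_inhibition: List[float]
    ic50_uM: Optional[float]
    hill: Optional[float]


def zn_dose_response(currents: Sequence[Tuple[float, float]]) -> ZnResponse:
    """Fractional current remaining versus [Zn²⁺] at a fixed test voltage.

    ``currents`` holds (zn_uM, steady_state_current_pA) including a zn = 0
    reference with positive current. A Hill curve (ic50, hill in [0.3, 4])
    is fitted when at least three nonzero concentrations are present."""
    pts = sorted((float(z), float(i)) for z, i in currents)
    zn = [z for z, _ in pts]
    if len(zn) != len(set(zn)):
        raise ValueError("duplicate Zn concentrations")
    if not pts or pts[0][0] != 0.0:
        raise ValueError("dose-response requires a zn = 0 reference")
    i0 = pts[0][1]
    if i0 <= 0:
        raise ValueError("no reference current: I_ss(0) <= 0")

    frac = [i / i0 for _, i in pts]
    pct = [100.0 * (1.0 - f) for f in frac]

    ic50 = hill = None
    nonzero = [(z, f) for (z, _), f in zip(pts, frac) if z > 0]
    if len(nonzero) >= 3:
        zs = np.array([z for z, _ in nonzero])
        fs = np.array([f for _, f in nonzero])

        def model(z, ic50, h):
            return 1.0 / (1.0 + (z / ic50) ** h)

        p0 = (float(np.exp(np.mean(np.log(zs)))), 1.0)
        try:
            popt, _ = optimize.curve_fit(
                model, zs, fs, p0=p0,
                bounds=([1e-6, 0.3], [1e9, 4.0]), maxfev=10000)
            ic50, hill = float(popt[0]), float(popt[1])
        except RuntimeError:
            pass

    return ZnResponse(concentrations_uM=zn, fraction_remaining=frac,
                      percent_inhibition=pct, ic50_uM=ic50, hill=hill)
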