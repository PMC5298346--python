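"""End-to-end measurement pipelines on simulated families.

These helpers encode the experimental design used throughout: pick a step
or tail protocol appropriate for the solution conditions (as an
experimenter would), simulate the family, and push it through the analysis
stage. The analysis itself never sees the generating parameters — only the
traces and their solution metadata.
"""

from __future__ import annotations

from dataclasses import replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .analysis import (RevPotentialEstimate, build_gv_curve,
                       estimate_vrev_direct, estimate_vrev_from_tails,
                       fit_single_exponential)
from .biophysics import SolutionConditions, nernst_potential
from .gating import (GatingShiftResult, VariedSide, ZnResponse,
                     dpH_gating_slope, zn_dose_response)
from .simulate import (GatingParams, NoiseModel, TraceFamily, VoltageProtocol,
                       effective_v_half, simulate_family,
                       simulate_tail_family)

__all__ = [
    "design_gv_protocol",
    "measure_vrev",
    "measure_v10",
    "dph_gating_pipeline",
    "selectivity_pipeline",
    "zn_inhibition_pipeline",
]

_DT_MS = 0.2  # satisfies the undersampling guard down to the 1 ms tau floor


def design_gv_protocol(conditions: SolutionConditions, gating: GatingParams,
                       step_increment_mV: float = 10.0,
                       step_duration_ms: float = 400.0) -> VoltageProtocol:
    """Step protocol spanning the activation range at these conditions:
    from 60 mV below to 80 mV above the expected midpoint."""
    vh = effective_v_half(conditions, gating)
    return VoltageProtocol(
        holding_mV=min(-60.0, vh - 70.0),
        step_start_mV=vh - 60.0, step_stop_mV=vh + 80.0,
        step_increment_mV=step_increment_mV,
        step_duration_ms=step_duration_ms, tail_duration_ms=150.0,
        sample_interval_ms=_DT_MS)


def measure_vrev(conditions: SolutionConditions, gating: GatingParams,
                 noise: NoiseModel, settle_ms: float = 2.0,
                 ) -> RevPotentialEstimate:
    """Measure the reversal potential the way the experiment does: from
    families of currents when the conductance activates negative to the
    expected reversal, otherwise from tail currents after an activating
    prepulse.

    The *expected* reversal used to center the probe voltages is the Nernst
    potential computed from the solution pH values — the quantity an
    experimenter knows when designing the protocol."""
    vh = effective_v_half(conditions, gating)
    e_h = nernst_potential(conditions)
    jp = conditions.junction_potential_mV
    if e_h >= vh - 10.0:
        # activation negative to reversal: direct family method
        protocol = VoltageProtocol(
            holding_mV=min(-60.0, vh - 70.0),
            step_start_mV=max(vh - 40.0, e_h - 40.0) + jp,
            step_stop_mV=e_h + 30.0 + jp, step_increment_mV=2.5,
            step_duration_ms=400.0, tail_duration_ms=150.0,
            sample_interval_ms=_DT_MS)
        family = simulate_family(protocol, conditions, gating, noise)
        return estimate_vrev_direct(family)
    # tails bracketing the expected reversal, offset off the grid so the
    # zero crossing is genuinely interpolated
    tails = e_h + jp + np.arange(-17.5, 10.0, 5.0)
    family = simulate_tail_family(
        conditions, gating, noise, prepulse_mV=vh + 60.0 + jp,
        tail_voltages_mV=tails, sample_interval_ms=_DT_MS)
    return estimate_vrev_from_tails(family, settle_ms=settle_ms)


def measure_v10(conditions: SolutionConditions, gating: GatingParams,
                noise: NoiseModel,
                rev: Optional[RevPotentialEstimate] = None,
                guard_mV: float = 5.0) -> float:
    """Full single-family pipeline: simulate a g-V family, measure V_rev,
    build the chord-conductance curve, and return the voltage at 10% of
    g_max."""
    if rev is None:
        rev = measure_vrev(conditions, gating, noise)
    protocol = design_gv_protocol(conditions, gating)
    family = simulate_family(protocol, conditions, gating, noise)
    gv = build_gv_curve(family, rev, guard_mV=guard_mV)
    if gv.v_at_10pct_mV is None:
        raise ValueError("10% crossing not bracketed by the g-V protocol")
    return gv.v_at_10pct_mV


def dph_gating_pipeline(pH_values: Sequence[float],
                        varied_side: VariedSide = VariedSide.PH_O,
                        fixed_pH: float = 7.0,
                        gating: Optional[GatingParams] = None,
                        noise: Optional[NoiseModel] = None,
                        temperature_C: float = 21.0,
                        saturation_pH: float = 8.0) -> GatingShiftResult:
    """Simulate-analyze-infer pipeline for the ΔpH gating slope: one family
    per pH value on the varied side, V(10% g_max) per family, pooled OLS
    slope versus pH."""
    gating = gating or GatingParams()
    noise = noise or NoiseModel()
    varied_side = VariedSide(varied_side)
    series = []
    for ph in pH_values:
        if varied_side is VariedSide.PH_O:
            cond = SolutionConditions(pH_o=ph, pH_i=fixed_pH,
                                      temperature_C=temperature_C)
        else:
            cond = SolutionConditions(pH_o=fixed_pH, pH_i=ph,
                                      temperature_C=temperature_C)
        series.append((ph, measure_v10(cond, gating, noise)))
    return dpH_gating_slope(series, varied_side=varied_side,
                            saturation_pH=saturation_pH)


def selectivity_pipeline(ph_pairs: Sequence[Tuple[float, float]],
                         gating: Optional[GatingParams] = None,
                         noise: Optional[NoiseModel] = None,
                         temperature_C: float = 21.0,
                         ) -> List[Tuple[SolutionConditions,
                                         RevPotentialEstimate]]:
    """Measure V_rev over a set of (pH_o, pH_i) pairs; returns the
    per-condition estimates for downstream regression."""
    gating = gating or GatingParams()
    noise = noise or NoiseModel()
    out = []
    for ph_o, ph_i in ph_pairs:
        cond = SolutionConditions(pH_o=ph_o, pH_i=ph_i,
                                  temperature_C=temperature_C)
        out.append((cond, measure_vrev(cond, gating, noise)))
    return out


def zn_inhibition_pipeline(zn_list: Sequence[float],
                           test_voltage_mV: float = 60.0,
                           gating: Optional[GatingParams] = None,
                           noise: Optional[NoiseModel] = None,
                           conditions: Optional[SolutionConditions] = None,
                           ) -> ZnResponse:
    """Steady-state current at the test voltage across Zn²⁺ concentrations
    (extrapolated from single-exponential fits), folded into a
    dose-response."""
    gating = gating or GatingParams()
    noise = noise or NoiseModel()
    base = conditions or SolutionConditions(pH_o=7.0, pH_i=7.0)
    protocol = VoltageProtocol(
        holding_mV=-60.0, step_start_mV=test_voltage_mV - 10.0,
        step_stop_mV=test_voltage_mV, step_increment_mV=10.0,
        step_duration_ms=400.0, tail_duration_ms=100.0,
        sample_interval_ms=1.0)
    currents = []
    for zn in zn_list:
        cond = replace(base, zn_uM=float(zn))
        family = simulate_family(protocol, cond, gating, noise)
        sweep = next(sw for sw in family.sweeps
                     if abs(sw.step_mV - test_voltage_mV) < 1e-9)
        fit = fit_single_exponential(sweep)
        if not fit.converged:
            raise RuntimeError(
                f"no resolvable current at {test_voltage_mV} mV, zn={zn}")
        currents.append((float(zn), fit.steady_state_pA))
    return zn_dose_response(currents)
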