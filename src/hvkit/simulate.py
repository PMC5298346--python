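"""Forward simulator of voltage-clamp families for a depolarization-activated,
proton-selective conductance with ΔpH-shifted gating.

The channel model is deliberately minimal: a single Boltzmann steady-state
open probability whose midpoint moves along the voltage axis with the pH
gradient, single-exponential relaxation toward that steady state, an
activation time constant that falls e-fold per ``k_tau_mV`` of
depolarization, instantaneous 1:1 Zn²⁺ block as a pure conductance scaling,
plus optional ohmic leak, a gated non-proton contaminant conductance, and
additive Gaussian recording noise.

Current convention: ``I = g·p·(V - E_H)`` (outward positive); sweeps carry
*command* voltages, the membrane sees ``command - junction_potential_mV``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .biophysics import Cation, SolutionConditions, nernst_potential

__all__ = [
    "GatingParams",
    "VoltageProtocol",
    "NoiseModel",
    "Sweep",
    "TraceFamily",
    "effective_v_half",
    "steady_state_open_prob",
    "tau_act_model",
    "zn_unblocked_fraction",
    "simulate_family",
    "simulate_tail_family",
    "simulate_cation_substitution",
]


@dataclass(frozen=True)
class GatingParams:
    """ΔpH-shifted Boltzmann/kinetic parameterization of the channel.

    Defaults are calibrated so that, at symmetric pH, the voltage at 10% of
    maximal conductance sits near +46 mV, the gating position moves 40 mV
    per unit pH (saturating above pH 8), and 100 µM Zn²⁺ blocks 63% of the
    current (Ki back-computed as 100·0.37/0.63 ≈ 58.7 µM).
    """

    v_half_dpH0_mV: float = 68.0
    slope_k_mV: float = 10.0
    shift_mV_per_pH: float = 40.0
    pH_saturation: float = 8.0
    g_max_nS: float = 10.0
    tau0_ms: float = 200.0
    k_tau_mV: float = 10.0
    tau_deact_ms: float = 50.0
    tau_floor_ms: float = 1.0
    zn_ki_uM: float = 58.73
    zn_hill: float = 1.0
    #: if True, pH saturates smoothly along a titration curve instead of a
    #: hard clamp at ``pH_saturation``.
    smooth_saturation: bool = False

    def __post_init__(self) -> None:
        for name in ("slope_k_mV", "g_max_nS", "tau0_ms", "k_tau_mV",
                     "tau_deact_ms", "tau_floor_ms", "zn_ki_uM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class VoltageProtocol:
    """Episodic step protocol: hold, depolarizing step, repolarizing tail.

    ``tail_voltages_mV`` (if given) overrides ``tail_mV`` sweep-by-sweep and
    turns the protocol into a tail scan with a fixed activating prepulse.
    """

    holding_mV: float = -60.0
    step_start_mV: float = -40.0
    step_stop_mV: float = 100.0
    step_increment_mV: float = 10.0
    step_duration_ms: float = 400.0
    tail_mV: Optional[float] = None  # defaults to holding
    tail_duration_ms: float = 150.0
    sample_interval_ms: float = 0.5
    tail_voltages_mV: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.step_increment_mV == 0:
            raise ValueError("step_increment_mV must be nonzero")
        for name in ("step_duration_ms", "tail_duration_ms", "sample_interval_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tail_mV is None:
            object.__setattr__(self, "tail_mV", self.holding_mV)
        if self.tail_voltages_mV is not None:
            object.__setattr__(
                self, "tail_voltages_mV", tuple(float(v) for v in self.tail_voltages_mV)
            )
            if len(self.tail_voltages_mV) < 2:
                raise ValueError("tail scan needs >= 2 tail voltages")
        elif len(self.step_voltages()) < 2:
            raise ValueError("protocol must contain >= 2 steps")

    def step_voltages(self) -> np.ndarray:
        """Command voltages of the step segment, one per sweep."""
        if self.tail_voltages_mV is not None:
            return np.full(len(self.tail_voltages_mV), self.step_start_mV)
        n = int(math.floor(
            (self.step_stop_mV - self.step_start_mV) / self.step_increment_mV + 1e-9
        )) + 1
        return self.step_start_mV + self.step_increment_mV * np.arange(max(n, 0))

    def tail_voltages(self) -> np.ndarray:
        if self.tail_voltages_mV is not None:
            return np.asarray(self.tail_voltages_mV, dtype=float)
        return np.full(len(self.step_voltages()), float(self.tail_mV))

    def time_base(self) -> np.ndarray:
        """Shared sample times (ms), t = 0 at step onset; the tail segment
        starts at ``step_duration_ms``."""
        total = self.step_duration_ms + self.tail_duration_ms
        n = int(round(total / self.sample_interval_ms))
        return np.arange(n) * self.sample_interval_ms

    @classmethod
    def tail_scan(cls, prepulse_mV: float, tail_voltages_mV: Sequence[float],
                  **kwargs) -> "VoltageProtocol":
        """Protocol with a fixed activating prepulse and varied tails."""
        return cls(step_start_mV=prepulse_mV, step_stop_mV=prepulse_mV,
                   tail_voltages_mV=tuple(tail_voltages_mV), **kwargs)


@dataclass(frozen=True)
class NoiseModel:
    """Recording artifacts: additive Gaussian noise, ohmic leak, and an
    optional gated contaminant (non-proton) conductance."""

    sigma_pA: float = 0.0
    leak_g_nS: float = 0.0
    leak_erev_mV: float = 0.0
    contaminant_g_nS: float = 0.0
    contaminant_erev_mV: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_pA", "leak_g_nS", "contaminant_g_nS"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Sweep:
    """One episodic sweep: step then tail, on the family's shared time base.

    Voltages are *command* voltages; ``step_duration_ms`` marks the tail
    onset within ``time_ms``.
    """

    step_mV: float
    tail_mV: float
    time_ms: np.ndarray
    current_pA: np.ndarray
    step_duration_ms: float

    @property
    def step_mask(self) -> np.ndarray:
        return self.time_ms < self.step_duration_ms

    @property
    def tail_mask(self) -> np.ndarray:
        return ~self.step_mask


@dataclass
class TraceFamily:
    """A family of sweeps over a step protocol plus its full provenance."""

    conditions: SolutionConditions
    protocol: VoltageProtocol
    sweeps: list
    gating: GatingParams
    noise: NoiseModel


# ---------------------------------------------------------------------------
# channel model
# ---------------------------------------------------------------------------

def _effective_pH(pH: float, gating: GatingParams) -> float:
    """pH as seen by the gating machinery; saturates above ``pH_saturation``."""
    if gating.smooth_saturation:
        # titration-curve soft clamp: approaches pH_saturation asymptotically
        return -math.log10(10.0 ** (-pH) + 10.0 ** (-gating.pH_saturation))
    return min(pH, gating.pH_saturation)


def effective_v_half(conditions: SolutionConditions, gating: GatingParams) -> float:
    """Boltzmann midpoint after the ΔpH shift (mV): moves negative with
    increasing pH_o and positive with increasing pH_i, 40 mV/unit by default,
    saturating above pH 8."""
    d = _effective_pH(conditions.pH_o, gating) - _effective_pH(conditions.pH_i, gating)
    return gating.v_half_dpH0_mV - gating.shift_mV_per_pH * d


def steady_state_open_prob(V, conditions: SolutionConditions,
                           gating: GatingParams):
    """Steady-state open probability p∞(V), a single Boltzmann."""
    v_half = effective_v_half(conditions, gating)
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, dtype=float) - v_half)
                               / gating.slope_k_mV))


def tau_act_model(V, conditions: SolutionConditions, gating: GatingParams):
    """Activation time constant τ(V) in ms: ``tau0`` at the effective
    midpoint, falling e-fold per ``k_tau_mV`` of depolarization, clamped
    below at ``tau_floor_ms``. pH shifts τ–V along the voltage axis exactly
    as it shifts p∞."""
    v_half = effective_v_half(conditions, gating)
    tau = gating.tau0_ms * np.exp(-(np.asarray(V, dtype=float) - v_half)
                                  / gating.k_tau_mV)
    return np.maximum(tau, gating.tau_floor_ms)


def zn_unblocked_fraction(zn_uM: float, gating: GatingParams) -> float:
    """Fraction of conductance remaining in Zn²⁺ (1:1 instantaneous block
    generalized by a Hill coefficient)."""
    if zn_uM < 0:
        raise ValueError("zn_uM must be >= 0")
    if zn_uM == 0:
        return 1.0
    return 1.0 / (1.0 + (zn_uM / gating.zn_ki_uM) ** gating.zn_hill)


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------

def _relax_tau(v_from: float, v_to: float, conditions, gating) -> float:
    """Relaxation time constant for a voltage transition: activation kinetics
    when depolarizing, the (unquantified, free-default) deactivation constant
    when repolarizing."""
    if v_to > v_from:
        return float(tau_act_model(v_to, conditions, gating))
    return gating.tau_deact_ms


def simulate_family(protocol: VoltageProtocol, conditions: SolutionConditions,
                    gating: GatingParams, noise: NoiseModel) -> TraceFamily:
    """Simulate one episodic family.

    The open probability relaxes single-exponentially from its value at the
    prior voltage toward p∞(V); current is
    ``I = zn·p·(g_max·(V-E_H) + g_cont·(V-E_cont)) + g_leak·(V-E_leak) + noise``.
    Deterministic given ``noise.seed``.

    Raises ``ValueError`` if the sample interval exceeds one fifth of the
    fastest activation time constant in the protocol (undersampling).
    """
    jp = conditions.junction_potential_mV
    v_steps_cmd = protocol.step_voltages()
    v_tails_cmd = protocol.tail_voltages()
    if len(v_steps_cmd) == 0:
        raise ValueError("protocol yields no steps")

    v_hold = protocol.holding_mV - jp
    v_steps = v_steps_cmd - jp
    v_tails = v_tails_cmd - jp

    depol = v_steps[v_steps > v_hold]
    if depol.size:
        tau_min = float(np.min(tau_act_model(depol, conditions, gating)))
        if protocol.sample_interval_ms > tau_min / 5.0:
            raise ValueError(
                f"sample_interval_ms={protocol.sample_interval_ms} undersamples "
                f"the fastest activation time constant ({tau_min:.3g} ms); "
                f"need <= {tau_min / 5.0:.3g} ms"
            )

    e_h = nernst_potential(conditions)
    zn = zn_unblocked_fraction(conditions.zn_uM, gating)
    t = protocol.time_base()
    step_mask = t < protocol.step_duration_ms
    t_step = t[step_mask]
    t_tail = t[~step_mask] - protocol.step_duration_ms

    rng = np.random.default_rng(noise.seed)
    p_hold = float(steady_state_open_prob(v_hold, conditions, gating))

    sweeps = []
    for v_step, v_tail, v_step_cmd, v_tail_cmd in zip(
            v_steps, v_tails, v_steps_cmd, v_tails_cmd):
        p_inf_step = float(steady_state_open_prob(v_step, conditions, gating))
        tau_step = _relax_tau(v_hold, v_step, conditions, gating)
        p_step = p_inf_step + (p_hold - p_inf_step) * np.exp(-t_step / tau_step)
        p_end = p_inf_step + (p_hold - p_inf_step) * math.exp(
            -protocol.step_duration_ms / tau_step)

        p_inf_tail = float(steady_state_open_prob(v_tail, conditions, gating))
        tau_tail = _relax_tau(v_step, v_tail, conditions, gating)
        p_tail = p_inf_tail + (p_end - p_inf_tail) * np.exp(-t_tail / tau_tail)

        i = np.empty_like(t)
        for seg_mask, p_seg, v in ((step_mask, p_step, v_step),
                                   (~step_mask, p_tail, v_tail)):
            gated = zn * p_seg * (
                gating.g_max_nS * (v - e_h)
                + noise.contaminant_g_nS * (v - noise.contaminant_erev_mV)
            )
            i[seg_mask] = gated + noise.leak_g_nS * (v - noise.leak_erev_mV)
        if noise.sigma_pA > 0:
            i = i + rng.normal(0.0, noise.sigma_pA, size=i.shape)

        sweeps.append(Sweep(step_mV=float(v_step_cmd), tail_mV=float(v_tail_cmd),
                            time_ms=t.copy(), current_pA=i,
                            step_duration_ms=protocol.step_duration_ms))

    return TraceFamily(conditions=conditions, protocol=protocol,
                       sweeps=sweeps, gating=gating, noise=noise)


def simulate_tail_family(conditions: SolutionConditions, gating: GatingParams,
                         noise: NoiseModel, prepulse_mV: float,
                         tail_voltages_mV: Sequence[float],
                         step_duration_ms: float = 400.0,
                         tail_duration_ms: float = 150.0,
                         sample_interval_ms: float = 0.5,
                         holding_mV: float = -60.0) -> TraceFamily:
    """Tail-scan family: fixed activating prepulse, varied repolarization
    levels — the protocol used to bracket the reversal potential."""
    protocol = VoltageProtocol.tail_scan(
        prepulse_mV, tail_voltages_mV, holding_mV=holding_mV,
        step_duration_ms=step_duration_ms, tail_duration_ms=tail_duration_ms,
        sample_interval_ms=sample_interval_ms)
    return simulate_family(protocol, conditions, gating, noise)


def simulate_cation_substitution(conditions: SolutionConditions,
                                 gating: GatingParams, noise: NoiseModel,
                                 protocol: VoltageProtocol,
                                 substitute_cation: Cation = Cation.NA,
                                 substitute_junction_mV: float = 0.0,
                                 substitute_contaminant_erev_mV: Optional[float] = None,
                                 ) -> tuple:
    """Simulate the bath-cation substitution experiment: the same family in
    the reference (TMA⁺) solution and in a substituted solution.

    With ``contaminant_g_nS == 0`` the two families differ only by noise
    realization and junction-potential metadata; a nonzero contaminant whose
    reversal shifts between solutions emulates imperfect selectivity.
    """
    fam_ref = simulate_family(protocol, conditions, gating, noise)
    cond_sub = replace(conditions, main_cation=substitute_cation,
                       junction_potential_mV=substitute_junction_mV)
    noise_sub = replace(noise, seed=noise.seed + 1)
    if substitute_contaminant_erev_mV is not None:
        noise_sub = replace(noise_sub,
                            contaminant_erev_mV=substitute_contaminant_erev_mV)
    fam_sub = simulate_family(protocol, cond_sub, gating, noise_sub)
    return fam_ref, fam_sub
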