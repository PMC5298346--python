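"""Per-family trace analysis: single-exponential fitting, tail-current
measurement, reversal-potential estimation, and conductance-voltage
construction.

All analysis operates on *corrected* voltages: the metadata junction
potential is subtracted from every command voltage before use. No leak
subtraction is performed by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .biophysics import nernst_potential
from .simulate import Sweep, TraceFamily

__all__ = [
    "ExpFit",
    "RevPotentialEstimate",
    "GVCurve",
    "VrevMethod",
    "UnbracketedReversalError",
    "NearReversalError",
    "NoActivatedConductanceError",
    "fit_single_exponential",
    "measure_tail_amplitude",
    "estimate_vrev_from_tails",
    "estimate_vrev_direct",
    "chord_conductance",
    "gh_from_tail",
    "build_gv_curve",
    "tau_v_curve",
]


class UnbracketedReversalError(ValueError):
    """No sign change across the probed voltages: reversal not bracketed."""


class NearReversalError(ValueError):
    """Driving force below the guard: chord conductance ill-conditioned."""


class NoActivatedConductanceError(ValueError):
    """Family contains no activated conductance (g_max <= 0)."""


class VrevMethod(str, Enum):
    TAILS = "tails"
    DIRECT_FAMILY = "direct_family"


@dataclass
class ExpFit:
    """Result of fitting I(t) = C + A·(1 - exp(-t/τ)) to a step segment.

    ``C + A`` is the steady-state current extrapolated to infinite time.
    """

    amplitude_pA: float
    tau_ms: float
    baseline_pA: float
    fit_start_ms: float
    rmse_pA: float
    converged: bool
    message: str = ""

    @property
    def steady_state_pA(self) -> float:
        return self.baseline_pA + self.amplitude_pA


@dataclass
class RevPotentialEstimate:
    vrev_mV: float
    method: VrevMethod
    bracket_mV: Tuple[float, float]
    e_h_mV: float

    @property
    def deviation_mV(self) -> float:
        return self.vrev_mV - self.e_h_mV


@dataclass
class GVCurve:
    """Chord-conductance points, their maximum, and the voltage at which the
    normalized conductance crosses 10% on the rising limb."""

    points: List[Tuple[float, float]]
    gh_max_nS: float
    v_at_10pct_mV: Optional[float]

    @property
    def normalized(self) -> List[Tuple[float, float]]:
        return [(v, g / self.gh_max_nS) for v, g in self.points]


# ---------------------------------------------------------------------------
# exponential fitting (variable projection over tau; C, A solved linearly)
# ---------------------------------------------------------------------------

def _varpro_exp(t: np.ndarray, y: np.ndarray, sign: float,
                tau_lo: float, tau_hi: float):
    """Least-squares fit of y = C + A·phi(t; tau) where phi is
    ``1 - exp(-t/tau)`` (sign=+1, rising) or ``exp(-t/tau)`` (sign=-1,
    decaying). tau is profiled out on a log grid + Brent polish; (C, A)
    solve linearly at each tau. Returns (C, A, tau, rmse)."""

    def coeffs(tau: float):
        if sign > 0:
            phi = 1.0 - np.exp(-t / tau)
        else:
            phi = np.exp(-t / tau)
        basis = np.column_stack([np.ones_like(t), phi])
        sol, *_ = np.linalg.lstsq(basis, y, rcond=None)
        resid = y - basis @ sol
        return sol[0], sol[1], float(resid @ resid)

    def sse_log(log_tau: float) -> float:
        return coeffs(math.exp(log_tau))[2]

    # coarse log grid avoids Brent landing in a shallow local minimum
    grid = np.linspace(math.log(tau_lo), math.log(tau_hi), 40)
    sse = [sse_log(g) for g in grid]
    k = int(np.argmin(sse))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(sse_log, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    tau = math.exp(res.x)
    c, a, sse_min = coeffs(tau)
    rmse = math.sqrt(sse_min / len(t))
    return c, a, tau, rmse


def fit_single_exponential(sweep: Sweep, window_start_ms: float = 2.0,
                           window_end_ms: Optional[float] = None,
                           noise_floor_factor: float = 3.0) -> ExpFit:
    """Fit a single rising exponential to the step segment of a sweep.

    Time is measured from step onset, so ``baseline + amplitude`` is the
    current extrapolated to infinite time. A flat or failed fit returns
    ``converged=False`` with a diagnostic instead of raising; a window with
    fewer than 20 samples, or extending outside the step segment, raises.
    """
    if window_end_ms is None:
        window_end_ms = sweep.step_duration_ms
    if window_end_ms > sweep.step_duration_ms + 1e-9:
        raise ValueError("fit window extends past the step segment")
    mask = (sweep.time_ms >= window_start_ms) & (sweep.time_ms < window_end_ms)
    t = sweep.time_ms[mask]
    y = sweep.current_pA[mask]
    if len(t) < 20:
        raise ValueError(f"fit window contains {len(t)} samples; need >= 20")

    span = window_end_ms - window_start_ms
    if float(np.std(y)) == 0.0:
        return ExpFit(amplitude_pA=0.0, tau_ms=float("nan"),
                      baseline_pA=float(y[0]), fit_start_ms=window_start_ms,
                      rmse_pA=0.0, converged=False, message="flat trace")
    dt = float(t[1] - t[0])
    try:
        c, a, tau, rmse = _varpro_exp(t, y, sign=+1.0,
                                      tau_lo=dt / 10.0, tau_hi=100.0 * span)
    except Exception as exc:  # pragma: no cover - defensive
        return ExpFit(amplitude_pA=0.0, tau_ms=float("nan"), baseline_pA=0.0,
                      fit_start_ms=window_start_ms, rmse_pA=float("nan"),
                      converged=False, message=f"optimizer failure: {exc}")

    converged = True
    message = ""
    if tau > 50.0 * span:
        converged, message = False, "tau exceeds 50x window length"
    elif abs(a) < noise_floor_factor * rmse:
        converged, message = False, "amplitude below noise floor"
    return ExpFit(amplitude_pA=float(a), tau_ms=float(tau),
                  baseline_pA=float(c), fit_start_ms=window_start_ms,
                  rmse_pA=rmse, converged=converged, message=message)


def measure_tail_amplitude(sweep: Sweep, settle_ms: float = 2.0) -> float:
    """Amplitude (pA, sign preserved) of the exponential relaxation in the
    tail segment, extrapolated back to the repolarization instant.

    Fitting starts ``settle_ms`` after repolarization; a tail shorter than
    3x the settle window is unusable and raises."""
    tail_mask = sweep.tail_mask
    if not tail_mask.any():
        raise ValueError("sweep has no tail segment")
    t_tail = sweep.time_ms[tail_mask] - sweep.step_duration_ms
    y_tail = sweep.current_pA[tail_mask]
    tail_len = float(t_tail[-1]) if len(t_tail) else 0.0
    if tail_len < 3.0 * settle_ms:
        raise ValueError(
            f"tail ({tail_len:.1f} ms) shorter than 3x settle window "
            f"({settle_ms} ms): unusable tail")
    mask = t_tail >= settle_ms
    t = t_tail[mask]
    y = y_tail[mask]
    if float(np.std(y)) == 0.0:
        return 0.0
    dt = float(t[1] - t[0])
    _, a, _, _ = _varpro_exp(t, y, sign=-1.0, tau_lo=dt / 10.0,
                             tau_hi=100.0 * tail_len)
    return float(a)


# ---------------------------------------------------------------------------
# reversal potential
# ---------------------------------------------------------------------------

def _interp_zero_crossing(v: np.ndarray, a: np.ndarray):
    """Zero crossing of a(v) by linear interpolation; exact zeros win.
    Returns (v_zero, (v_lo, v_hi)) or None."""
    exact = np.flatnonzero(a == 0.0)
    if exact.size:
        i = int(exact[0])
        return float(v[i]), (float(v[i]), float(v[i]))
    for i in range(len(v) - 1):
        if a[i] * a[i + 1] < 0:
            frac = -a[i] / (a[i + 1] - a[i])
            return (float(v[i] + frac * (v[i + 1] - v[i])),
                    (float(v[i]), float(v[i + 1])))
    return None


def estimate_vrev_from_tails(family: TraceFamily,
                             settle_ms: float = 2.0) -> RevPotentialEstimate:
    """Reversal potential from the direction and amplitude of tail-current
    relaxation over a range of tail voltages, following a fixed activating
    prepulse. Junction correction is applied before interpolation."""
    jp = family.conditions.junction_potential_mV
    pairs = []
    for sw in family.sweeps:
        amp = measure_tail_amplitude(sw, settle_ms=settle_ms)
        pairs.append((sw.tail_mV - jp, amp))
    pairs.sort()
    v = np.array([p[0] for p in pairs])
    a = np.array([p[1] for p in pairs])
    hit = _interp_zero_crossing(v, a)
    if hit is None:
        raise UnbracketedReversalError(
            "tail amplitudes do not change sign: unbracketed reversal")
    vrev, bracket = hit
    e_h = nernst_potential(family.conditions)
    return RevPotentialEstimate(vrev_mV=vrev, method=VrevMethod.TAILS,
                                bracket_mV=bracket, e_h_mV=e_h)


def estimate_vrev_direct(family: TraceFamily, window_start_ms: float = 2.0,
                         ) -> RevPotentialEstimate:
    """Reversal potential interpolated from the zero crossing of the
    extrapolated steady-state current versus step voltage; usable when the
    conductance activates negative to the reversal potential."""
    jp = family.conditions.junction_potential_mV
    pts = []
    for sw in family.sweeps:
        fit = fit_single_exponential(sw, window_start_ms=window_start_ms)
        if fit.converged:
            pts.append((sw.step_mV - jp, fit.steady_state_pA))
    if len(pts) < 2:
        raise UnbracketedReversalError(
            "fewer than two activated sweeps: unbracketed reversal")
    pts.sort()
    v = np.array([p[0] for p in pts])
    i_ss = np.array([p[1] for p in pts])
    hit = _interp_zero_crossing(v, i_ss)
    if hit is None:
        raise UnbracketedReversalError(
            "steady-state currents do not change sign: unbracketed reversal")
    vrev, bracket = hit
    e_h = nernst_potential(family.conditions)
    return RevPotentialEstimate(vrev_mV=vrev, method=VrevMethod.DIRECT_FAMILY,
                                bracket_mV=bracket, e_h_mV=e_h)


# ---------------------------------------------------------------------------
# conductance
# ---------------------------------------------------------------------------

def chord_conductance(i_ss_pA: float, v_mV: float, vrev_mV: float,
                      guard_mV: float = 5.0) -> float:
    """g = I_ss / (V - V_rev) in nS; refuses voltages within ``guard_mV`` of
    the reversal potential, where the tail-based route must be used."""
    if abs(v_mV - vrev_mV) < guard_mV:
        raise NearReversalError(
            f"V={v_mV} mV is within {guard_mV} mV of V_rev={vrev_mV:.1f} mV; "
            "near-reversal voltage; use tail-based gH")
    return i_ss_pA / (v_mV - vrev_mV)


def gh_from_tail(tail_amplitude_pA: float, v_tail_mV: float, vrev_mV: float,
                 v_step_mV: float, guard_mV: float = 5.0) -> float:
    """Conductance at the end of a step from its tail amplitude, scaled by
    the tail driving force; the route of choice for steps near V_rev."""
    if abs(v_tail_mV - vrev_mV) < guard_mV:
        raise NearReversalError(
            f"V_tail={v_tail_mV} mV is within {guard_mV} mV of V_rev; "
            "choose a tail level farther from reversal")
    return tail_amplitude_pA / (v_tail_mV - vrev_mV)


def build_gv_curve(family: TraceFamily, rev: RevPotentialEstimate,
                   window_start_ms: float = 2.0, settle_ms: float = 2.0,
                   guard_mV: float = 5.0) -> GVCurve:
    """Chord-conductance curve for one family.

    Per sweep: g from the extrapolated steady-state current (chord route);
    for steps within the guard of V_rev, fall back to the scaled tail
    amplitude. The 10% point is found by linear interpolation on the rising
    limb of the normalized curve; negative chords (noise) clamp to zero.
    """
    if len(family.sweeps) < 4:
        raise ValueError("need >= 4 analyzable sweeps for a g-V curve")
    jp = family.conditions.junction_potential_mV
    points = []
    for sw in family.sweeps:
        v = sw.step_mV - jp
        try:
            if abs(v - rev.vrev_mV) >= guard_mV:
                fit = fit_single_exponential(sw, window_start_ms=window_start_ms)
                if fit.converged:
                    i_ss = fit.steady_state_pA
                else:
                    step_i = sw.current_pA[sw.step_mask]
                    i_ss = float(np.mean(step_i[-max(len(step_i) // 10, 1):]))
                g = chord_conductance(i_ss, v, rev.vrev_mV, guard_mV=guard_mV)
            else:
                amp = measure_tail_amplitude(sw, settle_ms=settle_ms)
                g = gh_from_tail(amp, sw.tail_mV - jp, rev.vrev_mV, v,
                                 guard_mV=guard_mV)
        except NearReversalError:
            continue
        points.append((v, max(g, 0.0)))
    points.sort()
    if not points:
        raise NoActivatedConductanceError("no analyzable sweeps")
    g_arr = np.array([g for _, g in points])
    v_arr = np.array([v for v, _ in points])
    g_max = float(g_arr.max())
    if g_max <= 0.0:
        raise NoActivatedConductanceError("no activated conductance")

    v10 = _v_at_fraction(v_arr, g_arr / g_max, 0.10)
    return GVCurve(points=points, gh_max_nS=g_max, v_at_10pct_mV=v10)


def _v_at_fraction(v: np.ndarray, g_norm: np.ndarray,
                   frac: float) -> Optional[float]:
    """Voltage where the normalized conductance crosses ``frac`` on the
    rising limb (up to the curve maximum); exact ties return that voltage;
    the last upward crossing before the maximum wins."""
    k_max = int(np.argmax(g_norm))
    hit = None
    for i in range(k_max + 1):
        if g_norm[i] == frac:
            hit = float(v[i])
        elif i < k_max and g_norm[i] < frac <= g_norm[i + 1]:
            f = (frac - g_norm[i]) / (g_norm[i + 1] - g_norm[i])
            hit = float(v[i] + f * (v[i + 1] - v[i]))
    return hit


def tau_v_curve(family: TraceFamily,
                window_start_ms: float = 2.0) -> List[Tuple[float, float]]:
    """(V, τ_act) pairs from converged single-exponential fits, ordered by
    corrected voltage. Sweeps without a resolvable time-dependent component
    are simply omitted."""
    jp = family.conditions.junction_potential_mV
    out = []
    for sw in family.sweeps:
        fit = fit_single_exponential(sw, window_start_ms=window_start_ms)
        if fit.converged:
            out.append((sw.step_mV - jp, fit.tau_ms))
    out.sort()
    return out
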