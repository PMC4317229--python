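"""Regimen simulation and exposure metrics.

Dose events are handled by integration restarts: the ODE system is solved
piecewise between event times with a stiff-capable solver (LSODA,
rtol 1e-8 / atol 1e-10 nmol/L by default), applying IV boluses to the
central compartment and SC amounts to the depot at each restart.

A batched population solver stacks individuals that share a dose/observation
schedule into one ODE system; it backs the synthetic-data generator, the
VPC, and the population estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import models
from .models import ModelVariant, PKParameters
from .units import DEFAULT_DRUG, DrugProperties, Regimen, Route, molar_to_mass

__all__ = [
    "SimulatedProfile",
    "ExposureMetrics",
    "simulate_profile",
    "solve_population",
    "exposure_metrics",
    "time_above_threshold",
    "nca_bioavailability",
    "terminal_half_life_linear",
]

DAYS_PER_MONTH = 30.4375
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SolverError(RuntimeError):
    """ODE integration failure, carrying the last successful time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful time: {last_time:g} d)")
        self.last_time = last_time


@dataclass
class SimulatedProfile:
    """Deterministic concentration–time trajectory for one subject.

    ``c_free``/``c_total`` are in nmol/L on ``times`` (days); the free
    concentration is the model-observed quantity.  ``dose_times`` mark the
    dosing-interval boundaries.
    """

    times: np.ndarray
    c_free: np.ndarray
    c_total: np.ndarray
    dose_times: tuple[float, ...]
    variant: ModelVariant
    drug: DrugProperties = DEFAULT_DRUG

    @property
    def c_free_ugml(self) -> np.ndarray:
        return molar_to_mass(self.c_free, self.drug)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: time [d], free conc [µg/mL], total conc [nM]."""
        return pd.DataFrame(
            {
                "time_days": self.times,
                "c_free_ug_per_mL": self.c_free_ugml,
                "c_total_nM": self.c_total,
            }
        )

    def at(self, t) -> np.ndarray:
        """Free concentration (nmol/L) linearly interpolated at times t."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.c_free)


@dataclass
class ExposureMetrics:
    """NCA-style exposure summary in reporting units (µg/mL, µg·h/mL)."""

    cmax: float
    tmax: float
    auc_0_last: float
    auc_0_inf: Optional[float]
    terminal_half_life: Optional[float]
    auc_tau: Optional[float] = None
    tau_interval: Optional[tuple[float, float]] = None


def _variant_info(variant: ModelVariant):
    variant = ModelVariant(variant)
    if variant in (ModelVariant.QE, ModelVariant.QSS, ModelVariant.LINEAR):
        return 3, models.make_qe_rhs_batch
    if variant is ModelVariant.MM:
        return 3, models.make_mm_rhs_batch
    return 5, models.make_full_rhs_batch


def solve_population(
    params_list: Sequence[PKParameters],
    dose_times: Sequence[float],
    amounts_mg: np.ndarray,
    routes: Sequence[Route | str],
    eval_times: Sequence[float],
    variant: ModelVariant | str = ModelVariant.QE,
    cl_multipliers: Optional[np.ndarray] = None,
    cl_switch_times: Optional[np.ndarray] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    drug: DrugProperties = DEFAULT_DRUG,
):
    """Solve the model for n individuals sharing an event schedule.

    Parameters
    ----------
    params_list : individual parameter sets (length n).
    dose_times : shared dose times (days).
    amounts_mg : array (n, n_doses) or (n_doses,) of absolute amounts.
    routes : route per dose event (shared across individuals).
    eval_times : output grid (days), non-decreasing.
    cl_multipliers, cl_switch_times : optional per-individual fold-increase
        of linear clearance from an individual-specific switch time onward
        (empirical ADA effect).

    Returns
    -------
    (c_free, c_total) : arrays (n, len(eval_times)) in nmol/L.
    """
    variant = ModelVariant(variant)
    n = len(params_list)
    pa = models.params_to_arrays(params_list)
    if variant is ModelVariant.LINEAR:
        pa = dict(pa)
        pa["rtot"] = np.zeros(n)
    elif variant is ModelVariant.MM and not {"vmax", "km"} <= pa.keys():
        raise ValueError("MM variant requires vmax and km on every individual")
    elif variant is ModelVariant.FULL and not {"kon", "koff", "ksyn", "kdeg"} <= pa.keys():
        raise ValueError("FULL variant requires kon, koff, ksyn and kdeg")
    nstate, rhs_factory = _variant_info(variant)

    eval_times = np.asarray(eval_times, dtype=float)
    dose_times = [float(t) for t in dose_times]
    routes = [Route(r) for r in routes]
    amounts = np.atleast_1d(np.asarray(amounts_mg, dtype=float))
    if amounts.ndim == 1:
        amounts = np.broadcast_to(amounts, (n, len(dose_times))).copy()
    amounts_nmol = amounts * 1e6 / drug.molecular_weight

    events: set[float] = set(dose_times)
    if cl_switch_times is not None:
        events.update(float(t) for t in np.atleast_1d(cl_switch_times))
    t_end = float(eval_times[-1]) if len(eval_times) else max(events, default=0.0)
    event_list = sorted(t for t in events if t <= t_end)

    y = np.zeros(nstate * n)
    vc_l = pa["vc"] / 1000.0
    if variant is ModelVariant.FULL:
        y = y.reshape(5, n)
        y[2] = pa["ksyn"] / np.maximum(pa["kdeg"], 1e-300)
        y = y.ravel()

    base_cl_l = pa["cl"] / 1000.0

    def cl_at(t0: float) -> np.ndarray:
        if cl_multipliers is None or cl_switch_times is None:
            return base_cl_l
        switched = t0 >= np.asarray(cl_switch_times, dtype=float) - 1e-12
        return base_cl_l * np.where(switched, np.asarray(cl_multipliers, float), 1.0)

    out_free = np.zeros((n, len(eval_times)))
    out_total = np.zeros((n, len(eval_times)))
    filled = np.zeros(len(eval_times), dtype=bool)

    def record(idx_mask, y_now):
        ys = y_now.reshape(nstate, n)
        if variant is ModelVariant.FULL:
            cf = ys[1]
            ct = ys[1] + ys[3]
        elif variant is ModelVariant.MM or variant is ModelVariant.LINEAR:
            cf = ys[1]
            ct = ys[1]
        else:
            ct = np.maximum(ys[1], 0.0)
            cf = models._free_conc(ct, pa["rtot"], pa["kd"])
        for j in np.nonzero(idx_mask)[0]:
            out_free[:, j] = np.maximum(cf, 0.0)
            out_total[:, j] = np.maximum(ct, 0.0)
            filled[j] = True

    # walk segments between events
    seg_bounds = sorted(set(event_list + [0.0, t_end]))
    t_cursor = 0.0
    # apply any events at t=0 first
    def apply_doses(t0, y_flat):
        ys = y_flat.reshape(nstate, n)
        for k, td in enumerate(dose_times):
            if abs(td - t0) < 1e-12:
                if routes[k] is Route.IV:
                    ys[1] += amounts_nmol[:, k] / vc_l
                else:
                    ys[0] += amounts_nmol[:, k]
        return ys.ravel()

    y = apply_doses(0.0, y)
    record(np.isclose(eval_times, 0.0), y)

    for t_next in seg_bounds:
        if t_next <= t_cursor:
            continue
        mask = (eval_times > t_cursor + 1e-12) & (eval_times <= t_next + 1e-12)
        t_eval = np.clip(eval_times[mask], t_cursor, t_next)
        cl_l = cl_at(t_cursor)
        sol = solve_ivp(
            rhs_factory(pa, cl_l),
            (t_cursor, t_next),
            y,
            method="LSODA",
            t_eval=np.unique(np.concatenate([t_eval, [t_next]])),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverError(sol.message, t_cursor)
        # record requested points inside the segment (pre-dose at t_next)
        for tt, yy in zip(sol.t, sol.y.T):
            m = np.isclose(eval_times, tt) & mask
            if m.any():
                record(m, yy)
        y = sol.y[:, -1]
        t_cursor = t_next
        y = apply_doses(t_cursor, y)
        # post-dose value at an event time overrides the pre-dose record
        m_at = np.isclose(eval_times, t_cursor)
        if m_at.any():
            record(m_at, y)

    if not filled.all():
        record(~filled, y)  # times beyond last segment (should not happen)
    return out_free, out_total


def _default_grid(t_end: float, dose_times: Sequence[float]) -> np.ndarray:
    """Dense output grid: 20 points/day in the first week, 2/day after,
    refined just after each dose to capture Cmax."""
    pts = [np.arange(0.0, min(7.0, t_end) + 1e-9, 0.05)]
    if t_end > 7.0:
        pts.append(np.arange(7.0, t_end + 1e-9, 0.5))
    post = np.array([0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0])
    for td in dose_times:
        pts.append(np.clip(td + post, 0.0, t_end))
        pts.append([min(td, t_end)])
    pts.append([t_end])
    grid = np.unique(np.concatenate([np.atleast_1d(p) for p in pts]))
    return grid[grid <= t_end + 1e-12]


def simulate_profile(
    p: PKParameters,
    regimen: Regimen,
    variant: ModelVariant | str = ModelVariant.QE,
    horizon: Optional[float] = None,
    dense: bool = True,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    drug: DrugProperties = DEFAULT_DRUG,
    cl_multiplier: Optional[float] = None,
    cl_switch_time: Optional[float] = None,
) -> SimulatedProfile:
    """Solve one subject's regimen and return the trajectory.

    The output grid is the union of a dense default grid (when ``dense``)
    with the regimen's observation times and dose times.  ``horizon``
    extends the simulation beyond the last scheduled time (e.g. 18 months
    for single-dose human runs so that low occupancy-threshold crossings
    are captured).
    """
    dose_times = list(regimen.dose_times)
    obs = np.asarray(regimen.observation_times, dtype=float)
    t_end = max(
        [horizon or 0.0]
        + list(obs[-1:])
        + ([max(dose_times) + 1.0] if dose_times else [1.0])
    )
    if dense:
        grid = _default_grid(t_end, dose_times)
        grid = np.unique(np.concatenate([grid, obs, np.asarray(dose_times)]))
    else:
        grid = np.unique(np.concatenate([obs, np.asarray(dose_times, dtype=float)]))
    amounts = np.array([[d.amount for d in regimen.doses]])
    routes = [d.route for d in regimen.doses]
    cf, ct = solve_population(
        [p],
        dose_times,
        amounts,
        routes,
        grid,
        variant=variant,
        cl_multipliers=None if cl_multiplier is None else np.array([cl_multiplier]),
        cl_switch_times=None if cl_switch_time is None else np.array([cl_switch_time]),
        rtol=rtol,
        atol=atol,
        drug=drug,
    )
    return SimulatedProfile(
        times=grid,
        c_free=cf[0],
        c_total=ct[0],
        dose_times=tuple(dose_times),
        variant=ModelVariant(variant),
        drug=drug,
    )


def _terminal_slope(times: np.ndarray, conc: np.ndarray) -> tuple[float, float]:
    """Log-linear fit over the terminal tail: last 10% of the simulated
    span or the last 5 positive points, whichever covers more points.
    Returns (lambda_z, intercept) with conc ≈ exp(intercept - lambda_z*t)."""
    pos = conc > 0
    if pos.sum() < 3:
        raise ValueError("not enough positive concentrations for terminal fit")
    t_pos, c_pos = times[pos], conc[pos]
    t_cut = t_pos[-1] - 0.10 * (t_pos[-1] - t_pos[0])
    tail = t_pos >= t_cut
    if tail.sum() < 5:
        tail = np.zeros_like(tail)
        tail[-min(5, len(t_pos)) :] = True
    slope, intercept = np.polyfit(t_pos[tail], np.log(c_pos[tail]), 1)
    return -slope, intercept


def exposure_metrics(
    profile: SimulatedProfile,
    mode: str = "to_infinity",
    interval_index: Optional[int] = None,
) -> ExposureMetrics:
    """Compute Cmax/Tmax/AUC from a simulated profile.

    AUC is trapezoidal on the dense grid, in µg·h/mL (the day-based
    integral times 24).  ``to_infinity`` extends the last point with the
    fitted terminal log-linear slope; ``per_interval`` with
    ``interval_index=k`` (1-based) integrates within the k-th dosing
    interval instead.
    """
    if len(profile.times) == 0:
        raise ValueError("empty profile")
    c = profile.c_free_ugml
    t = profile.times
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_last = float(np.trapezoid(c, t)) * 24.0

    auc_inf = None
    thalf = None
    auc_tau = None
    tau = None
    if mode == "to_infinity":
        lam, _ = _terminal_slope(t, c)
        if lam <= 0:
            raise ValueError("non-positive terminal slope: AUC0-inf is infinite")
        thalf = float(np.log(2.0) / lam)
        auc_inf = auc_last + float(c[c > 0][-1] / lam) * 24.0
    elif mode == "per_interval":
        if interval_index is None or interval_index < 1:
            raise ValueError("per_interval mode requires interval_index >= 1")
        dt = list(profile.dose_times)
        if interval_index > len(dt):
            raise ValueError("interval_index exceeds number of doses")
        t0 = dt[interval_index - 1]
        t1 = dt[interval_index] if interval_index < len(dt) else t[-1]
        sel = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
        auc_tau = float(np.trapezoid(c[sel], t[sel])) * 24.0
        tau = (float(t0), float(t1))
        i_m = int(np.argmax(np.where(sel, c, -np.inf)))
        cmax, tmax = float(c[i_m]), float(t[i_m])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ExposureMetrics(
        cmax=cmax,
        tmax=tmax,
        auc_0_last=auc_last,
        auc_0_inf=auc_inf,
        terminal_half_life=thalf,
        auc_tau=auc_tau,
        tau_interval=tau,
    )


def time_above_threshold(profile: SimulatedProfile, threshold_ugml: float) -> float:
    """Total time (days) the free concentration exceeds a threshold,
    with linear interpolation at the crossings.  Returns 0 when the
    profile never exceeds the threshold."""
    if threshold_ugml <= 0:
        raise ValueError("threshold must be positive")
    t = profile.times
    c = profile.c_free_ugml
    above = c > threshold_ugml
    total = 0.0
    for i in range(len(t) - 1):
        t0, t1, c0, c1 = t[i], t[i + 1], c[i], c[i + 1]
        if above[i] and above[i + 1]:
            total += t1 - t0
        elif above[i] != above[i + 1] and c1 != c0:
            frac = (threshold_ugml - c0) / (c1 - c0)
            tc = t0 + frac * (t1 - t0)
            total += (tc - t0) if above[i] else (t1 - tc)
    return float(total)


def nca_bioavailability(
    auc_sc: float, auc_iv: float, dose_sc: float, dose_iv: float
) -> float:
    """Relative bioavailability F = (AUC_sc/dose_sc) / (AUC_iv/dose_iv)."""
    if auc_iv <= 0 or dose_iv <= 0 or dose_sc <= 0 or auc_sc < 0:
        raise ValueError("AUCs and doses must be positive")
    return (auc_sc / dose_sc) / (auc_iv / dose_iv)


def terminal_half_life_linear(p: PKParameters) -> float:
    """Terminal half-life of the linear two-compartment system,
    t1/2 = ln2/beta with beta the slow eigenvalue:

    beta = 0.5*[(k10+k12+k21) - sqrt((k10+k12+k21)^2 - 4*k21*k10)],
    k10 = CL/Vc.
    """
    if p.cl <= 0 or p.vc <= 0 or p.k12 < 0 or p.k21 <= 0:
        raise ValueError("requires positive CL, Vc, K21 and non-negative K12")
    k10 = p.cl / p.vc
    s = k10 + p.k12 + p.k21
    disc = s * s - 4.0 * p.k21 * k10
    beta = 0.5 * (s - np.sqrt(max(disc, 0.0)))
    if beta <= 0:
        raise ValueError("degenerate parameters: beta <= 0")
    return float(np.log(2.0) / beta)
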