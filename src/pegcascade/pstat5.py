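"""Indirect-response model linking receptor occupancy to pSTAT5 signalling.

Engagement of either the dimeric or the trimeric receptor phosphorylates
STAT5, so the driver is the summed total occupancy scaled by the CD3+
fraction of lymphocytes (pSTAT5 is read out on CD3+ T cells, 40% of the
pool).  The biomarker follows a turnover equation with stimulation of
production:

    dP/dt = k_in * (1 + s_max * O / (o_50 + O)) - k_out * P

with baseline P(0) = k_in / k_out and ceiling baseline * (1 + s_max).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import lmfit
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from .cascade import OccupancyProfile, SimulationResult, occupancy_profiles


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class IndirectResponseParams:
    """Turnover parameters of the pSTAT5 response.

    k_in in %/h, k_out in 1/h, s_max unitless, o_50 in % driver occupancy.
    """

    k_in: float
    k_out: float
    s_max: float
    o_50: float

    def __post_init__(self) -> None:
        for name, v in (("k_in", self.k_in), ("k_out", self.k_out), ("s_max", self.s_max), ("o_50", self.o_50)):
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def baseline(self) -> float:
        return self.k_in / self.k_out

    @property
    def ceiling(self) -> float:
        return self.baseline * (1.0 + self.s_max)


@dataclass(frozen=True)
class EffectProfile:
    """% pSTAT5-positive CD3+ cells vs time."""

    times_h: np.ndarray
    percent_pstat5: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.percent_pstat5, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "percent_pstat5", v)
        if np.any(v < 0):
            raise ValueError("effect values must be >= 0")


def cd3_scaled_occupancy(result: SimulationResult, cd3_fraction: float | None = None,
                         trimer_denominator: str = "beta") -> OccupancyProfile:
    """Summed total occupancy (beta-gamma + alpha-beta-gamma) scaled to the
    CD3+ T-cell compartment; the driver of the response model."""
    if cd3_fraction is None:
        cd3_fraction = result.params.physiology.cd3_fraction
    occ = {(p.receptor, p.analyte): p for p in occupancy_profiles(result, trimer_denominator)}
    total = occ[("betagamma", "total")].percent_occupied + occ[("alphabetagamma", "total")].percent_occupied
    return OccupancyProfile(result.times_h, cd3_fraction * total, "summed_cd3", "total")


def simulate_pstat5(
    driver: OccupancyProfile,
    params: IndirectResponseParams,
    t_grid: np.ndarray | None = None,
    rtol: float = 1e-9,
) -> EffectProfile:
    """Integrate the turnover equation driven by an occupancy time course.

    The driver is linearly interpolated between its samples and held at its
    edge values outside them; the response starts at baseline.
    """
    if t_grid is None:
        t_grid = driver.times_h
    t_grid = np.asarray(t_grid, dtype=float)
    drv = interp1d(
        driver.times_h, np.clip(driver.percent_occupied, 0.0, None),
        bounds_error=False,
        fill_value=(driver.percent_occupied[0], driver.percent_occupied[-1]),
    )

    def rhs(t, y):
        o = float(drv(t))
        stim = params.s_max * o / (params.o_50 + o)
        return [params.k_in * (1.0 + stim) - params.k_out * y[0]]

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [params.baseline], t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=1e-12, max_step=1.0)
    if not sol.success:
        raise RuntimeError(f"pSTAT5 integration failed: {sol.message}")
    return EffectProfile(sol.t, sol.y[0])


def auec(effect: EffectProfile, window: tuple[float, float] | None = None,
         baseline: float | None = None) -> float:
    """Baseline-subtracted area under the effect curve (%.h).

    ``baseline`` defaults to the pre-dose value (first sample); an effect
    identically at baseline therefore gives 0.
    """
    t, v = effect.times_h, effect.percent_pstat5
    if baseline is None:
        baseline = float(v[0])
    if window is None:
        window = (float(t[0]), float(t[-1]))
    t0, t1 = window
    if not (t[0] <= t0 < t1 <= t[-1]):
        raise ValueError(f"window [{t0}, {t1}] outside effect span or empty")
    grid = np.unique(np.concatenate([t[(t >= t0) & (t <= t1)], [t0, t1]]))
    vals = np.interp(grid, t, v) - baseline
    return float(np.trapezoid(vals, grid))


def fit_pstat5(observed: EffectProfile, driver: OccupancyProfile,
               k_out_init: float = 0.1) -> tuple[IndirectResponseParams, dict]:
    """Least-squares estimate of (k_in, k_out, s_max, o_50) from an observed
    effect curve and its occupancy driver."""
    t, y = observed.times_h, observed.percent_pstat5
    if t.size < 6:
        raise FitError("need at least 6 time points to fit the response model")
    if float(np.ptp(y)) < 1e-9:
        raise FitError("flat effect data: response parameters not identifiable")
    drv_peak = float(np.max(driver.percent_occupied))
    if drv_peak <= 0:
        raise FitError("zero driver cannot explain a varying response")

    baseline0 = max(float(y[0]), 1e-3)
    smax0 = max(float(np.max(y)) / baseline0 - 1.0, 0.1)
    p = lmfit.Parameters()
    p.add("baseline", value=baseline0, min=1e-6)
    p.add("k_out", value=k_out_init, min=1e-4, max=50.0)
    p.add("s_max", value=smax0, min=1e-3, max=1e4)
    p.add("o_50", value=max(drv_peak / 2, 1e-3), min=1e-4, max=1e4)

    def residual(pars):
        irm = IndirectResponseParams(
            k_in=pars["baseline"].value * pars["k_out"].value,
            k_out=pars["k_out"].value,
            s_max=pars["s_max"].value,
            o_50=pars["o_50"].value,
        )
        return simulate_pstat5(driver, irm, t_grid=t).percent_pstat5 - y

    out = lmfit.minimize(residual, p, method="leastsq")
    if not out.success:
        raise FitError(f"response-model fit failed: {out.message}")
    fitted = IndirectResponseParams(
        k_in=out.params["baseline"].value * out.params["k_out"].value,
        k_out=out.params["k_out"].value,
        s_max=out.params["s_max"].value,
        o_50=out.params["o_50"].value,
    )
    pred = simulate_pstat5(driver, fitted, t_grid=t)
    return fitted, {
        "redchi": float(out.redchi),
        "peak_percent": float(np.max(pred.percent_pstat5)),
        "peak_time_h": float(t[int(np.argmax(pred.percent_pstat5))]),
    }
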