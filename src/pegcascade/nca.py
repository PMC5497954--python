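"""Non-compartmental pharmacokinetic analysis.

AUC uses the linear-log trapezoidal rule: linear trapezoids on rising or
equal segments and on any segment touching zero, logarithmic trapezoids
(C1-C2)*dt/ln(C1/C2) on strictly declining positive segments — exact for
exponential decay.  The terminal slope lambda_z comes from a log-linear
regression over the suffix of points (>= 3, Tmax excluded) that maximises
adjusted r-squared, the convention of standard NCA software.  Sparse
designs (n animals per time point) are collapsed to per-timepoint means
before analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade import ConcentrationProfile


class NCAError(RuntimeError):
    pass


@dataclass(frozen=True)
class PKParameters:
    """Standard NCA outputs for one concentration-time profile."""

    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float
    half_life: float | None
    mrt_inf: float | None
    lambda_z: float | None
    lambda_z_r_squared: float | None
    lambda_z_n_points: int | None
    lambda_z_quality_flag: bool = False

    def as_dict(self) -> dict:
        return {
            "Cmax": self.cmax,
            "Tmax": self.tmax,
            "AUClast": self.auc_last,
            "AUCinf": self.auc_inf,
            "t_half": self.half_life,
            "MRTinf": self.mrt_inf,
            "lambda_z": self.lambda_z,
            "lambda_z_r2": self.lambda_z_r_squared,
        }


def _check_profile(times, conc):
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.shape != c.shape or t.size < 2:
        raise NCAError("need matching 1-D arrays with at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise NCAError("times must be strictly increasing")
    if np.any(c < 0):
        raise NCAError("concentrations must be non-negative")
    return t, c


def _declining(c1, c2):
    return (c2 < c1) & (c2 > 0)


def auc_linlog(times, concentrations) -> float:
    """Area under the curve between the first and last sample."""
    t, c = _check_profile(times, concentrations)
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    dec = _declining(c1, c2)
    ratio = np.ones_like(c1)
    np.divide(c1, c2, out=ratio, where=dec)
    seg = np.where(dec, (c1 - c2) * dt / np.log(np.where(dec, ratio, math.e)), 0.5 * (c1 + c2) * dt)
    return float(np.sum(seg))


def aumc_linlog(times, concentrations) -> float:
    """Area under the first-moment curve t*C(t), using the interpolant
    matched to the AUC rule (exponential on declining positive segments)."""
    t, c = _check_profile(times, concentrations)
    dt = np.diff(t)
    t1, t2, c1, c2 = t[:-1], t[1:], c[:-1], c[1:]
    dec = _declining(c1, c2)
    ratio = np.ones_like(c1)
    np.divide(c1, c2, out=ratio, where=dec)
    lam = np.where(dec, np.log(np.where(dec, ratio, math.e)) / dt, 1.0)
    log_seg = (t1 * c1 - t2 * c2) / lam + (c1 - c2) / lam**2
    lin_seg = 0.5 * (t1 * c1 + t2 * c2) * dt
    return float(np.sum(np.where(dec, log_seg, lin_seg)))


def terminal_slope(times, concentrations, exclude_tmax: bool = True) -> tuple[float, float, int]:
    """Terminal elimination rate lambda_z (h^-1), its r^2, and the number of
    points used.

    Scans all suffixes of >= 3 positive post-Tmax concentrations and keeps
    the one with the highest adjusted r-squared.
    """
    t, c = _check_profile(times, concentrations)
    i_max = int(np.argmax(c))
    start_min = i_max + 1 if exclude_tmax else i_max
    usable = np.nonzero(c > 0)[0]
    usable = usable[usable >= start_min]
    if usable.size < 3:
        raise NCAError("fewer than 3 usable terminal points; t1/2 not reportable")
    t_u, c_u = t[usable], np.log(c[usable])

    best = None
    for s in range(t_u.size - 2):
        tt, yy = t_u[s:], c_u[s:]
        n = tt.size
        slope, intercept = np.polyfit(tt, yy, 1)
        yhat = slope * tt + intercept
        ss_res = float(np.sum((yy - yhat) ** 2))
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if slope < 0 and (best is None or adj > best[0] + 1e-12):
            best = (adj, -slope, r2, n)
    if best is None:
        raise NCAError("no declining terminal phase found")
    _, lam, r2, n = best
    return float(lam), float(r2), int(n)


def collapse_sparse(df: pd.DataFrame, time_col: str = "time_hr", value_col: str = "value") -> ConcentrationProfile:
    """Mean concentration per time point for a sparse (n animals/time) design
    with uniform weighting."""
    g = df.groupby(time_col, sort=True)[value_col].mean()
    return ConcentrationProfile(g.index.to_numpy(dtype=float), g.to_numpy(dtype=float), "mean")


def nca_report(profile: ConcentrationProfile, r2_threshold: float = 0.8) -> PKParameters:
    """Full NCA for an IV-input profile.

    AUCinf = AUClast + Clast/lambda_z; AUMC extrapolation
    Clast*tlast/lambda_z + Clast/lambda_z^2; MRTinf = AUMCinf/AUCinf.
    If fewer than 3 terminal points are usable, the extrapolated quantities
    are left unreported (None) and AUCinf falls back to AUClast.
    """
    t, c = _check_profile(profile.times_h, profile.values)
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_last = auc_linlog(t, c)
    try:
        lam, r2, n = terminal_slope(t, c)
    except NCAError:
        return PKParameters(cmax, tmax, auc_last, auc_last, None, None, None, None, None)
    c_last, t_last = float(c[-1]), float(t[-1])
    auc_inf = auc_last + c_last / lam
    aumc_inf = aumc_linlog(t, c) + c_last * t_last / lam + c_last / lam**2
    return PKParameters(
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        auc_inf=auc_inf,
        half_life=math.log(2) / lam,
        mrt_inf=aumc_inf / auc_inf,
        lambda_z=lam,
        lambda_z_r_squared=r2,
        lambda_z_n_points=n,
        lambda_z_quality_flag=r2 < r2_threshold,
    )
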