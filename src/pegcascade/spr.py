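"""Surface-plasmon-resonance 1:1 binding kinetics.

Association follows R(t) = ka*C*Rmax/(ka*C+kd) * (1 - exp(-(ka*C+kd) t)),
dissociation the complementary R0 * exp(-kd t); a dilution series is fit
globally with a single (ka, kd, Rmax) shared across concentrations, the
standard Biacore practice.  The equilibrium dissociation constant is the
rate quotient Kd = kd / ka.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

from .params import KineticConstants, SPR_KINETICS

ASSOCIATION_SECONDS = 180.0  # 3-minute analyte exposure of the standard design


class IdentifiabilityWarning(UserWarning):
    """Sensorgrams carry too little curvature to pin down the rates."""


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class DilutionSeries:
    """Serial dilution design: ``n_levels`` concentrations spaced ``fold``-fold
    down from ``top_concentration_M``."""

    top_concentration_M: float = 100e-9
    fold: float = 3.0
    n_levels: int = 5

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 concentration levels")
        if self.fold <= 1:
            raise ValueError("dilution fold must exceed 1")
        if self.top_concentration_M <= 0:
            raise ValueError("top concentration must be > 0")

    def concentrations(self) -> np.ndarray:
        return self.top_concentration_M / self.fold ** np.arange(self.n_levels)


@dataclass
class Sensorgram:
    """Response-vs-time trace for one analyte concentration.

    ``times_s`` spans association then dissociation; ``t_assoc_s`` marks the
    switch to running buffer.
    """

    times_s: np.ndarray
    response_RU: np.ndarray
    concentration_M: float
    t_assoc_s: float = ASSOCIATION_SECONDS

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.response_RU = np.asarray(self.response_RU, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.response_RU)):
            raise ValueError("responses must be finite")


def association_response(ka: float, kd: float, C: float, Rmax: float, t) -> np.ndarray | float:
    """1:1 association-phase response in RU."""
    if min(ka, kd, C) < 0 or Rmax <= 0:
        raise ValueError("rates and concentration must be >= 0, Rmax > 0")
    t = np.asarray(t, dtype=float)
    kobs = ka * C + kd
    if kobs == 0:
        out = np.zeros_like(t)
    else:
        out = ka * C * Rmax / kobs * -np.expm1(-kobs * t)
    return float(out) if out.ndim == 0 else out


def dissociation_response(kd: float, R0: float, t) -> np.ndarray | float:
    """Pure exponential dissociation from response R0 at buffer switch."""
    if kd <= 0 or R0 < 0:
        raise ValueError("kd must be > 0 and R0 >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = R0 * np.exp(-kd * t)
    return float(out) if out.ndim == 0 else out


def sensorgram_model(ka: float, kd: float, Rmax: float, C: float, times_s, t_assoc_s: float = ASSOCIATION_SECONDS) -> np.ndarray:
    """Full association + dissociation trace on an arbitrary time grid."""
    times_s = np.asarray(times_s, dtype=float)
    assoc = times_s <= t_assoc_s
    out = np.empty_like(times_s)
    out[assoc] = association_response(ka, kd, C, Rmax, times_s[assoc])
    R0 = association_response(ka, kd, C, Rmax, t_assoc_s)
    out[~assoc] = dissociation_response(kd, R0, times_s[~assoc] - t_assoc_s)
    return out


def equilibrium_kd(ka: float, kd: float) -> float:
    """Kd = k_off / k_on (M)."""
    if ka <= 0:
        raise ValueError("association rate must be > 0")
    return kd / ka


def fold_change(kc_analyte: KineticConstants, kc_ref: KineticConstants) -> float:
    """Kd fold-change of an analyte relative to a reference at one surface."""
    if kc_analyte.receptor_surface != kc_ref.receptor_surface:
        raise ValueError(
            "fold change is only meaningful at a common receptor surface "
            f"({kc_analyte.receptor_surface} vs {kc_ref.receptor_surface})"
        )
    return kc_analyte.kd / kc_ref.kd


def fit_1to1(
    sensorgrams: list[Sensorgram],
    analyte: str = "IL2",
    receptor_surface: str = "beta",
) -> tuple[KineticConstants, dict]:
    """Global 1:1 fit of (ka, kd, Rmax) across a dilution series.

    All curves share the three parameters; per-curve Rmax is deliberately
    not allowed.  Returns the fitted constants and a diagnostics dict with
    Rmax, reduced chi-square, and an identifiability flag raised when no
    curve shows association-phase curvature.
    """
    if len(sensorgrams) < 2:
        raise FitError("global fitting needs at least 2 concentrations")
    if any(sg.concentration_M <= 0 for sg in sensorgrams):
        raise FitError("analyte concentrations must be positive")

    conc = np.array([sg.concentration_M for sg in sensorgrams])
    resp_scale = max(float(np.max(np.abs(sg.response_RU))) for sg in sensorgrams)
    if resp_scale == 0:
        raise FitError("all responses are zero")

    params = lmfit.Parameters()
    params.add("log_ka", value=math.log(1e6), min=math.log(1e2), max=math.log(1e12))
    params.add("log_kd", value=math.log(1e-2), min=math.log(1e-7), max=math.log(1e2))
    params.add("Rmax", value=resp_scale, min=1e-6)

    def residual(p):
        ka, kd = math.exp(p["log_ka"].value), math.exp(p["log_kd"].value)
        return np.concatenate(
            [
                sensorgram_model(ka, kd, p["Rmax"].value, sg.concentration_M, sg.times_s, sg.t_assoc_s)
                - sg.response_RU
                for sg in sensorgrams
            ]
        )

    out = lmfit.minimize(residual, params, method="leastsq")
    ka = math.exp(out.params["log_ka"].value)
    kd = math.exp(out.params["log_kd"].value)
    rmax = float(out.params["Rmax"].value)
    if not out.success:
        raise FitError(f"global 1:1 fit failed: {out.message}")

    # identifiability: association curvature requires kobs * t_assoc not >> 1
    kobs = ka * conc + kd
    plateau_only = bool(np.all(kobs * ASSOCIATION_SECONDS > 50.0))
    kc = KineticConstants(ka, kd, analyte=analyte, receptor_surface=receptor_surface)
    return kc, {
        "Rmax": rmax,
        "redchi": float(out.redchi),
        "plateau_only": plateau_only,
        "nfev": int(out.nfev),
    }


def kd_table(kinetics: dict[str, dict[str, KineticConstants]] | None = None) -> pd.DataFrame:
    """Tidy table of k_on, k_off, Kd (nM) per analyte and surface, with the
    Kd fold-change relative to free IL2 at the same surface."""
    kinetics = kinetics or SPR_KINETICS
    rows = []
    for analyte, per in kinetics.items():
        for surface, kc in per.items():
            rows.append(
                {
                    "receptor_surface": surface,
                    "analyte": analyte,
                    "k_on_M-1s-1": kc.k_on,
                    "k_off_s-1": kc.k_off,
                    "Kd_nM": kc.kd * 1e9,
                    "fold_vs_IL2": fold_change(kc, kinetics["IL2"][surface]),
                }
            )
    return pd.DataFrame(rows)


def sensorgrams_to_csv(sensorgrams: list[Sensorgram], path) -> None:
    frames = []
    for sg in sensorgrams:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": sg.times_s,
                    "response_RU": sg.response_RU,
                    "concentration_M": sg.concentration_M,
                    "phase": np.where(sg.times_s <= sg.t_assoc_s, "association", "dissociation"),
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def sensorgrams_from_csv(path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    out = []
    for conc, grp in df.groupby("concentration_M", sort=True):
        assoc = grp[grp["phase"] == "association"]
        t_assoc = float(assoc["time_s"].max()) if len(assoc) else ASSOCIATION_SECONDS
        out.append(Sensorgram(grp["time_s"].to_numpy(), grp["response_RU"].to_numpy(), float(conc), t_assoc))
    return out
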