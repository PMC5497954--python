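"""Synthetic-data generators for every input the pipeline consumes.

Each generator is a pure function of (ground truth, design, noise level,
seed) and emulates one of the study's measurement processes:

* PEG-release time courses (first-order truth, multiplicative noise);
* SPR sensorgrams from a 5-point 3-fold dilution series with a 3-minute
  association phase (additive response noise);
* sparse mouse PK composites — 5 animals per time point, composite
  analytes RC / AC / 1-PEG assay after a prodrug dose plus the free-IL2
  comparator — with multiplicative lognormal noise and an LLOQ flag;
* %pSTAT5+ CD3+ time courses over 240 h (additive noise).

Concentration noise is lognormal because bioanalytical assays have
roughly constant CV; the lognormal is mean-corrected (divided by
exp(sigma^2/2)) so replicate means converge to the truth.  Response-unit
and percent-positive noise are additive Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import ConcentrationProfile, simulate
from .calibration import predict_composites
from .params import DoseRegimen, KineticConstants, ModelParameters
from .pstat5 import EffectProfile, IndirectResponseParams, cd3_scaled_occupancy, simulate_pstat5
from .release import ReleaseTimecourse, fraction_released
from .spr import DilutionSeries, Sensorgram, sensorgram_model
from .regimens import build_regimen

#: sampling schedule of the sparse PK study (h)
PK_SAMPLING_H = (0.25, 1.0, 4.0, 8.0, 16.0, 24.0, 32.0, 48.0, 72.0, 96.0, 120.0, 168.0, 240.0)
#: pSTAT5 monitoring schedule (h)
PSTAT5_SAMPLING_H = (0.0, 0.5, 2.0, 4.0, 8.0, 16.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 168.0, 240.0)

#: ground-truth turnover parameters of the pSTAT5 generator, chosen once so
#: the simulated prodrug study reproduces the observed conditions: ~1.5%
#: baseline, peak near 15% positive cells ~2 days post dose, still well
#: above baseline at 96 h, while the free-IL2 comparator resolves toward
#: baseline far earlier (its receptor pulse lasts only hours).
DEFAULT_IRM_TRUTH = IndirectResponseParams(k_in=0.15, k_out=0.1, s_max=10.5, o_50=0.8)


@dataclass
class SyntheticConfig:
    """Ground truth, design, and noise levels of the virtual study."""

    truth: ModelParameters = field(default_factory=ModelParameters)
    irm_truth: IndirectResponseParams = DEFAULT_IRM_TRUTH
    dose_mg_per_kg: float = 0.8
    n_animals_per_timepoint: int = 5
    pk_times_h: tuple[float, ...] = PK_SAMPLING_H
    pstat5_times_h: tuple[float, ...] = PSTAT5_SAMPLING_H
    dilution: DilutionSeries = field(default_factory=DilutionSeries)
    pk_cv: float = 0.15
    spr_sigma_fraction_rmax: float = 0.01
    pstat5_sigma_percent: float = 1.0
    lloq_ug_ml: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.pk_cv, self.spr_sigma_fraction_rmax, self.pstat5_sigma_percent):
            if v < 0:
                raise ValueError("noise levels must be >= 0")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size) - sigma**2 / 2.0)


def gen_release(
    k: float,
    times_h: np.ndarray,
    cv: float = 0.10,
    seed: int = 0,
    pH: float = 7.4,
    temperature_K: float = 310.15,
) -> ReleaseTimecourse:
    """Noisy fraction-released course from first-order truth, clipped to [0, 1]."""
    rng = np.random.default_rng(seed)
    times_h = np.asarray(times_h, dtype=float)
    truth = fraction_released(k, times_h)
    noisy = np.clip(truth * _lognormal_factors(rng, cv, times_h.shape), 0.0, 1.0)
    return ReleaseTimecourse(times_h, noisy, pH=pH, temperature_K=temperature_K)


def gen_sensorgrams(
    kc: KineticConstants,
    series: DilutionSeries | None = None,
    rmax: float = 100.0,
    sigma_fraction_rmax: float = 0.01,
    seed: int = 0,
    dt_s: float = 1.0,
    dissociation_s: float = 300.0,
) -> list[Sensorgram]:
    """Sensorgram set over a dilution series with additive RU noise."""
    series = series or DilutionSeries()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 180.0 + dissociation_s + dt_s / 2, dt_s)
    out = []
    for conc in series.concentrations():
        resp = sensorgram_model(kc.k_on, kc.k_off, rmax, conc, t)
        resp = resp + rng.normal(0.0, sigma_fraction_rmax * rmax, t.shape)
        out.append(Sensorgram(t, resp, conc))
    return out


def gen_pk_study(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Sparse composite PK study as a tidy table.

    Columns: time_hr, animal, analyte (RC | AC | onePEG_assay |
    IL2_comparator), value (ug/mL), below_lloq.  Each animal at each time
    point gets an independent multiplicative error; composite sums of the
    noiseless truth satisfy AC <= RC by construction.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.pk_times_h, dtype=float)
    truth = predict_composites(config.truth, config.dose_mg_per_kg, t)
    rows = []
    for analyte, values in truth.items():
        for j, (tj, v) in enumerate(zip(t, values)):
            factors = _lognormal_factors(rng, config.pk_cv, config.n_animals_per_timepoint)
            for a, f in enumerate(factors):
                val = v * f
                rows.append(
                    {
                        "time_hr": tj,
                        "animal": a + 1,
                        "analyte": analyte,
                        "value": val,
                        "below_lloq": bool(val < config.lloq_ug_ml),
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["seed"] = config.seed
    return df


def mean_profiles(study: pd.DataFrame, drop_lloq: bool = True) -> dict[str, ConcentrationProfile]:
    """Collapse a sparse study to per-timepoint mean profiles per analyte."""
    if drop_lloq:
        study = study[~study["below_lloq"]]
    out = {}
    for analyte, grp in study.groupby("analyte", sort=False):
        g = grp.groupby("time_hr", sort=True)["value"].mean()
        out[str(analyte)] = ConcentrationProfile(
            g.index.to_numpy(dtype=float), g.to_numpy(dtype=float), str(analyte)
        )
    return out


def gen_pstat5(
    config: SyntheticConfig | None = None,
    regimen: DoseRegimen | None = None,
) -> tuple[pd.DataFrame, EffectProfile]:
    """Virtual pSTAT5 study: per-animal noisy measurements plus the noiseless
    truth curve.

    The driver is the CD3-scaled summed receptor occupancy simulated from
    the ground-truth model under the given regimen (single prodrug dose by
    default)."""
    config = config or SyntheticConfig()
    regimen = regimen or build_regimen("single_nktr214", config.dose_mg_per_kg)
    rng = np.random.default_rng(config.seed)
    t_obs = np.asarray(config.pstat5_times_h, dtype=float)
    t_grid = np.unique(np.concatenate([np.arange(0.0, t_obs[-1] + 0.5, 0.5), t_obs]))
    result = simulate(config.truth, regimen, t_grid)
    driver = cd3_scaled_occupancy(result)
    truth = simulate_pstat5(driver, config.irm_truth, t_grid=t_grid)
    truth_at_obs = np.interp(t_obs, truth.times_h, truth.percent_pstat5)
    rows = []
    for tj, v in zip(t_obs, truth_at_obs):
        for a in range(config.n_animals_per_timepoint):
            rows.append(
                {
                    "time_hr": tj,
                    "animal": a + 1,
                    "percent_pstat5": max(v + rng.normal(0.0, config.pstat5_sigma_percent), 0.0),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["seed"] = config.seed
    return df, EffectProfile(truth.times_h, truth.percent_pstat5)


def mean_effect(study: pd.DataFrame) -> EffectProfile:
    g = study.groupby("time_hr", sort=True)["percent_pstat5"].mean()
    return EffectProfile(g.index.to_numpy(dtype=float), g.to_numpy(dtype=float))
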