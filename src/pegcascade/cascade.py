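"""The mechanistic ODE system: sequential PEG release, per-species plasma
elimination, and IL2-receptor binding.

Sixteen state variables, all molar: five free drug species
(4-6)PEG -> 3PEG -> 2PEG -> 1PEG -> IL2 in a linear first-order chain, the
free alpha- and beta-subunit receptor pools on lymphocytes, and nine
ligand-receptor complexes (each active analyte bound to alpha, to beta, or
in the assembled alpha-beta trimer).  The trimer forms sequentially: the
analyte first binds the alpha subunit, and the A.alpha complex then
recruits a beta subunit; both dimeric and trimeric complexes draw on the
same beta pool.  Receptor pools are constant (no synthesis or
internalisation) and complexes are not eliminated.

Occupancy conventions: the dimeric (beta-gamma) occupancy of an analyte is
its beta complex as a percent of the total beta pool.  The trimeric
(alpha-beta-gamma) occupancy is by default also a percent of the total
beta pool — the limiting pool the gamma-containing complexes draw from
(1000 beta vs 10000 alpha per cell); the alpha-pool denominator is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .params import (
    ACTIVE_ANALYTES,
    DoseRegimen,
    ModelParameters,
    mass_to_molar,
    molar_to_mass,
)

# ---- state vector layout ------------------------------------------------

SPECIES_NAMES = ("PEG46", "PEG3", "PEG2", "PEG1", "IL2")
I_PEG46, I_PEG3, I_PEG2, I_PEG1, I_IL2 = range(5)
I_RA, I_RB = 5, 6
#: index of the free-species pool feeding each active analyte's complexes
ANALYTE_SPECIES = {"IL2": I_IL2, "1PEG": I_PEG1, "2PEG": I_PEG2}
#: first complex index per analyte; layout per analyte is (A.Ra, A.Rb, A.Rab)
COMPLEX_BASE = {an: 7 + 3 * j for j, an in enumerate(ACTIVE_ANALYTES)}
N_STATES = 16

STATE_NAMES = list(SPECIES_NAMES) + ["Ralpha_free", "Rbeta_free"] + [
    f"{an}.{c}" for an in ACTIVE_ANALYTES for c in ("Ralpha", "Rbeta", "Ralphabeta")
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConcentrationProfile:
    """A time grid with concentrations for one analyte or composite."""

    times_h: np.ndarray
    values: np.ndarray
    analyte: str
    unit: str = "ug/mL"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values", v)
        if np.any(np.diff(t) <= 0):
            raise ValueError("profile times must be strictly increasing")
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")


@dataclass(frozen=True)
class OccupancyProfile:
    """% receptor occupancy vs time for one (receptor complex, analyte)."""

    times_h: np.ndarray
    percent_occupied: np.ndarray
    receptor: str  # "betagamma" | "alphabetagamma"
    analyte: str   # "IL2" | "1PEG" | "2PEG" | "total"


@dataclass
class SimulationResult:
    """Trajectory of the full state vector with the generating inputs."""

    times_h: np.ndarray
    states: np.ndarray  # (16, n)
    params: ModelParameters
    regimen: DoseRegimen

    def state_profile(self, name: str) -> ConcentrationProfile:
        return ConcentrationProfile(self.times_h, self.states[STATE_NAMES.index(name)], name, unit="M")


# ---- right-hand side ----------------------------------------------------

def derivatives(state: np.ndarray, params: ModelParameters, infusion_molar_per_h: float = 0.0) -> np.ndarray:
    """Time derivative of the 16-state system (concentrations in M, t in h).

    The fully PEGylated pool has no release inflow, free IL2 no release
    outflow; the (4-6)PEG and 3PEG species are inactive and carry no
    binding terms.
    """
    y = np.asarray(state, dtype=float)
    d = np.zeros(N_STATES)
    kr = params.release.as_array()
    ke = params.k_elim.as_array()
    for i in range(4):
        flux = kr[i] * y[i]
        d[i] -= flux
        d[i + 1] += flux
    for i in range(5):
        d[i] -= ke[i] * y[i]
    d[I_IL2] += infusion_molar_per_h

    Ra, Rb = y[I_RA], y[I_RB]
    for an in ACTIVE_ANALYTES:
        i_sp = ANALYTE_SPECIES[an]
        i_c = COMPLEX_BASE[an]
        A = y[i_sp]
        ARa, ARb, ARab = y[i_c], y[i_c + 1], y[i_c + 2]
        b_a = params.binding[an]["alpha"]
        b_b = params.binding[an]["beta"]
        b_ab = params.binding[an]["alphabeta"]
        f_a = b_a.k_on * A * Ra - b_a.k_off * ARa
        f_b = b_b.k_on * A * Rb - b_b.k_off * ARb
        f_ab = b_ab.k_on * ARa * Rb - b_ab.k_off * ARab
        d[i_sp] -= f_a + f_b
        d[I_RA] -= f_a
        d[I_RB] -= f_b + f_ab
        d[i_c] += f_a - f_ab
        d[i_c + 1] += f_b
        d[i_c + 2] += f_ab
    return d


def il2_content_molar(state: np.ndarray) -> float:
    """Total IL2 protein content over free species and complexes (M).

    Release and binding only move material between pools, so with all
    elimination rates zero this quantity is conserved.
    """
    y = np.asarray(state, dtype=float)
    total = float(np.sum(y[:5]))
    for an in ACTIVE_ANALYTES:
        i_c = COMPLEX_BASE[an]
        total += float(np.sum(y[i_c : i_c + 3]))
    return total


# ---- dosing -------------------------------------------------------------

def _dose_volume_ml(params: ModelParameters, regimen: DoseRegimen) -> float:
    ph = params.physiology
    return ph.volume_of_distribution_ml if regimen.analyte_dosed == "NKTR214" else ph.volume_il2_ml


def _dose_species(regimen: DoseRegimen) -> int:
    return I_PEG46 if regimen.analyte_dosed == "NKTR214" else I_IL2


def _bolus_molar(dose_mg_per_kg: float, params: ModelParameters, regimen: DoseRegimen) -> float:
    ph = params.physiology
    dose_ug = dose_mg_per_kg * ph.body_weight_g  # mg/kg x g = ug
    return mass_to_molar(dose_ug / _dose_volume_ml(params, regimen), ph.il2_molar_mass)


def initial_state(regimen: DoseRegimen, params: ModelParameters) -> np.ndarray:
    """State at t = 0: receptors at full free pools, complexes empty, any
    t = 0 bolus placed in the dosed species pool."""
    y0 = np.zeros(N_STATES)
    y0[I_RA] = params.physiology.receptor_alpha_molar
    y0[I_RB] = params.physiology.receptor_beta_molar
    for ev in regimen.events:
        if ev.route == "bolus" and ev.time_h == 0.0:
            y0[_dose_species(regimen)] += _bolus_molar(ev.dose_mg_per_kg, params, regimen)
    return y0


# ---- integration --------------------------------------------------------

def simulate(
    params: ModelParameters,
    regimen: DoseRegimen,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-15,
    method: str = "BDF",
) -> SimulationResult:
    """Integrate the system over ``t_grid`` (hours, from 0), re-initialising
    the state additively at each bolus and applying zero-order input during
    infusions.  Tight tolerances are required because receptor complexes
    live at sub-picomolar scale while drug species reach sub-micromolar."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and increase strictly")
    t_end = float(t_grid[-1])
    for ev in regimen.events:
        if ev.time_h > t_end:
            raise ValueError("t_grid must cover all dose events")

    # segment boundaries: bolus times and infusion on/off switches
    boluses = [(ev.time_h, _bolus_molar(ev.dose_mg_per_kg, params, regimen))
               for ev in regimen.events if ev.route == "bolus"]
    infusions = []
    for ev in regimen.events:
        if ev.route == "infusion":
            conc = _bolus_molar(ev.dose_mg_per_kg, params, regimen)
            infusions.append((ev.time_h, min(ev.time_h + ev.duration_h, t_end), conc / ev.duration_h))
    cuts = {0.0, t_end}
    cuts.update(t for t, _ in boluses)
    cuts.update(t0 for t0, _, _ in infusions)
    cuts.update(t1 for _, t1, _ in infusions)
    cuts = sorted(c for c in cuts if 0.0 <= c <= t_end)

    y = initial_state(regimen, params)
    sp = _dose_species(regimen)
    out_t = [np.array([0.0])]
    out_y = [y[:, None].copy()]
    for t0, t1 in zip(cuts[:-1], cuts[1:]):
        for tb, amount in boluses:
            if tb == t0 and tb != 0.0:  # t = 0 boluses handled by initial_state
                y[sp] += amount
        rate = sum(r for (ta, tb_, r) in infusions if ta <= t0 < tb_)
        seg = t_grid[(t_grid > t0) & (t_grid <= t1)]
        t_eval = np.unique(np.concatenate([seg, [t1]]))
        sol = solve_ivp(
            lambda t, yy: derivatives(yy, params, rate),
            (t0, t1),
            y,
            t_eval=t_eval,
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"ODE integration failed on [{t0}, {t1}]: {sol.message}")
        y = sol.y[:, -1].copy()
        keep = np.isin(sol.t, seg)
        out_t.append(sol.t[keep])
        out_y.append(sol.y[:, keep])

    times = np.concatenate(out_t)
    states = np.concatenate(out_y, axis=1)
    # solver can undershoot zero by ~atol on the stiff complexes
    states = np.clip(states, 0.0, None)
    keep = np.isin(times, t_grid)
    return SimulationResult(times[keep], states[:, keep], params, regimen)


def linear_cascade_solution(params: ModelParameters, c0_molar: float, t_grid: np.ndarray) -> np.ndarray:
    """Analytic solution of the 5-species release/elimination chain with the
    binding terms absent (receptor pools are ~1e4-fold below drug levels, so
    binding does not perturb the free species measurably).

    Returns an (n_times, 5) array in M.  Solved by eigendecomposition of the
    bidiagonal chain matrix, falling back to the matrix exponential if the
    rate constants collide.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    kr = params.release.as_array()
    ke = params.k_elim.as_array()
    A = np.zeros((5, 5))
    for i in range(4):
        A[i, i] -= kr[i]
        A[i + 1, i] += kr[i]
    for i in range(5):
        A[i, i] -= ke[i]
    x0 = np.array([c0_molar, 0, 0, 0, 0.0])
    lam = np.diag(A)
    if np.min(np.abs(np.subtract.outer(lam, lam) + np.eye(5))) < 1e-10:
        return np.array([expm(A * t) @ x0 for t in t_grid])
    w, V = np.linalg.eig(A)
    c = np.linalg.solve(V, x0)
    return np.real(np.exp(np.outer(t_grid, w)) * c @ V.T)


# ---- derived profiles ---------------------------------------------------

def species_profiles(result: SimulationResult) -> dict[str, ConcentrationProfile]:
    """Free-species concentration profiles in ug/mL of IL2 content."""
    mw = result.params.physiology.il2_molar_mass
    return {
        name: ConcentrationProfile(result.times_h, molar_to_mass(result.states[i], mw), name)
        for i, name in enumerate(SPECIES_NAMES)
    }


def composite_profiles(profiles: dict[str, ConcentrationProfile]) -> dict[str, ConcentrationProfile]:
    """Bioanalytical composites from the species profiles.

    RC sums all five IL2-containing species; AC the active subset
    (2PEG + 1PEG + IL2); the 1-PEG assay sees 1PEG + IL2.
    """
    t = profiles["PEG46"].times_h
    for p in profiles.values():
        if p.times_h.shape != t.shape or np.any(p.times_h != t):
            raise ValueError("species profiles must share a common time grid")
    val = {k: profiles[k].values for k in SPECIES_NAMES}
    return {
        "RC": ConcentrationProfile(t, sum(val[k] for k in SPECIES_NAMES), "RC"),
        "AC": ConcentrationProfile(t, val["PEG2"] + val["PEG1"] + val["IL2"], "AC"),
        "onePEG_assay": ConcentrationProfile(t, val["PEG1"] + val["IL2"], "onePEG_assay"),
    }


def occupancy_profiles(
    result: SimulationResult,
    trimer_denominator: str = "beta",
) -> list[OccupancyProfile]:
    """Percent receptor occupancy per analyte and per receptor complex.

    ``trimer_denominator`` selects the pool the trimer percentage refers to:
    "beta" (default, the limiting beta pool) or "alpha".
    """
    if trimer_denominator not in ("beta", "alpha"):
        raise ValueError("trimer_denominator must be 'beta' or 'alpha'")
    ph = result.params.physiology
    rb_tot = ph.receptor_beta_molar
    tri_tot = rb_tot if trimer_denominator == "beta" else ph.receptor_alpha_molar
    t = result.times_h
    out = []
    total = {"betagamma": np.zeros_like(t), "alphabetagamma": np.zeros_like(t)}
    for an in ACTIVE_ANALYTES:
        i_c = COMPLEX_BASE[an]
        beta_pct = 100.0 * result.states[i_c + 1] / rb_tot
        tri_pct = 100.0 * result.states[i_c + 2] / tri_tot
        out.append(OccupancyProfile(t, beta_pct, "betagamma", an))
        out.append(OccupancyProfile(t, tri_pct, "alphabetagamma", an))
        total["betagamma"] = total["betagamma"] + beta_pct
        total["alphabetagamma"] = total["alphabetagamma"] + tri_pct
    for rec, pct in total.items():
        out.append(OccupancyProfile(t, pct, rec, "total"))
    return out


# ---- CSV I/O ------------------------------------------------------------

def profiles_to_csv(profiles: list[ConcentrationProfile] | dict[str, ConcentrationProfile], path: str | Path) -> None:
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    pd.concat(
        [
            pd.DataFrame({"time_hr": p.times_h, "analyte": p.analyte, "value": p.values, "unit": p.unit})
            for p in profiles
        ]
    ).to_csv(path, index=False)


def profiles_from_csv(path: str | Path) -> dict[str, ConcentrationProfile]:
    df = pd.read_csv(path)
    out = {}
    for analyte, grp in df.groupby("analyte", sort=False):
        out[analyte] = ConcentrationProfile(
            grp["time_hr"].to_numpy(), grp["value"].to_numpy(), str(analyte), unit=str(grp["unit"].iloc[0])
        )
    return out
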