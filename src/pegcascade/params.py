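"""Parameter containers for the PEG-IL2 prodrug cascade model.

Everything a simulation needs lives in a single :class:`ModelParameters`
object: the sequential PEG-release rates, per-species plasma elimination
rates, receptor binding kinetics per active analyte and binding step, and
physiology constants (lymphocyte density, receptor counts per cell, dosing
volume).  Parameter sets round-trip through YAML so a calibrated model can
be stored next to its results.

Units are fixed package-wide: time in hours, concentrations molar inside
the ODE system, mass concentrations in ug/mL of IL2 protein content at the
I/O boundary.  SPR rate constants are measured per second and converted to
per hour exactly once, in :func:`binding_from_spr`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

AVOGADRO = 6.02214076e23
#: molar mass of the IL2 protein (g/mol); PEG mass is ignored because doses
#: are expressed as IL2 protein content.
IL2_MOLAR_MASS = 15300.0

#: inactive species retained for mass balance but with no receptor binding
SPECIES = ("PEG46", "PEG3", "PEG2", "PEG1", "IL2")
#: analytes that bind and signal (<= 2 PEG chains remaining)
ACTIVE_ANALYTES = ("IL2", "1PEG", "2PEG")
#: receptor surfaces of the SPR study: isolated alpha subunit, isolated
#: beta subunit (dimeric beta-gamma mimic), and the 1:1 alpha+beta mixture
#: (trimeric alpha-beta-gamma mimic)
SURFACES = ("alpha", "beta", "alphabeta")


class ParameterError(ValueError):
    """Raised when a parameter container violates its invariants."""


@dataclass(frozen=True)
class ReleaseRateSet:
    """First-order rate constants of the sequential PEG-release cascade (h^-1).

    The four steps are (4-6)PEG -> 3PEG -> 2PEG -> 1PEG -> free IL2; the
    first step lumps the loss of the initial one-to-three chains.
    """

    k_46_to_3: float = 0.044
    k_3_to_2: float = 0.035
    k_2_to_1: float = 0.058
    k_1_to_0: float = 0.040

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"release rate {name} must be finite and > 0, got {v}")

    def as_array(self):
        return (self.k_46_to_3, self.k_3_to_2, self.k_2_to_1, self.k_1_to_0)


@dataclass(frozen=True)
class KineticConstants:
    """SPR-style 1:1 binding constants for one analyte at one surface.

    ``k_on`` in M^-1 s^-1, ``k_off`` in s^-1; ``kd`` is the derived
    equilibrium dissociation constant k_off / k_on in M.
    """

    k_on: float
    k_off: float
    analyte: str = "IL2"
    receptor_surface: str = "beta"

    def __post_init__(self) -> None:
        if not (self.k_on > 0 and math.isfinite(self.k_on)):
            raise ParameterError(f"k_on must be > 0, got {self.k_on}")
        if not (self.k_off > 0 and math.isfinite(self.k_off)):
            raise ParameterError(f"k_off must be > 0, got {self.k_off}")
        if self.analyte not in ACTIVE_ANALYTES:
            raise ParameterError(f"unknown analyte {self.analyte!r}")
        if self.receptor_surface not in SURFACES:
            raise ParameterError(f"unknown receptor surface {self.receptor_surface!r}")

    @property
    def kd(self) -> float:
        return self.k_off / self.k_on


#: Measured 1:1 binding kinetics (k_on M^-1 s^-1, k_off s^-1) per analyte at
#: each receptor surface.  These are the quantitative inputs of the binding
#: arm of the model and the ground truth of the sensorgram generator.
SPR_KINETICS: dict[str, dict[str, KineticConstants]] = {
    "IL2": {
        "alpha": KineticConstants(4.84e7, 0.415, "IL2", "alpha"),
        "beta": KineticConstants(1.26e6, 0.301, "IL2", "beta"),
        "alphabeta": KineticConstants(1.46e8, 0.014, "IL2", "alphabeta"),
    },
    "1PEG": {
        "alpha": KineticConstants(8.33e5, 0.158, "1PEG", "alpha"),
        "beta": KineticConstants(2.82e5, 0.499, "1PEG", "beta"),
        "alphabeta": KineticConstants(3.56e5, 0.111, "1PEG", "alphabeta"),
    },
    "2PEG": {
        "alpha": KineticConstants(3.74e5, 0.182, "2PEG", "alpha"),
        "beta": KineticConstants(1.66e5, 0.656, "2PEG", "beta"),
        "alphabeta": KineticConstants(2.41e5, 0.108, "2PEG", "alphabeta"),
    },
}


@dataclass(frozen=True)
class PhysiologyConstants:
    """Static mouse physiology used to size the receptor pools and the dose.

    ``volume_of_distribution_ml`` is derived from dose / C0 with the observed
    peak concentration of the total-conjugate assay (11.6 ug/mL after
    0.8 mg/kg in a 20 g mouse), i.e. ~69 mL/kg.  ``volume_il2_ml`` applies
    the same rule to the free-IL2 comparator (peak 6.6 ug/mL), whose smaller
    unPEGylated protein distributes into a larger apparent volume.
    """

    lymphocytes_per_nl: float = 3.9
    receptors_alpha_per_cell: float = 10000.0
    receptors_beta_per_cell: float = 1000.0
    cd3_fraction: float = 0.4
    gamma_affinity_factor: float = 10.0
    il2_molar_mass: float = IL2_MOLAR_MASS
    body_weight_g: float = 20.0
    volume_of_distribution_ml: float = 16.0 / 11.6
    volume_il2_ml: float = 16.0 / 6.6

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be finite and > 0, got {v}")
        if self.cd3_fraction > 1:
            raise ParameterError("cd3_fraction must lie in (0, 1]")

    @property
    def receptor_alpha_molar(self) -> float:
        return receptor_pool_concentration(self.lymphocytes_per_nl, self.receptors_alpha_per_cell)

    @property
    def receptor_beta_molar(self) -> float:
        return receptor_pool_concentration(self.lymphocytes_per_nl, self.receptors_beta_per_cell)


def receptor_pool_concentration(cells_per_nl: float, receptors_per_cell: float) -> float:
    """Molar concentration of a receptor pool spread over plasma volume.

    cells/nL x 1e9 nL/L x receptors/cell / N_A  ->  mol/L.
    """
    if cells_per_nl < 0 or receptors_per_cell < 0:
        raise ParameterError("cell and receptor counts must be non-negative")
    return cells_per_nl * 1e9 * receptors_per_cell / AVOGADRO


@dataclass(frozen=True)
class BindingStep:
    """One mass-action binding step of the in-vivo model, rates in h^-1 units
    (k_on in M^-1 h^-1)."""

    k_on: float
    k_off: float

    @property
    def kd(self) -> float:
        return self.k_off / self.k_on


def binding_from_spr(
    kinetics: dict[str, dict[str, KineticConstants]] | None = None,
    gamma_factor: float = 10.0,
) -> dict[str, dict[str, BindingStep]]:
    """Convert SPR constants (s^-1) to in-vivo binding steps (h^-1).

    The gamma chain stabilises the beta-containing receptor complexes; its
    measured ~10-fold affinity gain is applied by dividing k_off by
    ``gamma_factor`` for the beta surface and for the alpha-beta recruitment
    step.  The isolated alpha-subunit interaction has no gamma contact and
    keeps its SPR value.  This is the single point where seconds become
    hours.
    """
    kinetics = kinetics or SPR_KINETICS
    out: dict[str, dict[str, BindingStep]] = {}
    for analyte, per_surface in kinetics.items():
        out[analyte] = {}
        for surface, kc in per_surface.items():
            k_on = kc.k_on * 3600.0
            k_off = kc.k_off * 3600.0
            if surface in ("beta", "alphabeta"):
                k_off /= gamma_factor
            out[analyte][surface] = BindingStep(k_on, k_off)
    return out


@dataclass(frozen=True)
class EliminationRates:
    """First-order plasma disappearance rates (h^-1) per species.

    These lump clearance and tissue distribution; they are not printed in
    any table and are estimated by the calibration module.  Defaults are the
    pre-calibration starting points: ln2 / observed composite half-lives for
    the conjugates, and the aldesleukin C0/AUC quotient for free IL2 (whose
    printed 0.20 h mean residence time implies far faster disappearance than
    its terminal half-life suggests).
    """

    PEG46: float = math.log(2) / 15.5
    PEG3: float = math.log(2) / 15.0
    PEG2: float = math.log(2) / 15.0
    PEG1: float = math.log(2) / 10.8
    IL2: float = 6.6 / 1.38

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"elimination rate {name} must be > 0, got {v}")

    def as_array(self):
        return (self.PEG46, self.PEG3, self.PEG2, self.PEG1, self.IL2)


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set of the mechanistic model."""

    release: ReleaseRateSet = field(default_factory=ReleaseRateSet)
    k_elim: EliminationRates = field(default_factory=EliminationRates)
    physiology: PhysiologyConstants = field(default_factory=PhysiologyConstants)
    binding: dict[str, dict[str, BindingStep]] = field(default_factory=binding_from_spr)

    def __post_init__(self) -> None:
        for analyte in ACTIVE_ANALYTES:
            if analyte not in self.binding:
                raise ParameterError(f"binding entries missing for analyte {analyte!r}")
            for surface in SURFACES:
                if surface not in self.binding[analyte]:
                    raise ParameterError(f"binding step {analyte}/{surface} missing")
        for bad in ("PEG46", "PEG3"):
            if bad in self.binding:
                raise ParameterError(f"{bad} is inactive and must not carry binding entries")

    def replace_elimination(self, **rates: float) -> "ModelParameters":
        new = {**asdict(self.k_elim), **rates}
        return ModelParameters(self.release, EliminationRates(**new), self.physiology, self.binding)

    # ---- declarative config round-trip -------------------------------

    def to_dict(self) -> dict:
        return {
            "release": asdict(self.release),
            "k_elim": asdict(self.k_elim),
            "physiology": asdict(self.physiology),
            "binding": {
                a: {s: {"k_on": b.k_on, "k_off": b.k_off} for s, b in per.items()}
                for a, per in self.binding.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(
            release=ReleaseRateSet(**d["release"]),
            k_elim=EliminationRates(**d["k_elim"]),
            physiology=PhysiologyConstants(**d["physiology"]),
            binding={
                a: {s: BindingStep(**b) for s, b in per.items()}
                for a, per in d["binding"].items()
            },
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class DoseEvent:
    """A single dose: an instantaneous IV bolus or a zero-order infusion."""

    time_h: float
    dose_mg_per_kg: float
    route: str = "bolus"  # "bolus" | "infusion"
    duration_h: float = 0.0

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ParameterError("dose time must be >= 0")
        if self.dose_mg_per_kg <= 0:
            raise ParameterError("dose must be > 0")
        if self.route not in ("bolus", "infusion"):
            raise ParameterError(f"unknown route {self.route!r}")
        if self.route == "infusion" and self.duration_h <= 0:
            raise ParameterError("infusion requires a positive duration")


@dataclass(frozen=True)
class DoseRegimen:
    """A dosing schedule for one drug product.

    ``analyte_dosed`` is "NKTR214" (dose enters the fully PEGylated pool) or
    "aldesleukin" (dose enters the free-IL2 pool).  Doses are mg/kg of IL2
    protein content.
    """

    events: tuple[DoseEvent, ...]
    analyte_dosed: str = "NKTR214"

    def __post_init__(self) -> None:
        if self.analyte_dosed not in ("NKTR214", "aldesleukin"):
            raise ParameterError(f"unknown analyte_dosed {self.analyte_dosed!r}")
        if not self.events:
            raise ParameterError("regimen needs at least one dose event")

    @classmethod
    def single_bolus(cls, dose_mg_per_kg: float = 0.8, analyte: str = "NKTR214") -> "DoseRegimen":
        return cls((DoseEvent(0.0, dose_mg_per_kg),), analyte)


def mass_to_molar(ug_per_ml: float, molar_mass: float = IL2_MOLAR_MASS) -> float:
    """ug/mL of IL2 protein content -> mol/L."""
    return ug_per_ml * 1e-3 / molar_mass


def molar_to_mass(molar: float, molar_mass: float = IL2_MOLAR_MASS) -> float:
    """mol/L -> ug/mL of IL2 protein content."""
    return molar * molar_mass * 1e3
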