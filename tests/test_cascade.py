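"""The mechanistic ODE system: structure, conservation, analytic limits."""

import numpy as np
import pytest

import pegcascade as pc
from pegcascade.cascade import (
    ANALYTE_SPECIES,
    COMPLEX_BASE,
    I_IL2,
    I_PEG1,
    I_PEG46,
    I_RA,
    I_RB,
    N_STATES,
    composite_profiles,
    derivatives,
    il2_content_molar,
    initial_state,
    linear_cascade_solution,
    occupancy_profiles,
    simulate,
    species_profiles,
)
from pegcascade.params import (
    DoseRegimen,
    EliminationRates,
    ModelParameters,
    PhysiologyConstants,
    mass_to_molar,
    receptor_pool_concentration,
)
from scipy.integrate import solve_ivp


def tiny_receptor_params(**elim) -> ModelParameters:
    """Receptor pools shrunk ~1e13-fold so binding cannot perturb the cascade."""
    ph = PhysiologyConstants(receptors_alpha_per_cell=1e-9, receptors_beta_per_cell=1e-10)
    base = ModelParameters(physiology=ph)
    return base.replace_elimination(**elim) if elim else base


class TestReceptorPools:
    def test_alpha_pool_molarity(self):
        assert receptor_pool_concentration(3.9, 10000) == pytest.approx(6.476e-11, rel=1e-3)

    def test_beta_pool_molarity(self):
        assert receptor_pool_concentration(3.9, 1000) == pytest.approx(6.476e-12, rel=1e-3)

    def test_zero_cells_zero_pool(self):
        assert receptor_pool_concentration(0.0, 12345) == 0.0


class TestInitialState:
    def test_prodrug_bolus_lands_in_pegylated_pool(self, default_params):
        y0 = initial_state(DoseRegimen.single_bolus(0.8), default_params)
        c_ug_ml = y0[I_PEG46] * default_params.physiology.il2_molar_mass * 1e3
        assert c_ug_ml == pytest.approx(11.6, rel=1e-9)  # dose / V by construction
        assert np.all(y0[[i for i in range(5) if i != I_PEG46]] == 0.0)

    def test_free_il2_bolus_lands_in_il2_pool(self, default_params):
        y0 = initial_state(DoseRegimen.single_bolus(0.8, "aldesleukin"), default_params)
        assert y0[I_IL2] > 0
        assert np.all(y0[:4] == 0.0)

    def test_receptors_start_full_and_complexes_empty(self, default_params):
        y0 = initial_state(DoseRegimen.single_bolus(0.8), default_params)
        assert y0[I_RA] == default_params.physiology.receptor_alpha_molar
        assert y0[I_RB] == default_params.physiology.receptor_beta_molar
        assert np.all(y0[7:] == 0.0)


class TestDerivatives:
    def test_zero_state_zero_derivative(self, default_params):
        y = np.zeros(N_STATES)
        assert np.all(derivatives(y, default_params) == 0.0)

    def test_first_release_step_rate(self):
        # only the fully PEGylated pool present, eliminations negligible:
        # material moves 46PEG -> 3PEG at 0.044/h and nowhere else
        p = tiny_receptor_params(**{k: 1e-12 for k in ("PEG46", "PEG3", "PEG2", "PEG1", "IL2")})
        y = np.zeros(N_STATES)
        y[I_PEG46] = 1e-7
        d = derivatives(y, p)
        assert d[I_PEG46] == pytest.approx(-0.044 * 1e-7, rel=1e-6)
        assert d[I_PEG46 + 1] == pytest.approx(0.044 * 1e-7, rel=1e-6)
        assert np.allclose(d[2:5], 0.0, atol=1e-22)

    def test_release_and_binding_conserve_il2_content(self, default_params):
        # with elimination removed, the content-weighted derivative sums to zero
        p = default_params.replace_elimination(**{k: 1e-300 for k in ("PEG46", "PEG3", "PEG2", "PEG1", "IL2")})
        rng = np.random.default_rng(3)
        y = np.abs(rng.normal(1e-9, 1e-9, N_STATES))
        d = derivatives(y, p)
        content_flux = d[:5].sum() + sum(d[COMPLEX_BASE[a] : COMPLEX_BASE[a] + 3].sum() for a in ANALYTE_SPECIES)
        assert abs(content_flux) < 1e-9 * np.abs(d).max()


class TestSimulate:
    def test_one_peg_peaks_in_window(self, nktr_simulation):
        prof = species_profiles(nktr_simulation)["PEG1"]
        t_peak = prof.times_h[np.argmax(prof.values)]
        assert 24.0 <= t_peak <= 28.5

    def test_total_content_conserved_without_elimination(self, default_params):
        p = default_params.replace_elimination(**{k: 1e-15 for k in ("PEG46", "PEG3", "PEG2", "PEG1", "IL2")})
        t = np.linspace(0.0, 500.0, 201)
        res = simulate(p, DoseRegimen.single_bolus(0.8), t)
        totals = np.array([il2_content_molar(res.states[:, i]) for i in range(t.size)])
        assert np.max(np.abs(totals / totals[0] - 1.0)) < 1e-6

    def test_everything_decays_with_elimination(self, calibrated_params):
        t = np.linspace(0.0, 2000.0, 401)
        res = simulate(calibrated_params, DoseRegimen.single_bolus(0.8), t)
        assert il2_content_molar(res.states[:, -1]) < 1e-6 * il2_content_molar(res.states[:, 1])

    def test_zero_receptors_leave_complexes_empty(self):
        res = simulate(tiny_receptor_params(), DoseRegimen.single_bolus(0.8), np.linspace(0, 100, 51))
        assert np.all(res.states[7:] < 1e-20)

    def test_matches_linear_chain_matrix_exponential(self):
        # binding negligible -> the five species follow the analytic solution
        # of the linear compartment chain; compared where each species sits
        # above 1e-3 of its own peak (below that the comparison probes solver
        # round-off, not the model)
        p = tiny_receptor_params()
        t = np.linspace(0.0, 300.0, 121)
        res = simulate(p, DoseRegimen.single_bolus(0.8), t, rtol=1e-12, atol=1e-24)
        c0 = initial_state(DoseRegimen.single_bolus(0.8), p)[I_PEG46]
        analytic = linear_cascade_solution(p, c0, t)
        numeric = res.states[:5].T
        mask = analytic > 1e-3 * analytic.max(axis=0)[None, :]
        assert np.max(np.abs(numeric[mask] - analytic[mask]) / analytic[mask]) < 1e-8

    def test_receptor_mass_balances_along_trajectory(self, nktr_simulation):
        ph = nktr_simulation.params.physiology
        Y = nktr_simulation.states
        ra = Y[I_RA] + sum(Y[COMPLEX_BASE[a]] + Y[COMPLEX_BASE[a] + 2] for a in ANALYTE_SPECIES)
        rb = Y[I_RB] + sum(Y[COMPLEX_BASE[a] + 1] + Y[COMPLEX_BASE[a] + 2] for a in ANALYTE_SPECIES)
        assert np.max(np.abs(ra - ph.receptor_alpha_molar)) < 1e-6 * ph.receptor_alpha_molar
        assert np.max(np.abs(rb - ph.receptor_beta_molar)) < 1e-6 * ph.receptor_beta_molar

    def test_grid_must_cover_events(self, default_params):
        reg = DoseRegimen((pc.DoseEvent(0.0, 0.8), pc.DoseEvent(300.0, 0.8)), "NKTR214")
        with pytest.raises(ValueError):
            simulate(default_params, reg, np.linspace(0, 100, 11))

    def test_repeat_bolus_superposes_in_linear_regime(self):
        p = tiny_receptor_params()
        t = np.linspace(0.0, 96.0, 97)
        single = simulate(p, DoseRegimen.single_bolus(0.8), t)
        double = simulate(
            p, DoseRegimen((pc.DoseEvent(0.0, 0.8), pc.DoseEvent(24.0, 0.8)), "NKTR214"), t
        )
        i48 = np.searchsorted(t, 48.0)
        expected = single.states[:5, i48] + single.states[:5, np.searchsorted(t, 24.0)]
        assert double.states[:5, i48] == pytest.approx(expected, rel=1e-7)


class TestComposites:
    def test_only_pegylated_species_at_dose_time(self, nktr_simulation):
        comps = composite_profiles(species_profiles(nktr_simulation))
        assert comps["AC"].values[0] == 0.0
        assert comps["RC"].values[0] == pytest.approx(11.6, rel=1e-9)

    def test_active_subset_never_exceeds_total(self, nktr_simulation):
        comps = composite_profiles(species_profiles(nktr_simulation))
        assert np.all(comps["AC"].values <= comps["RC"].values + 1e-12)
        assert np.all(comps["onePEG_assay"].values <= comps["AC"].values + 1e-12)

    def test_mismatched_grids_rejected(self, nktr_simulation):
        sp = species_profiles(nktr_simulation)
        bad = dict(sp)
        bad["IL2"] = pc.ConcentrationProfile(sp["IL2"].times_h[:-1], sp["IL2"].values[:-1], "IL2")
        with pytest.raises(ValueError):
            composite_profiles(bad)


class TestOccupancy:
    def test_zero_drug_zero_occupancy(self, default_params):
        t = np.linspace(0, 48, 25)
        res = simulate(default_params, DoseRegimen.single_bolus(1e-12), t)
        for prof in occupancy_profiles(res):
            assert np.all(prof.percent_occupied < 1e-3)

    def test_bounded_between_zero_and_hundred(self, nktr_simulation, aldesleukin_simulation):
        for sim in (nktr_simulation, aldesleukin_simulation):
            for prof in occupancy_profiles(sim):
                assert np.all(prof.percent_occupied >= 0.0)
                assert np.all(prof.percent_occupied <= 100.0 + 1e-9)

    @staticmethod
    def _frozen_ligand_params(base: ModelParameters) -> ModelParameters:
        """Release and elimination frozen so the free ligand stays constant."""
        from pegcascade.params import ReleaseRateSet

        tiny = 1e-300
        return ModelParameters(
            release=ReleaseRateSet(tiny, tiny, tiny, tiny),
            k_elim=EliminationRates(tiny, tiny, tiny, tiny, tiny),
            physiology=base.physiology,
            binding=base.binding,
        )

    def test_equilibrium_matches_langmuir_isotherm(self, default_params):
        # constant free 2PEG (release/elimination frozen): the dimeric-pathway
        # occupancy settles on 100*C/(C+Kd_eff); receptor depletion is
        # negligible because the pools are picomolar
        p = self._frozen_ligand_params(default_params)
        kd_eff = p.binding["2PEG"]["beta"].kd
        conc = 2.0 * kd_eff
        y0 = np.zeros(N_STATES)
        y0[ANALYTE_SPECIES["2PEG"]] = conc
        y0[I_RA] = p.physiology.receptor_alpha_molar
        y0[I_RB] = p.physiology.receptor_beta_molar
        sol = solve_ivp(lambda t, y: derivatives(y, p), (0, 50.0), y0, method="BDF", rtol=1e-10, atol=1e-18)
        arb = sol.y[COMPLEX_BASE["2PEG"] + 1, -1]
        occupancy = 100.0 * arb / p.physiology.receptor_beta_molar
        assert occupancy == pytest.approx(100.0 * conc / (conc + kd_eff), rel=0.01)

    def test_saturation_limit(self, default_params):
        p = self._frozen_ligand_params(default_params)
        kd_eff = p.binding["2PEG"]["beta"].kd
        y0 = np.zeros(N_STATES)
        y0[ANALYTE_SPECIES["2PEG"]] = 1e3 * kd_eff
        y0[I_RA] = p.physiology.receptor_alpha_molar
        y0[I_RB] = p.physiology.receptor_beta_molar
        sol = solve_ivp(lambda t, y: derivatives(y, p), (0, 50.0), y0, method="BDF", rtol=1e-10, atol=1e-18)
        occupancy = 100.0 * sol.y[COMPLEX_BASE["2PEG"] + 1, -1] / p.physiology.receptor_beta_molar
        assert occupancy > 99.0


class TestProfileIO:
    def test_csv_roundtrip(self, nktr_simulation, tmp_path):
        from pegcascade.cascade import profiles_from_csv, profiles_to_csv

        comps = composite_profiles(species_profiles(nktr_simulation))
        path = tmp_path / "profiles.csv"
        profiles_to_csv(comps, path)
        back = profiles_from_csv(path)
        for name, prof in comps.items():
            assert np.allclose(back[name].values, prof.values)
            assert np.allclose(back[name].times_h, prof.times_h)

    def test_params_yaml_roundtrip(self, calibrated_params, tmp_path):
        path = tmp_path / "params.yaml"
        calibrated_params.save(path)
        loaded = ModelParameters.load(path)
        assert loaded.k_elim == calibrated_params.k_elim
        assert loaded.release == calibrated_params.release
        assert loaded.binding == calibrated_params.binding
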