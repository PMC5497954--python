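"""SPR 1:1 binding kinetics: closed forms, global fitting, Kd arithmetic."""

import numpy as np
import pytest

from pegcascade.params import SPR_KINETICS, KineticConstants
from pegcascade.spr import (
    DilutionSeries,
    FitError,
    Sensorgram,
    association_response,
    dissociation_response,
    equilibrium_kd,
    fit_1to1,
    fold_change,
    kd_table,
    sensorgram_model,
)
from pegcascade.synth import gen_sensorgrams

ALL_SETS = [(a, s) for a in SPR_KINETICS for s in SPR_KINETICS[a]]


def _series_for(analyte: str) -> DilutionSeries:
    # the measured design: 5 x 3-fold from 100 nM (free IL2) or 300 nM (conjugates)
    top = 100e-9 if analyte == "IL2" else 300e-9
    return DilutionSeries(top_concentration_M=top)


class TestClosedForms:
    def test_zero_concentration_gives_zero(self):
        t = np.linspace(0, 180, 10)
        assert np.all(association_response(1e6, 0.01, 0.0, 100.0, t) == 0.0)

    def test_half_maximal_plateau_at_kd(self):
        ka, kd = 1e6, 0.01
        plateau = association_response(ka, kd, kd / ka, 100.0, 1e9)
        assert plateau == pytest.approx(50.0, rel=1e-9)

    def test_il2_beta_surface_at_its_kd(self):
        # C equals the IL2/beta Kd so the 3-minute response sits at Rmax/2
        assert association_response(1.26e6, 0.301, 238.9e-9, 100.0, 180.0) == pytest.approx(50.0, abs=0.5)

    def test_association_plateau_matches_steady_state(self):
        ka, kd, C, rmax = 2e5, 0.005, 50e-9, 80.0
        kobs = ka * C + kd
        t = 10.0 / kobs
        expected = ka * C * rmax / kobs
        assert association_response(ka, kd, C, rmax, t) == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize(
        "kd, r0, t, expected",
        [
            (0.301, 100.0, 0.0, 100.0),
            (0.301, 100.0, np.log(2) / 0.301, 50.0),
            (0.014, 100.0, 180.0, 8.046),  # 100*exp(-2.52)
        ],
    )
    def test_dissociation(self, kd, r0, t, expected):
        assert dissociation_response(kd, r0, t) == pytest.approx(expected, abs=5e-3)


class TestEquilibriumKd:
    @pytest.mark.parametrize(
        "ka, kd, kd_nM",
        [
            (4.84e7, 0.415, 8.57),    # free IL2 at the alpha subunit
            (1.46e8, 0.014, 0.0959),  # free IL2 at the alpha+beta surface
        ],
    )
    def test_measured_rate_quotients(self, ka, kd, kd_nM):
        assert equilibrium_kd(ka, kd) * 1e9 == pytest.approx(kd_nM, rel=5e-3)

    def test_ratio_identity(self):
        assert equilibrium_kd(123.4, 123.4) == pytest.approx(1.0)

    def test_zero_ka_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_kd(0.0, 0.1)


class TestFoldChange:
    def test_one_peg_at_beta(self):
        f = fold_change(SPR_KINETICS["1PEG"]["beta"], SPR_KINETICS["IL2"]["beta"])
        assert f == pytest.approx(7.4, abs=0.05)

    def test_two_peg_at_alphabeta(self):
        f = fold_change(SPR_KINETICS["2PEG"]["alphabeta"], SPR_KINETICS["IL2"]["alphabeta"])
        assert f == pytest.approx(4668, rel=0.01)

    def test_self_fold_is_one(self):
        kc = SPR_KINETICS["IL2"]["beta"]
        assert fold_change(kc, kc) == 1.0

    def test_mismatched_surfaces_rejected(self):
        with pytest.raises(ValueError):
            fold_change(SPR_KINETICS["IL2"]["beta"], SPR_KINETICS["IL2"]["alpha"])

    def test_kd_ordering_monotone_in_peg_number(self):
        table = kd_table()
        for surface in ("alpha", "beta", "alphabeta"):
            sub = table[table["receptor_surface"] == surface].set_index("analyte")["Kd_nM"]
            assert sub["IL2"] < sub["1PEG"] < sub["2PEG"]


class TestGlobalFit:
    @pytest.mark.parametrize("analyte, surface", ALL_SETS)
    def test_noiseless_fit_inverts_generator(self, analyte, surface):
        truth = SPR_KINETICS[analyte][surface]
        sgs = gen_sensorgrams(truth, _series_for(analyte), sigma_fraction_rmax=0.0)
        kc, diag = fit_1to1(sgs, analyte, surface)
        assert kc.k_on == pytest.approx(truth.k_on, rel=1e-3)
        assert kc.k_off == pytest.approx(truth.k_off, rel=1e-3)
        assert kc.kd == pytest.approx(truth.kd, rel=2e-3)

    def test_noisy_fit_within_ten_percent(self):
        truth = SPR_KINETICS["IL2"]["beta"]
        sgs = gen_sensorgrams(truth, _series_for("IL2"), sigma_fraction_rmax=0.01, seed=11)
        kc, _ = fit_1to1(sgs)
        assert kc.k_on == pytest.approx(truth.k_on, rel=0.10)
        assert kc.k_off == pytest.approx(truth.k_off, rel=0.10)

    def test_single_curve_rejected(self):
        truth = SPR_KINETICS["IL2"]["beta"]
        sgs = gen_sensorgrams(truth, DilutionSeries(n_levels=2), sigma_fraction_rmax=0.0)
        with pytest.raises(FitError):
            fit_1to1(sgs[:1])

    def test_nonpositive_concentration_rejected(self):
        t = np.linspace(0, 400, 40)
        with pytest.raises((FitError, ValueError)):
            fit_1to1(
                [
                    Sensorgram(t, np.ones_like(t), 0.0),
                    Sensorgram(t, np.ones_like(t), 1e-9),
                ]
            )

    def test_plateau_only_data_flagged(self):
        # fast association: every curve reaches its plateau within a sample or
        # two, so the on-rate is carried mostly by the dissociation phase
        kc_fast = KineticConstants(1e7, 0.05, "IL2", "beta")
        sgs = gen_sensorgrams(kc_fast, DilutionSeries(top_concentration_M=1e-5), sigma_fraction_rmax=0.0)
        _, diag = fit_1to1(sgs)
        assert diag["plateau_only"]


def test_sensorgram_model_continuous_at_phase_switch():
    t = np.array([179.0, 180.0, 181.0])
    r = sensorgram_model(1e6, 0.01, 100.0, 50e-9, t)
    assert abs(r[1] - r[0]) < 1.0 and r[2] < r[1]
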