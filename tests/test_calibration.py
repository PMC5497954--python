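"""Parameter estimation: objective properties, recovery, determinism."""

import numpy as np
import pytest

from pegcascade.calibration import (
    CalibrationProblem,
    PK_ANCHORS,
    anchor_objective,
    calibrate,
    objective,
    pk_anchor_check,
    predict_composites,
)
from pegcascade.cascade import ConcentrationProfile
from pegcascade.params import EliminationRates, ModelParameters
from pegcascade.synth import SyntheticConfig, gen_pk_study, mean_profiles

ELIM_FREE = tuple(f"k_elim.{s}" for s in ("PEG46", "PEG3", "PEG2", "PEG1", "IL2"))


def _noiseless_problem(truth: ModelParameters, seed: int = 0) -> CalibrationProblem:
    study = gen_pk_study(SyntheticConfig(truth=truth, pk_cv=0.0, seed=seed))
    return CalibrationProblem(observed=mean_profiles(study), base_params=truth, seed=seed)


class TestObjective:
    def test_zero_at_truth_on_self_generated_data(self, default_params):
        problem = _noiseless_problem(default_params)
        truth_vec = np.array(default_params.k_elim.as_array())
        assert objective(truth_vec, problem) < 1e-16

    @pytest.mark.parametrize("which", range(5))
    def test_perturbing_any_rate_increases_it(self, default_params, which):
        problem = _noiseless_problem(default_params)
        truth_vec = np.array(default_params.k_elim.as_array())
        bumped = truth_vec.copy()
        bumped[which] *= 1.3
        assert objective(bumped, problem) > objective(truth_vec, problem) + 1e-6

    def test_log_residuals_scale_invariant(self, default_params):
        # multiplying observations and predictions by a common factor (here:
        # scaling the dose and the observed study together) leaves it unchanged
        study = gen_pk_study(SyntheticConfig(truth=default_params, pk_cv=0.10, seed=4))
        obs = mean_profiles(study)
        obs10 = {
            k: ConcentrationProfile(p.times_h, 10.0 * p.values, p.analyte) for k, p in obs.items()
        }
        p1 = CalibrationProblem(observed=obs, base_params=default_params, dose_mg_per_kg=0.8)
        p10 = CalibrationProblem(observed=obs10, base_params=default_params, dose_mg_per_kg=8.0)
        v = np.array(default_params.k_elim.as_array()) * 1.1
        assert objective(v, p1) == pytest.approx(objective(v, p10), rel=1e-9)

    def test_invalid_parameters_penalised_finitely(self, default_params):
        problem = _noiseless_problem(default_params)
        val = objective(np.array([-1.0, 0.1, 0.1, 0.1, 0.1]), problem)
        assert np.isfinite(val) and val >= 1e5


class TestCalibrate:
    def test_noiseless_recovery_within_two_percent(self, default_params):
        problem = _noiseless_problem(default_params, seed=9)
        result = calibrate(problem, ga_popsize=50, ga_maxiter=60)
        truth = dict(zip(ELIM_FREE, default_params.k_elim.as_array()))
        for name in ELIM_FREE:
            assert result.estimates[name] == pytest.approx(truth[name], rel=0.02)

    def test_bitwise_reproducible_given_seed(self, default_params):
        study = gen_pk_study(SyntheticConfig(truth=default_params, pk_cv=0.15, seed=21))
        obs = mean_profiles(study)
        kw = dict(ga_popsize=20, ga_maxiter=15)
        r1 = calibrate(CalibrationProblem(observed=obs, base_params=default_params, seed=21), **kw)
        r2 = calibrate(CalibrationProblem(observed=obs, base_params=default_params, seed=21), **kw)
        assert r1.estimates == r2.estimates
        assert r1.objective == r2.objective

    def test_truth_outside_bounds_gets_flagged(self, default_params):
        # bounds narrower than the generating truth: the fit clips and flags
        problem = _noiseless_problem(default_params, seed=3)
        problem.bounds["k_elim.PEG46"] = (1e-3, 0.02)  # truth ~0.045
        result = calibrate(problem, ga_popsize=20, ga_maxiter=25)
        assert result.bounds_hit["k_elim.PEG46"]
        assert result.flagged

    def test_release_rate_bounds_respect_twenty_percent(self, default_params):
        problem = CalibrationProblem(
            observed={}, base_params=default_params,
            free_parameters=("release.k_46_to_3",),
        )
        lo, hi = problem.bounds["release.k_46_to_3"]
        assert lo == pytest.approx(0.8 * 0.044)
        assert hi == pytest.approx(1.2 * 0.044)


class TestAnchorRoute:
    def test_anchor_objective_favors_calibrated_over_default(self, default_params, calibrated_params):
        problem = CalibrationProblem(observed={}, base_params=default_params)
        v_default = np.array(default_params.k_elim.as_array())
        v_cal = np.array(calibrated_params.k_elim.as_array())
        assert anchor_objective(v_cal, problem) < anchor_objective(v_default, problem)

    def test_anchor_check_self_consistency(self, calibrated_params):
        # the check's model column must reproduce NCA run on the model's own
        # composite predictions
        from pegcascade.nca import nca_report

        table = pk_anchor_check(calibrated_params).set_index(["composite", "statistic"])
        t = np.arange(0.0, 240.25, 0.25)
        pred = predict_composites(calibrated_params, 0.8, t)
        rep = nca_report(ConcentrationProfile(t, pred["AC"], "AC"))
        assert table.loc[("AC", "Cmax"), "model"] == pytest.approx(rep.cmax, rel=1e-12)
        assert table.loc[("AC", "AUClast"), "model"] == pytest.approx(rep.auc_last, rel=1e-12)

    def test_all_printed_anchors_reported(self, calibrated_params):
        table = pk_anchor_check(calibrated_params)
        assert len(table) == len(PK_ANCHORS)
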