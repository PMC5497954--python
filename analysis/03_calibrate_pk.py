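"""Calibrate the unprinted elimination rates and check the PK anchors.

Two estimation routes are run: (a) the anchor route — fit the five
per-species elimination rates to the published composite summary statistics
(Cmax / Tmax / AUC of the total-conjugate, active-conjugate and 1-PEG
assays plus the free-IL2 comparator); (b) the recovery route — generate a
noisy synthetic sparse study from known truth and re-estimate the rates
from the composite profiles, demonstrating identifiability.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pegcascade import ModelParameters
from pegcascade.calibration import (
    CalibrationProblem,
    calibrate,
    calibrate_to_anchors,
    pk_anchor_check,
)
from pegcascade.synth import SyntheticConfig, gen_pk_study, mean_profiles


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    params, result = calibrate_to_anchors(ModelParameters(), seed=args.seed)
    params.save(args.out_dir / "params_calibrated.yaml")
    check = pk_anchor_check(params)
    check.to_csv(args.out_dir / "pk_anchor_check.csv", index=False)
    print("anchor-route estimates:", {k: round(v, 4) for k, v in result.estimates.items()})
    print(check.round(4).to_string(index=False))
    n_ok = int((check["rel_deviation"].abs() <= 0.10).sum())
    print(f"{n_ok}/{len(check)} anchors within the 10% concordance band "
          "(the active-composite Tmax cannot peak before ~24 h under the "
          "sequential release cascade; see docs/methods.md).")

    truth_params = ModelParameters()
    config = SyntheticConfig(truth=truth_params, pk_cv=0.15, seed=args.seed)
    study = gen_pk_study(config)
    problem = CalibrationProblem(observed=mean_profiles(study), base_params=truth_params, seed=args.seed)
    rec = calibrate(problem, ga_popsize=50, ga_maxiter=60)
    truth = dict(zip(problem.free_parameters, truth_params.k_elim.as_array()))
    rows = [
        {"parameter": n, "truth": truth[n], "estimate": rec.estimates[n],
         "rel_error": rec.estimates[n] / truth[n] - 1.0}
        for n in problem.free_parameters
    ]
    recovery = pd.DataFrame(rows)
    recovery.to_csv(args.out_dir / "calibration_recovery.csv", index=False)
    print()
    print(recovery.round(4).to_string(index=False))
    print(f"\nAt 15% CV, n=5/time point, elimination rates recovered within "
          f"{recovery['rel_error'].abs().max() * 100:.0f}% on this realisation "
          "(the two upstream rates share a shallow objective valley; see docs/methods.md).")


if __name__ == "__main__":
    main()
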