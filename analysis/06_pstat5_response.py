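"""Downstream signalling: pSTAT5 as an indirect response to occupancy.

Drives the turnover model with the CD3-scaled total receptor occupancy of
the calibrated model, generates a noisy virtual pSTAT5 study, re-fits the
response parameters, and summarises the kinetic contrast between the
prodrug (slow rise, peak ~2 days, sustained for days) and free IL2 (brief
pulse resolving within hours).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pegcascade import DoseRegimen, simulate
from pegcascade.calibration import calibrated_parameters
from pegcascade.pstat5 import auec, cd3_scaled_occupancy, fit_pstat5, simulate_pstat5
from pegcascade.synth import DEFAULT_IRM_TRUTH, SyntheticConfig, gen_pstat5, mean_effect


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    params = calibrated_parameters(args.seed)
    t = np.arange(0.0, 240.0 + 0.25, 0.25)
    rows = []
    effects = {}
    for drug in ("NKTR214", "aldesleukin"):
        result = simulate(params, DoseRegimen.single_bolus(0.8, drug), t)
        driver = cd3_scaled_occupancy(result)
        effect = simulate_pstat5(driver, DEFAULT_IRM_TRUTH, t_grid=t)
        effects[drug] = effect
        i = int(np.argmax(effect.percent_pstat5))
        rows.append({"drug": drug, "peak_percent": effect.percent_pstat5[i],
                     "peak_time_h": effect.times_h[i],
                     "auec_pct_h": auec(effect, baseline=DEFAULT_IRM_TRUTH.baseline)})
    summary = pd.DataFrame(rows)

    config = SyntheticConfig(truth=params, seed=args.seed)
    study, truth_curve = gen_pstat5(config)
    observed = mean_effect(study)
    nktr = simulate(params, DoseRegimen.single_bolus(), t)
    fitted, diag = fit_pstat5(observed, cd3_scaled_occupancy(nktr))
    fit_rows = pd.DataFrame(
        {
            "parameter": ["k_in", "k_out", "s_max", "o_50"],
            "truth": [DEFAULT_IRM_TRUTH.k_in, DEFAULT_IRM_TRUTH.k_out,
                      DEFAULT_IRM_TRUTH.s_max, DEFAULT_IRM_TRUTH.o_50],
            "estimate": [fitted.k_in, fitted.k_out, fitted.s_max, fitted.o_50],
        }
    )
    fit_rows["rel_error"] = fit_rows["estimate"] / fit_rows["truth"] - 1.0

    summary.to_csv(args.out_dir / "pstat5_summary.csv", index=False)
    fit_rows.to_csv(args.out_dir / "pstat5_fit_recovery.csv", index=False)
    print(summary.round(2).to_string(index=False))
    print()
    print(fit_rows.round(3).to_string(index=False))
    n, a = summary.iloc[0], summary.iloc[1]
    print(f"\nprodrug pSTAT5 peaks at {n['peak_percent']:.1f}% around {n['peak_time_h']:.0f} h "
          f"(AUEC {n['auec_pct_h']:.0f} %.h) vs the free-IL2 pulse ({a['auec_pct_h']:.0f} %.h); "
          f"refit on the noisy virtual study reproduces the response peak at "
          f"{diag['peak_percent']:.1f}% / {diag['peak_time_h']:.0f} h.")


if __name__ == "__main__":
    main()
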