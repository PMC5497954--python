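"""PEG-release kinetics: half-lives, rate recovery from noisy data, Arrhenius.

Establishes the in-vitro release arm of the model: the pH dependence of the
first-order release constant (t1/2 ~12 h at pH 7.4 vs ~77 h at pH 6.4), rate
recovery from a simulated noisy release assay, the semi-log diagnostic for
first-order kinetics, and the activation energy from a temperature series.
"""

import argparse
import math
from pathlib import Path

import numpy as np
import pandas as pd

from pegcascade.release import arrhenius_fit, fit_release_rate, half_life, semilog_slope_check
from pegcascade.synth import gen_release


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for ph, k in ((7.4, 0.059), (6.4, 0.009)):
        rows.append({"quantity": f"half_life_pH{ph}_h", "value": half_life(k)})

    times = np.linspace(0.0, 72.0, 13)[1:]
    tc = gen_release(0.044, times, cv=0.10, seed=args.seed)
    k_fit, diag = fit_release_rate(tc)
    rows.append({"quantity": "fitted_k_pH7.4_noisy_h-1", "value": k_fit})
    rows.append({"quantity": "fitted_k_relative_error", "value": k_fit / 0.044 - 1.0})

    courses = [gen_release(0.044, times, cv=0.0, seed=args.seed) for _ in range(2)]
    slopes = semilog_slope_check(courses)
    rows.append({"quantity": "semilog_slope_h-1", "value": slopes[0]})

    temps = np.array([298.15, 303.15, 310.15, 313.15])
    ea, ln_a = 130.0, math.log(0.044) + 130e3 / (8.314 * 310.15)
    ks = np.exp(ln_a - ea * 1e3 / (8.314 * temps))
    fit = arrhenius_fit(list(zip(temps, ks)))
    rows.append({"quantity": "arrhenius_Ea_kJ_mol", "value": fit.activation_energy_kj_mol})
    rows.append({"quantity": "arrhenius_r_squared", "value": fit.r_squared})

    out = args.out_dir / "release_kinetics.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(pd.DataFrame(rows).to_string(index=False))
    print(f"\nRelease t1/2 spans {rows[1]['value']:.0f} h (pH 6.4) to {rows[0]['value']:.0f} h (pH 7.4); "
          f"a 10% CV assay still recovers k within {abs(rows[3]['value']) * 100:.1f}%. -> {out}")


if __name__ == "__main__":
    main()
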