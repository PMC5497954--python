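"""Receptor binding kinetics: Kd table, PEGylation fold-changes, SPR fit recovery.

Derives the equilibrium constants from the measured on/off rates at each
receptor surface, quantifies how PEGylation shifts affinity (modestly at the
dimeric beta surface, thousands-fold at the alpha-beta surface), and shows
that the global 1:1 sensorgram fit recovers the generating rates from a
noisy 5-point 3-fold dilution series.
"""

import argparse
from pathlib import Path

import pandas as pd

from pegcascade.params import SPR_KINETICS
from pegcascade.spr import DilutionSeries, fit_1to1, kd_table
from pegcascade.synth import gen_sensorgrams


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    table = kd_table()
    table.to_csv(args.out_dir / "binding_table.csv", index=False)
    print(table.round(3).to_string(index=False))

    rows = []
    for analyte, surface, top in (("IL2", "beta", 100e-9), ("1PEG", "alphabeta", 300e-9)):
        truth = SPR_KINETICS[analyte][surface]
        series = DilutionSeries(top_concentration_M=top * 30)  # span the Kd
        sgs = gen_sensorgrams(truth, series, sigma_fraction_rmax=0.01, seed=args.seed)
        kc, diag = fit_1to1(sgs, analyte, surface)
        rows.append(
            {
                "analyte": analyte,
                "surface": surface,
                "ka_err": kc.k_on / truth.k_on - 1.0,
                "kd_err": kc.k_off / truth.k_off - 1.0,
                "Kd_fit_nM": kc.kd * 1e9,
            }
        )
    rec = pd.DataFrame(rows)
    rec.to_csv(args.out_dir / "spr_fit_recovery.csv", index=False)
    print()
    print(rec.round(4).to_string(index=False))
    beta_fold = table.query("receptor_surface=='beta' and analyte=='1PEG'")["fold_vs_IL2"].iloc[0]
    ab_fold = table.query("receptor_surface=='alphabeta' and analyte=='2PEG'")["fold_vs_IL2"].iloc[0]
    print(f"\nPEGylation raises Kd {beta_fold:.1f}-fold at the beta surface but "
          f"{ab_fold:.0f}-fold at the alpha-beta surface; 1% RU noise leaves rate "
          f"recovery within {rec[['ka_err', 'kd_err']].abs().to_numpy().max() * 100:.1f}%.")


if __name__ == "__main__":
    main()
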