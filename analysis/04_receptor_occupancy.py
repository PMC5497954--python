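"""Receptor occupancy after a single prodrug dose: who occupies what.

Simulates the calibrated model after 0.8 mg/kg of the prodrug and
tabulates the occupancy AUC of each active analyte at the dimeric
(beta-gamma) and trimeric (alpha-beta-gamma) receptor complexes.  The
conjugated species dominate the dimeric receptor while the trace of free
IL2 dominates the trimeric one — the receptor-bias signature.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pegcascade import DoseRegimen, occupancy_profiles, simulate
from pegcascade.calibration import calibrated_parameters
from pegcascade.regimens import occupancy_auc


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    params = calibrated_parameters(args.seed)
    t = np.arange(0.0, 340.0 + 0.25, 0.25)
    result = simulate(params, DoseRegimen.single_bolus(), t)
    occ = {(p.receptor, p.analyte): p for p in occupancy_profiles(result)}

    rows = []
    for receptor in ("betagamma", "alphabetagamma"):
        total = occupancy_auc(occ[(receptor, "total")])
        for analyte in ("2PEG", "1PEG", "IL2"):
            a = occupancy_auc(occ[(receptor, analyte)])
            rows.append({"receptor": receptor, "analyte": analyte,
                         "occupancy_auc_pct_h": a, "share_of_total": a / total})
        rows.append({"receptor": receptor, "analyte": "total",
                     "occupancy_auc_pct_h": total, "share_of_total": 1.0})
    table = pd.DataFrame(rows)
    table.to_csv(args.out_dir / "occupancy_summary.csv", index=False)
    print(table.round(4).to_string(index=False))

    bg = table.query("receptor=='betagamma' and analyte=='total'")["occupancy_auc_pct_h"].iloc[0]
    tri = table.query("receptor=='alphabetagamma' and analyte=='total'")["occupancy_auc_pct_h"].iloc[0]
    il2_share = table.query("receptor=='alphabetagamma' and analyte=='IL2'")["share_of_total"].iloc[0]
    print(f"\nbeta-gamma/trimer occupancy AUC ratio {bg / tri:.2f}; free IL2 supplies "
          f"{il2_share * 100:.1f}% of the trimer occupancy despite its trace exposure.")


if __name__ == "__main__":
    main()
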