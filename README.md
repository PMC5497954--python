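# pegcascade

Mechanistic PK/PD modelling of **releasable-PEG IL2 prodrugs** — drugs like
NKTR-214 (bempegaldesleukin), in which the IL2 protein is silenced by six
hydrolysable ~20 kDa PEG chains placed over its IL2Rα-binding face. At
physiological pH the chains release sequentially with first-order kinetics,
producing a cascade of progressively more active conjugates
(4–6)-PEG-IL2 → 3-PEG-IL2 → 2-PEG-IL2 → 1-PEG-IL2 → free IL2. Because the
PEGs sit at the α-subunit interface, the active conjugates keep most of
their affinity for the dimeric receptor IL2Rβγ (CD8 T / NK cells) while
losing thousands-fold affinity for the trimeric IL2Rαβγ (constitutive on
regulatory T cells). The package is for PK/PD modellers and immunotherapy
scientists who want to simulate, calibrate, and interrogate that mechanism
quantitatively.

## The model

Sixteen ODE states, concentrations molar, time in hours:

* **Release cascade** — a linear chain with rates
  k_rel = (0.044, 0.035, 0.058, 0.040) h⁻¹ measured in vitro at pH 7.4 / 37 °C,
  plus a first-order plasma disappearance rate k_elim per species
  (1-compartment; V derived from dose/C₀).
* **Receptor binding** — for each active analyte A ∈ {IL2, 1-PEG-IL2,
  2-PEG-IL2}, mass-action binding to free IL2Rα and IL2Rβ pools on
  lymphocytes (3.9 cells/nL; 10 000 α and 1 000 β per cell), with sequential
  trimer assembly A·Rα + Rβ ⇌ A·Rαβ. SPR rate constants (k_on, k_off per
  analyte per surface) parameterize the steps; the γ-chain's ~10-fold
  affinity gain enters as k_off/10 on the β-containing steps.
* **Occupancy** — %IL2Rβγ = 100·[A·Rβ]/Rβ_tot; %IL2Rαβγ =
  100·[A·Rαβ]/Rβ_tot (β is the limiting pool; denominator switchable).
  The time-integral (%·h over 0–10 d) is the occupancy AUC, and the ratio
  βγ-AUC / αβγ-AUC is the **bias ratio** — the headline statistic.
* **pSTAT5 response** — an indirect-response (turnover) model
  dP/dt = k_in·(1 + s_max·O/(o_50+O)) − k_out·P driven by the CD3-scaled
  (×0.4) summed occupancy O(t).

Around the core sit: first-order release fitting and Arrhenius analysis,
global 1:1 sensorgram fitting, WinNonlin-style non-compartmental analysis
(linear-log trapezoid, best-adjusted-r² terminal slope), a two-stage
(differential evolution + local) calibrator for the unprinted elimination
rates, regimen builders (single dose, qdx5 × 2 cycles, AUC-matched constant
infusion), and seeded synthetic-data generators for every input.

## Worked example

```python
import pegcascade as pc

params = pc.calibrated_parameters(seed=0)      # fit k_elim to the printed PK anchors
print(pc.pk_anchor_check(params).round(3).to_string(index=False))

comparison = pc.compare_regimens(params, {
    "ald_single":  pc.build_regimen("single"),          # free IL2, one bolus
    "nktr_single": pc.build_regimen("single_nktr214"),  # prodrug, one bolus
})
print(comparison.occupancy_auc.round(1).to_string())
print(comparison.bias_ratios.round(2).to_string())
```

prints

```
     composite statistic   model  anchor  rel_deviation
            AC      Cmax   0.729    0.72          0.012
            AC      Tmax  25.000   16.00          0.562
            AC   AUClast  36.959   37.80         -0.022
  onePEG_assay      Cmax   0.130    0.13         -0.001
  onePEG_assay      Tmax  28.500   24.00          0.188
            RC   AUClast 308.320  308.00          0.001
IL2_comparator   AUClast   1.380    1.38          0.000
                ald_single  nktr_single
betagamma             24.5        671.9
alphabetagamma        85.2        232.9
ald_single     0.29
nktr_single    2.88
```

Reading it: after calibrating the five per-species elimination rates, the
simulated composite assays match the published exposure statistics within a
few percent (Cmax in µg/mL, AUC in µg·h/mL; the 25 h vs 16 h active-composite
peak-time gap is the known structural limit). The regimen table shows the
mechanism: a single prodrug dose accumulates ~670 %·h of occupancy at the
dimeric receptor against ~230 %·h at the trimer (bias ratio 2.9 > 1),
whereas the same IL2 dose given as free protein occupies the trimer more
than the dimer (0.29 < 1) — receptor bias is intrinsic to the conjugates,
not a by-product of slower PK.

The numbered scripts under `analysis/` walk the full study in order
(release kinetics → binding → PK calibration → occupancy → regimen
comparison → pSTAT5) and write their tables to `results/`:

```bash
python analysis/05_regimen_comparison.py --seed 0
```

A `pegcascade` console script exposes the same steps
(`simulate`, `occupancy`, `fit`, `nca`, `pstat5`, `synth`, `release-fit`,
`spr-fit`); try `pegcascade simulate --help`.

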