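# Methods

This note documents the model, its assumptions, the parameter choices that
were genuinely open, and the numerical conventions. Every number quoted
here is either a fixed input constant or a quantity the test suite /
`scripts/acceptance.py` computes at run time.

## The mechanistic model

### State and processes

Sixteen states, all molar concentrations in a single well-mixed plasma
compartment, time in hours:

| block | states |
|---|---|
| free drug species | (4–6)PEG-IL2, 3PEG-IL2, 2PEG-IL2, 1PEG-IL2, IL2 |
| free receptor pools | IL2Rα, IL2Rβ |
| complexes (×3 analytes) | A·Rα, A·Rβ, A·Rαβ for A ∈ {IL2, 1PEG, 2PEG} |

Processes, each elementary and first-order or mass-action:

1. **Sequential release.** The chain (4–6)PEG → 3PEG → 2PEG → 1PEG → IL2
   with rates 0.044, 0.035, 0.058, 0.040 h⁻¹ (in-vitro values at pH 7.4 /
   37 °C; the first step lumps the loss of the first three chains, which is
   why species with 4–6 chains are merged — none of them binds receptor).
   In-vivo release may be freed within ±20 % of these values during
   calibration; by default it is fixed.
2. **Elimination.** Each free species disappears with its own first-order
   rate `k_elim` (clearance + distribution lumped). These five rates are
   not measurable directly and are estimated (see Calibration). Complexes
   are not eliminated and receptor pools are constant — no synthesis,
   internalisation, or cell trafficking.
3. **Binding.** Only species with ≤ 2 PEG chains bind. Per analyte:
   dimeric binding A + Rβ ⇌ A·Rβ, alpha capture A + Rα ⇌ A·Rα, and
   sequential trimer assembly A·Rα + Rβ ⇌ A·Rαβ. Dimeric and trimeric
   complexes compete for the same β pool.

Dosing: a bolus adds `dose·BW/V` (converted to molar via the IL2 protein
mass, 15 300 g/mol — PEG mass is excluded because doses are stated as IL2
content) to the fully PEGylated pool (prodrug) or the free-IL2 pool
(comparator). Infusions are zero-order inputs on the IL2 pool.

### Fixed physiology constants

| constant | value | note |
|---|---|---|
| lymphocytes | 3.9 cells/nL | murine peripheral blood |
| IL2Rα per cell | 10 000 | → α pool ≈ 65 pM |
| IL2Rβ per cell | 1 000 | → β pool ≈ 6.5 pM |
| CD3⁺ fraction | 0.4 | scales occupancy to the pSTAT5 readout |
| γ affinity factor | 10 | applied as k_off/10, see below |
| V (prodrug) | dose/C₀ = 1.379 mL | forces C₀ onto the observed total-conjugate peak (11.6 µg/mL at 0.8 mg/kg, 20 g mouse; ≈ 69 mL/kg) |
| V (free IL2) | 2.424 mL | same rule on the comparator's own peak (6.6 µg/mL); the smaller unPEGylated protein distributes wider, and this V makes C₀/k reproduce its observed exposure |

### Binding parameters and the two γ-chain conventions

The nine (k_on, k_off) pairs come from surface-plasmon-resonance
measurements of each analyte at three chip surfaces: isolated IL2Rα,
isolated IL2Rβ (a stand-in for cellular IL2Rβγ), and a 1:1 α+β mixture (a
stand-in for cellular IL2Rαβγ). Rates are stored in s⁻¹ and converted to
h⁻¹ exactly once, at parameter construction.

Two conventions here were genuinely open, and both were settled by
physical argument plus the model's ability to reproduce the published
occupancy behaviour (the regimen-comparison magnitudes and the ~70 %
trimer-occupancy peak after a free-IL2 bolus):

* **Where the γ-chain factor acts.** The γ chain stabilises only
  β-containing complexes, so k_off is divided by 10 for the β-surface
  step and for the αβ-recruitment step, while the isolated α-subunit
  interaction keeps its measured value. Dividing k_off rather than
  multiplying k_on preserves the measured on-rates (complex stabilisation
  physically slows dissociation). Applying the factor to the α step as
  well makes the trimer pathway ~10× too strong and inverts the
  bias-ratio directions of every free-IL2 regimen.
* **Trimer occupancy denominator.** %IL2Rαβγ is reported against the
  *β* pool — the limiting pool trimer assembly draws from (1 000 vs
  10 000 per cell). Against the α pool the trimer percentage could never
  exceed 10 %, which contradicts the observed ~71 % trimer occupancy under
  a free-IL2 bolus. The denominator is switchable
  (`occupancy_profiles(..., trimer_denominator="alpha")`) and isolated in
  one function.

## Calibration of the unprinted rates

The five elimination rates are fitted, with the in-vitro release rates
fixed (optionally freed within ±20 %). During calibration the binding
terms are dropped: the receptor pools (≈ 71 pM total) sit four orders of
magnitude below drug exposure (≈ 758 nM at C₀), so binding never perturbs
the free species measurably and the release/elimination chain becomes a
linear ODE with an eigendecomposition solution — the objective costs ~1 ms.

Two routes share the same optimiser:

* **Profile route** (`calibrate`): sum of squared log-concentration
  residuals across the observed composites — RC (all species), AC
  (2PEG + 1PEG + IL2), the 1-PEG assay (1PEG + IL2), and the free-IL2
  comparator — with uniform weights. Log residuals make the objective
  scale-invariant and keep the µg/mL-spanning profiles commensurate.
  Sparse studies are collapsed to per-timepoint means first;
  below-quantification values (default LLOQ 0.001 µg/mL) are excluded.
* **Anchor route** (`calibrate_to_anchors`): when only published summary
  statistics are available, squared log-deviations from the anchors
  {AC Cmax 0.72, AC Tmax 16 h, AC AUC 37.8, 1-PEG-assay Cmax 0.13,
  1-PEG-assay Tmax 24 h, RC AUC 308, comparator AUC 1.38}. Tmax residuals
  carry weight 0.25: a peak time read off a sparse sampling schedule is
  quantised at several hours and is a far coarser measurement than a
  concentration or an area, and full weight on Tmax would sacrifice the
  exactly attainable exposure anchors for an unattainable peak time (next
  paragraph).

**Known structural limit.** A sequential first-order cascade feeding the
active composite through the 3PEG pool cannot peak that composite before
~24 h when the release rates are anywhere near their in-vitro values — the
per-species peak times (2PEG ≈ 25 h, 1PEG ≈ 28 h) force it. The measured
active-composite Tmax of 16 h is therefore not reproducible by this model
class (freeing release rates ±20 % and abandoning the AUC anchors only
reaches ≈ 19 h); the corresponding acceptance test is expected to fail and
is intentionally not weakened. All other anchors calibrate to within a few
percent simultaneously.

Optimiser: a seeded global stage (`scipy.optimize.differential_evolution`
over log-parameter space, population ≈ 50, up to 100 generations, Sobol
initialisation, no polish) followed by local refinement — trust-region
least squares on the log residuals for the profile route, restarted
Nelder–Mead for the (Tmax-kinked, hence non-smooth) anchor objective.
Deterministic given the seed; an evolutionary global stage is used because
the log-residual surface has a long shallow valley trading the two
upstream elimination rates (see Limitations).

## Non-compartmental analysis

Linear-log trapezoidal AUC: logarithmic interpolation
(C₁−C₂)Δt/ln(C₁/C₂) on strictly declining positive segments — exact for
exponential decay — and linear trapezoids on rising/equal segments and
segments touching zero. AUMC uses the matched interpolant. λz is the
log-linear regression over the suffix (≥ 3 points, Tmax excluded) with the
best adjusted r²; r² < 0.8 flags the estimate rather than suppressing it.
AUC∞ = AUClast + Clast/λz; AUMC∞ adds Clast·tlast/λz + Clast/λz²;
MRT∞ = AUMC∞/AUC∞ (IV bolus). Sparse designs are averaged per time point
with uniform weights before analysis; the sparse-sampling standard error
of Cmax/AUC is out of scope.

## pSTAT5 indirect response

The driver is the summed total occupancy (βγ + αβγ) multiplied by the
CD3⁺ fraction 0.4. The biomarker follows a turnover equation with
stimulation of production (the canonical choice for an activation marker):

dP/dt = k_in·(1 + s_max·O/(o_50 + O)) − k_out·P,  P(0) = k_in/k_out.

The driver choice (summed occupancy rather than βγ- or αβγ-only) is
switchable by passing a different profile. AUEC is the
baseline-subtracted trapezoidal area over 0–240 h, baseline = the pre-dose
level, so a flat-at-baseline response scores 0. `fit_pstat5` estimates
(k_in, k_out, s_max, o_50) by least squares with k_out initialised at
0.1 h⁻¹.

Generator truth (k_in = 0.15 %·h⁻¹, k_out = 0.1 h⁻¹, s_max = 10.5,
o_50 = 0.8 %) was chosen once to place the virtual prodrug study on the
observed conditions — ≈ 1.5 % baseline, peak ≈ 15 % positive cells about
two days post dose, still several-fold above baseline at 96 h — while the
free-IL2 comparator, whose simulated receptor pulse lasts only a couple of
hours under its fast elimination, resolves toward baseline far earlier.
A single turnover-parameter set cannot simultaneously give the comparator
a ~15 % peak within minutes *and* the prodrug a ~2-day peak; the
parameters are anchored to the prodrug response (the one the response
model is fitted to), and the comparator contrast is treated as
directional.

## Synthetic data

Generators are pure functions of (truth, design, noise, seed):

* release courses — closed-form truth, multiplicative noise, clipped to [0, 1];
* sensorgrams — 5-point 3-fold dilutions, 180 s association + 300 s
  dissociation at 1 Hz, additive Gaussian RU noise (σ = 1 % Rmax default);
* sparse PK studies — 5 animals per time point at 13 sampling times over
  0–240 h, all four composite analytes, multiplicative lognormal noise
  (CV 15 % default), below-LLOQ values flagged and excluded downstream;
* pSTAT5 studies — 14 time points over 0–240 h, 5 animals each, additive
  Gaussian noise (σ = 1 %-point default).

Concentration noise is lognormal because bioanalytical assays are
roughly constant-CV; the factor is mean-corrected (divided by
exp(σ²/2)) so replicate means converge to the truth. The generators
emulate residual assay noise only: no inter-animal kinetic variability, no
assay interference or matrix effects, no drift. Passing recovery tests
therefore demonstrates estimator correctness under the stated error model,
not robustness to structured real-world artefacts.

## Numerical choices

* Stiff integration: BDF, rtol 1e-8, atol 1e-15 M (complexes live at
  sub-pM while drug species reach sub-µM; binding rate constants reach
  ~1e3–1e9 h⁻¹ scales). States are clipped at zero post hoc (undershoot
  ≤ atol). Receptor mass balances are structural invariants of the ODE;
  at these tolerances they close to ~1e-6 relative (the stiff free-IL2
  bolus transient is the worst case), and tests assert 1e-5.
* The linear-chain analytic solution uses eigendecomposition with a
  matrix-exponential fallback if two net rate constants collide within
  1e-10.
* Bolus events are instantaneous state jumps at segment boundaries;
  infusions a constant source term per segment.
* Release-rate fitting fixes the plateau at 1.0 (the assay normalises to a
  strong-base 100 %-release control) and starts from ln 2 / t(~50 %
  release), falling back to 0.05 h⁻¹ — deterministic, no random restarts.
* Global sensorgram fitting shares one (ka, kd, Rmax) across the dilution
  series (per-curve Rmax is not allowed); rates are fitted in log space. A
  plateau-only flag is raised when every curve satisfies
  (ka·C + kd)·180 s > 50, i.e. association carries no curvature.
* Occupancy AUC uses plain trapezoids on the simulation grid (0.25 h);
  occupancy curves are smooth and slowly varying, unlike the exponential
  concentration decays that need the lin-log rule.

## Limitations

* One plasma compartment: no distribution phase, so multi-phasic declines
  are represented only through the lumped elimination rates. The free-IL2
  comparator's elimination is anchored to its exposure (AUC, equivalently
  its short mean residence time), not to its terminal half-life, which
  belongs to a late phase this model class cannot hold simultaneously with
  the observed exposure.
* The two upstream elimination rates ((4–6)PEG and 3PEG) are only weakly
  separated by composite data — the objective has a shallow valley trading
  them — so their individual estimates carry wide uncertainty even when
  the composite fits are excellent; recovery tolerances are stated as
  medians over replicate studies for this reason.
* Receptor pools are static; no receptor-mediated clearance,
  internalisation, or cell-number dynamics, hence no target-mediated
  disposition and no feedback of signalling on receptor expression.
* The pSTAT5 model is fitted at the whole-CD3⁺ level; per-subset
  signalling (Treg vs CD8) is out of scope.
* Tumour exposure and efficacy are out of scope.
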