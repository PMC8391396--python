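# Methods

This note documents the models and procedures implemented in `thermoflux`,
the defaults and tolerances that matter, what the synthetic study emulates,
and the design choices made where the design was genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Rate fitting

**Growth.** Cell counts are modelled as `X(t) = X0·e^{μt}` (exponential
phase only; no lag or death phase). The fit minimizes a soft-L1 robust loss
`Σ ρ(z_i)`, `ρ(z) = 2(√(1+z²) − 1)`, on **relative** residuals
`z_i = (X0·e^{μt_i} − y_i) / (y_i · f_scale)` with `f_scale = 0.3`. Counts
carry multiplicative noise (assays report coefficients of variation), so
relative residuals are the homoscedastic quantity; they also give every time
point equal leverage. With absolute residuals the exponential's gradient at
the latest time point dominates, and a single late outlier moves even the
*global* robust optimum far from the truth — we verified this against a
dense 2-D grid search on the objective. With the relative form,
`f_scale = 0.3` has a direct reading: deviations beyond ~30% are treated as
outliers. The optimizer (scipy `least_squares`, TRF) is restarted from a
few deterministic perturbations of the log-linear initial slope and the
lowest-cost solution kept, because the robust objective can have local
optima in outlier scenarios. Setting `robust=False` gives weighted least
squares on the same relative residuals.

Standard errors come from the Jacobian at the optimum,
`cov = s²(JᵀJ)⁻¹` with `s² = RSS/(n−2)` on relative residuals. Across 200
simulated conditions at 5% CV this yields ±1-SE coverage of μ near the
nominal 68% (the acceptance script recomputes it).

**Exchange rates.** A metabolite with specific exchange rate `q`
(mmol·gDW⁻¹·h⁻¹, secretion positive) and first-order abiotic decay `k`
obeys `dC/dt = q·B(t)/V − k·C` with `B(t) = B0·e^{μt}`, `B0 = X0·m_dw`.
The exact solution

    C(t) = C0·e^{−kt} + (q·B0/V)·(e^{μt} − e^{−kt})/(μ + k)

is linear in `(C0, q)`; `μ` and `B0` are fixed from the growth fit, `k`
from a log-linear fit to a cell-free control series (only compounds with a
control series are decay-corrected; a single control cannot identify richer
kinetics than first order). The `μ + k → 0` limit is handled analytically.
`C0` is fitted jointly with `q` by default; `fix_c0=` pins it to the
measured t=0 value instead. `V` is the medium volume (default 2 mL); the
volume term is required for concentrations in mM — without it, realistic
initial concentrations would make depletion invisible.

**Error propagation into bounds.** `propagate_bounds` gives
`estimate ∓ se` (propagated mode) or `estimate·(1 ∓ relSE)` (relative
mode), ordering enforced after sign handling. The exchange-rate SE combines
the regression SE with the relative errors of μ and of the dry mass per
cell in quadrature. Two calibration conventions coexist deliberately:

* μ's SE is the ordinary SE of the pooled estimate (±1 SE covers the truth
  at roughly the nominal rate);
* the exchange-rate SE is reported at **single-replicate** level (pooled
  regression SE × √replicates). Exchange rates become hard flux bounds on
  the model, and bounds tighter than what one replicate supports would
  over-constrain the instance; the conservative convention makes a
  zero-rate metabolite fall inside its error in well over 90% of noisy
  runs.

The biomass flux bound is `μ·(1 ∓ √(relSE_μ² + relSE_mdw²))`. All fitted
bounds are widened to a minimum half-width of 1e-6 flux units so that
noiseless data yield closed, solvable windows rather than degenerate
equalities.

## 2. Thermodynamically constrained flux analysis

Every reaction's net flux is split as `v = v⁺ − v⁻`, `v⁺, v⁻ ∈ [0, M]`
with `M = 1000` mmol·gDW⁻¹·h⁻¹ (the conventional open bound). Mass balance
`S(v⁺ − v⁻) = 0` holds for every species. For each reaction whose
participants are all covered by the thermodynamic table (exchanges and the
biomass reaction are excluded), the problem carries:

* a transformed reaction energy variable with
  `Δ_r G′ = Δ_r G′° + ε_G + RT·Σ_j s_j·ln c_j`, where the slack
  `ε_G ∈ [−err, +err]` absorbs the propagated formation-energy error
  `err = √(Σ_j s_j²·err_j²)`;
* log-concentration variables `ln c_j`, bounded by measured intervals where
  available (clipped into the default range with a warning) and by the
  default range `[10⁻¹², 0.1]` mol per total protein otherwise. Only
  concentration *ratios* enter `Δ_r G′`, so the unit convention cancels
  within a compartment;
* direction binaries `y⁺, y⁻` with `v⁺ ≤ M·y⁺`, `v⁻ ≤ M·y⁻`,
  `y⁺ + y⁻ ≤ 1`, and the indicator couplings
  `Δ_r G′ ≤ −ε + K(1−y⁺)` and `−Δ_r G′ ≤ −ε + K(1−y⁻)`.

`K` is computed per reaction as `|Δ_r G′°| + err + RT·Σ_j |s_j|·max|ln c_j|
+ ε + 1`, the tightest constant that never cuts feasible energies —
uniformly large constants make the MILP numerically loose.

`Δ_r G′°` is assembled from per-species standard transformed formation
energies plus, for transport, the electrical work `F·Σ_j s_j z_j ψ(comp_j)`
(ψ relative to the external medium; `F = 96.485` kJ·V⁻¹·mol⁻¹) and a
proton-gradient term: protons never get concentration variables — their
activity is fixed by compartment pH — contributing
`−RT·ln10·Σ_{j∈H⁺} s_j·pH(comp_j)`, i.e. `RT·ln10·ΔpH` per translocated
proton. Formation energies are taken as already transformed to compartment
conditions; no ionic-strength (Debye–Hückel) or pseudoisomer corrections
are applied. A single model temperature is required (compartments must
agree to 0.1 K; default 310.15 K).

Because `Δ_r G′` telescopes to zero around any closed cycle, the direction
couplings exclude thermodynamically infeasible loop flux by construction —
*provided* the cycle's formation-energy errors are zero; independent
per-reaction slacks can otherwise relax cycle closure (a known limitation
of per-reaction error slacks). The synthetic generator therefore assigns
zero error to the loop compounds.

**Solving.** FBA maximizes the biomass net flux within its measured band;
pFBA then fixes biomass at that optimum and minimizes `Σ(v⁺ + v⁻)` over all
reactions; pTFVA re-imposes the minimum total flux as a constraint and
minimizes/maximizes each reaction's net flux. Ranges always contain the
pFBA solution, and the per-reaction solves are independent, so any
partition over reactions gives identical results. Per-reaction solve
failures are logged and reported as missing ranges without aborting the
run. Maximizing biomass within the band (rather than fixing it to the
measured midpoint) is the default; reported pFBA vectors are diagnostic
only — results are ranges.

**Numerical tolerances.** The backend is HiGHS via `scipy.optimize.milp`
(deterministic, `mip_rel_gap = 0`). Two tolerances are set by the solver's
behaviour rather than by modelling intent:

* the strict-inequality surrogate on `Δ_r G′` is `ε = 10⁻³` kJ/mol. It must
  sit well above the MILP feasibility tolerance (~10⁻⁶), or a closed cycle
  could circulate within solver slack; 10⁻³ kJ/mol is still ~2600× below
  RT and has no thermodynamic significance;
* the pFBA total-flux minimum is re-imposed with a relative cushion of
  10⁻⁶ (plus 10⁻⁹ absolute). No modelling slack is intended; HiGHS's bound
  propagation rejects the exact minimum as infeasible. The same windowing
  is used when envelope sweeps pin a flux to a value. Test-oracle
  comparisons impose the identical constants, and two runs with the same
  inputs reproduce range endpoints to well within 10⁻⁶ relative.

Infeasible instances are diagnosed by a minimal-L1 elastic relaxation of
the reaction bounds; the reactions whose bounds must move, and by how much,
accompany the raised error.

**Blocked reactions** are removed beforehand with cobrapy's
`find_blocked_reactions` (plain FVA, no thermodynamics) at a zero cutoff of
10⁻⁹ — far below any measured exchange magnitude, above LP noise. The
pipeline runs the test per condition instance and removes the union of
blocked sets, so all four instances share one reaction universe.

## 3. Normalization cascade and difference statistic

1. **Growth normalization**: every range endpoint is divided by the
   instance's pFBA biomass flux; the biomass reaction maps to [1, 1]. This
   makes the cascade invariant to uniform rescaling of an instance's fluxes
   together with its biomass.
2. **Feature scaling**: per reaction, min–max scaling onto [0, 1] using the
   extremes over all eight endpoints across the four instances. Per-reaction
   (rather than global) scaling preserves cross-instance comparability
   without crushing small fluxes. Reactions whose across-instance span is
   zero *or below 0.1% of the value magnitude* map to 0.5 everywhere: such
   spans are measurement-window/solver noise, and min–max scaling would
   amplify them to the full unit interval.
3. **Control ratio**: per bound, scaled resistant values divided by the
   paired sensitive control. Scaled values below 0.5% of the feature range
   are numerically zero and treated as exact zeros; reactions whose control
   is zero in either bound are marked incomparable, excluded from flagging,
   and counted in the log. Endpoints are re-ordered where division inverts
   them. An effect shared by a resistant/control pair (e.g. a solvent
   background) cancels in this ratio.

At any stage, two instances are compared with the dual-bound rule: relative
difference per bound `|x_a − x_b| / max(|x_a|, |x_b|, δ)` with `δ = 10⁻⁸`
(symmetric and zero-safe; the baseline of "differs by ≥15%" is otherwise
undefined), flagged iff **both** bounds differ by at least the threshold
(default 0.15, the maximum relative standard error of the underlying
measurements). The rule is symmetric in its arguments; the reported
direction names the instance with the higher midpoint. Subsystem summaries
report the flagged proportion per subsystem and each subsystem's share of
all flagged reactions after excluding configured subsystems (transport by
default, which otherwise dominates); subsystems with no flags are omitted.
No further statistical testing (permutation nulls, FDR) is layered on top
of the threshold rule.

## 4. Production envelopes

Sweeps answer hypoxia counterfactuals on a constrained instance. The swept
exchange (oxygen, or the summed fatty-acid influx) is pinned by equality to
each grid value — equality is what produces the interior minimum of the
forced-influx oxygen curve, where excess fatty acid must be oxidized at an
oxygen cost; an upper-bound mode is available and makes the min-fatty-acid
curve monotone non-increasing. At every grid point the problem is
re-parsimonized (biomass maximized within its band, total flux minimized
and re-imposed) before the target influx is minimized, so the curve at the
instance's own operating point reproduces the instance's parsimonious
minimum. The fatty-acid and oxygen exchanges are opened for the sweep, and
`also_relax` lists further exchanges (typically the oxidation products) to
open so off-operating-point states are reachable; pipeline instances pin
them from data. Curves are reported both raw and per unit biomass flux.

The total-minimizing solution is degenerate across fatty-acid substrates;
the per-substrate breakdown is made unique by lexicographic secondary
minimization in the configured substrate order (with a looser pin window,
10⁻⁶ absolute, since only the split — not the envelope minimum — depends on
it; at knife-edge grid points the split observed in the total-minimization
solution is reported instead). Biomass levels for the oxygen sweep are an
explicit list of biomass-flux values in model units; no unit claim is made
for them.

## 5. The synthetic study

The generator emulates the structure of a four-condition drug-resistance
exometabolomics experiment: two resistant instances and their matched
sensitive controls share one network; pair B is grown in a solvent-spiked
medium. Defaults are the study conditions:

| parameter | default | why |
|---|---|---|
| growth rates | 0.032 / 0.024 (pair A), 0.031 / 0.025 (pair B) h⁻¹, ±2% seeded jitter | doubling times near 24 h; resistant slower; pair-A resistant slowest |
| X0 | 2×10⁵ cells | typical seeding density |
| dry mass per cell | 400 pg | typical adherent cell line |
| medium volume | 2 mL | well volume |
| sampling times | 0, 24, 48, 72 h | daily sampling over three days |
| replicates | 4 (parameter) | replicate counts differ between real assays, so exposed rather than fixed |
| noise | multiplicative lognormal, CV parameter (5% is the reference level) | concentrations are positive; assays report CVs |
| abiotic decay | 0.003 h⁻¹ on the glutamine analog | slow first-order decay; ~20% loss over 72 h, larger than the biotic signal, so the cell-free correction matters |
| reprogramming | β-oxidation ×2, glutamine oxidation ×1.6 in resistant conditions | two of the six subsystems, both >15% after growth normalization |
| solvent effect | polyol branch ×`solvent_scale` in both pair-B conditions (default 1.0 = off) | a pure medium effect, identical in a resistant/control pair |

The toy network (24 internal species; inert two-step detours pad larger
requests) routes glucose through glycolysis to lactate or mitochondrial
oxidation, oxidizes a glutamine analog (TCA label, decoupled from ATP),
β-oxidizes two fatty acids to an exported ketone body *with* ATP coupling
chosen to make fat the oxygen-efficient fuel (10 ATP per 0.5 O₂ vs 14 ATP
per 2 O₂ through pyruvate oxidation) — this produces the decreasing
min-fat-vs-oxygen envelope and the interior oxygen minimum — plus a
maintenance ATPase and a three-reaction closed cycle that can never
circulate. The solvent-responsive branch runs on its own medium substrate,
deliberately decoupled from energy metabolism, so a solvent background
shifts only that branch; the β-oxidation scale factors are small enough
that their knock-on shifts in oxidative phosphorylation stay below the 15%
threshold. Reference fluxes come from closed-form mass balance, are
verified to satisfy `S·v = 0` exactly at generation time, and define the
exchange rates each condition's time courses encode; a feasible flux vector
therefore exists for every dataset by construction.

Formation energies are assigned per species by a small LP that makes every
reference-direction reaction exergonic by a seeded 15–20 kJ/mol margin *at
the planned concentration midpoints* (seeded log-uniform around 10⁻³ mol
per total protein; measured intervals are [c/2, 2c] around them), so the
thermodynamic constraints are consistent with the reference flux while
still binding for the loop. Loop compounds carry zero formation error (see
§2). Measurement errors scale with the configured noise level — the
dry-mass relative error is 3% at the 5% reference CV and zero for noiseless
bundles — so noiseless pipelines pin instances at the ground truth and the
recovered flux ranges bracket the reference vector reaction-wise.

The oxygen and fatty-acid exchanges are constrained from their reference
rates like the other medium compounds (the oxygen series is a
respirometry-style calibration rather than a literal dissolved-gas time
course). `replace_pooled_supply` implements the alternative in which pooled
supply artifacts are removed and fatty-acid influx is left unconstrained.

**What passing tests show, and what they do not.** The generator produces
single-phase exponential growth, iid lognormal noise, exact first-order
decay, a fully covered thermodynamic table, and a network small enough for
exact oracles. Real data add lag/stationary phases, correlated and
heteroscedastic measurement error, partial thermodynamic coverage (most
reactions uncoupled), and solution-space degeneracy at genome scale.
Passing here demonstrates the *machinery* — correctness of the MILP, the
estimators, and the cascade logic against known truth — not the biological
accuracy of any particular real-data analysis. No LC-MS signal simulation,
isotope labelling, or instrument drift is attempted.

## 6. Problem sizes in the acceptance script

`scripts/acceptance.py` runs three full four-instance studies (baseline,
solvent-spiked, growth-only), a 40-instance second-law/containment sweep,
a 200-condition rate-fit calibration, and the envelope consistency and
interior-minimum checks — sizes chosen so the whole script completes in
about a minute on one CPU while every reported rate is estimated from at
least 40 draws. All randomness derives from `--seed`.

## 7. Known limitations

* Per-reaction Gibbs-energy error slacks can, in general, relax cycle
  closure; guaranteed loop exclusion requires zero error on cycle
  compounds (or compound-level shared slacks, not implemented).
* The cascade normalizes growth first and medium second; emergent effects
  that depend jointly on both are attributed to whichever step removes
  them first.
* Envelope curves report a lexicographic substrate split; other
  tie-breaking conventions would report different (equally optimal)
  splits.
* `FluxRangeSet` endpoints inherit the solver's 10⁻⁶-relative parsimony
  cushion; differences at or below that scale are not meaningful, which is
  why the cascade carries the numerical floors described in §3.
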