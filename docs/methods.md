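# Methods

## The model

`redoxcell` simulates the cytosolic redox state of a single cell treated
with an NQO1-bioactivatable ortho-quinone drug (β-lapachone).  The core is a
compartmental mass-action ODE system (extracellular medium + cytosol, molar
/ seconds / liters) with two coupled parts:

**Quinone futile cycle.**  Extracellular quinone (β-lap<sup>ext</sup>)
permeates down its gradient into the cytosol (rate k₃₄·A·([ext]−[in]),
divided by the receiving compartment volume).  NQO1 reduces the quinone
two-electron-wise to the hydroquinone (k₂₉·[β-lapQ]·[NADPH]); cytochrome
P450 reductase (POR) performs the one-electron steps through the semiquinone
radical (k₃₃).  O₂ reoxidizes hydroquinone and semiquinone (k₃₀, k₃₁),
producing superoxide, which SOD1 dismutates to H₂O₂ (k₃₂·[O₂•⁻]²).  Each
full cycle therefore burns one NADPH and delivers one H₂O₂ without
consuming drug.  The only drug sinks are glutathione conjugation
(k₃₅·[β-lapHQ]·[GSH]) and export of the conjugate (k₃₆·A·[β-lapHQSG]).
O₂ is clamped (no oxygen balance is modeled); extracellular drug is
depleted by permeation (mass-conserving), with a per-species `clamped`
switch available in the config.

**Antioxidant network.**  H₂O₂ from the cycle plus a constant
(zeroth-order) basal mitochondrial source is cleared by: the
peroxiredoxin–thioredoxin axis (Prx oxidation, hyperoxidation to the
sulfinic form, slow sulfiredoxin repair, Trx-mediated reduction, TrxR
regeneration of Trx by NADPH), the glutathione axis (a two-state GPX redox
cycle, GSR regeneration of GSH by NADPH, protein-thiol oxidation through a
sulfenic intermediate to the glutathionylated form, glutaredoxin repair),
catalase, and passive + aquaporin-mediated membrane permeation against a
clamped extracellular H₂O₂ level (the surrounding medium is treated as an
infinite sink/source at 1 nM).  NADPH is regenerated from NADP⁺ at a
first-order rate representing G6PD + GLUD1 supply.

Enzymes whose abundance is set per cell (GPX, catalase, Prx, Trx, Grx) are
explicit species; enzymes that scale a rate constant (NQO1, SOD1, POR,
TrxR, GSR, aquaporin, NADPH supply) are folded into the constant.  Writing
GPX and the protein thiols as explicit redox cycles (rather than lumped
catalytic rates) keeps every GSH-consuming rate law proportional to a
species that vanishes as its substrate empties, so trajectories cannot be
driven negative when NADPH supply collapses in extreme cells.

### Base parameterization

The antioxidant core descends from earlier Jurkat-cell H₂O₂-clearance
models whose full kinetic constants are not redistributed here.  The
packaged default config
(`data/default_model.yaml`) is therefore this package's own base
parameterization: effective literature-scale rate constants and resting
concentrations chosen so that the drug-free steady state is physiological
(H₂O₂ ≈ 1.4 nM, NADPH:NADP⁺ ≈ 125, GSH:GSSG ≈ 2×10⁵, Trx-SH:Trx-SS ≈ 1400)
and H₂O₂ clearance is distributed across Prx (~300 s⁻¹), GPX (~200 s⁻¹),
catalase (~150 s⁻¹), membrane permeation (~150 s⁻¹) and protein thiols
(minor), with no single system controlling the load.  The nine drug reactions carry
the canonical quinone-cycling rate-term forms (k₂₉–k₃₆) exactly.  The network
is fully declarative (YAML), so replacing the base kinetics with other
values requires no code change.

### Numerics

Integration uses `scipy.integrate.solve_ivp` with LSODA (stiff,
variable-order).  The reference `SolverSettings` defaults are 2 h of
simulated time, max step 1 s and absolute tolerance 10⁻⁸.  Batch runs
(cohort pipeline, sensitivity scans) use the same end time and relative
tolerance with an adaptive step and abstol 10⁻¹² — trace species
(superoxide, oxidized enzyme forms) rest near zero, and resolving them
below their natural scale prevents benign solver noise from being flagged
as negativity.  Halving the tolerance moves the 2 h endpoint by < 10⁻⁴ %.
Mass-action rate laws are evaluated at max(y, 0): stiff solvers probe
slightly negative states, and unguarded products of negative concentrations
can convert a benign overshoot into runaway positive feedback.  A
trajectory is **unstable** when the solver fails, produces a non-finite
value, or lets any concentration fall below −abstol at an accepted step;
unstable cells are retained in output tables but excluded from statistics
(single-cell ODE cohorts conventionally drop such runs).

Conserved moieties — total NADP(H), thioredoxin, peroxiredoxin, GPX,
protein thiols, glutathione (GSH + 2·GSSG + glutathionylated pools) and the
drug across all six redox forms — are declared in the config and audited as
volume-weighted totals; drifts stay below 0.1% over 2 h at reference
settings.

## From transcripts to cell models

Protein abundance per gene is the equilibrium of a linear
synthesis/degradation model, P* = k_sp·R/k_dp, with per-gene constants from
a TSV table.  The packaged table (`synthetic_rate_constants.tsv`) is a
clearly labelled synthetic stand-in with plausible scales (translation
1–100 h⁻¹, half-lives 1–100 h) and empty provenance slots; real analyses
should substitute measured constants.  AQP3, which lacks such constants,
uses a linear RNA→protein regression.  Copy numbers convert to molar
through the cytosolic volume.

Each cell's model is the base network with

* rate constants multiplied by the cell's expression relative to the
  cohort-wide mean (the ratio reading of "percent change from the
  average" — a literal percent multiplier would null every rate for an
  average cell), and
* initial enzyme abundances scaled by the cell's protein-level ratio
  (equilibrium-model weighting by default, raw expression as fallback).

G6PD+GLUD1 and PRDX1+PRDX2 act additively: the multiplier is the ratio of
summed levels.  AQP3 scales the aquaporin H₂O₂ permeation (its established
transport role); a config switch can extend it to drug permeation.
Ratios are floored at ε = 10⁻³ so a dropout zero yields a near-null rather
than exactly-null reaction; floored multipliers are logged.  Cells are
processed in sorted-ID order, making cohort tables bit-reproducible and
independent of input order.

The extracellular dose is a calibration knob.  The default, 10 µM, is the
smallest round value at which the average cell shows an order-of-magnitude
H₂O₂ excursion over baseline (~15×) while the NADPH:NADP⁺ ratio drops
~50-fold — a clear but non-saturating oxidative insult within the
pharmacological range for this drug class.

## Sensitivity analysis

One parameter at a time is moved ±10%, the model re-integrated to 2 h, and
the effect on cytosolic H₂O₂ and the NADPH:NADP⁺, Trx-SH:Trx-SS and
GSH:GSSG ratios reported both raw ((x_pert−x_base)/(k_pert−k_base), the
literal finite-difference ∂x/∂k) and normalized ((Δx/x)/(±δ),
dimensionless).  Only the normalized form is comparable across parameters;
"most sensitivities below 1" is only meaningful there, so both are always
emitted.  Perturbed runs that go unstable are flagged rows, not numbers.
On the default dosed model, control is distributed: the largest normalized
H₂O₂ sensitivity (~0.6, NQO1) is well within 10× the median of the top ten,
and the permeation constants rank among the top ten — export capacity
matters to a cell's oxidative load.

## Cohort statistics

Per patient, endpoint cytosolic H₂O₂ of malignant vs non-malignant cells is
compared with a two-tailed Welch's t-test (unequal variances,
Welch–Satterthwaite df), implemented from the closed-form formulas and
cross-checked against `scipy.stats.ttest_ind(equal_var=False)` in tests.
No multiple-testing correction is applied (per-patient tests are reported
individually).  Box summaries use the IQR with 1.5·IQR whiskers and the
group mean as the center line.

## PLSR and VIP

The endpoint NADPH:NADP⁺ ratio is regressed on the 14 model protein
concentrations after log₁₀ transform and autoscaling.  The log offset for
a column containing dropout zeros is half its smallest positive value.
The decomposition is NIPALS; with a single response the inner iteration is
exact in closed form (w = X'y/‖X'y‖ per component; the two-block iteration
oscillates in sign for PLS1).  Q² = 1 − PRESS/SS is estimated by 7-fold
cross-validation on contiguous blocks after a seeded shuffle, with the
preprocessing refit inside each training fold.  The component count is the
smallest A whose incremental Q² gain is < 0.01, or can be fixed directly
(the cohort runs fix 4 components for malignant and 3 for non-malignant
cells).  VIP scores
use VIPⱼ = √(p·Σₐ SSYₐw²ₐⱼ/Σₐ SSYₐ); the mean squared VIP is identically 1.
`sklearn.cross_decomposition.PLSRegression` serves as an independent oracle
in tests, never as the implementation.

## The synthetic cohort

`synthetic_data` emulates the structure of the multi-patient tumor
scRNA-seq dataset the pipeline was designed for: 10 patients × 200 cells
per class by default (hundreds of cells per patient, ~4000 total — the
scale of published multi-patient HNSCC single-cell studies), a
35-gene redox panel containing the 14 mapped genes, lognormal expression
with additive log-scale effects

    expression = exp(log base mean + patient offset + malignant·LFC + noise)

and Bernoulli dropout (default 30%).  Cell-level dispersion is per-gene:
0.4 (natural log) base, elevated to 0.8 for NQO1, GLUD1, TXN and TXNRD1,
the genes HNSCC tumors express with pronounced cell-to-cell
heterogeneity.  Patient
offsets (SD 0.3) make cells cluster by patient, reproducing the observed
patient-wise structure.  The default class effect is a two-fold malignant
NQO1 up-shift.  Pre-dropout values, offsets and implanted fold changes are
kept as ground truth.

What the generator does **not** emulate: read-level sequencing artifacts,
library-size variation, expression-dependent dropout (real dropout is rarer
for highly expressed genes), gene–gene correlation beyond the implanted
patient/class structure, and cell types within the non-malignant pool.
Passing cohort tests therefore show that the pipeline recovers implanted
structure through the full ODE + statistics stack — not that it would
recover the same structure from raw sequencing data.

`nqo1_dominant_design()` is a deliberately constructed variant for the
VIP detection property: elevated NQO1 dispersion with every other gene at
base dispersion and no dropout, so the implanted NQO1 effect genuinely
dominates the endpoint NADPH ratio.  Under flat 30% dropout the NADPH
ratio is instead co-dominated by the NADPH-supply genes — double dropout
of the additive G6PD+GLUD1 pair hits the ε-floor and swings the log ratio
by ~7 units, handing linear correlations to the supply side (mirroring the
biology of non-malignant cells, whose drug response hinges more on NADPH
supply than on drug activation).  The default-cohort NQO1 rank is reported
alongside the detection battery for transparency.

## Problem sizes

Test and acceptance runs use: the full default model (26 species, 25
reactions) for all kinetic checks; 10 patients × 400 cells for the cohort
comparison (~60–90 s); ten replicate cohorts of 10 patients × 100 cells for
the VIP battery; 200 replicates for the Welch null calibration; toy 1–2
species networks for analytic oracles.

## Known limitations

* The base antioxidant kinetics are effective constants, not a measured
  set; absolute concentrations are indicative, comparisons and rankings
  are the supported outputs.
* One-electron chemistry is simplified (no comproportionation,
  semiquinone–GSH chemistry, or NQO1 saturation kinetics).
* Mitochondrial antioxidant systems, NADPH-oxidase superoxide and
  Nrf2-driven transcriptional feedback are deliberately out of scope (the
  2 h horizon assumes constant enzyme totals).
* The NADPH:NADP⁺ ratio can reach extreme values in cells whose consumption
  collapses (NADP⁺ nearly empties); ratios are reported as-is and
  log-transformed before regression.
* Welch tests on raw endpoint H₂O₂ are heavy-tail sensitive; per-patient
  power depends strongly on cell count (hundreds of cells per patient are
  needed for a reliable significance pattern).
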