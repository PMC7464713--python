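# Methods

## The model

`wntredox` implements a compartmental (cytosol / nucleus) reaction network of
intracellular canonical Wnt signaling in osteoblast-like cells growing on a
titanium surface, under two conditions: an unstructured reference surface
(Ref) and sharp-edged 5 µm micro-pillars (P5) that impose oxidative stress.
There is no extracellular Wnt stimulus and no membrane/receptor signalosome:
per the study design, all membrane-associated components (Wnt ligands,
Frizzled/LRP receptors, WLS, SOST, SFRP4) are deliberately outside the model
scope, and `apply_scenario_scaling` refuses their gene symbols.

The network has 16 species and 18 labeled reaction groups (R1–R18, ~40
elementary reactions), with formal semantics of a continuous-time Markov
chain over integer copy numbers:

* **β-catenin backbone (R1–R5, R18).** β-catenin (BC) is synthesized in the
  cytosol, degraded by the destruction complex (DC, with DC as a catalytic
  modifier) plus a slow basal route, and shuttles between cytosol and
  nucleus. The DC assembles from AXIN against a constant scaffold pool
  (APC/GSK3β/CK1 availability); AXIN is the rate-limiting, low-copy
  component, with basal synthesis and degradation. AXIN and its homologue
  AXIN2 are merged into a single AXIN species.
* **Redox arm (R6–R9).** A dimensionless ROS input releases DVL from its
  redox-sensitive complex with Nucleoredoxin (NRX·DVL → DVL, propensity ∝
  ROS). Free DVL re-associates with NRX, or self-aggregates through a Hill
  switch once its copy number passes a threshold; each aggregate consumes
  m = 2 monomers. Aggregates bind AXIN with high affinity (k_on ≫ k_off).
  AXIN bound to the DVL platform is additionally turned over
  (DVL·AXIN → DVL_agg). This last reaction is a deliberate model choice:
  without any sink acting on the sequestered form, the free-AXIN steady
  state is pinned at synthesis/degradation by an exact budget argument and
  the entire redox arm becomes inert at steady state. DVL-promoted AXIN
  degradation is a documented canonical-Wnt mechanism and gives ROS its
  observed effect: sequestration depletes free AXIN, the DC shrinks, and
  β-catenin accumulates Wnt-independently.
* **Transcription arm (R10, R11, R17).** Nuclear β-catenin binds TCF
  reversibly to form the transcriptionally active TCF/β-catenin complex
  (TCFBC). TCFBC drives a lumped TargetProtein reporter (target-gene
  expression rate ≡ k_tx × TCFBC) and, as the AXIN2 negative feedback,
  AXIN production (feature flag `feedback`).
* **Inhibitors (R12–R16).** ICAT (CTNNBIP1) is synthesized in the cytosol,
  shuttles into the nucleus, and binds β-catenin reversibly in both
  compartments without degrading it; the nuclear ICAT·β-catenin complex is
  exported (flag `icat_export`), which makes ICAT a net nucleus→cytosol
  β-catenin pump. SOX17 acts only in the nucleus and catalytically targets
  the whole TCF/β-catenin complex for proteasomal degradation, independent
  of AXIN and GSK3β (flag `sox17_codegradation`).

**Turnover of bound protein.** ICAT and TCF turn over at the same first-order
rate whether free or in a complex; complex decay releases the partner
(β-catenin). This models turnover as independent of binding status and makes
the total-ICAT and total-TCF pools exactly linear in their synthesis rates:
at steady state, total ICAT = k_icat_syn/k_icat_deg and total TCF =
k_tcf_syn/k_tcf_deg (the latter once SOX17 co-degradation is disabled), so a
synthesis multiplier of 1.65/1.58/1.55 propagates to the steady-state
abundance ratio exactly. SOX17 participates only catalytically, so its total
is linear by construction.

## Units, kinetics, numerics

* Units: molecules per cell and hours; the default simulation horizon is
  24 h, matching the in vitro cultivation window (readouts at 1 h and 24 h).
* Compartments: cytosol 0.7 and nucleus 0.3 of the cell volume. Bimolecular
  stochastic rate constants are divided by the volume fraction of their
  compartment; cross-compartment bimolecular steps are rejected by
  validation.
* Propensities: stochastic mass action with falling factorials (order ≤ 2);
  the DVL aggregation switch uses a = c·x·xⁿ/(Kⁿ + xⁿ) with x the free-DVL
  copy number (defaults n = 4, K = 50 = half the total DVL pool of 100).
  A propensity is zero whenever a reactant count is below its stoichiometric
  requirement; non-negativity is enforced by propensity zeroing, never by
  clipping.
* SSA: Gillespie's direct method with a numba-compiled inner loop; one
  seeded Mersenne-Twister generator per run, ensemble run *i* uses seed
  `seed + i` (mod 2³¹); identical inputs give bit-identical trajectories.
  Grid sampling is last-event hold (right-continuous), matching CTMC
  semantics. If the total propensity reaches zero the state is held constant
  to `t_end` and the trajectory is flagged absorbing.
* ODE: the mean-field limit dx/dt = Sᵀ·v(x) (plain powers instead of falling
  factorials) integrated with LSODA (rtol = atol = 1e−8 by default).
* Steady states: ODE mode integrates until the maximum relative derivative
  falls below 1e−8 h⁻¹ (at most 10× the horizon), then polishes the fixed
  point with a Newton-type root solve, giving solver-precision levels (the
  acceptance ratios are exact to < 1e−6). SSA mode time-averages the second
  half of a 10×-horizon window over ≥ 50 runs.

## Scenarios and readouts

Ref is baseline: ROS input 1, identity multipliers. P5 applies the measured
mRNA fold changes as synthesis-rate multipliers — ICAT 1.65, SOX17 1.58,
TCF 1.55 — at the mRNA-appropriate point (zero-order synthesis reactions
only) plus a calibrated ROS input of 7.7 (dimensionless, relative to Ref).
ROS is an input parameter, not a species, constant within a scenario: the
study measures a fold elevation, not ROS kinetics, and the in vitro
fluorescence fold (~1.19 at 24 h, elevated from 1 h) is treated as a
qualitative anchor only, because assay fluorescence is not a copy-number
measurement. Protein-level folds are emergent model output, never imposed.

Paired experiments (`run_virtual_experiment`) simulate both scenarios from
the same template with matched seeds (common random numbers), so an
identical pair gives fold 1 exactly. Readouts include nuclear β-catenin
(BC_n + ICAT-bound + TCF-bound), cytosolic β-catenin, the TCFBC level, the
target-expression rate k_tx × TCFBC, and free TCF.

## Calibration

The backbone constants are fixed at values giving a reference cell with
~700 total β-catenin copies (≈190 free cytosolic, ≈60 free nuclear), ~30
copies of AXIN/DC (low-copy, rate-limiting), a 100-monomer DVL pool and a
30-copy SOX17 pool — magnitudes in the spirit of the classic kinetic model
of the Wnt pathway rescaled to a ~2 pL cell at modest copy numbers. The
extension constants (redox arm, ICAT, SOX17, TCF kinetics) and the P5 ROS
level are free parameters; their defaults were obtained with this package's
multi-start least-squares machinery against the study's qualitative headline
re-expressed as fold targets:

* nuclear β-catenin P5/Ref ≈ 1.5 at 24 h (clearly above the 1.2 acceptance
  threshold; the study reports significant accumulation but prints no fold),
* target-expression P5/Ref ≈ 1.0 at 24 h (the "unchanged transcriptional
  activity" headline; acceptance band [0.9, 1.1]),
* a ROS-only control (elevated ROS, no inhibitor/TCF upregulation) whose
  target-expression ratio rises well above 1.1 — demonstrating that the
  coordinated inhibitor expression, not the pathway wiring, keeps
  transcription flat,
* free TCF not depleted under P5 (the TCF4 upregulation prevents the
  depletion point).

Residuals are taken on the log scale (all readouts positive, multiplicative
noise model); the deterministic ODE engine makes the objective smooth, with
the stochastic engine reserved for post-fit validation. Fits run as
multi-start local least squares (Latin-hypercube starts over log-scaled
bounds, default 20 starts); all parameters are positive and fitted in log
space. With the calibrated defaults the model yields a 24 h nuclear fold of
≈1.36 with a target-expression ratio of ≈0.99, a ROS-only ratio of ≈1.16,
and removing the AXIN2 feedback raises the P5 fold to ≈1.41 (negative
feedback dampens accumulation).

## Synthetic data

`synthetic_data` generates everything the tests and the recovery study
consume; no downloads are needed. Expression tables emulate the shape of the
microarray comparison: 21,448 genes with ~1.47% truly regulated, balanced
up/down (matching the observed 157/158 split), signed log2 effects of mean
magnitude 1.0 with per-gene Gaussian noise (σ = 0.1 log2 units), Beta(0.5,
20) p-values for regulated genes (sharply sub-0.05 mass; the study reports
no p-value distribution, so this is a documented, configurable choice) and
uniform p-values for nulls. Time-course tables multiply deterministic model
readouts at 1 h and 24 h by lognormal noise, mimicking the replicate
structure of the flow-cytometry readouts. What these generators do *not*
emulate — array hybridization artifacts, probe effects, normalization,
fluorescence nonlinearity — bounds what passing tests show about real data:
they validate the filtering arithmetic and the estimation machinery, not the
upstream measurement process.

The parameter-recovery study (`calibration.recover`) regenerates noisy
tables from known truth, refits, and reports per-parameter bias, RMSE and
median relative error. At lognormal σ = 0.1 with 20 replicates the three
synthesis multipliers are recovered with median relative error well under
15%, and the error decreases monotonically as σ shrinks.

## Problem sizes used by the test suite

Stochastic checks run at sizes chosen to make their statistics decisive while
keeping the suite quick: 200-run ensembles for SSA↔ODE cross-validation
(ensemble-mean agreement within 10%), 1000 runs for the Poisson
goodness-of-fit (χ² at α = 0.01), 400-run ensembles at system sizes ×1/×10/
×100 for the mean-field convergence check, 50 runs for the stochastic
steady-state average, and 20 replicates for the σ = 0.1 recovery study.

## Known limitations

* The DEG stage implements only the downstream filter and summary
  arithmetic; SST-RMA summarization and LIMMA statistics are out of scope.
* ROS is a constant scalar input per scenario; no ROS kinetics, scavenging
  (SOD), lipid peroxidation, or FOXO/β-catenin diversion are modeled.
* The DVL aggregation threshold is a two-parameter Hill switch, not an
  explicit oligomerization cascade; aggregate bookkeeping uses a fixed
  monomer count m = 2.
* Parameter defaults are calibration outputs constrained by fold-change
  observations, not directly measured rate constants; absolute copy numbers
  are order-of-magnitude choices, and conclusions should be read at the
  level of ratios and qualitative behavior.
* Sub-copy-number species (e.g. the DVL·AXIN pool under Ref) show the usual
  fluctuation corrections relative to the mean-field ODE; cross-engine
  agreement checks therefore apply to species above a few copies.
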