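# Methods

## Model

The pathway is an ordinary-differential-equation model of IFNα-induced
JAK/STAT signaling in hepatocyte-like cells.  Extracellular IFNα (pM) is a
clamped input: doses are large compared with the receptor pool, so ligand
depletion from the medium is neglected and the input changes only at dosing
and washout events, where integration is stopped and restarted.
Roferon (IFNα-2a) differs from research-grade IFNα only through the
ligand-binding term; equipotent doses (608 pM Roferon ≡ 1,400 pM IFNα,
from replicon-assay IC50s) are encoded as a fixed potency factor.

States and reactions:

* **Receptor.**  IFNAR1/2 with JAK1/TYK2 are lumped into one species `Rec`
  with basal turnover.  Activation `Rec → aRecIFN` is proportional to
  `BindIFN · IFN` and inhibited by SOCS1 and SOCS3 through a shared
  `1/(1 + (SOCS1+SOCS3)/KiSOCS)` factor.  Active complexes deactivate
  (`deactRec`) and are degraded enzymatically; the four structural variants
  differ only here: degradation catalyzed by SOCS1, by USP18, by the
  SOCS1:USP18 pair (product of both modifier saturations,
  `V · S/(Km+S) · U/(Km+U)`), or by SOCS1 *and* the pair (two separate
  reactions; the variant with both has 75 reactions, the others 74).
* **STAT activation.**  Phosphorylation and dimerization are lumped into
  single reactions.  Homodimer formation is
  `actSTAT1 · aRecIFN · STAT1c²`; heterodimer formation is second order in
  the active receptor (`actSTAT2 · aRecIFN² · STAT1c · STAT2c`) because the
  lumped reaction comprises two receptor-catalyzed phosphorylation events.
  This makes the 1-h pSTAT2 dose response steeper than pSTAT1's, which is
  what the measured anchors (50% vs 10% of maximum at 2.8 pM) require.
  Both reactions are inhibited by USP18 (`1/(1+USP18/KiUSP18)`).
* **Complexes.**  ISGF3 forms from the heterodimer and IRF9; all three
  complexes import into the nucleus with one shared rate, dissociate there
  (dimer/heterodimer share a rate; ISGF3 has its own — it is one of the
  hepatocyte-specific parameters), and the monomers shuttle between
  compartments (shared export rate).
* **Promoters.**  Occupancy states in [0, 1]:
  `d/dt OccGASbs = actGAS · pSTAT1dimn · (1−Occ) − decayOcc · Occ` and
  analogously for the combined GAS+ISRE sites, driven by both the nuclear
  heterodimer and (more strongly per molecule) ISGF3.
* **Gene expression.**  Seven transcripts with basal synthesis, induced
  synthesis (SOCS3 from the GAS sites; the rest from the GAS+ISRE sites;
  IRF9 transcription saturates at very low occupancy via `KmIRF9occ`, which
  is the mechanistic source of low-dose hypersensitization; SOCS1 is
  repressed by IRF2), first-order decay, and translation through two-step
  linear chains (gene-specific delay τ, step rate 2/τ).  USP18 transcription
  is scaled by the siRNA knockdown factor; overexpression adds a constitutive
  synthesis term (`synthUSP18mRNAbasal_OE`).

With two chain intermediates per gene the network has 41 species; the dual
degradation variant has 75 reactions.  The chain length is fixed by that
species count; per-gene delays remain free parameters.

## Parameters and steady state

All estimated parameters live on log10 scale.  The Huh7.5-like estimation
configuration has 85 parameters: 12 initial abundances (receptor pool,
total STAT1/STAT2/IRF9, basal SOCS1/SOCS3/IRF2 protein, five basal mRNA
levels), 17 observation scalings/offsets, and 56 dynamical parameters
(including `BindIFN`, `synthUSP18` — the USP18 abundance parameter — and
the four overexpression/inhibitor parameters).  Basal SOCS3/IRF2 mRNA
levels are fixed constants: fold-change observables make them structurally
non-identifiable.

The steady-state transform closes the resting state exactly rather than by
simulation: basal synthesis rates (receptor and all transcripts), the
translation rates of SOCS1/SOCS3/IRF2 and the degradation rates of the
STAT1/STAT2/IRF9 monomers are derived so the unstimulated system is a fixed
point at the specified abundances; chain intermediates and the
cytoplasm/nucleus split of the monomers have closed forms.  Compartments
carry no explicit volume ratio — shuttling rates absorb volume factors.

Observables are `scale × (stoichiometry-weighted state sum) + offset`;
total-STAT observables sum the free and complexed moiety of a compartment.

Integration uses LSODA with rtol 1e−8 / atol 1e−10 for acceptance-grade
runs and 1e−6 / 1e−8 inside fits, on numba-compiled generated right-hand
sides.

## Nominal synthetic truth

The generator's nominal parameter set is the package's study condition.  It
was calibrated once, deterministically, in two stages: (i) a bounded
least-squares fit of the receptor/activation parameters to the 1-h
dose-response anchors — pSTAT1 half-maximal at 2.8 pM and ≥99% of maximum
at 1,400 pM, pSTAT2 ≈10% of maximum at 2.8 pM, both observables peaking
0.5 h after a saturating dose — and (ii) direct calibration of the feedback
arms so that 24 h of low-dose prestimulation leaves IRF9 high (saturating
transcription) but USP18/SOCS1 only mildly induced (hypersensitization:
relative antiviral response 1.30 at 1.2 pM Roferon), while high-dose
prestimulation induces USP18 ~12-fold and depletes the receptor pool
(desensitization: relative response ≈ 0.002).  `nominal_parameters()`
re-verifies the anchors by simulation at every call and fails loudly if
they drift.  The printed 28-pM anchors (90%/80%) are treated as soft
targets; the calibrated set realizes 93%/76%, a known limitation of the
lumped receptor stage.

What the generators emulate — and what they do not: multi-gel immunoblots
with log-normal noise (default σ_log 0.2) and log-normal gel factors with a
detection floor; qRT-PCR Cq values (default σ 0.3 cycles) with per-sample
pipetting shifts removed by reference-gene normalization; spike-in
calibrator curves; log-normal plasma IFNα.  Not emulated: saturation or
background structure of densitometry, correlated within-gel errors, probe
efficiencies differing between genes, or biological cell-to-cell
variability within a culture.  Passing recovery tests therefore demonstrate
the statistical machinery under the stated error model, not robustness to
every artifact of real blots.

## Scaling and error model

For each target independently, `log y = log s_gel + log x_(condition,time)`
is solved by linear least squares with the reference gel fixed at 1
(gels must form a connected graph through shared design cells; disconnected
components are an error, never silently dropped).  The noise variance is
estimated from the residual degrees of freedom (constant variance in log
space per target — the simplest identifiable choice under the log-normal
assumption), and 1σ intervals come from the inverse normal-equation
curvature.  Single-replicate estimates are flagged and can borrow the noise
SD of a densely replicated donor time course (`borrow_sigma`), the
procedure used for per-patient hepatocyte data where the high-dose
prestimulated time course is assumed constant after stimulation.
Calibration curves pick the contiguous spike subset (≥3 points) maximizing
R² of a linear fit and refuse to extrapolate outside it.

## Calibration, identifiability, selection

The objective is the weighted residual sum of squares plus the weak L2
prior `Σ (log10 θ / 5)²` (one unit at five decades from 1); optimization is
unbounded, the prior provides soft containment, and the prior is subtracted
for identifiability analyses.  Multi-start optimization draws uniform
log10 starts (default box ±5 decades, seeded) and runs a trust-region
least-squares solver with a finite-difference Jacobian (relative step 1e−4,
chosen well above ODE-solver noise); results are sorted into a waterfall
and grouped into plateaus at 0.1 objective units.  Profiles step adaptively
(target rise ≈ Δ/5 per step), bisect the threshold crossing, and classify
parameters by which sides cross Δ (default 3.84, the 95% χ²₁ quantile;
prediction profiles use the 68% quantile ≈ 1.0 via a stiff quadratic pin on
the prediction).  Structure comparison uses `BIC = k ln n + χ²` — additive
likelihood constants cancel between variants on the same data.

Cell-type transfer: ratio parameters Δ (log10, relative to the control
model) over the 60 eligible parameters (everything except the four
abundance parameters and the four overexpression/inhibitor parameters) are
estimated with `λ Σ (|Δ| + Δ²)`.  The inner solver is a prox-linear
Gauss–Newton method: the residuals are linearized (finite-difference
Jacobian), the elastic-net subproblem is solved exactly by coordinate
descent (true soft-thresholding, exact zeros), and a Levenberg damping
parameter guards the step — this is much more robust on ODE objectives than
smoothed-penalty quasi-Newton methods, whose tiny finite-difference steps
drown in solver noise.  The path is run from large to small λ with warm
starts.  Model size is selected by `4 ln(n) k − 2 ln L` with every distinct
support refit penalty-free before scoring (the shrinkage would otherwise
bias the comparison), followed by backward elimination of the weakest ratio
parameter while the score improves, since a coarse λ grid can jump over the
exact support.  The zero threshold is 1e−3 decades.

## Cohort analysis

Virtual patients draw five quantities from moment-matched log-normals
(μ = ln(m²/√(m²+v)), σ² = ln(1+v/m²)): plasma IFNα (mean 0.0440 pM,
SD 0.0362 pM) and STAT1/STAT2/IRF9/USP18 abundances whose config moments
are anchored to the printed per-cell ranges for primary hepatocytes (STAT1
1e5–1e6, STAT2 1e4–1e5, IRF9 comparable to STAT2, USP18 slightly lower and
highly variable); they are configuration values, not measured ground truth.
Abundance overrides enter through the steady-state transform (USP18 through
its synthesis rate); residual plasma IFNα acts as a constant prestimulation
input for the first 24 h and is not cleared.  The antiviral response is the
trapezoid AUC (step 0.05 h) of occupied promoter sites over 24–28 h,
baseline-subtracted against the same patient's unstimulated simulation;
degenerate cases are exact by construction (no stimulation → absolute 0; no
prestimulation → relative 1).  Thresholds are located on a coarse log-dose
grid and refined by bisection to 1% relative tolerance; when several
crossings exist the largest dose below which the response stays ≥1 is
reported together with all crossings.  Spearman correlations use average
ranks and the t-approximation p-value.

## Problem sizes used by the test suite

The recovery analyses run on deliberately small designs chosen as this
package's standard quick-verification scale: structure recovery uses 3
conditions × ~40 data points per observable panel at σ_log 0.1 with 3
starts per variant; cell-type recovery uses 2 conditions (~100 points,
σ_log 0.04, replicate-averaged), a 10-parameter candidate ratio set
containing both scenario truths plus distractors, and a 9-point λ grid over
4 decades centered at n/2 (where an order-of-magnitude difference is
penalized at the χ² scale of the data).  Full-size runs (1,000 starts,
25 λ, the complete 60-parameter ratio set) are plain function arguments.

## Known limitations

* The 28-pM dose-response anchors are met only approximately (see above).
* The elastic-net candidate set used by the quick scenarios is restricted;
  running the full 60-parameter set is supported but slow.
* Analytic forward sensitivities are not implemented; gradients everywhere
  are finite-difference with noise-aware steps, and the analytic-gradient
  pathway of the objective class is exercised with user-supplied Jacobians
  (e.g. linear models).
* The SBML reader reconstructs rate laws from the document's structured
  annotation; kinetic-law MathML is written but not parsed back.
* Washout experiments are supported as events but were not part of the
  calibration of the nominal truth.
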