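# Methods

## Scope and purpose

`mtpa` answers an early-discovery question: *given a dose, a dosing
scheme, an antibody net charge, a target form and a site of action, which
combinations of binding affinity (K_D), target baseline (T_0) and target
half-life (t_1/2) achieve high target occupancy at the steady-state
trough?*  It answers it by brute force plus interpretation: simulate
thousands of virtual antibody–target pairs through a mechanistic
disposition model, label each pair by its trough occupancy, and let a
shallow decision tree turn the labels into axis-aligned property cutoffs.

## Disposition model

The pharmacokinetic core is a minimal physiologically based model for
IgG-like antibodies with four compartments: plasma, lumped *tight* tissue
(muscle, skin, adipose, brain — low vascular permeability), lumped *leaky*
tissue (visceral organs), and lymph.  Antibody extravasates convectively
with lymph flow `L_i` filtered by vascular reflection coefficients
`sigma_i`, drains from the interstitium to lymph past a lymphatic
reflection coefficient `sigma_L`, and returns to plasma:

    V_p dC_p/dt = L·C_ly − [L_t(1−σ_t) + L_l(1−σ_l)]·C_p − CL_p·C_p − V_p·R_bind,p
    V_t dC_t/dt = L_t(1−σ_t)·C_p − L_t(1−σ_L)·C_t − CL_up,t·C_t − V_t·R_bind,t
    V_l dC_l/dt = L_l(1−σ_l)·C_p − L_l(1−σ_L)·C_l − CL_up,l·C_l − V_l·R_bind,l
    V_ly dC_ly/dt = L_t(1−σ_L)·C_t + L_l(1−σ_L)·C_l − L·C_ly

with `L = L_t + L_l`.  Nonspecific elimination acts in plasma
(FcRn-limited catabolism, `CL_p`) and in each tissue (pinocytotic uptake,
`CL_up`).  Net Fv charge `Q` scales both multiplicatively:

    CL_p(Q)  = CL_p · exp(a_cl · Q),      CL_up(Q) = CL_up · exp(a_up · Q)

so a positively charged antibody clears faster and is taken up by tissue
faster; the baseline is recovered at `Q = 0`.

Target-mediated disposition runs at each expression site (plasma, tight,
leaky by default, same baseline everywhere).  Free target `T` turns over
(`ksyn = kdeg·T_0`, `kdeg = ln2/t_1/2`), binds free drug with on-rate
`kon` and off-rate `koff = kon·K_D`, and the complex internalizes with
first-order rate `kint`:

    dT/dt  = ksyn − kdeg·T − kon·C·T + koff·DT
    dDT/dt = kon·C·T − koff·DT − kint·DT

`kint = kdeg` for membrane-bound targets (the complex is degraded with the
receptor) and `kint = kel = CL_p(Q)/V_p` for soluble targets (the complex
is cleared like the antibody).  This single switch is what separates the
optimal property spaces of the two target forms.

Dosing is intravenous: each administration adds `dose·BW·10⁶/MW / V_p` nM
to plasma instantaneously (solver restart at dose times, no smoothing).

### Parameter values

All physiology lives in `src/mtpa/data/default_config.yaml` and describes
a 70 kg human with literature-typical second-generation minimal-PBPK
values: V_p 2.6 L, interstitial volumes 8.1 / 4.37 L (tight / leaky,
accessible fraction 0.8), lymph 5.2 L, total lymph flow 2.9 L/day split
1:2 tight:leaky, σ_t 0.95, σ_l 0.30, σ_L 0.2, CL_p 0.25 L/day, baseline
tissue uptake 0.02 L/day per tissue.  σ_l sits at the permeable end of
published fitted ranges, chosen so that leaky-tissue troughs are
comparable to plasma troughs — the qualitative behaviour this framework
attributes to visceral tissue (drug accumulates in leaky tissue and the
affinity cutoffs at the plasma and leaky sites nearly coincide); the
site-of-action contrast then comes from the tight tissue, where only ~5%
of the plasma convective flux enters.  The
charge coefficients are 0.15 per unit charge for clearance and uptake, so
a ±5 variant spans roughly a 4.5-fold clearance range; the monotone
direction is the contract, the magnitude is an explicit calibration knob.
`kon` is fixed at 0.36 nM⁻¹h⁻¹ (typical antibody association rate): only
K_D is screened, so every extracted cutoff is conditional on this `kon`.

### Numerics

States are concentrations in nM, time in hours.  The reference path
integrates one candidate with LSODA at rtol 1e-8 / atol 1e-10 nM; the
cohort path stacks all candidates of a physical scenario into one
block-diagonal system and uses banded LSODA (`ml = mu = 9`), compacting
converged candidates out of the active set after every dosing interval.
Both paths share the same equations and agree to solver tolerance (tested).
States are clipped at zero after integration; a negative excursion beyond
1e-7 relative is an error.  On a batch failure the affected chunk is
re-run candidate-by-candidate and only the offending candidates are marked
failed; a failure fraction above 5% aborts the cohort.

Steady state is declared when the end-of-interval plasma concentration
changes by less than 1e-3 (relative) between consecutive intervals; the
endpoint window is that final interval, sampled at 201 points.  The
interval cap is 30: with this parameterization the slowest case (weekly
dosing of a non-TMDD candidate, terminal half-life ≈ 2 weeks) converges
around interval 24.  Candidates that hit the cap are flagged and excluded
from the learning stage.  Single-bolus scenarios use a fixed 28-day
evaluation horizon instead, since no periodic trough exists.

## Endpoints and labels

TO% = 100·DT/(T+DT), read at the instant where the *evaluation site's*
drug concentration reaches its trough (and peak) inside the steady-state
window; for the plasma site this is exactly the plasma C_min/C_max
instant.  If no target is present the ratio is undefined and a 0 sentinel
is returned with a warning.  Plasma C_min, C_max and the trapezoidal
AUC_ss over the window are reported alongside but never enter the
classifier.  Binary label: optimal iff TO% at trough > 90 (strict;
90.0 is non-optimal).  Three-band label: low ≤ 50 < medium ≤ 90 < high.

## Virtual cohort

Candidates are sampled independently log-uniformly: K_D and T_0 over
1 pM – 1000 nM, t_1/2 over 1 min – 300 h; 10,000 candidates in the
full-scale profile.  One candidate table is shared across the scenarios of
a sweep so that cutoff differences between scenarios are not sampling
noise; per-scenario resampling is available.  The scenario grid crosses
dose (0.1/1/10 mg/kg), regimen (bolus/Q1W/Q2W/Q4W), charge (−5/0/+5),
target form (soluble/membrane) and evaluation site (plasma/leaky/tight);
the default set reproduces the headline sweeps with the base scenario at
1 mg/kg Q2W, charge 0, soluble, plasma.

## Learning and rule extraction

Features are log10(K_D), log10(T_0), log10(t_1/2) — the sampling is
log-uniform, so interpolating or splitting in raw nM space would distort
the minority manifold.  The optimal class is usually the minority; SMOTE
oversamples it to the majority count by uniform interpolation between a
minority point and one of its 5 nearest minority neighbours.  SMOTE runs
*before* the 90/10 stratified split by default (the balanced set is
treated as ground truth); the leakage-free order is available via
`split_first=True`.  The classifier is a CART tree with max depth 5, Gini
criterion, `min_samples_split=3`, best splitter and balanced class
weights, cross-validated with stratified five folds on the training 90%
and evaluated on the held-out 10%.

Rules are root-to-leaf conjunctions, simplified to the tightest bound per
feature and direction, back-transformed to nM / h, and ranked by ascending
leaf Gini impurity, then descending leaf accuracy, then descending
support.  Ties between several exactly pure leaves are therefore broken by
support, which selects the bulk optimal region rather than a boundary
sliver.  The scenario's "optimal rule" is the top-ranked optimal-class
rule.

Three cutoff readouts coexist, from most literal to most stable:

- ``cutoff_table(mode="top")`` quotes the top-ranked rule's own bounds
  (optionally falling back down the ranking).  This is one leaf's
  *sufficient* box and can sit well inside the optimal region.
- ``cutoff_table(mode="envelope")`` — the pipeline's ``cutoffs.csv`` —
  reports the outer bound of the optimal region: the loosest bound per
  feature over the credible optimal leaves (Gini ≤ 0.05, support ≥ 1%,
  excluding few-row slivers), present only when every credible leaf
  constrains the feature.  This matches the "maximum cut-off needed to
  reach the occupancy criterion" but inherits the placement noise of
  individual splits.
- ``property_cutoff`` / ``halflife_lower_bound`` read the cutoff off the
  classifier's decision surface: scan one feature over its sampled range
  with the others held at fixed anchors — K_D and T_0 at 0.1 nM (a
  decade inside every scenario's cutoff) and t_1/2 at 2.24 h, the
  geometric median of its range — and report where the predicted class
  flips.  Every leaf along the dense profile votes, so this readout is
  markedly more seed-stable than any single leaf's edge; the full-scale
  script uses it.  The membrane half-life scan needs the full-scale
  cohort (the profile region is too sparse at n = 2000).

Rules are validated by probing: fresh candidates sampled inside a rule's
box are simulated and the fraction agreeing with the rule's class is
reported.

## Target-form boundary

For the soluble-vs-membrane comparison (leaky-tissue trough), candidates
optimal as a soluble target but non-optimal as a membrane target mark the
region where fast receptor turnover destroys membrane occupancy.  The separator is the
tightest origin-anchored line T_0 = m·t_1/2 lying above those points;
its slope is estimated as the per-bin maximum of T_0/t_1/2 over
log-spaced half-life bins, medianed across bins for robustness.  The
construction is this package's own reconstruction — the boundary
definition is genuinely open — and the slope is strongly
parameterization-dependent.

## What the synthetic cohort does and does not emulate

The generator reproduces the screening design itself (independent
log-uniform axes over the stated ranges), not real antibody programmes:
real candidates correlate affinity with development stage, targets do not
populate the (T_0, t_1/2) plane uniformly, and expression is rarely equal
across plasma and both tissue groups.  Passing tests therefore certify the
pipeline's internal consistency — simulator invariants, balanced learning,
faithful rule extraction, correct monotone orderings of the cutoffs — and
the rough location of the cutoffs under this parameterization, not
clinical accuracy for any particular molecule.  The mechanistic layer
likewise omits FcRn-affinity variation, subcutaneous dosing,
inter-individual variability and any pharmacodynamic link.

## Problem sizes

The packaged `full` profile runs 10,000 candidates.  The test suite and
the acceptance script use 2,000 candidates per sweep — a size at which
the envelope cutoffs are stable to within the stochastic scatter of the
sampling — except for the membrane-target scenario, which runs at 10,000
because its half-life decision boundary needs the extra resolution; the
`smoke` profile (200) exercises every stage in minutes.

## Known limitations

- The exact fitted parameterization behind the published cutoffs is not
  public; the shipped defaults are literature-typical, so quantitative
  cutoffs should be read as order-of-magnitude anchors (the tests band
  them within a factor of 3) while orderings across sweeps are robust.
- Tissue occupancy is evaluated on the lumped tissue compartment
  concentration; models that distinguish tissue vasculature from
  interstitium may shift tissue-site cutoffs.
- With SMOTE applied before the split, the held-out accuracy is measured
  partly on synthetic points and is optimistic; `split_first=True`
  quantifies the difference.
- The default candidate count per rule-validation probe run is small
  (tens); probe agreement is a sanity report, not a calibrated error rate.
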