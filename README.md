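# mtpa — minimal-PBPK / ML target pharmacology assessment

`mtpa` is a screening tool for early antibody discovery. It asks, before
any wet-lab optimization: *for a given dose, dosing scheme, antibody net
charge, target form and site of action, which combinations of binding
affinity (K_D), target baseline (T_0) and target half-life (t_1/2) can
reach high target occupancy at the steady-state trough?*

It answers by simulation plus interpretation:

1. **Simulate.** Thousands of virtual antibody–target pairs (log-uniform
   K_D, T_0, t_1/2) are pushed through a minimal physiologically based
   pharmacokinetic (mPBPK) model — plasma, lumped tight and leaky tissue,
   lymph — with full target-mediated drug disposition (TMDD) at every
   expression site, under repeated IV dosing to steady state.
2. **Label.** Each pair gets its target occupancy at the trough,
   TO% = 100·DT/(T+DT); pairs with TO% > 90 are *optimal*.
3. **Learn.** After SMOTE class balancing, a depth-5 Gini CART
   (`min_samples_split=3`, balanced class weights, stratified 5-fold CV on
   a 90/10 split) classifies the pairs; its root-to-leaf paths are
   extracted as ranked, human-readable rules whose thresholds are the
   property cutoffs (e.g. "K_D ≤ 9 nM and T_0 ≤ 4 nM").

The audience is DMPK / modeling-and-simulation scientists who want
dose-conditional property bounds ("at 0.1 mg/kg you need sub-nanomolar
affinity") rather than black-box predictions.

## Model sketch

Drug transport follows second-generation mPBPK conventions: convective
extravasation with lymph flow filtered by vascular reflection coefficients
(σ_tight ≫ σ_leaky), lymphatic return past σ_L, nonspecific clearance in
plasma and pinocytotic uptake in tissue, both scaled by `exp(coeff ×
charge)`. At each expression site the target turns over
(`kdeg = ln2/t_1/2`, `ksyn = kdeg·T_0`), binds drug (`koff = kon·K_D`,
`kon` fixed at 0.36 nM⁻¹h⁻¹), and the complex internalizes at `kdeg`
(membrane-bound target) or at the drug's elimination rate (soluble
target). All physiology is a versioned YAML config (70 kg human defaults);
see `docs/methods.md` for equations, values and design rationale.

## Worked example

```python
from mtpa import (default_config, PhysiologyParams, Scenario,
                  sample_candidates, run_cohort, OccupancyRuleModel,
                  cutoff_table)

cfg = default_config()
phys = PhysiologyParams.from_config(cfg)

# 2000 virtual pairs, base scenario: 1 mg/kg IV Q2W, neutral charge,
# soluble target, occupancy read at the plasma trough
cand = sample_candidates(2000, cfg["sampling"], seed=42)
base = Scenario()   # d1_Q2W_c+0_soluble_plasma
data = run_cohort(cand, [base], phys, cfg)[base.scenario_id]

res = OccupancyRuleModel(data, ml_cfg=cfg["ml"]).fit(seed=1)
print(res.summary("optimal"))
print(cutoff_table({base.scenario_id: res.rules("optimal")},
                   mode="envelope"))
```

prints

```
Occupancy rule model (depth-5 Gini CART)
================================================
training rows              2059
held-out rows               229
CV accuracy (5-fold)     0.9806 +/- 0.0038
held-out accuracy        0.9913
held-out ROC AUC         0.9911

top rules (optimal):
  -> optimal      gini=0.000 acc=1.000 support=0.019  KD <= 9.72 nM & T0 <= 7.11 nM & T0 > 3.22 nM & THALF > 10.3 h
  -> optimal      gini=0.000 acc=1.000 support=0.004  KD <= 9.72 nM & T0 <= 13.6 nM & T0 > 7.11 nM & THALF > 50.5 h
  -> optimal      gini=0.000 acc=1.000 support=0.001  KD <= 9.72 nM & KD > 9.53 nM & T0 <= 3.22 nM
  -> optimal      gini=0.000 acc=1.000 support=0.001  KD <= 10.4 nM & KD > 9.72 nM & T0 <= 1 nM
  -> optimal      gini=0.000 acc=1.000 support=0.000  KD <= 9.72 nM & T0 <= 7.69 nM & T0 > 7.11 nM & THALF <= 50.5 h & THALF > 16.7 h
              scenario_id  kd_cutoff_nM  t0_cutoff_nM  thalf_bound_h thalf_direction rule_id
d1_Q2W_c+0_soluble_plasma      9.716128      7.111045            NaN            None  leaf14
```

Reading: the balanced cohort is classified with ~99% held-out accuracy,
and the envelope over the credible optimal leaves puts the outer cutoffs
near K_D ≈ 9.7 nM and T_0 ≈ 7.1 nM — a soluble target with baseline below
a few nM is reachable (TO > 90% at the steady-state trough) by any
antibody binding tighter than roughly 10 nM at this dose and schedule,
with no half-life requirement. Lowering the dose to 0.1 mg/kg drags the
K_D cutoff to ~1 nM; a +5-charged variant (faster clearance and uptake)
to ~3 nM.

The same machinery runs end to end from the shell:

```bash
mtpa run --profile smoke --n 200 --seed 3 --out my_run    # minutes
mtpa run --profile full --seed 7 --out full_run           # n=10,000
```

producing labeled tables, rule CSVs, tree JSONs, cutoff tables, pairwise
scatter/KDE figures and a manifest with every seed in `my_run/`.

## Layout

| path | contents |
| --- | --- |
| `src/mtpa/model_core.py` | mPBPK+TMDD types and reference simulator |
| `src/mtpa/batch.py` | vectorized banded-LSODA cohort integrator |
| `src/mtpa/endpoints.py` | TO%, C_min/C_max/AUC_ss, class labels |
| `src/mtpa/cohort.py` | candidate sampling, scenario grid, cohort runner |
| `src/mtpa/ml_rules.py` | SMOTE, CART fit, rule extraction/validation |
| `src/mtpa/report.py` | cutoff tables, boundary fit, figures |
| `src/mtpa/cli.py` | `mtpa` CLI and the end-to-end pipeline |
| `src/mtpa/data/default_config.yaml` | the versioned physiology/scenario config |
| `docs/methods.md` | model equations, assumptions, design decisions |
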