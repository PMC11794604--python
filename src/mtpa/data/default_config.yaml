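# Default scenario/physiology configuration: 70 kg human, IgG-like antibody.
# Volumes in L, lymph flows and clearances in L/day, body weight in kg.
# Values are literature-typical for a second-generation minimal PBPK model
# of monoclonal-antibody disposition; every number here is a config entry,
# not a code constant.
physiology:
  v_plasma: 2.6
  v_tight: 8.1          # 0.65 of interstitial water, accessible fraction 0.8
  v_leaky: 4.37         # 0.35 of interstitial water, accessible fraction 0.8
  v_lymph: 5.2
  l_tight: 0.957        # one third of total lymph flow (2.9 L/day)
  l_leaky: 1.943
  sigma_tight: 0.95
  sigma_leaky: 0.3
  sigma_lymph: 0.2
  cl_plasma: 0.25       # baseline nonspecific (FcRn-limited) plasma clearance
  cl_up_tight: 0.02     # baseline pinocytotic uptake clearance per tissue
  cl_up_leaky: 0.02
  bw: 70.0
  charge_cl_coeff: 0.15  # per unit Fv charge, log-clearance slope
  charge_up_coeff: 0.15  # per unit Fv charge, log-tissue-uptake slope

drug_defaults:
  mw: 150000.0          # g/mol
  kon: 0.36             # nM^-1 h^-1, fixed association rate (KD is sampled)
  charge: 0

sampling:
  kd: [0.001, 1000.0]       # nM  (1 pM - 1000 nM)
  t0: [0.001, 1000.0]       # nM
  t_half: [0.0166666667, 300.0]  # h  (1 min - 300 h)

solver:
  rtol: 1.0e-8
  atol: 1.0e-10         # nM
  n_points_per_interval: 201

steady_state:
  trough_rtol: 1.0e-3
  max_intervals: 30
  bolus_horizon_days: 28.0

labels:
  binary_threshold: 90.0    # TO% at steady-state trough; optimal iff > threshold
  multi_thresholds: [50.0, 90.0]

ml:
  max_depth: 5
  min_samples_split: 3
  class_weight: balanced
  criterion: gini
  test_size: 0.1
  cv_folds: 5
  smote_k_neighbors: 5
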