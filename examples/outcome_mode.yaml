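# Outcome-mode pipeline: simulate replicate outcome tables from the mixed
# model, screen, fit, and compute limits of agreement.
mode: outcome
seed: 1
simulate:
  n_individuals: 246
  scenario_counts:
    none: 648
    washin-pre: 47
    washout-pre: 56
  params:
    lci:
      mu: 6.82
      alpha: {none: 0.0, washin-pre: -0.135, washout-pre: 0.362}
      omega: 0.296
      tau: 0.186
      sigma: {none: 0.437, washin-pre: 0.36, washout-pre: 0.89}
    frc:
      mu: 0.0876
      alpha: {none: 0.0, washin-pre: 0.000503, washout-pre: 0.00226}
      omega: 0.0193
      tau: 0.00609
      sigma: {none: 0.00716, washin-pre: 0.00383, washout-pre: 0.00823}
reproducibility:
  include: [washin-pre]
model:
  min_scenario_n: 20
  n_starts: 5
  outlier_rules:
    - {lci: 9.5}
    - {cev_l: 1.4, lci: 9.0}
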