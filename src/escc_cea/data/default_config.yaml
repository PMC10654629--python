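# Default model configuration: first-line serplulimab + chemotherapy (cisplatin/5-FU)
# versus chemotherapy alone for PD-L1-positive advanced ESCC, Chinese health-care
# perspective. Costs are USD per monthly cycle (converted at $1 = CNY 6.77, dosing
# at BSA 1.72 m^2 / 65 kg); Weibull survival parameters per PD-L1 CPS population.
settings:
  cycle_length_months: 1
  horizon_cycles: 120
  discount_rate_annual: 0.05
  wtp_per_qaly: 37663.26
  half_cycle_correction: true

utilities:
  pfs: 0.68
  pd: 0.42

costs:
  intervention:
    pfs_components:
      serplulimab: 3415.47
      chemotherapy: 705.15
      antiemetics: 200.16
      tests: 384.63
      adverse_events: 50.13
      hospitalization: 40.34
    pd_per_cycle: 430.95
  comparator:
    pfs_components:
      chemotherapy: 578.75
      antiemetics: 164.28
      tests: 330.37
      adverse_events: 40.86
      hospitalization: 33.11
    pd_per_cycle: 869.24

populations:
  cps_ge1:
    intervention:
      pfs_weibull: {scale_lambda: 0.0594, shape_gamma: 1.275}
      os_weibull: {scale_lambda: 0.0119, shape_gamma: 1.478}
    comparator:
      pfs_weibull: {scale_lambda: 0.0595, shape_gamma: 1.532}
      os_weibull: {scale_lambda: 0.0158, shape_gamma: 1.482}
  cps_1to10:
    intervention:
      pfs_weibull: {scale_lambda: 0.0678, shape_gamma: 1.258}
      os_weibull: {scale_lambda: 0.0176, shape_gamma: 1.396}
    comparator:
      pfs_weibull: {scale_lambda: 0.0655, shape_gamma: 1.513}
      os_weibull: {scale_lambda: 0.0125, shape_gamma: 1.667}
  # Note: the published chemotherapy-arm Weibull parameters for CPS>=10 imply an
  # OS median of ~4.8 months, inconsistent with the trial's reported 13.9 months;
  # they are shipped as printed (see docs/methods.md).
  cps_ge10:
    intervention:
      pfs_weibull: {scale_lambda: 0.0456, shape_gamma: 1.294}
      os_weibull: {scale_lambda: 0.0086, shape_gamma: 1.504}
    comparator:
      pfs_weibull: {scale_lambda: 0.0228, shape_gamma: 1.354}
      os_weibull: {scale_lambda: 0.0536, shape_gamma: 1.619}

owsa:
  span: 0.20
  parameters:
    - costs.intervention.pfs_total
    - costs.comparator.pfs_total
    - costs.intervention.components.serplulimab
    - costs.intervention.components.chemotherapy
    - costs.comparator.components.chemotherapy
    - costs.intervention.components.antiemetics
    - costs.comparator.components.antiemetics
    - costs.intervention.components.tests
    - costs.comparator.components.tests
    - costs.intervention.components.adverse_events
    - costs.comparator.components.adverse_events
    - costs.intervention.components.hospitalization
    - costs.comparator.components.hospitalization
    - costs.intervention.pd_per_cycle
    - costs.comparator.pd_per_cycle
    - utilities.pfs
    - utilities.pd

psa:
  iterations: 1000
  se_fraction: 0.20
  seed: 20230731
  wtp_grid:
    start: 0
    stop: 250000
    step: 2500
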