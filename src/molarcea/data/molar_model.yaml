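# Thirty-year Markov cohort model of prosthetic options for a single
# missing lower first molar under the Japanese payer setting.
#
# Strategies: single implant (Implant), insurance-covered fixed dental
# prosthesis (IFDP, gold-silver-palladium bridge) and privately funded
# fixed dental prosthesis (PFDP, ceramic bridge).  A failed prosthesis is
# replaced once; a second failure leads to a removable partial denture
# (RPD) and, if that is abandoned, to an untreated missing tooth (MT).
# Effectiveness is the GOHAI oral-health QOL score rescaled to [0, 1] and
# accrued per year alive; all costs in euros (EUR 1 = JPY 114.60).
schema_version: 1

settings:
  start_age: 50          # years at first prosthetic treatment
  horizon: 30            # annual cycles
  cycle_length: 1.0      # years
  discount_rate: 0.02    # per year, costs and effects alike
  half_cycle_correction: false
  use_failure_qol: false # lost-prosthesis utilities stored but not accrued

life_table:
  kind: gompertz         # log-linear interpolation between the anchors
  anchors:
    50: 0.0016
    80: 0.0252

parameters:
  # oral-health QOL, converted GOHAI scale (dimensionless), beta-distributed
  qol_implant:      {family: beta, mean: 0.88, sd: 0.14}
  qol_lost_implant: {family: beta, mean: 0.71, sd: 0.23}
  qol_fdp:          {family: beta, mean: 0.83, sd: 0.13}
  qol_lost_fdp:     {family: beta, mean: 0.68, sd: 0.17}
  qol_rpd:          {family: beta, mean: 0.71, sd: 0.23}
  qol_mt:           {family: beta, mean: 0.70, sd: 0.18}
  # treatment and maintenance costs (EUR), gamma-distributed
  cost_implant:     {family: gamma, mean: 2744.0, sd: 274.4}
  cost_ifdp:        {family: gamma, mean: 420.0,  sd: 42.0}
  cost_pfdp:        {family: gamma, mean: 2618.0, sd: 261.8}
  cost_maint_fixed: {family: gamma, mean: 261.8,  sd: 26.2}   # implant/FDP/MT
  cost_rpd:         {family: gamma, mean: 368.0,  sd: 36.8}
  cost_maint_rpd:   {family: gamma, mean: 305.0,  sd: 43.6}

states:
  Implant:
    entry_cost: cost_implant
    maintenance_cost: cost_maint_fixed
    qol: qol_implant
    failure_qol: qol_lost_implant
    annual_failure_rate: 0.0052
    failure_allocation: {secondImplant: 1.0}
  secondImplant:
    entry_cost: cost_implant
    maintenance_cost: cost_maint_fixed
    qol: qol_implant
    failure_qol: qol_lost_implant
    annual_failure_rate: 0.02
    failure_allocation: {IFDP: 1.0}
  IFDP:
    entry_cost: cost_ifdp
    maintenance_cost: cost_maint_fixed
    qol: qol_fdp
    failure_qol: qol_lost_fdp
    annual_failure_rate: 0.11
    failure_allocation: {secondIFDP: 0.998, RPD: 0.002}
  secondIFDP:
    entry_cost: cost_ifdp
    maintenance_cost: cost_maint_fixed
    qol: qol_fdp
    failure_qol: qol_lost_fdp
    annual_failure_rate: 0.15
    failure_allocation: {RPD: 1.0}
  PFDP:
    entry_cost: cost_pfdp
    maintenance_cost: cost_maint_fixed
    qol: qol_fdp
    failure_qol: qol_lost_fdp
    annual_failure_rate: 0.044
    failure_allocation: {secondPFDP: 0.998, RPD: 0.002}
  secondPFDP:
    entry_cost: cost_pfdp
    maintenance_cost: cost_maint_fixed
    qol: qol_fdp
    failure_qol: qol_lost_fdp
    annual_failure_rate: 0.084
    failure_allocation: {RPD: 1.0}
  RPD:
    entry_cost: cost_rpd
    maintenance_cost: cost_maint_rpd
    qol: qol_rpd
    annual_failure_rate: 0.168
    failure_allocation: {MT: 1.0}
  MT:
    entry_cost: 0.0
    maintenance_cost: cost_maint_fixed
    qol: qol_mt
    annual_failure_rate: 0.0
    failure_allocation: {}
  dead:
    entry_cost: 0.0
    maintenance_cost: 0.0
    qol: 0.0
    annual_failure_rate: 0.0
    failure_allocation: {}

strategies:
  Implant: Implant
  IFDP: IFDP
  PFDP: PFDP
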