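# Planning example: bronchodilator trial in chronic obstructive pulmonary
# disease (indacaterol vs tiotropium, FEV1 outcome).  The budget is the total
# number of subjects (c_sp = c_s2p = 1, all other costs 0); plausible ICC
# ranges are [0.10, 0.70] for treatment A and [0.30, 0.90] for treatment B.
name: copd_bronchodilator
c_A: 0
c_B: 0
c_t: 0
c_sp: 1
c_s2p: 1
c_ts: 0
rhoA_low: 0.10
rhoA_high: 0.70
rhoB_low: 0.30
rhoB_high: 0.90
ES: 0.5
alpha: 0.05
power: 0.80
effect: treatment
designs: [crossover, extended_parallel, parallel]
sigma_y_sq: 2.0
n_sim: 0
seed: 1
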