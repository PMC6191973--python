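"""Maximin sample size for a COPD bronchodilator crossover trial.

Plan: detect a medium standardized effect (ES = 0.5) with 80% power in a
two-tailed test at alpha = 0.05, minimizing the number of subjects, with
ICC ranges [0.10, 0.70] (treatment A) and [0.30, 0.90] (treatment B).
"""

import maximindesign as md

config = md.load_config(md.example_config_path())
plan = md.maximin_sample_size(
    md.DesignKind.CROSSOVER,
    config.effect,
    config.power_spec,
    config.costs,
    config.rect,
)

print(f"worst-case ICCs            rho* = {plan.rho_star}")
print(f"unrounded total            n_raw = {plan.n_raw:.1f}")
print(f"per-sequence before corr.  {plan.n1_pre} / {plan.n2_pre}")
print(f"t-correction per sequence  +{plan.correction_per_arm} ({plan.test} t-test)")
print(f"final plan                 N = {plan.N} ({plan.n1} AB + {plan.n2} BA)")

# 54 subjects satisfy the normal-approximation power identity at the worst
# case (0.10, 0.30); one extra subject per sequence compensates for the
# pooled-variance t-test's estimated variance, giving 28 per sequence.
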