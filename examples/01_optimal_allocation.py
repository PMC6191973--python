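"""Optimal allocation and estimator variance at known intraclass correlations.

Scenario: treatment A costs 4 per subject, B costs 1, each measurement 0.5,
recruiting a subject 2 (one-period) or 3 (two-period).  With rho_A = 0.3 and
rho_B = 0.6 the outcome variance under A is twice that under B
(phi = rho_B / rho_A = 2).
"""

import maximindesign as md

costs = md.CostStructure(c_A=4, c_B=1, c_t=0.5, c_sp=2, c_s2p=3)
rhoA, rhoB = 0.3, 0.6
C = 100.0  # net budget in the same currency units

print(f"variance ratio phi = {md.variance_ratio(rhoA, rhoB):.2f}")
for design in md.DesignKind:
    ratio = md.optimal_allocation(design, md.EffectOfInterest.TREATMENT, costs, rhoA, rhoB)
    var = md.optimal_variance(design, md.EffectOfInterest.TREATMENT, costs, rhoA, rhoB, C=C)
    n = md.subjects_for_budget(design, C, ratio / (1 + ratio), costs)
    print(
        f"{design.value:18s} allocation n1/n2 = {ratio:5.3f}  "
        f"Var(beta_treat) = {var:6.4f}  subjects affordable = {n:5.1f}"
    )

# The allocation ratio is n1/n2 with arm 1 the A (or AA/AB) sequence: the
# expensive, high-variance A arm gets fewer subjects in the parallel designs,
# while the crossover always splits 1:1.  Smaller variance = more efficient
# use of the same budget.
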