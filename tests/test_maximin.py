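"""Maximin designs: closed form vs grid oracle, dominance, efficiencies."""

import numpy as np
import pytest

from maximindesign import (
    CostStructure,
    DesignKind,
    EffectOfInterest,
    ICCRectangle,
    ScenarioGridSpec,
    evaluation_grid,
    maximin_params,
    maximin_params_grid_oracle,
    optimal_variance,
    relative_efficiency,
)
from .conftest import random_costs, random_rect

D = DesignKind
E = EffectOfInterest

COMBOS = [
    (D.PARALLEL, E.TREATMENT),
    (D.EXTENDED_PARALLEL, E.TREATMENT),
    (D.CROSSOVER, E.TREATMENT),
    (D.EXTENDED_PARALLEL, E.TREATMENT_BY_PERIOD),
    (D.CROSSOVER, E.TREATMENT_BY_PERIOD),
]


class TestClosedFormCases:
    def test_crossover_treatment_worst_case_is_lower_corner(self, subject_costs, copd_rect):
        mm = maximin_params(D.CROSSOVER, E.TREATMENT, subject_costs, copd_rect)
        assert mm.rho_star == (0.10, 0.30)
        assert mm.allocation_ratio == 1.0
        assert mm.variance == pytest.approx(0.85)

    def test_extended_parallel_treatment_upper_corners(self, subject_costs, copd_rect):
        mm = maximin_params(D.EXTENDED_PARALLEL, E.TREATMENT, subject_costs, copd_rect)
        assert mm.rho_star == (0.70, 0.90)
        assert mm.branch == "both upper corners"

    def test_parallel_interior_locus_value(self, subject_costs):
        # equal arm costs put phi* = 1 inside [0.7, 1/0.7]; the worst-case
        # variance is then c_A + c_B + 2(c_t + c_sp) = 2 for unit subject cost
        rect = ICCRectangle(0.70, 1.00, 0.70, 1.00)
        mm = maximin_params(D.PARALLEL, E.TREATMENT, subject_costs, rect)
        assert mm.branch == "phi* interior"
        assert mm.variance == pytest.approx(2.0)
        assert mm.rho_star[1] / mm.rho_star[0] == pytest.approx(1.0)

    def test_crossover_interaction_upper_corner(self, subject_costs):
        rect = ICCRectangle(0.2, 0.4, 0.2, 0.4)
        mm = maximin_params(D.CROSSOVER, E.TREATMENT_BY_PERIOD, subject_costs, rect)
        assert mm.rho_star == (0.4, 0.4)

    @pytest.mark.parametrize("design, effect", COMBOS)
    def test_degenerate_rectangle_reduces_to_optimal(self, subject_costs, design, effect):
        rect = ICCRectangle(0.45, 0.45, 0.65, 0.65)
        mm = maximin_params(design, effect, subject_costs, rect)
        assert mm.branch == "degenerate"
        assert mm.rho_star == (0.45, 0.65)
        assert mm.variance == pytest.approx(
            optimal_variance(design, effect, subject_costs, 0.45, 0.65,
                             sigma_y_sq=1.0, C=1.0)
        )


class TestGridOracle:
    def test_monotone_corners(self, subject_costs):
        rect = ICCRectangle(0.2, 0.4, 0.2, 0.4)
        lo = maximin_params_grid_oracle(D.CROSSOVER, E.TREATMENT, subject_costs, rect)
        hi = maximin_params_grid_oracle(D.CROSSOVER, E.TREATMENT_BY_PERIOD,
                                        subject_costs, rect)
        assert lo.rho_star == (0.2, 0.2)
        assert hi.rho_star == (0.4, 0.4)

    def test_point_rectangle(self, subject_costs):
        rect = ICCRectangle(0.3, 0.3, 0.5, 0.5)
        mm = maximin_params_grid_oracle(D.PARALLEL, E.TREATMENT, subject_costs, rect)
        assert mm.rho_star == (0.3, 0.5)

    @pytest.mark.parametrize("design, effect", COMBOS)
    def test_closed_form_agrees_with_oracle(self, design, effect):
        """The closed form must dominate every grid point and exceed the grid
        maximum by at most the grid's own discretization error."""
        rng = np.random.default_rng(101)
        for _ in range(30):
            costs = random_costs(rng)
            rect = random_rect(rng)
            mm = maximin_params(design, effect, costs, rect)
            oracle = maximin_params_grid_oracle(design, effect, costs, rect, 201)
            assert mm.variance >= oracle.variance * (1 - 1e-9)
            assert mm.variance <= oracle.variance * (1 + 5e-3)
            assert rect.contains(*mm.rho_star)


class TestMaximinProperties:
    def test_dominates_whole_rectangle(self):
        """Defining property: the maximin variance is >= the optimal variance
        at every grid point of the rectangle."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            costs = random_costs(rng)
            rect = random_rect(rng)
            for design, effect in COMBOS:
                mm = maximin_params(design, effect, costs, rect)
                ra = np.linspace(rect.rhoA_low, rect.rhoA_high, 200)
                rb = np.linspace(rect.rhoB_low, rect.rhoB_high, 200)
                A, B = np.meshgrid(ra, rb, indexing="ij")
                V = optimal_variance(design, effect, costs, A, B,
                                     sigma_y_sq=1.0, C=1.0)
                assert mm.variance >= np.max(V) * (1 - 1e-9)

    def test_monotone_in_rectangle_inclusion(self):
        """Enlarging the rectangle never decreases the maximin variance."""
        rng = np.random.default_rng(77)
        for _ in range(15):
            costs = random_costs(rng)
            inner = random_rect(rng)
            grow = rng.uniform(0.0, 0.3, 4)
            outer = ICCRectangle(
                max(inner.rhoA_low - grow[0], 0.005),
                min(inner.rhoA_high + grow[1], 1.0),
                max(inner.rhoB_low - grow[2], 0.005),
                min(inner.rhoB_high + grow[3], 1.0),
            )
            for design, effect in COMBOS:
                vi = maximin_params(design, effect, costs, inner).variance
                vo = maximin_params(design, effect, costs, outer).variance
                assert vo >= vi * (1 - 1e-12)

    def test_interaction_extended_parallel_dominates_crossover(self):
        """For the treatment-by-period interaction the maximin AA/BB design is
        always at least as efficient as the maximin AB/BA design."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            costs = random_costs(rng)
            rect = random_rect(rng)
            ep = maximin_params(D.EXTENDED_PARALLEL, E.TREATMENT_BY_PERIOD, costs, rect)
            co = maximin_params(D.CROSSOVER, E.TREATMENT_BY_PERIOD, costs, rect)
            assert ep.variance <= co.variance * (1 + 1e-12)
            # the intermediate bound: the crossover worst case is itself
            # above 4 * (c_A + c_B + 2 c_t + c_s2p) per sigma_y^2/C
            assert co.variance >= 4 * costs.crossover_subject_cost

    def test_subject_budget_crossover_needs_fewer_than_parallel(self):
        """Under a subject-count budget the maximin crossover treatment-effect
        variance never exceeds the maximin parallel one."""
        rng = np.random.default_rng(13)
        costs = CostStructure.subject_count()
        for _ in range(200):
            rect = random_rect(rng)
            co = maximin_params(D.CROSSOVER, E.TREATMENT, costs, rect)
            pa = maximin_params(D.PARALLEL, E.TREATMENT, costs, rect)
            assert co.variance <= pa.variance * (1 + 1e-12)


class TestRelativeEfficiency:
    def test_reference_efficiencies(self, subject_costs):
        rect = ICCRectangle(0.01, 0.10, 0.90, 1.00)
        sols = [maximin_params(d, E.TREATMENT, subject_costs, rect)
                for d in (D.CROSSOVER, D.PARALLEL, D.EXTENDED_PARALLEL)]
        effs = relative_efficiency(sols)
        assert effs[0] == 1.0
        assert effs[1] == pytest.approx(0.61, abs=0.005)
        assert effs[2] == pytest.approx(0.96, abs=0.005)

    def test_duplicated_design_ties(self, subject_costs, copd_rect):
        sol = maximin_params(D.CROSSOVER, E.TREATMENT, subject_costs, copd_rect)
        assert relative_efficiency([sol, sol]) == [1.0, 1.0]

    def test_mixed_effects_rejected(self, subject_costs, copd_rect):
        a = maximin_params(D.CROSSOVER, E.TREATMENT, subject_costs, copd_rect)
        b = maximin_params(D.CROSSOVER, E.TREATMENT_BY_PERIOD, subject_costs, copd_rect)
        with pytest.raises(ValueError):
            relative_efficiency([a, b])


class TestEvaluationGrid:
    def test_range_construction(self):
        spec = ScenarioGridSpec(widths=(0.3,))
        ranges = spec.ranges()
        assert (0.01, 0.31) in ranges
        assert (0.70, 1.00) in ranges
        assert all(hi <= 1.0 for _, hi in ranges)

    def test_equal_cheap_costs_crossover_always_best(self):
        """With CR_p = 1 and equal treatment cost ratios of 1, the crossover
        is the most efficient design whenever both ICC lower bounds are at
        least 0.15."""
        spec = ScenarioGridSpec(cr_a_values=(1.0,), cr_b_values=(1.0,),
                                cr_p_values=(1.0,))
        ranges = [r for r in spec.ranges() if r[0] >= 0.15]
        pairs = [(ra, rb) for ra in ranges for rb in ranges]
        table = evaluation_grid(spec, E.TREATMENT, rect_pairs=pairs)
        assert (table.best_design == "crossover").all()

    def test_interaction_extended_parallel_always_best(self):
        spec = ScenarioGridSpec(cr_a_values=(10.0, 1.0), cr_b_values=(1.0, 0.1),
                                cr_p_values=(1.0, 2.0), widths=(0.3,))
        table = evaluation_grid(spec, E.TREATMENT_BY_PERIOD)
        assert table.best_design.str.contains("extended_parallel").all()

    def test_single_cell_consistent_with_relative_efficiency(self, subject_costs):
        spec = ScenarioGridSpec(cr_a_values=(0.0,), cr_b_values=(0.0,),
                                cr_p_values=(1.0,))
        pair = ((0.10, 0.70), (0.30, 0.90))
        table = evaluation_grid(spec, E.TREATMENT, rect_pairs=[pair])
        assert len(table) == 1
        rect = ICCRectangle(0.10, 0.70, 0.30, 0.90)
        sols = [maximin_params(d, E.TREATMENT, subject_costs, rect)
                for d in (D.CROSSOVER, D.PARALLEL, D.EXTENDED_PARALLEL)]
        row = table.iloc[0]
        assert row.var_crossover == pytest.approx(sols[0].variance)
        assert row.var_parallel == pytest.approx(sols[1].variance)
        assert row.var_extended_parallel == pytest.approx(sols[2].variance)
        assert row.best_design == "crossover"
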