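"""Drug-resistance application graphs and their closed forms."""

import math

import numpy as np
import pytest

from evopaths.analytics import (
    HittingTimeApprox,
    median_hitting_time,
    path_probability,
    time_advantage,
    weight_table,
)
from evopaths.graph import enumerate_paths, validate_graph
from evopaths.scenarios import (
    CombinationParams,
    MonotherapyParams,
    TwoPathMDRParams,
    build_combination,
    build_monotherapy,
    build_two_step_mdr,
    cml_analysis,
    combination_median_curve,
    combination_metrics,
    direct_paths,
    drug_switch_condition,
    mdr_two_path_analysis,
    monotherapy_median,
    monotherapy_order_probability,
    stepwise_paths,
)

MONO = dict(alpha=1.0, beta=0.4, nu=1e-6, m=0.05, s=5e-3, d=1e-2, z=100)


def combo_params(**over):
    n_tot = 1e7
    base = dict(
        alpha=0.7, beta=0.3, nu=1e-6, m=0.05, s=1e-3, d=0.9,
        n_S=0.05 * n_tot, n_D=0.05 * n_tot, n_DD=0.9 * n_tot, gamma=1e-3,
    )
    base.update(over)
    return CombinationParams(**base)


class TestMonotherapy:
    def test_graph_valid_and_two_paths(self):
        g = build_monotherapy(MonotherapyParams(**MONO))
        assert validate_graph(g) == []
        assert len(enumerate_paths(g)) == 2

    def test_path_weights_nu_m_over_costs(self):
        p = MonotherapyParams(**MONO)
        table = weight_table(build_monotherapy(p))
        w = {s.seq[1]: table.weight(s) for s in table.sequences}
        assert w["S_resistant"] == pytest.approx(p.nu * p.m / p.s)  # mutation-migration
        assert w["D_sensitive"] == pytest.approx(p.nu * p.m / p.d)  # migration-mutation

    def test_mutation_first_probability_is_cost_fraction(self):
        p = MonotherapyParams(**MONO)
        expected = p.d / (p.s + p.d)
        assert monotherapy_order_probability(p) == pytest.approx(expected)
        table = weight_table(build_monotherapy(p))
        mm = next(s for s in table.sequences if s.seq[1] == "S_resistant")
        assert path_probability(table, mm) == pytest.approx(expected, rel=1e-12)

    def test_median_matches_three_term_decomposition(self):
        p = MonotherapyParams(**MONO)
        lam = p.lam
        expected = (
            math.log(lam**2 / p.alpha) / lam
            - math.log(p.nu * p.m / p.s + p.nu * p.m / p.d) / lam
            + math.log(p.alpha / (p.z * lam)) / lam
        )
        assert monotherapy_median(p).value == pytest.approx(expected, rel=1e-12)
        # and equals the generic pipeline on the built graph
        g = build_monotherapy(p)
        h = HittingTimeApprox.from_graph(g)
        assert median_hitting_time(h).value == pytest.approx(expected, rel=1e-12)

    def test_symmetry_under_swapping_mutation_and_migration_roles(self):
        p = MonotherapyParams(**MONO)
        swapped = MonotherapyParams(
            alpha=p.alpha, beta=p.beta, nu=p.m, m=p.nu, s=p.d, d=p.s, z=p.z
        )
        t1 = weight_table(build_monotherapy(p))
        t2 = weight_table(build_monotherapy(swapped))
        assert sorted(t1.log_w.values()) == pytest.approx(sorted(t2.log_w.values()))
        assert monotherapy_order_probability(swapped) == pytest.approx(
            1 - monotherapy_order_probability(p)
        )


class TestDrugSwitch:
    def test_condition_is_sanctuary_ratio_vs_cost_ratio(self):
        p_a = MonotherapyParams(**MONO)
        p_b = MonotherapyParams(**{**MONO, "d": 5e-2, "z": 60})
        dec = drug_switch_condition(p_a, p_b)
        assert dec.switch == (p_a.z / p_b.z > (1 + p_a.s / p_b.d) / (1 + p_a.s / p_a.d))
        assert dec.switch == (dec.margin > 0)

    def test_identical_drugs_never_favoured(self):
        p = MonotherapyParams(**MONO)
        dec = drug_switch_condition(p, p)
        assert not dec.switch and dec.margin == pytest.approx(0.0)

    def test_infinitely_effective_drug_limit(self):
        p_a = MonotherapyParams(**MONO)
        dec = drug_switch_condition(p_a, MonotherapyParams(**{**MONO, "d": 1e12}))
        assert dec.limit_threshold == pytest.approx(1 / (1 + p_a.s / p_a.d))
        assert dec.threshold == pytest.approx(dec.limit_threshold, rel=1e-9)

    def test_boundary_grid_matches_inequality(self):
        # penetration (z ratio) x efficacy (d_B) plane, fixed d_A and s
        p_a = MonotherapyParams(**{**MONO, "z": 1000})
        for d_b in np.logspace(-3, 0, 6):
            for z_b in (200, 600, 900, 990, 1200):
                p_b = MonotherapyParams(**{**MONO, "d": float(d_b), "z": z_b})
                dec = drug_switch_condition(p_a, p_b)
                assert dec.switch == (
                    p_a.z / z_b > (1 + MONO["s"] / d_b) / (1 + MONO["s"] / MONO["d"])
                )


class TestCombination:
    def test_twelve_states_and_eighteen_paths(self):
        g = build_combination(combo_params())
        assert g.n_vertices == 12
        assert [v for v in validate_graph(g) if v.severity == "error"] == []
        paths = enumerate_paths(g)
        assert len(paths) == 18
        assert len(direct_paths(g)) == 6
        assert len(stepwise_paths(g)) == 12

    def test_migration_rates_destination_proportional(self):
        p = combo_params()
        g = build_combination(p)
        assert g.nu("S:00", "DD:00") == pytest.approx(p.m * p.n_DD / (p.n_D + p.n_DD))
        assert g.nu("S:00", "D:00") == pytest.approx(p.m * p.n_D / (p.n_D + p.n_DD))
        assert g.nu("D:00", "DD:00") == pytest.approx(p.m * p.n_DD / (p.n_S + p.n_DD))
        # sanctuary out-migration totals m per cell (both destinations forward)
        out_m = g.nu("S:00", "D:00") + g.nu("S:00", "DD:00")
        assert out_m == pytest.approx(p.m)

    def test_stepwise_exemplar_path_present(self):
        g = build_combination(combo_params())
        seqs = {p.seq for p in stepwise_paths(g)}
        assert ("S:00", "S:A", "D:A", "D:AB", "DD:AB") in seqs

    def test_nonnested_geometry_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            build_combination(combo_params(), geometry="disjoint")

    def test_acceleration_condition_flips_at_threshold(self):
        # (n_S + n_D)/n_Tot = 0.1; condition: s/m below that
        m = combination_metrics(combo_params(s=1e-3, m=0.05))  # s/m = 0.02 < 0.1
        assert m.acceleration_condition
        m2 = combination_metrics(combo_params(s=1e-2, m=0.05))  # s/m = 0.2 > 0.1
        assert not m2.acceleration_condition

    def test_stepwise_probability_increases_with_single_drug_region(self):
        curve = combination_median_curve(combo_params(), ratios=[0.2, 1.0, 4.0])
        probs = curve["stepwise_probability"].to_numpy()
        assert np.all(np.diff(probs) > 0)

    def test_stepwise_closed_form_converges_to_exact_as_s_shrinks(self):
        rel_errs = []
        for s in (9e-3, 9e-4, 9e-5):
            m = combination_metrics(combo_params(s=s))
            rel_errs.append(
                abs(m.stepwise_probability_exact - m.stepwise_probability_approx)
                / m.stepwise_probability_exact
            )
        assert rel_errs[0] > rel_errs[1] > rel_errs[2]
        assert rel_errs[2] < 1e-6

    def test_most_probable_stepwise_path_is_mutA_migrate_mutB_migrate(self):
        m = combination_metrics(combo_params())
        assert m.most_probable_stepwise_path in {
            ("S:00", "S:A", "D:A", "D:AB", "DD:AB"),
            ("S:00", "S:B", "D:B", "D:AB", "DD:AB"),  # label symmetry
        }


class TestCML:
    def test_rate_competition_gives_one_in_eleven(self):
        r = cml_analysis(nu_pm=8e-8, nu_ga=8e-7, s=1e-3)
        assert r.p_point_mutation_first == pytest.approx(1 / 11)

    def test_two_amplification_model(self):
        for s in (1e-7, 1e-6, 1e-3):
            r = cml_analysis(8e-8, 8e-7, s=s)
            assert r.p_point_mutation_two_step == pytest.approx(1 / (1 + 8e-6 / s))
        r = cml_analysis(8e-8, 8e-7, s=1.0)
        assert r.s_threshold_vs_half == pytest.approx(8e-6)
        assert r.s_threshold_vs_single == pytest.approx(8e-7)

    def test_equal_survival_adjustment_cancels(self):
        r = cml_analysis(8e-8, 8e-7, s=1e-3, rho_pm=0.25, rho_ga=0.25)
        assert r.p_point_mutation_first_adjusted == pytest.approx(1 / 11)

    def test_survival_adjustment_threshold(self):
        # point mutation more probable than amplification iff rho_pm > 10 rho_ga
        just_above = cml_analysis(8e-8, 8e-7, s=1e-3, rho_pm=0.51, rho_ga=0.05)
        just_below = cml_analysis(8e-8, 8e-7, s=1e-3, rho_pm=0.49, rho_ga=0.05)
        assert just_above.p_point_mutation_first_adjusted > 0.5
        assert just_below.p_point_mutation_first_adjusted < 0.5


class TestMDR:
    PARAMS = dict(alpha=1.0, beta=0.1, nu_1=1e-9, nu_2=1e-9)

    def test_rifampicin_first_probability(self):
        p = TwoPathMDRParams(**self.PARAMS, r_1=0.88, r_2=0.71)
        res = mdr_two_path_analysis(p, t=10.0)
        assert res.p_first_order == pytest.approx((1 - 0.71) / ((1 - 0.88) + (1 - 0.71)))
        assert round(res.p_first_order, 1) == 0.7

    def test_equal_costs_give_even_odds(self):
        p = TwoPathMDRParams(**self.PARAMS, r_1=0.8, r_2=0.8)
        assert mdr_two_path_analysis(p, t=10.0).p_first_order == pytest.approx(0.5)

    def test_order_probability_matches_generic_pipeline(self):
        p = TwoPathMDRParams(**self.PARAMS, r_1=0.88, r_2=0.71)
        g = build_two_step_mdr(p)
        assert [v for v in validate_graph(g) if v.severity == "error"] == []
        table = weight_table(g)
        generic = time_advantage(table, ("wt", "res1", "res12"), 0.0)
        assert generic == pytest.approx(mdr_two_path_analysis(p, t=0.0).p_first_order, rel=1e-12)

    def test_hitting_cdf_uses_symmetric_weight_total(self):
        p = TwoPathMDRParams(**self.PARAMS, r_1=0.8, r_2=0.8)
        s = p.cost(1)
        res = mdr_two_path_analysis(p, t=30.0, s=s)
        lam = p.lam
        mu = math.log(lam**2 / p.alpha) / lam + math.log(s / (2 * p.nu_1 * p.nu_2)) / lam
        assert res.mu == pytest.approx(mu, rel=1e-12)
        u = math.exp(lam * (30.0 - mu))
        expected = 1 - ((lam / p.alpha) / (1 + u) + p.beta / p.alpha)
        assert res.p_hit_by_t == pytest.approx(expected, rel=1e-12)

    def test_equal_lineage_rates_relative_probability_one(self):
        p = TwoPathMDRParams(**self.PARAMS, r_1=0.88, r_2=0.71)
        res = mdr_two_path_analysis(
            p, t=10.0, lineage_rates=((1e-9, 1e-9), (1e-9, 1e-9))
        )
        assert res.relative_probability == 1.0 and res.small_time_limit == 1.0

    def test_lineage_rate_ratio_and_validity_flag(self):
        p = TwoPathMDRParams(**self.PARAMS, r_1=0.88, r_2=0.71)
        hot, cold = (5e-9, 4e-9), (1e-9, 1e-9)
        res = mdr_two_path_analysis(p, t=5.0, lineage_rates=(hot, cold))
        assert res.small_time_limit == pytest.approx(20.0)
        assert res.limit_form_valid
        late = mdr_two_path_analysis(p, t=60.0, lineage_rates=(hot, cold))
        assert not late.limit_form_valid
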