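"""Constraint compilation: blending, guideline rules, acceptability, bioavailability."""

from __future__ import annotations

import numpy as np
import pytest

from dietopt.constraints import (
    AcceptabilityConfig,
    BioavailabilityParams,
    FbdgConfig,
    NutrientReference,
    added_fat_energy_constraint,
    apply_bioavailability,
    blend_reference_values,
    build_acceptability,
    build_fbdg_constraints,
    compile_constraints,
    default_fbdg_rules,
    energy_band,
    format_daily_bound,
    weekly_to_daily,
)
from dietopt.food_model import DietVector, diet_totals
from dietopt.synthetic_data import (
    default_bioavailable_lower,
    default_nutrient_references,
    generate_food_db,
)

from conftest import toy_db, toy_stats


class TestBlending:
    def test_identical_strata_pass_through(self):
        refs = {s: NutrientReference("calcium_mg", 950, 2500) for s in ("a", "b", "c")}
        out = blend_reference_values(refs, {"a": 0.5, "b": 0.25, "c": 0.25})
        assert out.lower == pytest.approx(950) and out.upper == pytest.approx(2500)

    def test_hand_blend(self):
        refs = {
            "male": NutrientReference("iron_mg", 10),
            "female_high_iron": NutrientReference("iron_mg", 16),
            "female_low_mod_iron": NutrientReference("iron_mg", 11),
        }
        weights = {"male": 0.5, "female_high_iron": 0.25, "female_low_mod_iron": 0.25}
        assert blend_reference_values(refs, weights).lower == pytest.approx(11.75)

    def test_single_stratum_weight_one(self):
        refs = {"m": NutrientReference("zinc_mg", 11), "f": NutrientReference("zinc_mg", 8)}
        out = blend_reference_values(refs, {"m": 1.0, "f": 0.0})
        assert out.lower == pytest.approx(11)

    def test_weights_must_sum_to_one(self):
        refs = {"m": NutrientReference("zinc_mg", 11), "f": NutrientReference("zinc_mg", 8)}
        with pytest.raises(ValueError, match="sum to 1"):
            blend_reference_values(refs, {"m": 0.6, "f": 0.5})


class TestEnergyBand:
    @pytest.mark.parametrize("eer, lo, hi", [
        (2000.0, 1840.0, 2160.0),
        (2580.0, 2373.6, 2786.4),
    ])
    def test_eight_percent_band(self, eer, lo, hi):
        db = toy_db([1.0], energy=[100.0])
        lower, upper = energy_band(eer, db)
        assert lower.rhs == pytest.approx(lo)
        assert upper.rhs == pytest.approx(hi)
        # relative symmetry: midpoint equals the requirement
        assert (lower.rhs + upper.rhs) / 2 == pytest.approx(eer)

    def test_nonpositive_requirement_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            energy_band(0.0, toy_db([1.0]))


class TestWeeklyToDaily:
    @pytest.mark.parametrize("weekly, decimals, printed", [
        (500.0, 1, 71.4),   # red meat
        (150.0, 1, 21.4),   # processed meat
        (400.0, 0, 57.0),   # pulses / wholegrains
        (200.0, 2, 28.57),  # total seafood
    ])
    def test_printed_daily_bounds(self, weekly, decimals, printed):
        assert format_daily_bound(weekly, decimals) == printed

    def test_exact_value_unrounded(self):
        assert weekly_to_daily(500.0) == pytest.approx(500.0 / 7.0, rel=1e-15)
        assert weekly_to_daily(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            weekly_to_daily(-1.0)


@pytest.fixture(scope="module")
def db47():
    return generate_food_db()


class TestFbdgRules:
    def test_red_meat_rule_caps_tagged_groups(self, db47):
        cons = build_fbdg_constraints(default_fbdg_rules(), db47)
        red = next(c for c in cons if c.label == "red_meat_max")
        assert red.sense == "<=" and red.rhs == pytest.approx(500.0 / 7.0)
        g = db47.n_groups
        mask = db47.tag_mask("is_red_meat")
        assert np.array_equal(red.coeffs[:g] != 0, mask)
        assert np.array_equal(red.coeffs[g:] != 0, mask)

    def test_sweet_drinks_zero_equality(self, db47):
        cons = build_fbdg_constraints(default_fbdg_rules(), db47)
        zero = next(c for c in cons if c.label == "sweet_drinks_zero")
        assert zero.sense == "==" and zero.rhs == 0.0

    def test_fruit_veg_floor_credits_juice_up_to_one_portion(self, db47):
        # veg 300 + fruit 80 + juice 200 (credited at most 150) = 530 >= 400
        cons = build_fbdg_constraints(default_fbdg_rules(), db47)
        with_juice = next(c for c in cons if c.label == "fruit_veg_min_with_juice")
        capped = next(c for c in cons if c.label == "fruit_veg_min_juice_capped")
        totals = np.zeros(db47.n_groups)
        totals[db47.group_index("fruiting_vegetables")] = 300.0
        totals[db47.group_index("temperate_fruit")] = 80.0
        totals[db47.group_index("fruit_juice")] = 200.0
        x = DietVector.from_totals(totals).stacked()
        assert with_juice.residual(x) <= 0  # 580 >= 400
        assert capped.residual(x) <= 0  # 380 >= 400 - 150
        # without the juice, the credit-capped side fails the floor
        totals[db47.group_index("fruiting_vegetables")] = 100.0
        x = DietVector.from_totals(totals).stacked()
        assert capped.residual(x) > 0

    def test_dairy_portion_equality_counts_portions(self, db47):
        cons = build_fbdg_constraints(default_fbdg_rules(), db47)
        dairy = next(c for c in cons if c.label == "dairy_portions")
        totals = np.zeros(db47.n_groups)
        totals[db47.group_index("cheese")] = 30.0  # one portion
        totals[db47.group_index("yogurt")] = 125.0  # one portion
        x = DietVector.from_totals(totals).stacked()
        assert dairy.value(x) == pytest.approx(2.0)
        assert dairy.residual(x) == pytest.approx(0.0, abs=1e-12)

    def test_added_fat_linearization_matches_ratio_oracle(self):
        db = toy_db([1.0, 1.0], energy=[900.0, 100.0],
                    tags={0: ("is_added_fat",)})
        con = added_fat_energy_constraint(db, frac_max=0.16)
        rng = np.random.default_rng(3)
        for _ in range(50):
            diet = DietVector(rng.uniform(0, 50, 2), rng.uniform(0, 50, 2))
            x = diet.stacked()
            totals = diet_totals(diet, db)
            fat_energy = 9.0 * (diet.q_conv[0] + diet.q_org[0])
            if totals.energy_kcal == 0:
                continue
            true_ok = fat_energy / totals.energy_kcal <= 0.16 + 1e-12
            linear_ok = con.residual(x) <= 1e-9
            assert true_ok == linear_ok

    def test_boundary_diet_makes_added_fat_active(self):
        db = toy_db([1.0, 1.0], energy=[800.0, 100.0], tags={0: ("is_added_fat",)})
        con = added_fat_energy_constraint(db, frac_max=0.16)
        # fat energy share exactly 16%: 8q = 0.16 (8q + r) -> r = 42 q
        diet = DietVector([10.0, 420.0], [0.0, 0.0])
        assert con.residual(diet.stacked()) == pytest.approx(0.0, abs=1e-9)


class TestAcceptability:
    def test_exempt_group_gets_no_cap(self, db47):
        stats = toy_stats(np.full(47, 50.0), np.full(47, 10.0))
        pulses = int(np.flatnonzero(db47.tag_mask("is_pulse"))[0])
        cons = build_acceptability(stats, "p99", exempt=[pulses], db=db47)
        g = db47.n_groups
        assert all(c.coeffs[pulses] == 0 and c.coeffs[g + pulses] == 0 for c in cons)

    def test_per_group_cap_at_percentile(self):
        stats = toy_stats([50.0, 80.0], [5.0, 5.0], p99=[120.0, 300.0])
        cons = build_acceptability(stats, "p99")
        assert cons[0].rhs == pytest.approx(120.0) and cons[0].sense == "<="

    def test_coupled_groups_share_one_cap_on_the_sum(self):
        stats = toy_stats([50.0, 80.0, 10.0], [5.0] * 3, p99=[120.0, 300.0, 40.0])
        stats.coupling_caps[(0, 1)] = {"p95": 330.0, "p99": 350.0}
        cons = build_acceptability(stats, "p99", coupling=[(0, 1)])
        coupled = [c for c in cons if c.provenance == "coupling"]
        assert len(coupled) == 1 and coupled[0].rhs == pytest.approx(350.0)
        # a diet exceeding group 0's own P99 is allowed while the sum fits
        x = DietVector.from_totals([200.0, 100.0, 0.0]).stacked()
        assert coupled[0].residual(x) <= 0

    def test_coupling_overlapping_exemption_rejected(self):
        stats = toy_stats([50.0, 80.0], [5.0, 5.0])
        with pytest.raises(ValueError, match="overlap"):
            build_acceptability(stats, "p99", coupling=[(0, 1)], exempt=[0])


class TestBioavailability:
    def test_zero_intake_zero_available(self, db47):
        diet = DietVector(np.zeros(47), np.zeros(47))
        iron, zinc = apply_bioavailability("parametric", diet, db47)
        assert iron == 0.0 and zinc == 0.0

    def test_constant_model_is_a_product(self, db47):
        totals = np.zeros(47)
        totals[db47.group_index("pulses")] = 500.0
        diet = DietVector.from_totals(totals)
        params = BioavailabilityParams(iron_base=0.1)
        iron, _ = apply_bioavailability("constant", diet, db47, params)
        intake = diet_totals(diet, db47).nutrients["iron_mg"]
        assert iron == pytest.approx(0.1 * intake)

    def test_monotone_in_intake_at_fixed_composition(self, db47):
        base = np.zeros(47)
        base[db47.group_index("pulses")] = 100.0
        base[db47.group_index("beef")] = 30.0
        values = []
        for scale in np.linspace(0.5, 4.0, 12):
            diet = DietVector.from_totals(base * scale)
            values.append(apply_bioavailability("parametric", diet, db47)[0])
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_unregistered_model_rejected(self, db47):
        with pytest.raises(KeyError, match="unregistered"):
            apply_bioavailability("nope", DietVector(np.zeros(47), np.zeros(47)), db47)


class TestCompiledSet:
    def test_every_constraint_is_linear_and_labelled(self, db47, scenario):
        cs = scenario.constraints
        assert len(cs) > 20
        for con in cs:
            assert con.coeffs.shape == (2 * 47,)
            assert np.any(con.coeffs != 0)
        audit = cs.audit_table()
        assert set(audit.columns) == {"label", "sense", "rhs", "unit", "provenance"}
        assert audit["provenance"].isin(
            ["nutrient", "energy", "fbdg", "acceptability", "coupling"]).all()

    def test_unmatched_tag_fails_compilation(self):
        db = toy_db([1.0, 2.0])  # no tags at all
        stats = toy_stats([50.0, 80.0], [5.0, 5.0])
        with pytest.raises(ValueError, match="match no food group|no group tagged"):
            compile_constraints(db, stats, nutrient_refs=[],
                                fbdg=FbdgConfig(), acceptability=AcceptabilityConfig())
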