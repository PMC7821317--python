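import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opsel.reproduction import (
    GroupFitness,
    MatingGroup,
    ReproductionParams,
    contest_share,
    female_fecundity,
    fertilized_fraction,
    group_reproduction,
)

conditions = st.floats(0.0, 5.0, allow_nan=False)
pos_conditions = st.floats(0.01, 5.0, allow_nan=False)


class TestContestShare:
    @pytest.mark.parametrize(
        "cf,cr,g,expected",
        [
            (1, 1, 2, 0.5),        # symmetry
            (2, 1, 2, 0.8),        # 2^2/(2^2+1^2)
            (0.3, 1.7, 0, 0.5),    # g=0 removes condition dependence
            (0, 0, 2, 0.5),        # defined tie at the origin
            (0, 1, 2, 0.0),        # zero-condition focal loses
            (1, 0, 2, 1.0),
        ],
    )
    def test_known_values(self, cf, cr, g, expected):
        assert contest_share(cf, cr, g) == pytest.approx(expected, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            contest_share(-1, 1, 2)
        with pytest.raises(ValueError):
            contest_share(1, 1, -2)

    @given(a=pos_conditions, b=pos_conditions, g=st.floats(0, 10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_shares_sum_to_one(self, a, b, g):
        assert contest_share(a, b, g) + contest_share(b, a, g) == pytest.approx(1.0)

    def test_winner_take_all_limit(self):
        # 10% condition advantage at very large g decides the contest
        assert contest_share(1.1, 1.0, 200) == pytest.approx(1.0, abs=1e-6)
        assert contest_share(1.0, 1.1, 200) == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_focal_condition(self):
        shares = [contest_share(c, 1.0, 2) for c in (0.5, 1.0, 1.5, 2.0)]
        assert shares == sorted(shares)


class TestFemaleFecundity:
    def test_baseline_is_condition(self):
        assert female_fecundity(0.8, (1.0, 1.0), ReproductionParams()) == 0.8

    def test_zero_gift_coefficient_recovers_baseline(self):
        p = ReproductionParams(nuptial_gift=True, gift=0.0)
        assert female_fecundity(1.0, (2.0, 0.5), p) == 1.0

    def test_harm_halves_fecundity_at_mean_male_condition_one(self):
        p = ReproductionParams(male_harm=True, harm=0.5)
        assert female_fecundity(1.0, (1.0, 1.0), p) == pytest.approx(0.5)

    def test_harm_is_floored_at_zero(self):
        p = ReproductionParams(male_harm=True, harm=2.0)
        assert female_fecundity(1.0, (3.0, 3.0), p) == 0.0

    def test_gift_raises_fecundity(self):
        p = ReproductionParams(nuptial_gift=True, gift=0.3)
        assert female_fecundity(1.0, (1.0, 1.0), p) == pytest.approx(1.3)


class TestFertilizedFraction:
    def test_baseline_sperm_never_limiting(self):
        assert fertilized_fraction(0.1, 0.1, ReproductionParams()) == 1.0

    def test_sperm_limitation_linear_below_cap(self):
        p = ReproductionParams(sperm_limitation=True, mc=0.5)
        assert fertilized_fraction(1.0, 1.0, p) == pytest.approx(0.5)

    def test_sperm_limitation_saturates_at_one(self):
        p = ReproductionParams(sperm_limitation=True, mc=10.0)
        assert fertilized_fraction(1.0, 1.0, p) == 1.0

    def test_mc_required_positive_when_flag_on(self):
        with pytest.raises(ValueError):
            ReproductionParams(sperm_limitation=True, mc=0.0)


def random_params(draw_variants, rng):
    flags = {
        "female_competition": bool(rng.integers(2)) and draw_variants,
        "sperm_limitation": bool(rng.integers(2)) and draw_variants,
        "male_harm": bool(rng.integers(2)) and draw_variants,
        "nuptial_gift": bool(rng.integers(2)) and draw_variants,
    }
    return ReproductionParams(
        g_m=float(rng.uniform(0, 5)),
        g_f=float(rng.uniform(0, 5)),
        mc=float(rng.uniform(0.1, 3)),
        harm=float(rng.uniform(0, 1)),
        gift=float(rng.uniform(0, 1)),
        **flags,
    )


class TestGroupReproduction:
    def test_symmetric_group_all_fitness_one(self):
        fit = group_reproduction(MatingGroup(1, 1, 1, 1), ReproductionParams(g_m=2))
        assert (fit.wf1, fit.wf2, fit.wm1, fit.wm2) == (1.0, 1.0, 1.0, 1.0)

    def test_male_contest_splits_total_female_fitness(self):
        fit = group_reproduction(MatingGroup(1, 1, 2, 1), ReproductionParams(g_m=2))
        assert (fit.wf1, fit.wf2) == (1.0, 1.0)
        assert fit.wm1 == pytest.approx(1.6)
        assert fit.wm2 == pytest.approx(0.4)

    def test_baseline_female_fitness_independent_of_males(self, rng):
        """With flags off, female fitness equals fecundity regardless of males."""
        for _ in range(50):
            cf1, cf2 = rng.uniform(0, 3, 2)
            cm_a = rng.uniform(0, 3, 2)
            cm_b = rng.uniform(0, 3, 2)
            fa = group_reproduction(MatingGroup(cf1, cf2, *cm_a), ReproductionParams())
            fb = group_reproduction(MatingGroup(cf1, cf2, *cm_b), ReproductionParams())
            assert (fa.wf1, fa.wf2) == (fb.wf1, fb.wf2) == (cf1, cf2)

    def test_conservation_across_all_variants(self, rng):
        """Total male fitness equals total female fitness in every variant."""
        for _ in range(500):
            params = random_params(draw_variants=True, rng=rng)
            g = MatingGroup(*rng.uniform(0, 3, 4))
            fit = group_reproduction(g, params)
            assert fit.wm1 + fit.wm2 == pytest.approx(fit.wf1 + fit.wf2, abs=1e-12)

    def test_g_zero_gives_even_split(self):
        fit = group_reproduction(MatingGroup(1.0, 0.5, 2.5, 0.1), ReproductionParams(g_m=0))
        assert fit.wm1 == pytest.approx(fit.wm2)

    def test_female_competition_with_gf_one_is_baseline(self, rng):
        """Linear fecundity already splits the pool by condition, so g_f=1
        female competition reproduces the baseline exactly."""
        for _ in range(100):
            g = MatingGroup(*rng.uniform(0.01, 3, 4))
            base = group_reproduction(g, ReproductionParams())
            comp = group_reproduction(
                g, ReproductionParams(female_competition=True, g_f=1.0)
            )
            assert comp.wf1 == pytest.approx(base.wf1, rel=1e-12)
            assert comp.wf2 == pytest.approx(base.wf2, rel=1e-12)
            assert comp.wm1 == pytest.approx(base.wm1, rel=1e-12)

    def test_variant_coefficients_at_zero_recover_baseline(self, rng):
        neutral = ReproductionParams(
            nuptial_gift=True, gift=0.0, male_harm=True, harm=0.0,
            sperm_limitation=True, mc=1000.0,
        )
        for _ in range(100):
            g = MatingGroup(*rng.uniform(0.01, 3, 4))
            base = group_reproduction(g, ReproductionParams())
            var = group_reproduction(g, neutral)
            assert var == base


class TestParamsSerialization:
    def test_round_trip(self):
        p = ReproductionParams(g_m=3.0, male_harm=True, harm=0.2)
        assert ReproductionParams.from_dict(p.to_dict()) == p

    def test_defaults_are_baseline_with_gm_two(self):
        p = ReproductionParams()
        assert p.g_m == 2.0
        assert not any(
            [p.female_competition, p.sperm_limitation, p.male_harm, p.nuptial_gift]
        )
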