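"""Feeding-cycle fitness components and the one-generation recursion.

Frozen expected values were computed with an independent transcription
of the closed-form expressions (direct substitution, and a truncated
geometric series for the repeat-search success probability).
"""

import math

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from itnevo import (
    AlleleFrequencies,
    FitnessTable,
    Genotype,
    ModelParameters,
    PopulationExtinctError,
    Sex,
    build_fitness_table,
    expected_lifespan,
    female_fitness,
    male_fitness,
    mean_fitness,
    next_allele_frequencies,
)
from itnevo.fitness import (
    genotype_frequencies_after_selection,
    gonotrophic_cycle_survival,
    insecticide_survival,
    larval_survival,
    lifetime_feeding_success,
    single_attempt_success,
)

GENOTYPES = (Genotype.SS, Genotype.RS, Genotype.RR)


def table_for(w_ss, w_rs, w_rr):
    """Fitness table with identical male and female entries."""
    return FitnessTable(
        {
            (sex, g): w
            for sex in Sex
            for g, w in zip(GENOTYPES, (w_ss, w_rs, w_rr))
        }
    )


# Parameter sets in realistic ranges; constrained away from the
# divergent corners (per-cycle survival 1, repeat-search ratio 1).
params_strategy = st.builds(
    ModelParameters,
    phi=st.floats(0.0, 1.0),
    psi=st.floats(0.0, 1.0),
    Q=st.floats(0.0, 1.0),
    r=st.floats(0.0, 1.0),
    s=st.floats(0.0, 0.5),
    sigma=st.floats(0.5, 0.99),
    mu=st.floats(0.01, 0.3),
    gt=st.floats(1.0, 5.0),
    mu_r=st.floats(0.0, 0.1),
    h=st.floats(0.0, 1.0),
    rho=st.floats(0.0, 1.0),
    Z=st.floats(0.0, 0.5),
).filter(lambda p: p.Q * p.phi * p.r * (1 - p.mu_r) < 0.999)


class TestSurvivalComponents:
    @pytest.mark.parametrize(
        "genotype,changes,expected",
        [
            (Genotype.SS, {}, 0.16),  # sensitive survival is s itself
            (Genotype.RS, {"h": 0.0}, 0.16),  # zero dominance collapses RS to SS
            (Genotype.RR, {}, 0.958),  # s + rho*(1-s) = 0.16 + 0.95*0.84
        ],
    )
    def test_insecticide_survival(self, genotype, changes, expected):
        p = ModelParameters(**changes)
        assert insecticide_survival(genotype, p) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "genotype,changes,expected",
        [
            (Genotype.RR, {"psi": 0.0}, 1.0),  # unexposed larvae all survive
            (Genotype.SS, {"psi": 0.25}, 0.75),
            (Genotype.RS, {"psi": 0.2}, 0.8475),  # 1 - 0.2*(1 - 0.25*0.95)
        ],
    )
    def test_larval_survival(self, genotype, changes, expected):
        p = ModelParameters(**changes)
        assert larval_survival(genotype, p) == pytest.approx(expected)


class TestFeedingCycle:
    def test_single_attempt_reduces_to_sigma_without_net_contact(self):
        # No ITNs, or all feeds on animals: only feeding risk remains.
        for changes in ({"phi": 0.0}, {"Q": 0.0, "phi": 0.7}):
            p = ModelParameters(**changes)
            assert single_attempt_success(p, 0.16) == pytest.approx(p.sigma)

    def test_single_attempt_at_typical_values(self):
        p = ModelParameters(phi=0.7)
        # 0.9 * (1 - 0.49 * (1 - 0.3*0.16))
        assert single_attempt_success(p, 0.16) == pytest.approx(0.480168)

    def test_lifetime_success_equals_single_attempt_without_repellency(self):
        p = ModelParameters(phi=0.7, r=0.0)
        assert lifetime_feeding_success(p, 0.16) == pytest.approx(
            single_attempt_success(p, 0.16), rel=1e-15
        )

    def test_lifetime_success_closed_form(self):
        p = ModelParameters(phi=0.7)
        assert lifetime_feeding_success(p, 0.16) == pytest.approx(
            0.7195791934541204, rel=1e-12
        )

    @settings(max_examples=200, deadline=None)
    @given(params=params_strategy, surv=st.floats(0.0, 1.0))
    def test_closed_form_matches_truncated_series(self, params, surv):
        """The geometric-series closed form equals the explicit partial
        sum over repeat host searches."""
        ratio = params.Q * params.phi * params.r * (1 - params.mu_r)
        # Truncation at n=200 only resolves the limit when the tail is
        # below the comparison tolerance.
        assume(ratio < 0.85)
        xi = single_attempt_success(params, surv)
        partial = sum(xi * ratio**n for n in range(201))
        assert lifetime_feeding_success(params, surv) == pytest.approx(
            partial, abs=1e-10
        )

    def test_cycle_survival(self):
        p = ModelParameters(phi=0.7, mu_gt=0.27)
        assert gonotrophic_cycle_survival(p, 0.16) == pytest.approx(
            0.5252928112215078, rel=1e-12
        )
        assert gonotrophic_cycle_survival(p.replace(mu_gt=1.0), 0.16) == 0.0
        p0 = ModelParameters(phi=0.0, r=0.0, mu_gt=0.0)
        assert gonotrophic_cycle_survival(p0, 0.16) == pytest.approx(p0.sigma)


class TestExpectedLifespan:
    def test_typical_values(self, printed):
        p = printed.replace(phi=0.7)
        assert expected_lifespan(Genotype.SS, p) == pytest.approx(2.1065617366637777)
        assert expected_lifespan(Genotype.RR, p) == pytest.approx(2.783885967384917)

    def test_genotype_independent_without_nets(self, printed):
        p = printed.replace(phi=0.0)
        spans = [expected_lifespan(g, p) for g in GENOTYPES]
        assert spans[0] == pytest.approx(2.915451895043732)
        assert spans[0] == spans[1] == spans[2]

    def test_full_repellency_equalizes_lifespans(self, defaults):
        # r=1 removes every insecticide encounter, so survival no longer
        # depends on the resistance genotype.
        p = defaults.replace(r=1.0, phi=0.8, psi=0.0)
        spans = [expected_lifespan(g, p) for g in GENOTYPES]
        assert abs(spans[0] - spans[1]) < 1e-12
        assert abs(spans[1] - spans[2]) < 1e-12

    @pytest.mark.parametrize("phi_grid", [[i / 10 for i in range(11)]])
    def test_resistant_lifespan_ordering_under_nets(self, defaults, phi_grid):
        # With rho > 0 resistance can only help an adult female:
        # L_RR >= L_RS >= L_SS across the whole coverage range.
        for phi in phi_grid:
            p = defaults.replace(phi=phi)
            l_ss, l_rs, l_rr = (expected_lifespan(g, p) for g in GENOTYPES)
            assert l_rr >= l_rs >= l_ss

    def test_lifespan_decreases_with_coverage(self, defaults):
        spans = [
            expected_lifespan(Genotype.SS, defaults.replace(phi=phi))
            for phi in (0.0, 0.3, 0.6, 0.9)
        ]
        assert all(a > b for a, b in zip(spans, spans[1:]))


class TestFitnesses:
    @pytest.mark.parametrize(
        "genotype,changes,expected",
        [
            (Genotype.SS, {"psi": 0.0}, 1.0),
            (Genotype.RR, {"psi": 0.0}, 0.9),  # only the cost Z remains
            (Genotype.RS, {"psi": 0.2}, 0.8263125),  # 0.8475 * 0.975
        ],
    )
    def test_male_fitness(self, genotype, changes, expected):
        assert male_fitness(genotype, ModelParameters(**changes)) == pytest.approx(
            expected
        )

    def test_female_fitness_typical(self, printed):
        p = printed.replace(phi=0.7, psi=0.0)
        # kappa * lifespan = 100 * 2.1066
        assert female_fitness(Genotype.SS, p) == pytest.approx(210.65617366637775)

    def test_neutral_alleles_give_equal_fitness(self, defaults):
        p = defaults.replace(rho=0.0, Z=0.0, psi=0.0, phi=0.6)
        for sex_fn in (male_fitness, female_fitness):
            values = [sex_fn(g, p) for g in GENOTYPES]
            assert values[0] == pytest.approx(values[1]) == pytest.approx(values[2])

    def test_total_larval_kill_zeroes_fitness(self, defaults):
        p = defaults.replace(psi=1.0, rho=0.0)
        assert female_fitness(Genotype.RR, p) == 0.0

    def test_table_typical_ratio(self, printed):
        table = build_fitness_table(printed.replace(phi=0.7, psi=0.0))
        ratio = table[Sex.FEMALE, Genotype.RR] / table[Sex.FEMALE, Genotype.SS]
        assert ratio == pytest.approx(1.189377613311468, rel=1e-12)

    def test_table_full_repellency_differs_only_by_cost(self, defaults):
        table = build_fitness_table(defaults.replace(r=1.0, psi=0.0, phi=0.8))
        w_f = [table[Sex.FEMALE, g] for g in GENOTYPES]
        # Lifespans equal, so female entries scale as 1 : 1-hZ : 1-Z.
        assert w_f[1] / w_f[0] == pytest.approx(1 - 0.25 * 0.1, rel=1e-12)
        assert w_f[2] / w_f[0] == pytest.approx(1 - 0.1, rel=1e-12)


class TestSelectionRecursion:
    def test_mean_fitness_is_convex_combination(self):
        table = table_for(1.0, 1.0, 1.0)
        freqs = AlleleFrequencies(0.3, 0.8)
        assert mean_fitness(table, freqs, Sex.MALE) == pytest.approx(1.0)
        assert mean_fitness(table_for(5, 3, 2), AlleleFrequencies(0, 0), Sex.FEMALE) == 5

    def test_mean_fitness_weighted_example(self):
        table = table_for(1.0, 2.0, 4.0)
        # 4*0.25 + 2*0.5 + 1*0.25
        assert mean_fitness(table, AlleleFrequencies(0.5, 0.5), Sex.MALE) == pytest.approx(2.25)

    def test_genotype_proportions_hardy_weinberg_when_neutral(self):
        props = genotype_frequencies_after_selection(
            table_for(1, 1, 1), AlleleFrequencies(0.5, 0.5), Sex.MALE
        )
        assert props == pytest.approx((0.25, 0.5, 0.25))

    def test_genotype_proportions_fixed_population(self):
        props = genotype_frequencies_after_selection(
            table_for(1, 1, 1), AlleleFrequencies(1.0, 1.0), Sex.FEMALE
        )
        assert props == pytest.approx((0.0, 0.0, 1.0))

    def test_genotype_proportions_weighted_example(self):
        props = genotype_frequencies_after_selection(
            table_for(1.0, 2.0, 4.0), AlleleFrequencies(0.5, 0.5), Sex.MALE
        )
        assert props == pytest.approx((1 / 9, 4 / 9, 4 / 9))
        assert sum(props) == pytest.approx(1.0, abs=1e-12)

    def test_extinct_population_raises(self):
        with pytest.raises(PopulationExtinctError):
            genotype_frequencies_after_selection(
                table_for(0.0, 0.0, 0.0), AlleleFrequencies(0.5, 0.5), Sex.MALE
            )
        with pytest.raises(PopulationExtinctError):
            next_allele_frequencies(table_for(0, 0, 0), AlleleFrequencies(0.5, 0.5))

    def test_boundaries_absorb(self):
        table = table_for(1.0, 0.9, 2.0)
        for p in (0.0, 1.0):
            nxt = next_allele_frequencies(table, AlleleFrequencies(p, p))
            assert (nxt.p_m, nxt.p_f) == (p, p)

    def test_neutral_recursion_averages_the_sexes(self):
        table = table_for(3.0, 3.0, 3.0)
        nxt = next_allele_frequencies(table, AlleleFrequencies(0.2, 0.6))
        assert nxt.p_m == pytest.approx(0.4, abs=1e-15)
        assert nxt.p_f == pytest.approx(0.4, abs=1e-15)

    @settings(max_examples=200, deadline=None)
    @given(
        params=params_strategy,
        p_m=st.floats(0.0, 1.0),
        p_f=st.floats(0.0, 1.0),
    )
    def test_neutrality_preserves_mean_frequency(self, params, p_m, p_f):
        """With rho = Z = 0 selection cannot distinguish genotypes, so
        the sex-averaged allele frequency is invariant for any phi, psi."""
        neutral = params.replace(rho=0.0, Z=0.0)
        assume(neutral.psi < 1.0)  # psi=1 kills every larva regardless
        table = build_fitness_table(neutral)
        freqs = AlleleFrequencies(p_m, p_f)
        nxt = next_allele_frequencies(table, freqs)
        assert nxt.mean == pytest.approx(freqs.mean, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        params=params_strategy,
        p_m=st.floats(0.0, 1.0),
        p_f=st.floats(0.0, 1.0),
    )
    def test_frequencies_stay_in_unit_interval(self, params, p_m, p_f):
        assume(params.psi < 1.0 or params.rho > 0.0)
        table = build_fitness_table(params)
        freqs = AlleleFrequencies(p_m, p_f)
        try:
            nxt = next_allele_frequencies(table, freqs)
        except PopulationExtinctError:
            return
        assert 0.0 <= nxt.p_m <= 1.0
        assert 0.0 <= nxt.p_f <= 1.0
        props = genotype_frequencies_after_selection(table, freqs, Sex.FEMALE)
        assert sum(props) == pytest.approx(1.0, abs=1e-12)
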