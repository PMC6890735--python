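import numpy as np
import pytest

from lampsim import (
    GrowthParams, ModelParams, Pool, SystemState,
    advance_ages, body_length, draw_growth_parameter, mature_juveniles,
    transform_larvae, transformation_age_days, initialize_population,
)
from lampsim.demography import Individual, LAKE


def make_pool(age_days, k, alleles=None, sex=None, natal=None):
    n = len(age_days)
    return Pool(
        np.asarray(age_days), np.asarray(k, float),
        np.zeros(n) if alleles is None else np.asarray(alleles),
        np.zeros(n) if sex is None else np.asarray(sex),
        np.zeros(n) if natal is None else np.asarray(natal),
    )


class TestBodyLength:
    def test_direct_evaluation(self):
        # three-year-old larva with the mean growth coefficient
        assert body_length(0.001, 1095, 150.0, -15.0) == pytest.approx(100.57, abs=0.01)

    def test_zero_at_t0(self):
        assert body_length(0.001, -15.0, 150.0, -15.0) == 0.0

    def test_asymptote_and_monotonicity(self):
        ages = np.array([0, 1000, 10000, 1e7])
        lengths = body_length(0.001, ages, 150.0, -15.0)
        assert np.all(np.diff(lengths) > 0)
        assert lengths[-1] == pytest.approx(150.0)
        assert np.all(lengths <= 150.0)

    def test_transformation_age_inverts_length(self):
        g = GrowthParams()
        for k in (0.0007, 0.001, 0.002):
            age = transformation_age_days(k, g, 120.0)
            assert body_length(k, age, g.L_inf_larva, g.t0) == pytest.approx(120.0)


class TestGrowthParameterDraws:
    def test_degenerate_spread_returns_mean_exactly(self, rng):
        g = GrowthParams(k_spread=0.0)
        draws = draw_growth_parameter(rng, g, size=100)
        assert np.all(draws == 0.001)

    def test_sd_interpretation_sample_mean(self, rng):
        g = GrowthParams(k_spread=0.0002, spread_is="sd", transform_window_years=None)
        draws = draw_growth_parameter(rng, g, size=100_000)
        se = 0.0002 / np.sqrt(100_000)
        assert abs(draws.mean() - 0.001) < 3 * se

    def test_sd_interpretation_three_sigma_coverage(self, rng):
        g = GrowthParams(k_spread=0.0002, spread_is="sd", transform_window_years=None)
        draws = draw_growth_parameter(rng, g, size=50_000)
        inside = np.mean((draws > 0.0004) & (draws < 0.0016))
        assert inside >= 0.99

    def test_all_draws_positive_even_with_wide_spread(self, rng):
        g = GrowthParams(transform_window_years=None)  # literal variance, untruncated
        draws = draw_growth_parameter(rng, g, size=20_000)
        assert np.all(draws > 0)

    def test_default_window_puts_transformation_in_two_to_seven_years(self, rng):
        g = GrowthParams()
        draws = draw_growth_parameter(rng, g, size=20_000)
        ages_years = transformation_age_days(draws, g, 120.0) / 365.0
        assert ages_years.min() >= 2.0 - 1e-9
        assert ages_years.max() <= 7.0 + 1e-9

    def test_scalar_draw(self, rng):
        k = draw_growth_parameter(rng, GrowthParams())
        assert isinstance(k, float) and k > 0


class TestStageTransitions:
    def _state(self, params, larvae_by_trib, lake=None):
        tribs = [make_pool(*ages_k) for ages_k in larvae_by_trib]
        return SystemState(year=1, tributaries=tribs,
                           lake=lake if lake is not None else Pool.empty())

    def test_advance_ages_adds_one_year_everywhere(self, small_params):
        state = self._state(small_params, [([730], [0.001])] * small_params.n_tributaries)
        before = state.total_individuals()
        advance_ages(state)
        assert state.tributaries[0].age_days[0] == 1095
        assert state.total_individuals() == before

    def test_advance_empty_state_is_noop(self, small_params):
        state = self._state(small_params, [([], [])] * small_params.n_tributaries)
        advance_ages(state)
        assert state.total_individuals() == 0

    def test_larva_at_threshold_transforms(self):
        params = ModelParams()
        # transformation age for k=0.001 is ~1594.4 d; 1595 is past it
        state = self._state(params, [([1595, 1095], [0.001, 0.001])]
                            + [([], [])] * (params.n_tributaries - 1))
        transform_larvae(state, params)
        assert len(state.lake) == 1
        assert len(state.tributaries[0]) == 1
        assert state.tributaries[0].age_days[0] == 1095  # 100.6 mm stays a larva

    def test_no_larva_above_threshold_remains(self, rng):
        params = ModelParams()
        g = params.growth
        k = draw_growth_parameter(rng, g, size=400)
        ages = rng.integers(0, 9 * 365, 400)
        state = self._state(params, [(ages, k)] + [([], [])] * (params.n_tributaries - 1))
        transform_larvae(state, params)
        remaining = state.tributaries[0]
        lengths = body_length(remaining.k, remaining.age_days, g.L_inf_larva, g.t0)
        assert np.all(lengths < params.transform_length_mm)
        assert len(remaining) + len(state.lake) == 400

    def test_fresh_transformers_do_not_mature_same_year(self):
        params = ModelParams()
        state = self._state(params, [([1700], [0.001])]
                            + [([], [])] * (params.n_tributaries - 1))
        transform_larvae(state, params)
        assert state.fresh_juveniles == 1
        mature_juveniles(state, params)
        assert len(state.adults_staged) == 0
        assert len(state.lake) == 1

    def test_juvenile_matures_one_year_after_transformation(self):
        # transformed last year at ~120 mm larval scale -> 640 mm juvenile scale
        params = ModelParams()
        lake = make_pool([1595 + 365], [0.001])
        state = self._state(params, [([], [])] * params.n_tributaries, lake=lake)
        mature_juveniles(state, params)
        assert len(state.adults_staged) == 1
        assert len(state.lake) == 0

    def test_short_juvenile_stays(self):
        # a young juvenile below 450 mm on the juvenile curve stays in the lake
        params = ModelParams()
        lake = make_pool([400], [0.001])  # ~270 mm juvenile scale
        state = self._state(params, [([], [])] * params.n_tributaries, lake=lake)
        mature_juveniles(state, params)
        assert len(state.adults_staged) == 0
        assert len(state.lake) == 1


def test_initialize_population_counts_and_genotypes(rng):
    params = ModelParams()
    state = initialize_population(params, rng)
    assert state.n_tributaries == 20
    assert all(len(p) == 1200 for p in state.tributaries)
    assert len(state.lake) == 8000
    assert state.total_individuals() == 32_000
    assert all(int((p.alleles != 0).sum()) == 0 for p in state.tributaries)
    assert int((state.lake.alleles != 0).sum()) == 0
    # 50:50 sex ratio within 3 binomial sigma
    males = sum(int(p.sex.sum()) for p in state.tributaries) + int(state.lake.sex.sum())
    n = 32_000
    assert abs(males - n / 2) < 3 * np.sqrt(n * 0.25)


def test_individual_record_validation():
    with pytest.raises(ValueError):
        Individual(0, 0, 100, 0.001, "larva", 3, 0, 0)
    with pytest.raises(ValueError):
        Individual(0, 0, 100, -0.001, "larva", 0, 0, 0)
    with pytest.raises(ValueError):
        Individual(0, 0, 100, 0.001, "juvenile", 0, 0, 5)  # juveniles live in the lake
    ind = Individual(7, 1, 365, 0.001, "juvenile", 1, 3, LAKE)
    pool = Pool.from_individuals([ind])
    back = pool.to_individuals("juvenile", LAKE, start_id=7)[0]
    assert back == ind
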