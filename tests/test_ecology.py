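import numpy as np
import pytest

from pestevol import SimConfig, expected_covariance
from pestevol.ecology import (
    SEX_FEMALE,
    SEX_MALE,
    _draw_pests,
    feed_step,
    immigration_step,
    metabolism_step,
    mortality_step,
    movement_step,
    pesticide_step,
    reproduction_step,
    run_time_step,
)

from conftest import make_state


def base_cfg(**over) -> SimConfig:
    """A quiet 4x4 world: nothing happens unless a test switches it on."""
    defaults = dict(
        repro="asexual",
        reproduction_type="lambda",
        lambda_value=0.0,
        xdim=4,
        ydim=4,
        farms=1,
        crop_number=1,
        crop_per_cell=4.0,
        food_consume=1.0,
        pesticide_consume=0.0,
        pesticide_per_cell=0.0,
        max_age=50,
        move_distance=0,
        N0=1,
        time_steps=1,
        land_edge="torus",
    )
    defaults.update(over)
    return SimConfig(**defaults)


class TestInitPopulation:
    def test_fresh_pests_have_age_zero(self, identity_network):
        state = make_state(base_cfg(N0=40), identity_network)
        assert np.all(state.pop.age == 0)

    def test_rand_age_uniform_over_lifespan(self, identity_network):
        cfg = base_cfg(N0=5000, rand_age=True, max_age=4)
        state = make_state(cfg, identity_network, seed=1)
        counts = np.bincount(state.pop.age, minlength=5)
        np.testing.assert_allclose(counts / 5000, np.full(5, 0.2), atol=0.03)

    def test_positions_within_grid(self, identity_network):
        state = make_state(base_cfg(N0=200, xdim=6, ydim=3), identity_network)
        assert np.all((state.pop.x >= 0) & (state.pop.x < 6))
        assert np.all((state.pop.y >= 0) & (state.pop.y < 3))

    def test_biparental_sexes_are_even(self, identity_network):
        cfg = base_cfg(N0=4000, repro="biparental")
        state = make_state(cfg, identity_network, seed=2)
        frac_f = np.mean(state.pop.sex == SEX_FEMALE)
        assert abs(frac_f - 0.5) < 0.03
        assert state.pop.ploidy == 2

    def test_bound_trait_index_out_of_range_rejected(self, identity_network):
        cfg = base_cfg(pesticide_consume="T3")
        with pytest.raises(ValueError):
            make_state(cfg, identity_network)


class TestFeeding:
    def test_plentiful_cell_gives_full_ability(self, identity_network):
        state = make_state(base_cfg(), identity_network)
        state.pop.x[:], state.pop.y[:] = 1, 1
        state.landscape.crop_amount[:] = 4.0
        feed_step(state)
        assert state.pop.food[0, 0] == 1.0
        assert state.landscape.crop_amount[1, 1] == 3.0

    def test_scarce_cell_consumed_to_zero(self, identity_network):
        state = make_state(base_cfg(), identity_network)
        state.pop.x[:], state.pop.y[:] = 0, 0
        state.landscape.crop_amount[:] = 0.3
        feed_step(state)
        assert state.pop.food[0, 0] == pytest.approx(0.3)
        assert state.landscape.crop_amount[0, 0] == pytest.approx(0.0)

    def test_crowded_cell_conserves_crop_mass(self, identity_network):
        """Six pests able to eat 1 each share a cell holding 3.5 units:
        total intake equals the crop removed, first-come first-served."""
        state = make_state(base_cfg(N0=6), identity_network)
        state.pop.x[:], state.pop.y[:] = 2, 2
        state.landscape.crop_amount[:] = 0.0
        state.landscape.crop_amount[2, 2] = 3.5
        feed_step(state)
        gained = state.pop.food.sum()
        assert gained == pytest.approx(3.5)
        assert state.landscape.crop_amount[2, 2] == pytest.approx(0.0)
        intakes = np.sort(state.pop.food[:, 0])
        np.testing.assert_allclose(intakes, [0, 0, 0.5, 1, 1, 1])

    def test_sequential_order_matches_per_pest_loop(self, identity_network):
        """The vectorised grouped consumption equals a literal sequential
        loop over pests in the same shuffled order."""
        cfg = base_cfg(N0=40)
        state = make_state(cfg, identity_network, seed=5)
        rng_clone = np.random.default_rng(0)
        state.rng = np.random.default_rng(0)
        state.landscape.crop_amount[:] = 1.3
        supply_before = state.landscape.crop_amount.copy()
        feed_step(state)
        # oracle: replay with the same permutation
        order = rng_clone.permutation(np.arange(40))
        supply = supply_before.copy()
        food = np.zeros(40)
        for i in order:
            x, y = state.pop.x[i], state.pop.y[i]
            take = min(1.0, supply[x, y])
            supply[x, y] -= take
            food[i] += take
        np.testing.assert_allclose(state.pop.food[:, 0], food, atol=1e-12)
        np.testing.assert_allclose(state.landscape.crop_amount, supply, atol=1e-12)


class TestPesticideUptake:
    def test_negative_bound_trait_takes_nothing(self, identity_network):
        cfg = base_cfg(pesticide_consume="T1", pesticide_per_cell=1.0)
        state = make_state(cfg, identity_network)
        state.pop.traits[0] = (-0.7, 0.0)
        pesticide_step(state)
        assert state.pop.pesticide[0, 0] == 0.0

    def test_positive_bound_trait_uptake_without_depletion(self, identity_network):
        cfg = base_cfg(pesticide_consume="T1", pesticide_per_cell=1.0)
        state = make_state(cfg, identity_network)
        state.pop.traits[0] = (0.3, 0.0)
        cell = (state.pop.x[0], state.pop.y[0])
        pesticide_step(state)
        assert state.pop.pesticide[0, 0] == pytest.approx(0.3)
        assert state.landscape.pesticide_amount[cell] == pytest.approx(1.0)

    def test_shared_cell_equal_opportunity(self, identity_network):
        cfg = base_cfg(N0=2, pesticide_consume=0.4, pesticide_per_cell=1.0)
        state = make_state(cfg, identity_network)
        state.pop.x[:], state.pop.y[:] = 0, 0
        pesticide_step(state)
        np.testing.assert_allclose(state.pop.pesticide[:, 0], [0.4, 0.4])


class TestMovement:
    def test_zero_distance_never_moves(self, identity_network):
        state = make_state(base_cfg(N0=30, move_distance=0, movement_bouts=3),
                           identity_network)
        x0, y0 = state.pop.x.copy(), state.pop.y.copy()
        movement_step(state)
        np.testing.assert_array_equal(state.pop.x, x0)
        np.testing.assert_array_equal(state.pop.y, y0)

    def test_destinations_within_chebyshev_radius_on_torus(self, identity_network):
        cfg = base_cfg(N0=300, xdim=64, ydim=64, move_distance=2, movement_bouts=1)
        state = make_state(cfg, identity_network, seed=3)
        x0, y0 = state.pop.x.copy(), state.pop.y.copy()
        movement_step(state)
        dx = np.abs(state.pop.x - x0)
        dy = np.abs(state.pop.y - y0)
        dx = np.minimum(dx, 64 - dx)
        dy = np.minimum(dy, 64 - dy)
        assert np.max(np.maximum(dx, dy)) <= 2

    def test_leaky_edge_only_removes(self, identity_network):
        cfg = base_cfg(N0=200, xdim=4, ydim=4, move_distance=6, movement_bouts=2,
                       land_edge="leaky")
        state = make_state(cfg, identity_network, seed=4)
        movement_step(state)
        assert state.pop.size < 200  # some certainly walked off
        assert np.all((state.pop.x >= 0) & (state.pop.x < 4))
        assert np.all((state.pop.y >= 0) & (state.pop.y < 4))


class TestReproduction:
    def test_food_based_offspring_floor(self, identity_network):
        cfg = base_cfg(reproduction_type="food_based", food_needed_repr=1.0)
        state = make_state(cfg, identity_network)
        state.pop.food[0, 0] = 2.7
        before = state.pop.size
        reproduction_step(state)
        assert state.pop.size - before == 2

    def test_mates_must_share_cell_at_distance_zero(self, identity_network):
        cfg = base_cfg(repro="biparental", N0=2, mating_distance=0,
                       reproduction_type="lambda", lambda_value=5.0)
        state = make_state(cfg, identity_network, seed=6)
        state.pop.sex[:] = [SEX_FEMALE, SEX_MALE]
        state.pop.x[:], state.pop.y[:] = [0, 3], [0, 3]
        before = state.pop.size
        reproduction_step(state)
        assert state.pop.size == before  # out of range: no offspring
        state.pop.x[:], state.pop.y[:] = [1, 1], [2, 2]
        reproduction_step(state)
        assert state.pop.size > before

    def test_paternity_is_a_fair_raffle(self, identity_network):
        """Three equidistant males sire ~1/3 of a female's offspring each."""
        cfg = base_cfg(repro="biparental", N0=4, mating_distance=1,
                       reproduction_type="lambda", lambda_value=0.0)
        state = make_state(cfg, identity_network, seed=7)
        state.pop.sex[:] = [SEX_FEMALE, SEX_MALE, SEX_MALE, SEX_MALE]
        state.pop.x[:], state.pop.y[:] = 1, 1
        for k, mark in enumerate([0.0, 10.0, 20.0, 30.0]):
            state.pop.haps[k, :, :] = mark
        # one big brood from the single female
        lam = np.zeros(4)
        state.cfg.bindings["lambda_value"] = (None, 1)
        state.pop.traits[:] = 0.0
        state.pop.traits[0, 0] = 3000.0  # bound lambda: female expects ~3000
        before = state.pop.size
        reproduction_step(state)
        brood = state.pop.haps[before:, 1, 0]  # paternal gamete marker
        n = brood.size
        assert n > 2000
        shares = np.array([np.mean(brood == m) for m in (10.0, 20.0, 30.0)])
        np.testing.assert_allclose(shares, 1 / 3, atol=0.03)

    def test_birth_carrying_capacity_caps_cohort(self, identity_network):
        cfg = base_cfg(N0=30, reproduction_type="lambda", lambda_value=4.0,
                       K_on_birth=7)
        state = make_state(cfg, identity_network, seed=8)
        before = state.pop.size
        reproduction_step(state)
        assert state.pop.size - before == 7

    def test_pesticide_tolerance_blocks_reproduction(self, identity_network):
        cfg = base_cfg(reproduction_type="lambda", lambda_value=5.0,
                       pesticide_tolerated_repr=0.1)
        state = make_state(cfg, identity_network, seed=9)
        state.pop.pesticide[0, 0] = 0.2
        before = state.pop.size
        reproduction_step(state)
        assert state.pop.size == before


class TestMetabolismAndMortality:
    def test_metabolism_closed_form(self, identity_network):
        cfg = base_cfg(metabolism=1.0)
        state = make_state(cfg, identity_network)
        state.pop.food[0, 0] = 3.0
        metabolism_step(state)
        metabolism_step(state)
        assert state.pop.food[0, 0] == pytest.approx(1.0)
        metabolism_step(state)
        metabolism_step(state)
        assert state.pop.food[0, 0] == pytest.approx(0.0)  # floored

    def test_max_age_removal(self, identity_network):
        state = make_state(base_cfg(max_age=4, N0=3), identity_network)
        state.pop.age[:] = [3, 4, 5]
        mortality_step(state)
        assert state.pop.size == 2
        assert state.deaths_this_step == 1

    def test_any_pesticide_kills_at_threshold_age(self, identity_network):
        cfg = base_cfg(N0=3, pesticide_tolerated_surv=0.0,
                       age_pesticide_threshold=2, max_age=10)
        state = make_state(cfg, identity_network)
        state.pop.age[:] = [1, 2, 2]
        state.pop.pesticide[:, 0] = [0.001, 0.001, 0.0]
        mortality_step(state)
        # under-age pest and clean pest survive; poisoned at-threshold dies
        assert state.pop.size == 2
        np.testing.assert_array_equal(np.sort(state.pop.age), [1, 2])

    def test_zero_uptake_never_poisoned(self, identity_network):
        cfg = base_cfg(N0=5, pesticide_tolerated_surv=0.0, age_pesticide_threshold=0)
        state = make_state(cfg, identity_network)
        state.pop.age[:] = 3
        mortality_step(state)
        assert state.pop.size == 5

    def test_food_checkpoint_at_end_of_feeding_window(self, identity_network):
        cfg = base_cfg(N0=4, food_needed_surv=1.0, max_age_feed=2, max_age=10)
        state = make_state(cfg, identity_network)
        state.pop.age[:] = [1, 2, 2, 3]
        state.pop.food[:, 0] = [0.0, 0.5, 1.0, 0.0]
        mortality_step(state)
        # only the age-2 pest short of food dies; the check is one-off
        assert state.pop.size == 3
        np.testing.assert_array_equal(np.sort(state.pop.age), [1, 2, 3])


class TestImmigration:
    def test_zero_rate_no_arrivals(self, identity_network):
        state = make_state(base_cfg(immigration_rate=0.0), identity_network)
        before = state.pop.size
        immigration_step(state)
        assert state.pop.size == before

    def test_poisson_mean_arrivals(self, identity_network):
        cfg = base_cfg(immigration_rate=10.0)
        state = make_state(cfg, identity_network, seed=10)
        before = state.pop.size
        for _ in range(400):
            immigration_step(state)
        per_step = (state.pop.size - before) / 400
        assert abs(per_step - 10.0) < 4 * np.sqrt(10.0 / 400)

    def test_diploid_founder_variance_modes(self, example_network):
        """Literal allele summing doubles founder trait variance; the
        variance-preserving mode scales loci by 1/sqrt(2) to keep it."""
        exp = expected_covariance(example_network)
        covs = {}
        for preserve in (False, True):
            cfg = base_cfg(repro="sexual", N0=6000,
                           founder_variance_preserving=preserve)
            state = make_state(cfg, example_network, seed=20 + preserve)
            covs[preserve] = np.cov(state.pop.traits, rowvar=False)
        np.testing.assert_allclose(covs[False], 2 * exp, rtol=0.12, atol=0.1)
        np.testing.assert_allclose(covs[True], exp, rtol=0.12, atol=0.1)

    def test_immigrant_traits_follow_founding_network(self, example_network):
        """Immigrant trait covariance tracks the founding network's expected
        covariance regardless of any resident evolution."""
        cfg = base_cfg()
        state = make_state(cfg, example_network, seed=11)
        arrs = _draw_pests(4000, cfg, example_network, state.landscape, state.rng, 0)
        cov = np.cov(arrs["traits"], rowvar=False)
        np.testing.assert_allclose(
            cov, expected_covariance(example_network), atol=5 / np.sqrt(4000)
        )


class TestTimeStep:
    def test_quiet_world_only_ages(self, identity_network):
        cfg = base_cfg(N0=25)
        state = make_state(cfg, identity_network, seed=12)
        snapshot = {
            "x": state.pop.x.copy(), "y": state.pop.y.copy(),
            "food": state.pop.food.copy(), "pest": state.pop.pesticide.copy(),
            "haps": state.pop.haps.copy(), "age": state.pop.age.copy(),
        }
        run_time_step(state)
        assert state.pop.size == 25
        np.testing.assert_array_equal(state.pop.age, snapshot["age"] + 1)
        np.testing.assert_array_equal(state.pop.x, snapshot["x"])
        np.testing.assert_array_equal(state.pop.haps, snapshot["haps"])
        np.testing.assert_array_equal(state.pop.pesticide, snapshot["pest"])
        # quiet pests still eat from their cells, nothing else changes
        assert len(state.stats_rows) == 1

    def test_crop_mass_balance_over_a_season(self, identity_network):
        """Closed world, no rotation: initial crop + growth - remaining
        equals the food stored in the population, to 1e-9."""
        cfg = base_cfg(N0=40, crop_per_cell=2.0, crop_growth=0.5,
                       crop_growth_type="increment", food_consume=0.7)
        state = make_state(cfg, identity_network, seed=13)
        initial = state.landscape.crop_amount.sum()
        grown = 0.0
        for _ in range(10):
            before = state.landscape.crop_amount.sum()
            run_time_step(state)
            # growth happened first within the step; infer it from the config
            grown += 0.5 * state.landscape.crop_amount.size
        remaining = state.landscape.crop_amount.sum()
        eaten = state.pop.food.sum()
        assert initial + grown - remaining == pytest.approx(eaten, abs=1e-9)

    def test_network_values_frozen_without_network_mutation(self, example_network):
        """50 generations of reproduction with loci-only mutation leave the
        set of network values in the population unchanged."""
        cfg = base_cfg(
            N0=30, reproduction_type="lambda", lambda_value=1.2, max_age=1,
            mutation_pr=0.3, net_mu_layers=0, K_on_birth=60,
            crop_per_cell=5.0,
        )
        state = make_state(cfg, example_network, seed=14)
        founder_net = example_network.to_flat()
        for _ in range(50):
            run_time_step(state)
        assert state.pop.size > 0
        L = state.pop.layout.loci
        net_vals = state.pop.haps[:, :, L:]
        assert np.all(net_vals == founder_net)

    def test_rotation_clocks_are_independent(self, identity_network):
        cfg = base_cfg(
            crop_number=2, pesticide_number=2, crop_rotation_time=3,
            pesticide_rotation_time=5, crop_rotation_type=3,
            pesticide_rotation_type=3, crop_init=[1], pesticide_init=[1],
            pesticide_per_cell=1.0, N0=1, food_consume=0.0,
        )
        state = make_state(cfg, identity_network, seed=15)
        crop_types, pest_types = [], []
        for _ in range(15):
            run_time_step(state)
            crop_types.append(int(state.crop_assign[0]))
            pest_types.append(int(state.pesticide_assign[0]))
        # crop cycles every 3 steps, pesticide independently every 5
        assert crop_types == [1, 1, 2, 2, 2, 1, 1, 1, 2, 2, 2, 1, 1, 1, 2]
        assert pest_types == [1, 1, 1, 1, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1, 2]
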