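"""Adaptation kernel, MTE rates, dispersal kernel, and the yearly processes."""

import numpy as np
import pytest
from scipy import stats

from invasim import (
    ContractViolation,
    IdCounter,
    MTEConstants,
    Population,
    adaptation,
    build_island,
    competition_step,
    disturbance_step,
    dispersal_step,
    gauss,
    growth_step,
    mte_rate,
    reproduction_step,
    sample_dispersal_distance,
    spawn_individual,
    survival_step,
    transport_step,
)
from invasim.demography import ADAPTATION_FLOOR
from invasim.genetics import ADULT_MASS, SEED_MASS

from conftest import make_species


def make_patch(island, row, col, individuals, registry):
    patch = island.patch(row, col)
    patch.individuals = Population.from_individuals(individuals, registry)
    return patch


def populate(island, species, n, rng, row=0, col=0, stage="adult", cv=0.05):
    inds = [
        spawn_individual(species, rng, cv=cv, stage=stage, location=(row, col), individual_id=i)
        for i in range(n)
    ]
    return make_patch(island, row, col, inds, [species])


class TestGauss:
    def test_peaks_at_one_at_the_optimum(self):
        assert gauss(17.3, 2.2, 17.3) == 1.0

    def test_one_sd_analytic_value(self):
        assert gauss(0.0, 1.0, 1.0) == pytest.approx(np.exp(-0.5), abs=1e-15)

    def test_scale_invariance(self):
        assert gauss(0.0, 2.0, 2.0) == gauss(0.0, 1.0, 1.0)

    def test_symmetric_and_decreasing_in_distance(self):
        d = np.linspace(0, 5, 20)
        left = gauss(0.0, 1.5, -d)
        right = gauss(0.0, 1.5, d)
        assert np.allclose(left, right)
        assert np.all(np.diff(right) < 0)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ContractViolation):
            gauss(0.0, 0.0, 1.0)

    def test_matches_symbolic_transcription(self, rng):
        """Direct symbol-by-symbol transcription of the adaptation product."""
        island = build_island(side=5, base_temperature=15.0)
        for _ in range(2_000):
            topt, ttol = rng.uniform(0, 30), rng.uniform(0.1, 5)
            popt, ptol = rng.uniform(-5, 15), rng.uniform(0.1, 5)
            patch = island.patch(rng.integers(5), rng.integers(5))
            sp = make_species(
                temp_optimum=topt, temp_tolerance=ttol,
                precip_optimum=popt, precip_tolerance=ptol,
            )
            a = adaptation(sp.mean_traits, patch)
            expected_t = np.exp(-((patch.temperature - topt) ** 2) / (2 * ttol**2))
            expected_p = np.exp(-((patch.precipitation - popt) ** 2) / (2 * ptol**2))
            assert abs(a.temp_component - expected_t) < 1e-12
            assert abs(a.precip_component - expected_p) < 1e-12
            assert abs(a.combined - expected_t * expected_p) < 1e-12


class TestAdaptation:
    def test_double_peak_gives_one(self, island5):
        patch = island5.patch(2, 2)
        sp = make_species(temp_optimum=patch.temperature, precip_optimum=patch.precipitation)
        assert adaptation(sp.mean_traits, patch).combined == 1.0

    def test_one_sd_offset_in_precipitation(self, island5):
        patch = island5.patch(2, 2)
        sp = make_species(
            temp_optimum=patch.temperature,
            precip_optimum=patch.precipitation + 3.0,
            precip_tolerance=3.0,
        )
        assert adaptation(sp.mean_traits, patch).combined == pytest.approx(np.exp(-0.5))

    def test_product_bounded_by_components(self, island5, rng):
        for _ in range(200):
            sp = make_species(
                temp_optimum=rng.uniform(0, 30),
                precip_optimum=rng.uniform(-5, 15),
            )
            a = adaptation(sp.mean_traits, island5.patch(0, 0))
            assert a.combined <= min(a.temp_component, a.precip_component)
            assert 0 < a.combined <= 1


class TestMTERate:
    def test_zero_activation_energy_removes_temperature_dependence(self):
        c = MTEConstants(activation_energy=0.0)
        assert mte_rate(100.0, 10.0, 0.75, 2.0, c) == pytest.approx(2.0 * 100.0**0.75)
        assert mte_rate(100.0, 35.0, 0.75, 2.0, c) == pytest.approx(2.0 * 100.0**0.75)

    def test_quarter_power_mass_ratio(self, mte):
        r1 = mte_rate(10.0, 20.0, -0.25, mte.mort_coeff, mte)
        r16 = mte_rate(160.0, 20.0, -0.25, mte.mort_coeff, mte)
        assert r1 / r16 == pytest.approx(2.0)

    def test_monotone_in_temperature(self, mte):
        masses = np.logspace(np.log10(150), np.log10(1.2e6), 7)
        for m in masses:
            rates = [mte_rate(m, t, 0.75, 1.0, mte) for t in (5, 15, 25, 35)]
            assert np.all(np.diff(rates) > 0)

    def test_nonpositive_mass_rejected(self, mte):
        with pytest.raises(ContractViolation):
            mte_rate(0.0, 20.0, 0.75, 1.0, mte)


class TestDispersalKernel:
    def test_median_equals_scale(self):
        rng = np.random.default_rng(5)
        d = sample_dispersal_distance(1.0, 2.0, rng, size=100_000)
        assert np.median(d) == pytest.approx(1.0, rel=0.02)

    def test_matches_log_logistic_cdf(self):
        """KS distance against the closed-form CDF x^s / (a^s + x^s)."""
        rng = np.random.default_rng(6)
        a, s = 1.5, 2.5
        d = sample_dispersal_distance(a, s, rng, size=100_000)
        cdf = lambda x: x**s / (a**s + x**s)
        res = stats.kstest(d, cdf)
        assert res.statistic < 0.01

    def test_smaller_shape_means_heavier_tail(self):
        rng = np.random.default_rng(7)
        heavy = sample_dispersal_distance(1.0, 1.2, rng, size=50_000)
        light = sample_dispersal_distance(1.0, 3.0, rng, size=50_000)
        assert np.quantile(heavy, 0.99) > np.quantile(light, 0.99)

    def test_invalid_parameters_rejected(self, rng):
        with pytest.raises(ContractViolation):
            sample_dispersal_distance(0.0, 2.0, rng)
        with pytest.raises(ContractViolation):
            sample_dispersal_distance(1.0, 1.0, rng)


class TestSurvival:
    def test_zero_mortality_coefficient_kills_nobody(self, island5, rng):
        patch = populate(island5, make_species(), 500, rng)
        removed = survival_step(patch, MTEConstants(mort_coeff=0.0), rng)
        assert len(removed) == 0
        assert len(patch.individuals) == 500

    def test_worse_temperature_adaptation_doubles_hazard(self, mte):
        """Raw hazard is inversely proportional to temperature adaptation."""
        island = build_island(side=5, base_temperature=20.0)
        patch = island.patch(0, 0)
        base = mte_rate(1000.0, patch.temperature, -0.25, mte.mort_coeff, mte)
        p_full = min(1.0, base / max(1.0, ADAPTATION_FLOOR))
        p_half = min(1.0, base / max(0.5, ADAPTATION_FLOOR))
        assert p_half == pytest.approx(2 * p_full)

    def test_death_count_binomial(self, island5, mte):
        rng = np.random.default_rng(11)
        n = 10_000
        sp = make_species(temp_optimum=island5.patch(0, 0).temperature)
        patch = populate(island5, sp, n, rng, cv=0.0)
        # per-individual death probability implied by the constants
        base = mte_rate(1000.0, patch.temperature, -0.25, mte.mort_coeff, mte)
        p = min(1.0, base)
        removed = survival_step(patch, mte, rng)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(len(removed) - n * p) < 3 * sd


class TestGrowth:
    def test_adults_do_not_grow(self, island5, rng, mte):
        patch = populate(island5, make_species(), 50, rng, stage="adult", cv=0.0)
        before = patch.individuals.mass.copy()
        growth_step(patch, mte)
        assert np.array_equal(patch.individuals.mass, before)

    def test_zero_growth_coefficient(self, island5, rng):
        patch = populate(island5, make_species(), 50, rng, stage="seed", cv=0.0)
        before = patch.individuals.mass.copy()
        growth_step(patch, MTEConstants(growth_coeff=0.0))
        assert np.array_equal(patch.individuals.mass, before)

    def test_warmer_patch_grows_faster_and_mass_caps_at_adult(self, rng, mte):
        cold = build_island(side=3, base_temperature=10.0)
        warm = build_island(side=3, base_temperature=30.0)
        sp = make_species()
        pc = populate(cold, sp, 100, rng, stage="seed", cv=0.0)
        pw = populate(warm, sp, 100, rng, stage="seed", cv=0.0)
        growth_step(pc, mte)
        growth_step(pw, mte)
        assert pw.individuals.mass[0] > pc.individuals.mass[0]
        for _ in range(500):
            growth_step(pw, mte)
        assert np.all(pw.individuals.mass <= pw.individuals.phen[:, ADULT_MASS])
        assert np.all(pw.individuals.mass == pw.individuals.phen[:, ADULT_MASS])


class TestCompetition:
    def test_no_removals_under_capacity(self, island5, rng):
        patch = populate(island5, make_species(), 100, rng)  # 100 kg << 2 t
        removed = competition_step(patch, rng)
        assert len(removed) == 0

    def test_two_plants_over_capacity_lower_precip_adaptation_loses(self, island5, rng):
        strong = make_species("S", precip_optimum=0.0, adult_mass=1_200_000.0, seed_mass=100.0)
        weak = make_species("W", precip_optimum=9.0, adult_mass=1_200_000.0, seed_mass=100.0)
        inds = [
            spawn_individual(strong, rng, cv=0.0, stage="adult", individual_id=1),
            spawn_individual(weak, rng, cv=0.0, stage="adult", individual_id=2),
        ]
        patch = make_patch(island5, 0, 0, inds, [strong, weak])
        removed = competition_step(patch, rng)
        assert len(removed) == 1
        assert removed.ids[0] == 2  # the weakly adapted plant lost
        assert patch.individuals.ids[0] == 1

    def test_biomass_capped_or_single_survivor(self, island5):
        rng = np.random.default_rng(21)
        patch = populate(island5, make_species(adult_mass=900_000.0, seed_mass=100.0), 40, rng)
        assert patch.individuals.biomass > patch.capacity
        competition_step(patch, rng)
        assert patch.individuals.biomass <= patch.capacity or len(patch.individuals) == 1


class TestReproduction:
    def test_single_adult_cannot_self(self, island5, rng, mte):
        patch = populate(island5, make_species(), 1, rng)
        seeds = reproduction_step(patch, mte, rng, IdCounter())
        assert len(seeds) == 0

    def test_seed_count_scales_with_allocation(self, island5, rng):
        sp = make_species(temp_optimum=15.0)
        patch = populate(island5, sp, 20, rng, cv=0.0)
        base = reproduction_step(patch, MTEConstants(fecund_fraction=0.25), rng, IdCounter())
        double = reproduction_step(patch, MTEConstants(fecund_fraction=0.5), rng, IdCounter())
        # doubling the allocation doubles every mother's count up to rounding
        assert abs(len(double) - 2 * len(base)) <= 2 * 20

    def test_seed_count_inversely_proportional_to_seed_mass(self, island5, rng, mte):
        a = populate(island5, make_species("A", seed_mass=20.0), 10, rng, cv=0.0)
        b = populate(island5, make_species("B", seed_mass=40.0), 10, rng, row=1, cv=0.0)
        seeds_a = reproduction_step(a, mte, rng, IdCounter())
        seeds_b = reproduction_step(b, mte, rng, IdCounter())
        # halving seed mass doubles every mother's count up to rounding
        assert abs(len(seeds_a) - 2 * len(seeds_b)) <= 2 * 10

    def test_seeds_start_at_their_own_seed_mass(self, island5, rng, mte):
        patch = populate(island5, make_species(), 10, rng, cv=0.0)
        seeds = reproduction_step(patch, mte, rng, IdCounter())
        assert len(seeds) > 0
        assert np.allclose(seeds.mass, seeds.phen[:, SEED_MASS])

    def test_juveniles_do_not_reproduce(self, island5, rng, mte):
        patch = populate(island5, make_species(), 30, rng, stage="seed")
        seeds = reproduction_step(patch, mte, rng, IdCounter())
        assert len(seeds) == 0


class TestDisturbance:
    def test_zero_and_total_disturbance(self, island5, rng):
        patch = populate(island5, make_species(), 200, rng)
        assert len(disturbance_step(patch, 0.0, rng)) == 0
        assert len(patch.individuals) == 200
        disturbance_step(patch, 1.0, rng)
        assert len(patch.individuals) == 0

    def test_removals_binomial(self, island5):
        rng = np.random.default_rng(31)
        n, d = 10_000, 0.1
        patch = populate(island5, make_species(), n, rng)
        removed = disturbance_step(patch, d, rng)
        sd = np.sqrt(n * d * (1 - d))
        assert abs(len(removed) - n * d) < 3 * sd

    def test_invalid_fraction_rejected(self, island5, rng):
        patch = populate(island5, make_species(), 5, rng)
        with pytest.raises(ContractViolation):
            disturbance_step(patch, 1.5, rng)


class TestTransport:
    def _alien_setup(self, rng, n_species=100):
        species = [
            make_species(f"A{i:03d}", precip_optimum=float(rng.uniform(-4, 14)))
            for i in range(n_species)
        ]
        means = np.stack([sp.mean_traits.as_array() for sp in species])
        return species, means

    def test_exactly_p_arrivals_at_entry(self, island3):
        rng = np.random.default_rng(41)
        species, means = self._alien_setup(rng)
        for p in island3:
            p.individuals = Population.empty()
        established, drawn = transport_step(
            island3, means, np.arange(100), 10, rng,
            year=101, burn_in=100, cv=0.05, threshold=0.0,
            architecture=species[0].architecture, ids=IdCounter(),
        )
        assert len(drawn) == 10
        # threshold 0 lets every arrival establish, all at the entry cell
        assert len(established) == 10
        assert len(island3.entry_patch.individuals) == 10
        others = [p for p in island3 if not p.is_entry]
        assert all(len(p.individuals) == 0 for p in others)

    def test_zero_pressure_introduces_nothing(self, island3, rng):
        species, means = self._alien_setup(rng)
        for p in island3:
            p.individuals = Population.empty()
        established, drawn = transport_step(
            island3, means, np.arange(100), 0, rng,
            year=101, burn_in=100, cv=0.05, threshold=0.05,
            architecture=species[0].architecture, ids=IdCounter(),
        )
        assert len(established) == 0 and len(drawn) == 0

    def test_burn_in_call_rejected(self, island3, rng):
        species, means = self._alien_setup(rng)
        with pytest.raises(ContractViolation):
            transport_step(
                island3, means, np.arange(100), 1, rng,
                year=100, burn_in=100, cv=0.05, threshold=0.05,
                architecture=species[0].architecture, ids=IdCounter(),
            )

    def test_species_drawn_uniformly(self, island3):
        """Multinomial check: each pool species drawn ~ P*years/pool times."""
        rng = np.random.default_rng(51)
        species, means = self._alien_setup(rng, n_species=100)
        for p in island3:
            p.individuals = Population.empty()
        counts = np.zeros(100)
        years = 1_000
        for y in range(years):
            _, drawn = transport_step(
                island3, means, np.arange(100), 10, rng,
                year=101 + y, burn_in=100, cv=0.0, threshold=2.0,  # nobody establishes
                architecture=species[0].architecture, ids=IdCounter(),
            )
            np.add.at(counts, drawn, 1)
        expect = 10 * years / 100
        sd = np.sqrt(10 * years * (1 / 100) * (99 / 100))
        assert np.all(np.abs(counts - expect) < 5 * sd)


class TestDispersalStep:
    def _seed_batch(self, species, rng, n, registry=None, cv=0.0):
        inds = [
            spawn_individual(species, rng, cv=cv, stage="seed", individual_id=i)
            for i in range(n)
        ]
        return Population.from_individuals(inds, registry or [species])

    def test_tiny_scale_keeps_seeds_in_natal_patch(self, island5, rng, mte):
        sp = make_species(dispersal_scale=1e-2, temp_optimum=15.0, precip_optimum=5.0)
        seeds = self._seed_batch(sp, rng, 200)
        for p in island5:
            p.individuals = Population.empty()
        established, stats_ = dispersal_step(island5, [(2, 2, seeds)], rng, threshold=0.0)
        assert stats_["off_island"] == 0
        assert len(established) == 200
        assert len(island5.patch(2, 2).individuals) == 200

    def test_hopelessly_maladapted_seed_never_establishes(self, island5, rng):
        sp = make_species(temp_optimum=-40.0, temp_tolerance=0.02)
        seeds = self._seed_batch(sp, rng, 200)
        for p in island5:
            p.individuals = Population.empty()
        established, stats_ = dispersal_step(island5, [(2, 2, seeds)], rng, threshold=0.05)
        assert len(established) == 0
        assert stats_["unsuitable"] + stats_["off_island"] == 200

    def test_directions_are_isotropic(self, island5):
        """Quadrant counts of landing directions from the center are uniform."""
        rng = np.random.default_rng(61)
        sp = make_species(dispersal_scale=1.0, dispersal_shape=2.0)
        n = 100_000
        seeds = self._seed_batch(sp, rng, n)
        for p in island5:
            p.individuals = Population.empty()
        # use a huge island so nothing is lost off the border
        big = build_island(side=21, base_temperature=20.0)
        for p in big:
            p.individuals = Population.empty()
        src = (big.side - 1) // 2
        dispersal_step(big, [(src, src, seeds)], rng, threshold=0.0)
        quad = np.zeros(4)
        for p in big:
            dr, dc = p.row - src, p.col - src
            if dr == 0 or dc == 0:
                continue  # axis cells are shared between quadrants; skip
            q = (0 if dr < 0 else 2) + (0 if dc < 0 else 1)
            quad[q] += len(p.individuals)
        res = stats.chisquare(quad)
        assert res.pvalue > 0.01

    def test_conservation_ledger(self, island5, rng, mte):
        """Seeds are conserved: established + off-island + unsuitable = produced."""
        sp = make_species(dispersal_scale=2.0, temp_optimum=15.0, precip_optimum=2.0)
        seeds = self._seed_batch(sp, rng, 5_000, cv=0.3)
        for p in island5:
            p.individuals = Population.empty()
        established, st_ = dispersal_step(island5, [(0, 0, seeds)], rng, threshold=0.05)
        assert st_["produced"] == 5_000
        assert st_["established"] + st_["off_island"] + st_["unsuitable"] == 5_000
        assert sum(len(p.individuals) for p in island5) == len(established)
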