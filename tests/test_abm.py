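"""Stochastic cell processes: migration, division, differentiation, death."""

import numpy as np
import pytest

from osteosim import abm
from osteosim import geometry as geo
from osteosim.scenario import (MechanoThresholds, build_healthy_scenario,
                               build_t2dm_scenario)

from conftest import make_open_lattice


def center_index(lat):
    nx, ny, nz = lat.shape
    return (nx // 2) * lat.strides[0] + (ny // 2) * lat.strides[1] + nz // 2


class TestMigration:
    def test_zero_rate_is_identity(self, open_lattice, rng):
        open_lattice.occupancy[center_index(open_lattice)] = geo.MSC
        before = open_lattice.occupancy.copy()
        abm.migrate(open_lattice, geo.MSC, 0.0, 1.0, rng)
        assert np.array_equal(open_lattice.occupancy, before)

    def test_mean_squared_displacement_matches_step_count(self):
        # 30 um/h on a 10 um lattice -> exactly 3 unit moves per hour, so the
        # mean squared displacement of a free random walker is 3 h^2.
        trials, total = 800, 0.0
        for t in range(trials):
            lat = make_open_lattice(n=14, spacing_um=10.0)
            c = center_index(lat)
            lat.occupancy[c] = geo.MSC
            abm.migrate(lat, geo.MSC, 30.0, 1.0, np.random.default_rng(t))
            pos = np.nonzero(lat.occupancy == geo.MSC)[0]
            d = lat.site_coords(pos) - lat.site_coords(np.array([c]))
            total += float((d ** 2).sum()) / lat.spacing_mm ** 2
        assert total / trials == pytest.approx(3.0, rel=0.15)

    def test_fully_blocked_cell_stays(self, open_lattice, rng):
        c = center_index(open_lattice)
        open_lattice.occupancy[c] = geo.MSC
        for off in abm._offsets(open_lattice):
            open_lattice.occupancy[c + off] = geo.FIBROBLAST
        abm.migrate(open_lattice, geo.MSC, 1000.0, 1.0, rng)
        assert open_lattice.occupancy[c] == geo.MSC

    def test_migration_conserves_cell_count(self, open_lattice, rng):
        idx = np.nonzero(open_lattice.in_domain)[0]
        open_lattice.occupancy[rng.choice(idx, 200, replace=False)] = geo.MSC
        before = int((open_lattice.occupancy == geo.MSC).sum())
        for _ in range(24):
            abm.migrate(open_lattice, geo.MSC, 30.0, 1.0, rng)
        assert int((open_lattice.occupancy == geo.MSC).sum()) == before


class TestProliferation:
    def test_sparse_growth_matches_branching_mean(self):
        # mean growth factor per day is 1 + rate*dt while space lasts
        rate, days, reps, factor = 0.6, 5, 12, []
        for rep in range(reps):
            lat = make_open_lattice(n=30)
            rng = np.random.default_rng(rep)
            idx = np.nonzero(lat.in_domain)[0]
            seeds = rng.choice(idx, 12, replace=False)
            lat.occupancy[seeds] = geo.MSC
            for _ in range(days):
                abm.proliferate(lat, geo.MSC, rate, 1.0, rng)
            factor.append((lat.occupancy == geo.MSC).sum() / len(seeds))
        assert np.mean(factor) == pytest.approx(1.6 ** days, rel=0.10)

    def test_full_lattice_is_contact_inhibited(self, open_lattice, rng):
        open_lattice.occupancy[open_lattice.in_domain] = geo.MSC
        before = int((open_lattice.occupancy == geo.MSC).sum())
        abm.proliferate(open_lattice, geo.MSC, 0.6, 1.0, rng)
        assert int((open_lattice.occupancy == geo.MSC).sum()) == before

    def test_zero_rate_is_identity(self, open_lattice, rng):
        open_lattice.occupancy[center_index(open_lattice)] = geo.MSC
        abm.proliferate(open_lattice, geo.MSC, 0.0, 1.0, rng)
        assert int((open_lattice.occupancy == geo.MSC).sum()) == 1

    def test_rates_above_one_are_substepped(self, rng):
        lat = make_open_lattice(n=20)
        idx = np.nonzero(lat.in_domain)[0]
        lat.occupancy[rng.choice(idx, 10, replace=False)] = geo.MSC
        abm.proliferate(lat, geo.MSC, 2.4, 1.0, rng)  # p>1 requires splitting
        grown = int((lat.occupancy == geo.MSC).sum())
        assert grown > 10


class TestDifferentiation:
    def make_msc_field(self, n_cells, rng):
        lat = make_open_lattice(n=16)
        idx = np.nonzero(lat.in_domain)[0]
        cells = rng.choice(idx, n_cells, replace=False)
        lat.occupancy[cells] = geo.MSC
        return lat

    def test_window_selects_target_phenotype(self, rng):
        th = MechanoThresholds()
        q, b, c = th.bounds
        rates = {"fibroblast": 1.0, "chondrocyte": 1.0,
                 "immature_osteoblast": 1.0}
        for stim, expected in (((q + b) / 2, geo.OB_IMMATURE),
                               ((b + c) / 2, geo.CHONDROCYTE),
                               (2 * c, geo.FIBROBLAST)):
            lat = self.make_msc_field(50, rng)
            abm.differentiate(lat, np.full(lat.occupancy.size, stim), th,
                              rates, 1.0, rng)
            occ = lat.occupancy[lat.in_domain]
            assert (occ == expected).sum() == 50

    def test_lazy_zone_keeps_progenitors(self, rng):
        th = MechanoThresholds(lazy_zone=(1.275e-3, 1.875e-3))
        lat = self.make_msc_field(50, rng)
        mid = sum(th.lazy_zone) / 2
        abm.differentiate(lat, np.full(lat.occupancy.size, mid), th,
                          {"fibroblast": 1.0, "chondrocyte": 1.0,
                           "immature_osteoblast": 1.0}, 1.0, rng)
        assert (lat.occupancy[lat.in_domain] == geo.MSC).sum() == 50

    def test_zero_rate_changes_nothing(self, rng):
        th = MechanoThresholds()
        lat = self.make_msc_field(50, rng)
        stim = np.full(lat.occupancy.size, sum(th.bounds[:2]) / 2)
        abm.differentiate(lat, stim, th,
                          {"fibroblast": 0.0, "chondrocyte": 0.0,
                           "immature_osteoblast": 0.0}, 1.0, rng)
        assert (lat.occupancy[lat.in_domain] == geo.MSC).sum() == 50

    def test_invalid_stimulus_rejected(self, rng):
        lat = self.make_msc_field(5, rng)
        with pytest.raises(ValueError):
            abm.differentiate(lat, np.full(lat.occupancy.size, -1.0),
                              MechanoThresholds(),
                              {"fibroblast": 1.0, "chondrocyte": 1.0,
                               "immature_osteoblast": 1.0}, 1.0, rng)


class TestDeathAndMaturation:
    def test_survival_follows_geometric_decay(self):
        rate, days, reps = 0.1, 10, 10
        survivors = []
        for rep in range(reps):
            lat = make_open_lattice(n=16)
            rng = np.random.default_rng(rep)
            idx = np.nonzero(lat.in_domain)[0]
            lat.occupancy[rng.choice(idx, 500, replace=False)] = geo.CHONDROCYTE
            for _ in range(days):
                abm.apoptose(lat, geo.CHONDROCYTE, rate, 1.0, rng)
            survivors.append((lat.occupancy == geo.CHONDROCYTE).sum())
        assert np.mean(survivors) == pytest.approx(500 * 0.9 ** days, rel=0.10)

    def test_certain_death_eliminates_phenotype(self, open_lattice, rng):
        idx = np.nonzero(open_lattice.in_domain)[0]
        open_lattice.occupancy[idx[:100]] = geo.FIBROBLAST
        abm.apoptose(open_lattice, geo.FIBROBLAST, 1.0, 1.0, rng)
        assert not np.any(open_lattice.occupancy == geo.FIBROBLAST)

    def test_immature_pool_decays_exponentially(self):
        rate, days, reps = 0.2, 5, 10
        remaining = []
        for rep in range(reps):
            lat = make_open_lattice(n=16)
            rng = np.random.default_rng(rep)
            idx = np.nonzero(lat.in_domain)[0]
            lat.occupancy[rng.choice(idx, 800, replace=False)] = geo.OB_IMMATURE
            for _ in range(days):
                abm.mature(lat, rate, 1.0, rng)
            remaining.append((lat.occupancy == geo.OB_IMMATURE).sum())
        assert np.mean(remaining) == pytest.approx(800 * 0.8 ** days, rel=0.10)
        # matured cells are conserved as mature osteoblasts
        assert np.all(np.isin(remaining, np.arange(0, 801)))

    def test_zero_maturation_is_identity(self, open_lattice, rng):
        idx = np.nonzero(open_lattice.in_domain)[0]
        open_lattice.occupancy[idx[:50]] = geo.OB_IMMATURE
        abm.mature(open_lattice, 0.0, 1.0, rng)
        assert (open_lattice.occupancy == geo.OB_IMMATURE).sum() == 50


class TestGuidance:
    def test_disabled_guidance_is_identity(self):
        s = build_t2dm_scenario(guidance=False)
        assert abm.effective_rates(s, True) == s.rates
        assert abm.effective_rates(s, False) == s.rates

    def test_healthy_zone_rates_enhanced_ten_percent(self):
        s = build_healthy_scenario(guidance=True)
        zone = abm.effective_rates(s, True)
        assert zone.msc_proliferation == pytest.approx(0.66)
        assert zone.msc_migration == pytest.approx(33.0)
        assert abm.effective_rates(s, False) == s.rates

    def test_diabetic_zone_restores_healthy_rates(self):
        s = build_t2dm_scenario(guidance=True)
        zone = abm.effective_rates(s, True)
        assert zone == build_healthy_scenario().rates
        assert abm.effective_rates(s, False) == s.rates


class TestDailyStep:
    def _prepared(self, seed):
        lat = make_open_lattice(n=16)
        rng = np.random.default_rng(seed)
        idx = np.nonzero(lat.in_domain)[0]
        lat.occupancy[rng.choice(idx, 300, replace=False)] = geo.MSC
        scn = build_healthy_scenario()
        stim = np.full(lat.occupancy.size, 2.0e-3)  # osteogenic window
        return lat, scn, stim

    def test_all_zero_rates_is_fixed_point(self):
        lat, scn, stim = self._prepared(3)
        zero = scn.rates.replace(**{f: 0.0 for f in
                                    scn.rates.as_dict()})
        import dataclasses
        scn0 = dataclasses.replace(scn, rates=zero)
        before = lat.occupancy.copy()
        abm.daily_step(lat, stim, scn0, np.random.default_rng(0),
                       maturation_rate=0.0)
        assert np.array_equal(lat.occupancy, before)

    def test_identical_seeds_reproduce_trajectory(self):
        results = []
        for _ in range(2):
            lat, scn, stim = self._prepared(5)
            rng = np.random.default_rng(42)
            for _ in range(3):
                abm.daily_step(lat, stim, scn, rng)
            results.append(lat.occupancy.copy())
        assert np.array_equal(results[0], results[1])

    def test_occupancy_invariant_after_composite_step(self):
        lat, scn, stim = self._prepared(7)
        rng = np.random.default_rng(11)
        for _ in range(5):
            abm.daily_step(lat, stim, scn, rng)
            abm.check_occupancy(lat)
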