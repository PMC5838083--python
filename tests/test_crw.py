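"""CRW null model: step geometry, simulation, weighting, filtering."""

import numpy as np
import pandas as pd
import pytest

import cpforage.crw as crw
from cpforage._geo import destination, great_circle_km
from cpforage.tracks import Trip, TripPhase


def _phase(lons, lats, phase="outgoing", start="2006-11-02"):
    dates = pd.date_range(start, periods=len(lons), freq="D")
    return TripPhase("T01", phase, (-120.0, 34.0),
                     pd.DataFrame({"date": dates, "lon": lons, "lat": lats}))


def _walk_phase(n=8, step_km=20.0, heading=270.0, turn=15.0):
    """Deterministic phase built by successive destination steps."""
    lons, lats = [-121.0], [34.0]
    h = heading
    for i in range(n - 1):
        lon, lat = destination(lons[-1], lats[-1], h, step_km)
        lons.append(float(lon))
        lats.append(float(lat))
        h += turn
    return _phase(lons, lats)


class TestObservedSteps:
    def test_collinear_eastward_has_zero_turns(self):
        lons = [-121.0, -120.8, -120.6, -120.4]
        s = crw.observed_steps(_phase(lons, [0.0] * 4))
        np.testing.assert_allclose(s.turning_angles_deg, 0.0, atol=1e-9)

    def test_east_then_north_turns_left_90(self):
        lon1, lat1 = destination(-121.0, 34.0, 90.0, 20.0)
        lon2, lat2 = destination(lon1, lat1, 0.0, 20.0)
        s = crw.observed_steps(_phase([-121.0, lon1, lon2],
                                      [34.0, lat1, lat2]))
        assert s.turning_angles_deg[0] == pytest.approx(-90.0, abs=0.5)

    def test_closed_triangle_of_equal_sides(self):
        a = (-121.0, 34.0)
        b = destination(*a, 90.0, 15.0)
        c = destination(*b, 90.0 + 120.0, 15.0)
        s = crw.observed_steps(_phase([a[0], b[0], c[0], a[0]],
                                      [a[1], b[1], c[1], a[1]]))
        np.testing.assert_allclose(s.step_lengths_km, 15.0, atol=0.05)
        np.testing.assert_allclose(np.abs(s.turning_angles_deg), 120.0, atol=0.5)

    def test_single_position_raises(self):
        with pytest.raises(ValueError):
            crw.observed_steps(_phase([-121.0], [34.0]))


class TestNetDisplacement:
    def test_closed_loop_convention(self):
        nd = crw.net_displacement(_phase([-121.0, -120.5, -121.0],
                                         [34.0, 34.2, 34.0]).positions)
        assert nd.distance_km == 0.0
        assert nd.bearing_deg == 0.0

    def test_due_north(self):
        nd = crw.net_displacement(_phase([-121.0, -121.0], [34.0, 34.5]).positions)
        assert nd.bearing_deg == pytest.approx(0.0, abs=1e-6)

    def test_one_degree_east_at_equator(self):
        nd = crw.net_displacement(_phase([0.0, 1.0], [0.0, 0.0]).positions)
        assert nd.distance_km == pytest.approx(111.19, abs=0.01)
        assert nd.bearing_deg == pytest.approx(90.0, abs=1e-6)


class TestWeight:
    def test_identity_is_zero(self):
        nd = crw.NetDisplacement(137.0, 42.0)
        assert crw.crw_weight(nd, nd) == 0.0

    def test_worked_example(self):
        w = crw.crw_weight(crw.NetDisplacement(100.0, 0.0),
                           crw.NetDisplacement(80.0, 45.0))
        assert w == pytest.approx(0.9, abs=1e-12)

    def test_opposite_bearings_wrap_to_180(self):
        w = crw.crw_weight(crw.NetDisplacement(100.0, 10.0),
                           crw.NetDisplacement(100.0, 190.0))
        assert w == pytest.approx(2.0, abs=1e-12)

    def test_degenerate_track_raises(self):
        with pytest.raises(ValueError):
            crw.crw_weight(crw.NetDisplacement(0.0, 0.0),
                           crw.NetDisplacement(10.0, 0.0))

    def test_monotone_decreasing_in_sim_distance(self):
        track = crw.NetDisplacement(100.0, 0.0)
        w = [crw.crw_weight(track, crw.NetDisplacement(d, 30.0))
             for d in (20.0, 60.0, 100.0, 140.0)]
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_angular_term_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = crw.NetDisplacement(100.0, rng.uniform(0, 360))
            s = crw.NetDisplacement(100.0, rng.uniform(0, 360))
            assert 0.0 <= crw.crw_weight(t, s) <= 2.0

    def test_configuration_switches(self):
        t = crw.NetDisplacement(100.0, 0.0)
        s = crw.NetDisplacement(120.0, 45.0)
        literal = crw.crw_weight(t, s)
        assert literal == pytest.approx(2 * (-0.2) + 0.5)
        assert crw.crw_weight(t, s, absolute_differences=True) == pytest.approx(
            2 * 0.2 + 0.5)
        assert crw.crw_weight(t, s, scale_whole_sum=True) == pytest.approx(
            2 * (-0.2 + 0.5))


class TestSimulation:
    def test_step_lengths_preserved_without_land(self):
        phase = _walk_phase()
        obs = np.sort(crw.observed_steps(phase).step_lengths_km)
        sims = crw.simulate_crw(phase, landmask=None, n_sims=100, seed=5)
        for s in sims:
            lon = s.positions["lon"].values
            lat = s.positions["lat"].values
            steps = np.sort(great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:]))
            np.testing.assert_allclose(steps, obs, atol=1e-9)
            assert len(s.positions) == len(phase.positions)

    def test_zero_spread_angles_give_straight_line(self):
        # collinear phase: all turning angles zero, so simulations are
        # straight lines with the same total length
        lons = -121.0 - 0.2 * np.arange(6)
        phase = _phase(list(lons), [34.0] * 6)
        sims = crw.simulate_crw(phase, landmask=None, n_sims=5, seed=1)
        total_obs = crw.observed_steps(phase).step_lengths_km.sum()
        for s in sims:
            nd = crw.net_displacement(s.positions)
            assert nd.distance_km == pytest.approx(total_obs, rel=1e-4)

    def test_fixed_seed_is_deterministic(self):
        phase = _walk_phase()
        a = crw.simulate_crw(phase, landmask=None, n_sims=10, seed=3)
        b = crw.simulate_crw(phase, landmask=None, n_sims=10, seed=3)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.positions, y.positions)

    def test_start_on_land_raises(self):
        phase = _walk_phase()
        with pytest.raises(ValueError):
            crw.simulate_crw(phase, landmask=lambda lon, lat: True, n_sims=10)

    def test_land_rejection_keeps_sims_at_sea(self, demo_env, demo_landmask):
        # phase hugging the synthetic coast: rejections must occur and all
        # simulated positions stay off land
        coast = float(demo_env.attrs["coast_lon"])
        lons = [coast - 0.25] * 6
        lats = [34.0 + 0.15 * i for i in range(6)]
        sims = crw.simulate_crw(_phase(lons, lats), landmask=demo_landmask,
                                n_sims=20, seed=2)
        for s in sims:
            if not s.land_violation:
                assert not demo_landmask(s.positions["lon"].values,
                                         s.positions["lat"].values).any()


class TestFilterAndSelect:
    def _scored(self, weights, violations=None):
        violations = violations or [False] * len(weights)
        out = []
        for i, (w, v) in enumerate(zip(weights, violations)):
            out.append(crw.CRWSim("T", "outgoing", i,
                                  pd.DataFrame({"date": [], "lon": [], "lat": []}),
                                  weight=w, land_violation=v))
        return out

    def test_upper_quartile_removed(self):
        kept = crw.filter_sims(self._scored([1, 2, 3, 4, 5, 6, 7, 8]))
        assert sorted(s.weight for s in kept) == [1, 2, 3, 4, 5, 6]

    def test_equal_weights_keep_everything(self):
        kept = crw.filter_sims(self._scored([2.0] * 6))
        assert len(kept) == 6

    def test_land_violators_removed_first(self):
        sims = self._scored([1, 2, 3, 4], violations=[True, False, False, False])
        kept = crw.filter_sims(sims)
        assert all(not s.land_violation for s in kept)
        assert 1 not in [s.weight for s in kept]

    def test_single_retained_sim_is_selected(self):
        sims = self._scored([1.0])
        assert crw.select_pseudoabsence(sims, seed=9) is sims[0]

    def test_selection_deterministic_and_uniform(self):
        sims = self._scored([1, 2, 3, 4])
        first = crw.select_pseudoabsence(sims, seed=11).sim_id
        assert crw.select_pseudoabsence(sims, seed=11).sim_id == first
        counts = np.zeros(4)
        for seed in range(10000):
            counts[crw.select_pseudoabsence(sims, seed=seed).sim_id] += 1
        p = 0.25
        se = np.sqrt(10000 * p * (1 - p))
        assert np.all(np.abs(counts - 2500) < 3 * se)

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            crw.select_pseudoabsence([], seed=0)


class TestTripLevel:
    def test_retained_pseudoabsences_off_land(self, demo_env, demo_rookery,
                                              demo_landmask):
        import cpforage as cf
        raw = cf.generate_tracks(demo_env, demo_rookery, cf.TruthPreference(),
                                 2, 2, seed=13)
        import cpforage.pipeline as pl
        trips = pl.preprocess_tracks(raw, demo_rookery, demo_landmask)
        for i, trip in enumerate(trips):
            retained = crw.simulate_trip_nulls(trip, landmask=demo_landmask,
                                               n_sims=10, seed=100 + i)
            for sims in retained.values():
                for s in sims:
                    assert not demo_landmask(s.positions["lon"].values,
                                             s.positions["lat"].values).any()

    def test_null_trip_matches_observed_dates(self, demo_env, demo_rookery,
                                              demo_landmask):
        import cpforage as cf
        import cpforage.pipeline as pl
        raw = cf.generate_tracks(demo_env, demo_rookery, cf.TruthPreference(),
                                 1, 1, seed=17)
        trip = pl.preprocess_tracks(raw, demo_rookery, demo_landmask)[0]
        retained = crw.simulate_trip_nulls(trip, landmask=demo_landmask,
                                           n_sims=10, seed=0)
        null = crw.null_trip_positions(retained, seed=1)
        np.testing.assert_array_equal(pd.to_datetime(null["date"]).values,
                                      pd.to_datetime(trip.positions["date"]).values)
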