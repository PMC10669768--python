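"""Cage geometry, DO threshold, and the three calculation series."""

import dataclasses
import math

import numpy as np
import pytest

from cageoxy import (
    FitError,
    StockingSpec,
    cage_geometry,
    cs1_depletion,
    cs1_threshold_time_analytic,
    cs2_profile,
    cs3_flow_sweep,
    do_threshold,
    fish_density,
    fit_threshold_line,
    hill_ceiling,
    scenario_from_dict,
)

# the four published salmonid feed-intake thresholds behind the regression
THRESHOLD_POINTS = [(15, 68.9), (11, 53), (15, 66), (19, 76)]


class TestGeometry:
    def test_reference_cage(self):
        cage = cage_geometry(160.0, 8.0)
        assert cage.volume == pytest.approx(16297.5, abs=0.5)
        assert cage.diameter == pytest.approx(50.9, abs=0.05)

    def test_unit_circle_cage(self):
        cage = cage_geometry(2 * math.pi, 1.0)
        assert cage.radius == pytest.approx(1.0)
        assert cage.volume == pytest.approx(math.pi)

    def test_volume_scales_with_circumference_squared(self):
        v1 = cage_geometry(80.0, 8.0).volume
        v2 = cage_geometry(160.0, 8.0).volume
        assert v2 == pytest.approx(4 * v1)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            cage_geometry(0.0, 8.0)


class TestDensity:
    def test_zero_fish(self):
        assert fish_density(0, 1.5, 16297.5) == 0.0

    def test_reference_density(self):
        assert fish_density(271_625, 1.5, 16297.5) == pytest.approx(
            25.0, abs=0.1
        )

    def test_halves_when_volume_doubles(self):
        assert fish_density(1000, 1.5, 200.0) == pytest.approx(
            2 * fish_density(1000, 1.5, 400.0)
        )

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            fish_density(10, 1.5, 0.0)

    def test_stocking_requires_count_or_density(self):
        with pytest.raises(ValueError):
            StockingSpec(mean_mass=1.5, mean_length=45.0)


class TestDoThreshold:
    @pytest.mark.parametrize(
        "temp,sol,pct,conc",
        [(15, 8.44, 65.975, 5.57), (20, 7.63, 80.35, 6.13)],
    )
    def test_published_thresholds(self, temp, sol, pct, conc):
        got_pct, got_conc = do_threshold(temp, sol)
        assert got_pct == pytest.approx(pct, abs=0.001)
        assert round(got_conc, 2) == conc

    def test_clamped_at_full_saturation(self):
        pct, conc = do_threshold(30.0, 7.0)
        assert pct == 100.0
        assert conc == 7.0

    def test_strictly_increasing_in_temperature(self):
        pcts = [do_threshold(t, 8.0)[0] for t in range(-2, 27)]
        assert np.all(np.diff(pcts) > 0)


class TestFitThresholdLine:
    def test_recovers_published_regression(self):
        line = fit_threshold_line(THRESHOLD_POINTS)
        assert line.slope == pytest.approx(2.875, abs=1e-9)
        assert line.intercept == pytest.approx(22.85, abs=1e-9)

    def test_exact_on_collinear_points(self):
        pts = [(10, 40.0), (20, 60.0)]
        line = fit_threshold_line(pts)
        assert line.slope == pytest.approx(2.0)
        assert line.intercept == pytest.approx(20.0)

    def test_agrees_with_brute_force_sse_grid(self):
        line = fit_threshold_line(THRESHOLD_POINTS)
        t = np.array([p[0] for p in THRESHOLD_POINTS], dtype=float)
        y = np.array([p[1] for p in THRESHOLD_POINTS], dtype=float)
        slopes = np.linspace(2.5, 3.25, 151)
        inters = np.linspace(20.0, 26.0, 241)
        sse = np.array(
            [
                [np.sum((y - (s * t + c)) ** 2) for c in inters]
                for s in slopes
            ]
        )
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert slopes[i] == pytest.approx(line.slope, abs=0.005)
        assert inters[j] == pytest.approx(line.intercept, abs=0.025)

    def test_identical_temperatures_rejected(self):
        with pytest.raises(FitError):
            fit_threshold_line([(15, 60.0), (15, 70.0)])


class TestCS1:
    def test_reference_threshold_crossing(self, scen15):
        res = cs1_depletion(scen15, horizon=2.0)
        assert res.threshold_crossing_min_floor == 36

    def test_euler_matches_analytic_within_half_percent(self, scen15):
        res = cs1_depletion(scen15, dt=1.0, horizon=2.0)
        analytic = cs1_threshold_time_analytic(scen15)
        assert res.threshold_crossing_min == pytest.approx(
            analytic, rel=0.005
        )

    def test_euler_step_convergence(self, scen15):
        coarse = cs1_depletion(scen15, dt=1.0, horizon=1.5)
        fine = cs1_depletion(scen15, dt=0.1, horizon=1.5)
        assert coarse.threshold_crossing_min == pytest.approx(
            fine.threshold_crossing_min, rel=0.001
        )

    def test_no_fish_means_no_depletion(self, scen15):
        scen = dataclasses.replace(
            scen15,
            stocking=StockingSpec(
                mean_mass=1.5, mean_length=45.0, density=0.0
            ),
        )
        res = cs1_depletion(scen, horizon=1.0)
        assert res.threshold_crossing_min is None
        assert np.all(res.conc == scen.inlet_o2)

    def test_crossing_earlier_at_higher_density(self, scen15):
        denser = dataclasses.replace(
            scen15,
            stocking=StockingSpec(
                mean_mass=1.5, mean_length=45.0, density=35.0
            ),
        )
        assert (
            cs1_depletion(denser, horizon=2.0).threshold_crossing_min
            < cs1_depletion(scen15, horizon=2.0).threshold_crossing_min
        )

    def test_crossing_earlier_at_higher_temperature(
        self, scen10, scen15, scen20
    ):
        times = [
            cs1_depletion(s, horizon=2.0).threshold_crossing_min
            for s in (scen10, scen15, scen20)
        ]
        assert times[0] > times[1] > times[2]

    def test_fed_crosses_before_unfed(self, scen15):
        unfed = dataclasses.replace(scen15, fed=False)
        assert (
            cs1_depletion(scen15, horizon=2.0).threshold_crossing_min
            < cs1_depletion(unfed, horizon=2.0).threshold_crossing_min
        )

    def test_hypoxic_tail_is_capped_and_concave(self, scen20):
        # start already in the Hill-limited region
        scen = dataclasses.replace(scen20, inlet_o2=2.0)
        res = cs1_depletion(scen, horizon=12.0)
        assert np.all(res.conc >= 0)
        assert np.all(np.diff(res.conc) <= 0)
        # every recorded uptake respects the ceiling at its concentration
        k = scen.water.kpa_per_mgl
        for c, m in zip(res.conc[:-1], res.mo2[:-1]):
            assert m <= hill_ceiling(scen.hill, c * k) * (1 + 1e-9)
        # swim speed is reduced below Upref
        assert res.speed_bl_s[0] < scen.upref
        # depletion decelerates: the tail is concave upward
        rates = -np.diff(res.conc)
        assert rates[-1] < rates[0]

    def test_anoxia_unreachable_under_hill_cap(self, scen15):
        res = cs1_depletion(scen15, horizon=6.0)
        assert res.anoxia_crossing_min is None


class TestCS2:
    def test_reference_downstream_edge(self, scen10):
        res = cs2_profile(scen10)
        assert round(res.downstream_edge_conc, 1) == 7.9

    def test_reference_max_diameter(self, scen10):
        res = cs2_profile(scen10)
        assert res.max_diameter_to_threshold == pytest.approx(
            156.9, abs=0.5
        )

    def test_concentration_non_increasing(self, scen15):
        res = cs2_profile(scen15)
        assert np.all(np.diff(res.conc) <= 0)

    def test_washout_limit(self, scen15):
        fast = dataclasses.replace(scen15, current_velocity=500.0)
        res = cs2_profile(fast)
        assert res.downstream_edge_conc == pytest.approx(
            scen15.inlet_o2, rel=0.01
        )

    def test_mass_conservation_along_transect(self, scen15):
        res = cs2_profile(scen15)
        v = scen15.current_velocity / 100.0
        dt = np.diff(res.x_m) / v
        consumed = np.sum(
            0.5 * (res.mo2[:-1] + res.mo2[1:]) * scen15.density / 3.6e6 * dt
        )
        drop = scen15.inlet_o2 - res.downstream_edge_conc
        assert consumed == pytest.approx(drop, rel=0.005)

    def test_zero_flow_directed_to_cs1(self, scen15):
        still = dataclasses.replace(scen15, current_velocity=0.0)
        with pytest.raises(ValueError, match="cs1"):
            cs2_profile(still)


class TestCS3:
    def test_reference_min_flow(self, scen15):
        res = cs3_flow_sweep(scen15, policy="upref_floor")
        # closed-form crossing of the linear profile is 2.322 cm/s
        assert res.min_flow_cm_s == pytest.approx(2.32, abs=0.02)

    def test_downstream_conc_increases_with_flow_below_upref(self, scen15):
        res = cs3_flow_sweep(
            scen15, policy="upref_floor",
            v_grid=np.arange(0.5, 40.0, 0.5),
        )
        below = res.v_cm_s / scen15.stocking.mean_length <= scen15.upref
        assert np.all(np.diff(res.conc[below]) > 0)

    def test_policies_coincide_when_current_matches_upref(self, scen15):
        v_star = scen15.upref * scen15.stocking.mean_length  # 49.5 cm/s
        grid = [v_star]
        match = cs3_flow_sweep(scen15, "match_current", grid)
        floor = cs3_flow_sweep(scen15, "upref_floor", grid)
        assert match.conc[0] == pytest.approx(floor.conc[0], rel=1e-12)
        assert match.speed_bl_s[0] == pytest.approx(scen15.upref)

    def test_min_flow_increases_with_temperature(
        self, scen10, scen15, scen20
    ):
        flows = [
            cs3_flow_sweep(s).min_flow_cm_s
            for s in (scen10, scen15, scen20)
        ]
        assert flows[0] < flows[1] < flows[2]

    def test_empty_grid_rejected(self, scen15):
        with pytest.raises(ValueError):
            cs3_flow_sweep(scen15, v_grid=[])


class TestScenarioIO:
    def test_from_dict_round_trip(self):
        d = {
            "water": {"temperature": 15, "salinity": 30, "solubility": 8.44},
            "cage": {"circumference": 160, "depth": 8},
            "stocking": {"mean_mass": 1.5, "mean_length": 45,
                         "density": 25},
            "curve": {"a": 60.5, "b": 0.909},
            "hill": {"amr": 414.9, "p50": 6.04, "hill_coef": 5.51},
            "upref": 1.1,
            "fed": True,
            "current_velocity": 5,
        }
        scen = scenario_from_dict(d)
        assert scen.density == 25
        assert scen.threshold_conc == pytest.approx(5.568, abs=0.001)

    def test_missing_section_reported(self):
        with pytest.raises(ValueError, match="missing"):
            scenario_from_dict({"water": {"temperature": 15}})
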