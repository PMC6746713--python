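import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from typescreen.dynamics import (
    DynamicsSequences,
    FilterConfig,
    apply_timing_filters,
    compute_distances,
    compute_dynamics,
    compute_flight_times,
    compute_hold_times,
    compute_speed_and_pfr,
    extract_dynamics,
    flag_outlier_sessions,
    is_valid_session,
)

from conftest import make_session, random_session


class TestHoldAndFlight:
    def test_hold_times_formula(self):
        s = make_session([0, 500], holds=[120, 150])
        assert compute_hold_times(s).tolist() == [120, 150]

    def test_zero_hold_times(self):
        s = make_session([0, 300, 700], holds=[0, 0, 0])
        assert compute_hold_times(s).tolist() == [0, 0, 0]

    def test_flight_time_formula(self):
        s = make_session([0, 400], holds=[100, 100])
        # release at 100, next press at 400
        assert compute_flight_times(s).tolist() == [300]

    def test_negative_flight_under_overlap(self):
        # release of key 1 at 500, key 2 pressed at 450 (two-handed typing)
        s = make_session([0, 450], holds=[500, 100])
        assert compute_flight_times(s).tolist() == [-50]

    def test_single_event_session_has_no_flights(self):
        s = make_session([0], holds=[100])
        assert compute_flight_times(s).tolist() == []

    def test_random_sessions_match_subtraction_oracle(self, rng):
        for _ in range(200):
            s = random_session(rng, n_keys=int(rng.integers(2, 25)))
            ht = compute_hold_times(s)
            ft = compute_flight_times(s)
            for n, e in enumerate(s.events):
                assert ht[n] == e.release_time - e.press_time
            for n in range(len(s.events) - 1):
                assert ft[n] == s.events[n + 1].press_time - s.events[n].release_time


class TestDistances:
    def test_unit_conversion_identity(self):
        # 254 px at 254 ppi is exactly one inch = 25.4 mm
        s = make_session([0, 400], coords=[(0, 0), (254, 0)], density=254.0)
        assert compute_distances(s).tolist() == pytest.approx([25.4])

    def test_zero_displacement(self):
        s = make_session([0, 400], coords=[(7, 9), (7, 9)])
        assert compute_distances(s).tolist() == [0.0]

    def test_matches_euclidean_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 15))
            coords = [(float(rng.integers(0, 2000)), float(rng.integers(0, 1200)))
                      for _ in range(n)]
            dx_ppi, dy_ppi = float(rng.uniform(100, 600)), float(rng.uniform(100, 600))
            s = make_session(np.arange(n) * 400, coords=coords, density=1.0)
            object.__setattr__(s, "screen_density_x", dx_ppi)
            object.__setattr__(s, "screen_density_y", dy_ppi)
            got = compute_distances(s)
            for k in range(n - 1):
                ex = math.sqrt(
                    ((coords[k + 1][0] - coords[k][0]) / dx_ppi * 25.4) ** 2
                    + ((coords[k + 1][1] - coords[k][1]) / dy_ppi * 25.4) ** 2
                )
                assert got[k] == pytest.approx(ex)

    def test_axis_swap_isotropy(self, rng):
        coords = [(10, 700), (600, 40), (222, 333)]
        swapped = [(y, x) for x, y in coords]
        s1 = make_session([0, 400, 800], coords=coords)
        s2 = make_session([0, 400, 800], coords=swapped)
        assert compute_distances(s1).tolist() == pytest.approx(
            compute_distances(s2).tolist()
        )

    def test_privacy_mode_equals_coordinate_mode(self, rng):
        s = random_session(rng, n_keys=10)
        d = compute_distances(s)
        events = [
            type(e)(press_time=e.press_time, release_time=e.release_time,
                    x=None, y=None, is_delete=e.is_delete)
            for e in s.events
        ]
        priv = type(s)(
            subject_id=s.subject_id, session_id=s.session_id,
            start_time=s.start_time, events=events,
            screen_density_x=s.screen_density_x, screen_density_y=s.screen_density_y,
            distances_mm=list(d),
        )
        a, b = extract_dynamics(s), extract_dynamics(priv)
        assert a.ht.tolist() == b.ht.tolist()
        assert a.ft.tolist() == b.ft.tolist()
        assert a.sp.tolist() == pytest.approx(b.sp.tolist())
        assert a.pfr.tolist() == pytest.approx(b.pfr.tolist())


class TestSpeedAndPfr:
    def test_ratios(self):
        sp, pfr = compute_speed_and_pfr([150.0], [300.0], [10.0])
        assert pfr.tolist() == [0.5]
        sp, _ = compute_speed_and_pfr([100.0], [100.0], [10.0])
        assert sp.tolist() == [0.1]

    def test_rejects_nonpositive_ft(self):
        with pytest.raises(ValueError):
            compute_speed_and_pfr([100.0], [-1.0], [5.0])

    def test_matches_division_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            ht = rng.uniform(10, 300, n + 1)
            ft = rng.uniform(1, 3000, n)
            dist = rng.uniform(0, 40, n)
            sp, pfr = compute_speed_and_pfr(ht, ft, dist)
            assert sp.tolist() == pytest.approx([dist[k] / ft[k] for k in range(n)])
            assert pfr.tolist() == pytest.approx([ht[k] / ft[k] for k in range(n)])


class TestTimingFilters:
    def _dyn(self, ht, ft, dist=None):
        ht, ft = list(ht), list(ft)
        dist = dist if dist is not None else [1.0] * len(ft)
        return DynamicsSequences(
            ht_raw=np.array(ht, float), ft_raw=np.array(ft, float),
            dist=np.array(dist, float),
        )

    def test_ft_threshold_and_sign_filter(self):
        dyn = self._dyn([100] * 5, [100, 3500, -20, 2999])
        out = apply_timing_filters(dyn)
        assert out.ft.tolist() == [100, 2999]

    def test_boundary_ft_values(self):
        dyn = self._dyn([100] * 5, [3000, 3001, 0, 1])
        out = apply_timing_filters(dyn)
        # 3000 ms inclusive stays, 0 removed
        assert out.ft.tolist() == [3000, 1]

    def test_long_press_removed_and_counted(self):
        dyn = self._dyn([120, 310], [100])
        out = apply_timing_filters(dyn)
        assert out.ht.tolist() == [120]
        assert out.long_press_count == 1
        # 300 ms is at the threshold, kept
        out2 = apply_timing_filters(self._dyn([300, 301], [100]))
        assert out2.ht.tolist() == [300]

    def test_noop_when_all_within_bounds(self):
        dyn = self._dyn([100, 200, 250], [500, 900])
        out = apply_timing_filters(dyn)
        assert out.ht.tolist() == dyn.ht_raw.tolist()
        assert out.ft.tolist() == dyn.ft_raw.tolist()

    def test_cascade_semantics(self):
        # key 0 long-pressed: PFR_0 dropped but FT_0/SP_0 kept;
        # FT_1 overlap: SP_1 and PFR_1 dropped
        dyn = self._dyn([400, 100, 100], [200, -5], dist=[10.0, 20.0])
        out = apply_timing_filters(dyn)
        assert out.ft.tolist() == [200]
        assert out.sp.tolist() == pytest.approx([10.0 / 200])
        assert out.pfr.tolist() == []

    @given(
        ht=st.lists(st.floats(0, 1000, allow_nan=False), min_size=1, max_size=30),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_filtering_idempotent_and_subsequence(self, ht):
        n = len(ht)
        rng = np.random.default_rng(7)
        ft = rng.uniform(-100, 4000, n - 1)
        dyn = self._dyn(ht, ft, dist=list(rng.uniform(0, 30, n - 1)))
        once = apply_timing_filters(dyn)
        twice = apply_timing_filters(once)
        assert once.ht.tolist() == twice.ht.tolist()
        assert once.ft.tolist() == twice.ft.tolist()
        assert once.pfr.tolist() == twice.pfr.tolist()
        assert once.long_press_count == twice.long_press_count
        # order-preserving subsequence
        it = iter(dyn.ht_raw.tolist())
        assert all(any(x == y for y in it) for x in once.ht.tolist())


class TestValidityAndOutliers:
    @pytest.mark.parametrize("n,expected", [(8, True), (7, False), (0, False), (20, True)])
    def test_eight_key_validity(self, rng, n, expected):
        if n == 0:
            import dataclasses

            s = random_session(rng, n_keys=2)
            s = dataclasses.replace(s, events=[], distances_mm=None)
            assert is_valid_session(s) is False
        else:
            assert is_valid_session(random_session(rng, n_keys=n)) is expected

    def _dyn_with_ft_median(self, med, n=9):
        ft = np.full(n, float(med))
        return DynamicsSequences(
            ht_raw=np.full(n + 1, 100.0), ft_raw=ft, dist=np.ones(n), filtered=True,
        )

    def test_outlier_session_flagged(self, rng):
        medians = rng.normal(200, 10, 20)
        sessions = [self._dyn_with_ft_median(m) for m in medians]
        sessions.append(self._dyn_with_ft_median(2000.0))
        mask = flag_outlier_sessions(sessions)
        assert mask.tolist() == [False] * 20 + [True]

    def test_identical_medians_never_flag(self):
        sessions = [self._dyn_with_ft_median(200.0) for _ in range(5)]
        assert not flag_outlier_sessions(sessions).any()

    def test_single_session_user_never_flags(self):
        assert not flag_outlier_sessions([self._dyn_with_ft_median(5.0)]).any()

    def test_matches_three_sigma_oracle(self, rng):
        for _ in range(50):
            meds = rng.uniform(50, 2000, int(rng.integers(2, 15)))
            sessions = [self._dyn_with_ft_median(m) for m in meds]
            mask = flag_outlier_sessions(sessions)
            mu, sigma = np.mean(meds), np.std(meds)
            expect = [abs(m - mu) > 3 * sigma for m in meds]
            assert mask.tolist() == expect
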