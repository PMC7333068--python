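import itertools
import math

import numpy as np
import pandas as pd
import pytest

from passivecbt import mobility as mb
from _utils import TSTART, fixes_from_minutes, sessions_from_minutes, stays_from_minutes

HOME = (42.0, -71.0)
AWAY = (42.01, -71.0)  # ~1.1 km north
FAR = (42.05, -71.0)  # ~5.6 km


def _stationary(minutes, latlon, **kw):
    return fixes_from_minutes([(m, latlon[0], latlon[1]) for m in minutes], **kw)


class TestHaversine:
    def test_one_hundredth_degree_latitude(self):
        d = mb.haversine_m(42.0, -71.0, 42.01, -71.0)
        assert d == pytest.approx(1112.0, rel=0.01)

    def test_zero_distance(self):
        assert mb.haversine_m(*HOME, *HOME) == 0.0


class TestDetectStays:
    def test_stationary_run_becomes_one_stay(self):
        fx = _stationary([0, 15, 30, 45], HOME)
        stays = mb.detect_stays(fx)
        assert len(stays) == 1
        assert stays["dwell_min"][0] == 45.0

    def test_short_dwell_is_transit(self):
        fx = fixes_from_minutes(
            [(0, *HOME), (10, *HOME), (20, FAR[0], FAR[1])]
        )
        assert len(mb.detect_stays(fx)) == 0

    def test_two_planted_stays_with_transit(self):
        points = (
            [(m, *HOME) for m in range(0, 121, 15)]
            + [(130, 42.005, -71.0)]
            + [(m, *AWAY) for m in range(140, 261, 15)]
        )
        fx = fixes_from_minutes(points)
        stays = mb.detect_stays(fx)
        assert len(stays) == 2
        assert list(stays["dwell_min"]) == [120.0, 120.0]
        # all-pairs oracle: within each detected run, every pairwise
        # distance stays within the radius
        for row in stays.itertuples(index=False):
            sel = fx[(fx.timestamp >= row.start) & (fx.timestamp <= row.end)]
            for a, b in itertools.combinations(sel.itertuples(index=False), 2):
                assert mb.haversine_m(a.lat, a.lon, b.lat, b.lon) <= 100.0

    def test_duplicate_fix_densification_invariance(self):
        fx = _stationary([0, 15, 30, 45], HOME)
        dup = pd.concat([fx, fx]).sort_values("timestamp").reset_index(drop=True)
        a, b = mb.detect_stays(fx), mb.detect_stays(dup)
        assert len(a) == len(b) == 1
        assert a["dwell_min"][0] == b["dwell_min"][0]

    def test_long_fix_gap_splits_stay(self):
        # an overnight observation hole must not be claimed as dwell
        fx = _stationary([0, 15, 30, 45, 45 + 2 * 1440, 45 + 2 * 1440 + 45], HOME)
        stays = mb.detect_stays(fx)
        assert len(stays) == 2
        assert stays["dwell_min"].max() < 100
        bridged = mb.detect_stays(fx, max_gap_min=None)
        assert len(bridged) == 1

    def test_out_of_range_coordinates_raise(self):
        with pytest.raises(ValueError, match="WGS84"):
            mb.detect_stays(fixes_from_minutes([(0, 95.0, 0.0), (30, 95.0, 0.0)]))


class TestAnonymize:
    def _clusters(self, centroids):
        rows = []
        for k, (lat, lon) in enumerate(centroids):
            rows.append(
                {
                    "participant_id": "p1",
                    "start": pd.Timestamp("2019-01-07") + pd.Timedelta(hours=k),
                    "end": pd.Timestamp("2019-01-07") + pd.Timedelta(hours=k, minutes=40),
                    "dwell_min": 40.0,
                    "centroid_lat": lat,
                    "centroid_lon": lon,
                    "tz_offset_min": 0,
                }
            )
        return pd.DataFrame(rows)

    def test_same_place_same_id(self):
        stays = mb.anonymize_stays(self._clusters([HOME, HOME]), seed=1)
        assert stays["location_id"].nunique() == 1

    def test_distant_places_distinct_ids(self):
        stays = mb.anonymize_stays(self._clusters([HOME, FAR]), seed=1)
        assert stays["location_id"].nunique() == 2

    def test_ids_are_opaque(self):
        stays = mb.anonymize_stays(self._clusters([HOME]), seed=1)
        assert stays["location_id"].str.match(r"ID\d+").all()

    def test_no_coordinates_in_output(self):
        stays = mb.anonymize_stays(self._clusters([HOME, AWAY]), seed=3)
        leaked = [c for c in stays.columns if "lat" in c or "lon" in c or "centroid" in c]
        assert leaked == []
        assert list(stays.columns) == mb.STAY_COLUMNS

    def test_permutation_yields_bijective_relabeling(self):
        centroids = [HOME, AWAY, HOME, FAR, AWAY, HOME]
        a = mb.anonymize_stays(self._clusters(centroids), seed=5)
        perm = [3, 0, 5, 2, 4, 1]
        b = mb.anonymize_stays(self._clusters([centroids[i] for i in perm]), seed=5)
        # b's row j holds centroids[perm[j]]; realign to a's original order
        b_ids = [None] * len(perm)
        for j, i in enumerate(perm):
            b_ids[i] = b["location_id"].iloc[j]
        mapping = {}
        for ida, idb in zip(a["location_id"], b_ids):
            assert mapping.setdefault(ida, idb) == idb
        assert len(set(mapping.values())) == len(mapping)


class TestInferHome:
    def test_single_location_is_home(self):
        stays = stays_from_minutes([("ID7", 0, 600), ("ID7", 1440, 2000)])
        home = mb.infer_home(stays)
        assert home.home_location_id == "ID7"
        assert home.n_night_observations >= 1

    def test_no_night_overlap_means_absent(self):
        # stays only between 10:00 and 20:00 local
        stays = stays_from_minutes([("ID7", 600, 1200), ("ID8", 2040, 2640)])
        home = mb.infer_home(stays)
        assert home.home_location_id is None
        assert home.n_night_observations == 0

    def test_most_night_minutes_wins(self):
        stays = stays_from_minutes(
            [
                ("work", 3 * 60, 4 * 60),  # one night hour
                ("home", 1440 + 3 * 60, 1440 + 6 * 60),  # three night hours
            ]
        )
        assert mb.infer_home(stays).home_location_id == "home"

    def test_tz_offset_shifts_night_window(self):
        # 01:00-04:00 UTC with +120 min offset is 03:00-06:00 local
        stays = stays_from_minutes([("ID1", 60, 240)], tz=120)
        assert mb.infer_home(stays).home_location_id == "ID1"
        assert mb.infer_home(stays_from_minutes([("ID1", 60, 240)], tz=0)).home_location_id == "ID1"
        # 07:00-09:00 local has no overlap
        assert mb.infer_home(stays_from_minutes([("ID1", 420, 540)])).home_location_id is None


class TestAssessmentWindow:
    @pytest.mark.parametrize(
        "day,expected", [(42, (39, 45)), (0, (0, 3)), (84, (81, 87))]
    )
    def test_windows(self, day, expected):
        assert mb.assessment_window(day) == expected


class TestPercentTimeAtHome:
    def _home(self):
        return mb.HomeModel("p1", "home", 5)

    def test_all_time_at_home(self):
        stays = stays_from_minutes([("home", 0, 1440), ("home", 1500, 2000)])
        feat = mb.percent_time_at_home(stays, self._home(), (0, 6), TSTART)
        assert feat.pct_time_at_home == 100.0

    def test_no_time_at_home(self):
        stays = stays_from_minutes([("away", 0, 600)])
        feat = mb.percent_time_at_home(stays, self._home(), (0, 6), TSTART)
        assert feat.pct_time_at_home == 0.0

    def test_absent_when_nothing_observed_in_window(self):
        stays = stays_from_minutes([("home", 0, 600)])
        feat = mb.percent_time_at_home(stays, self._home(), (10, 16), TSTART)
        assert math.isnan(feat.pct_time_at_home)
        assert feat.observed_minutes == 0.0

    def test_matches_minute_counting_oracle(self):
        rng = np.random.default_rng(9)
        rows, t = [], 0.0
        for _ in range(40):
            t += float(rng.integers(10, 300))
            d = float(rng.integers(30, 400))
            rows.append((rng.choice(["home", "awayA", "awayB"]), t, t + d))
            t += d
        stays = stays_from_minutes(rows)
        window = (1, 4)
        feat = mb.percent_time_at_home(stays, self._home(), window, TSTART)
        # minute-by-minute counting
        lo, hi = window[0] * 1440, (window[1] + 1) * 1440
        grid = np.arange(lo, hi, dtype=float) + 0.5
        at, total = 0, 0
        for lid, s, e in rows:
            sel = (grid >= s) & (grid < e)
            total += sel.sum()
            if lid == "home":
                at += sel.sum()
        assert feat.pct_time_at_home == pytest.approx(100.0 * at / total, abs=0.2)

    def test_missing_days_counted_from_fixes(self):
        stays = stays_from_minutes([("home", 0, 1440)])
        fixes = fixes_from_minutes([(10, *HOME), (2 * 1440 + 10, *HOME)])
        feat = mb.percent_time_at_home(
            stays, self._home(), (0, 3), TSTART, fixes=fixes
        )
        assert feat.missing_days == 2


class TestAppUseLocationContext:
    def test_session_inside_home_stay(self):
        stays = stays_from_minutes([("home", 0, 600)])
        ses = sessions_from_minutes([(100, 110, 10.0)])
        ctx = mb.app_use_location_context(ses, stays, mb.HomeModel("p1", "home", 1), TSTART)
        assert ctx[0] == pytest.approx(100.0)

    def test_session_half_home_half_away(self):
        stays = stays_from_minutes([("home", 0, 100), ("away", 100, 200)])
        ses = sessions_from_minutes([(90, 110, 20.0)])
        ctx = mb.app_use_location_context(ses, stays, mb.HomeModel("p1", "home", 1), TSTART)
        assert ctx[0] == pytest.approx(50.0)

    def test_session_with_no_concurrent_stay_is_excluded(self):
        stays = stays_from_minutes([("home", 0, 50)])
        ses = sessions_from_minutes([(1000, 1010, 10.0)])
        ctx = mb.app_use_location_context(ses, stays, mb.HomeModel("p1", "home", 1), TSTART)
        assert math.isnan(ctx[0])


class TestGpsMissingness:
    def test_fixes_every_day(self):
        fx = fixes_from_minutes([(d * 1440.0 + 60, *HOME) for d in range(10)])
        assert mb.gps_missingness(fx, TSTART, 10) == (0, 0.0)

    def test_no_fixes(self):
        assert mb.gps_missingness(fixes_from_minutes([]), TSTART, 10) == (10, 1.0)

    def test_planted_pattern_recovered_exactly(self):
        present = [0, 2, 3, 7, 9]
        fx = fixes_from_minutes([(d * 1440.0 + 5, *HOME) for d in present])
        missing, frac = mb.gps_missingness(fx, TSTART, 10)
        assert missing == 5 and frac == 0.5
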