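"""Trajectory statistics: linking, speed, MSD, power-law fits, dwell stats."""

import math

import numpy as np
import pytest

from conftest import make_track, random_walk_tracks, straight_track
from nkpatrol import track_analysis as ta


def det(frame, pos, t=None, label="nk"):
    return ta.Detection(
        frame_index=frame,
        time=frame * 0.5 if t is None else t,
        position=np.asarray(pos, dtype=float),
        class_label=label,
    )


# ---------------------------------------------------------------------------
# linking


class TestLinking:
    def test_consecutive_within_threshold_linked(self):
        tracks = ta.link_detections([det(0, [0, 0, 0]), det(1, [20, 0, 0])])
        assert len(tracks) == 1
        assert tracks[0].n_samples == 2

    def test_beyond_threshold_discarded(self):
        tracks = ta.link_detections([det(0, [0, 0, 0]), det(1, [40, 0, 0])])
        assert tracks == []

    def test_frame_gap_bridged_and_recorded(self):
        tracks = ta.link_detections([det(1, [0, 0, 0]), det(3, [15, 0, 0])])
        assert len(tracks) == 1
        assert tracks[0].gaps == [2]
        assert tracks[0].duration == pytest.approx(1.0)

    def test_gap_beyond_max_not_bridged(self):
        tracks = ta.link_detections(
            [det(0, [0, 0, 0]), det(3, [5, 0, 0])], max_frame_gap=2
        )
        assert tracks == []

    def test_conservation_on_random_detections(self, rng):
        """Every detection joins at most one track; total linked samples
        never exceed the detection count."""
        detections = [
            det(f, rng.uniform(0, 100, size=3)) for f in range(20) for _ in range(8)
        ]
        tracks = ta.link_detections(detections, max_distance=25.0)
        total = sum(tr.n_samples for tr in tracks)
        assert total <= len(detections)
        # sample positions must each correspond to a distinct detection
        used = set()
        all_pos = {tuple(d.position): i for i, d in enumerate(detections)}
        for tr in tracks:
            for p in tr.positions:
                key = tuple(p)
                assert key in all_pos
                assert (key, all_pos[key]) not in used
                used.add((key, all_pos[key]))

    def test_inconsistent_frame_timing_rejected(self):
        bad = [det(0, [0, 0, 0], t=0.0), det(0, [5, 0, 0], t=0.3)]
        with pytest.raises(ValueError, match="frame timing"):
            ta.link_detections(bad)


# ---------------------------------------------------------------------------
# instantaneous speed


class TestSpeed:
    def test_constant_velocity(self):
        track = straight_track(4.8, n_samples=12)
        speeds = ta.instantaneous_speed(track, dt=0.5)
        assert speeds == pytest.approx(np.full(11, 4.8))

    def test_stationary(self):
        track = make_track(np.zeros((8, 3)))
        assert ta.instantaneous_speed(track) == pytest.approx(np.zeros(7))

    def test_matches_brute_force_on_random_walks(self, rng):
        tracks = random_walk_tracks(rng, n_tracks=100, n_steps=30)
        for tr in tracks:
            fast = ta.instantaneous_speed(tr, dt=0.5)
            slow = [
                np.linalg.norm(tr.positions[i + 1] - tr.positions[i]) / 0.5
                for i in range(tr.n_samples - 1)
            ]
            assert fast == pytest.approx(np.asarray(slow))

    def test_gap_bridging_pairs_skipped(self):
        # samples at frames 0,1,3: the 1->3 step spans a gap
        track = ta.Track(
            track_id="g",
            cell_class="nk",
            times=np.array([0.0, 0.5, 1.5]),
            positions=np.array([[0, 0, 0], [1, 0, 0], [9, 0, 0]], float),
            gaps=[2],
        )
        speeds = ta.instantaneous_speed(track, dt=0.5)
        assert speeds == pytest.approx([2.0])  # only the 0->1 pair

    def test_dt_must_be_frame_multiple(self):
        with pytest.raises(ValueError, match="multiple"):
            ta.instantaneous_speed(straight_track(1.0), dt=0.3)


# ---------------------------------------------------------------------------
# MSD


def brute_force_msd(tracks, max_lag, dt=0.5):
    """Naive double loop over time origins and lags."""
    max_k = int(max_lag / dt)
    sums = np.zeros(max_k + 1)
    counts = np.zeros(max_k + 1)
    for tr in tracks:
        idx = tr.frame_indices()
        lookup = dict(zip(idx, range(len(idx))))
        for k in range(1, max_k + 1):
            for i0 in idx:
                if i0 + k in lookup and i0 in lookup:
                    d = tr.positions[lookup[i0 + k]] - tr.positions[lookup[i0]]
                    sums[k] += d @ d
                    counts[k] += 1
    lags, msd = [0.0], [0.0]
    for k in range(1, max_k + 1):
        if counts[k]:
            lags.append(k * dt)
            msd.append(sums[k] / counts[k])
    return np.array(lags), np.array(msd)


class TestMSD:
    def test_static_track_zero_everywhere(self):
        curve = ta.ensemble_msd([make_track(np.zeros((20, 3)))], max_lag=5)
        assert curve.msd_values == pytest.approx(np.zeros(len(curve.lags)))
        assert curve.lags[0] == 0.0

    def test_ballistic_track_quadratic(self):
        v = 3.0
        curve = ta.ensemble_msd([straight_track(v, n_samples=40)], max_lag=10)
        assert curve.msd_values == pytest.approx(v**2 * curve.lags**2, rel=1e-12)

    def test_matches_brute_force_and_brownian_closed_form(self, rng):
        D = 2.0  # µm²/min
        dt = 0.5
        tracks = []
        for i in range(200):
            steps = rng.normal(0, math.sqrt(2 * D * dt), size=(60, 3))
            pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
            tracks.append(make_track(pos, track_id=f"b{i}"))
        curve = ta.ensemble_msd(tracks, max_lag=10.0)
        lags_bf, msd_bf = brute_force_msd(tracks, max_lag=10.0)
        assert curve.lags == pytest.approx(lags_bf)
        assert curve.msd_values == pytest.approx(msd_bf, rel=1e-10)
        # 3D Brownian motion: MSD = 6 D tau
        mask = curve.lags > 0
        assert curve.msd_values[mask] == pytest.approx(
            6 * D * curve.lags[mask], rel=0.15
        )

    def test_first_origin_mode_matches_literal_definition(self, rng):
        tracks = random_walk_tracks(rng, n_tracks=30, n_steps=25)
        curve = ta.ensemble_msd(tracks, max_lag=8.0, origins="first")
        for lag, msd in zip(curve.lags[1:], curve.msd_values[1:]):
            k = int(round(lag / 0.5))
            sq = [
                np.sum((tr.positions[k] - tr.positions[0]) ** 2)
                for tr in tracks
                if tr.n_samples > k
            ]
            assert msd == pytest.approx(np.mean(sq), rel=1e-10)

    def test_empty_track_list_rejected(self):
        with pytest.raises(ValueError):
            ta.ensemble_msd([])


class TestPowerLawFit:
    def test_linear_msd_exact(self):
        lags = np.arange(0, 21) * 0.5
        curve = ta.MSDCurve(lags, 4.0 * lags, np.ones_like(lags), np.ones_like(lags))
        fit = ta.fit_msd_powerlaw(curve)
        assert fit.alpha == pytest.approx(1.0, abs=1e-6)
        assert fit.prefactor == pytest.approx(4.0, abs=1e-6)

    @pytest.mark.parametrize("alpha", [0.56, 1.0, 2.0])
    def test_exact_power_law_recovered(self, alpha):
        lags = np.arange(0, 101) * 0.5
        curve = ta.MSDCurve(
            lags, 2.5 * lags**alpha, np.ones_like(lags), np.ones_like(lags)
        )
        fit = ta.fit_msd_powerlaw(curve)
        assert fit.alpha == pytest.approx(alpha, abs=1e-6)

    def test_window_restriction(self):
        lags = np.arange(0, 101) * 0.5
        msd = 2.0 * lags**0.7
        msd[lags > 20] = 5.0  # corrupt outside the window
        curve = ta.MSDCurve(lags, msd, np.ones_like(lags), np.ones_like(lags))
        fit = ta.fit_msd_powerlaw(curve, fit_window=(0.5, 20.0))
        assert fit.alpha == pytest.approx(0.7, abs=1e-6)
        assert fit.fit_window == (0.5, 20.0)

    def test_too_few_points_rejected(self):
        curve = ta.MSDCurve(
            np.array([0.0, 0.5, 1.0]),
            np.array([0.0, 1.0, 2.0]),
            np.ones(3),
            np.ones(3),
        )
        with pytest.raises(ValueError):
            ta.fit_msd_powerlaw(curve)


# ---------------------------------------------------------------------------
# crawl durations


class TestCrawlDurations:
    def test_median_of_three(self):
        tracks = [
            make_track(np.zeros((n + 1, 3)), dt=1.0, track_id=f"d{n}")
            for n in (1, 2, 3)
        ]
        stats = ta.crawl_duration_stats(tracks)
        assert stats.median_min == pytest.approx(2.0)

    def test_exponential_sample_recovery(self, rng):
        """1000 exponential dwells with median 2.5 min: sample median and
        ln2/rate both within 10% of the generator median."""
        median = 2.5
        durations = rng.exponential(median / math.log(2), size=1000)
        tracks = [
            ta.Track(
                track_id=f"e{i}",
                cell_class="nk",
                times=np.array([0.0, d]),
                positions=np.zeros((2, 3)),
            )
            for i, d in enumerate(durations)
        ]
        stats = ta.crawl_duration_stats(tracks)
        assert stats.median_min == pytest.approx(median, rel=0.10)
        assert stats.exp_median_min == pytest.approx(median, rel=0.10)

    def test_equal_durations(self):
        tracks = [make_track(np.zeros((5, 3)), track_id=f"c{i}") for i in range(4)]
        stats = ta.crawl_duration_stats(tracks)
        assert stats.median_min == pytest.approx(2.0)
        assert stats.rate_per_min == pytest.approx(0.5)

    def test_censored_excluded_by_default(self):
        short = make_track(np.zeros((3, 3)), track_id="s")
        long = make_track(np.zeros((100, 3)), track_id="l", censored=True)
        stats = ta.crawl_duration_stats([short, long])
        assert stats.n_censored == 1
        assert stats.median_min == pytest.approx(1.0)

    def test_detection_floor_corrects_left_truncation(self, rng):
        """Dropping dwells below the floor and shifting survivors leaves the
        floor-corrected MLE unbiased."""
        median, floor = 2.5, 0.25
        raw = rng.exponential(median / math.log(2), size=4000)
        observed = raw[raw > floor]
        tracks = [
            ta.Track(
                track_id=f"f{i}",
                cell_class="nk",
                times=np.array([0.0, d]),
                positions=np.zeros((2, 3)),
            )
            for i, d in enumerate(observed)
        ]
        stats = ta.crawl_duration_stats(tracks, detection_floor=floor)
        assert stats.exp_median_min == pytest.approx(median, rel=0.07)


# ---------------------------------------------------------------------------
# I/O


def test_track_table_round_trip(tmp_path, rng):
    tracks = random_walk_tracks(rng, n_tracks=5, n_steps=20)
    # introduce a gap in one track
    t0 = tracks[0]
    keep = np.r_[0:5, 6:21]
    tracks[0] = ta.Track(
        track_id=t0.track_id,
        cell_class="nk",
        times=t0.times[keep],
        positions=t0.positions[keep],
        gaps=[5],
    )
    path = tmp_path / "tracks.tsv"
    ta.write_tracks(tracks, path)
    back = ta.read_tracks(path)
    assert len(back) == len(tracks)
    by_id = {tr.track_id: tr for tr in back}
    for tr in tracks:
        got = by_id[tr.track_id]
        assert got.times == pytest.approx(tr.times)
        assert got.positions == pytest.approx(tr.positions)
        assert got.gaps == tr.gaps
    # tracks reaching the movie's last frame are flagged censored
    assert all(by_id[tr.track_id].censored for tr in tracks[1:])
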