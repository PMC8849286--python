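"""Generators: determinism, network geometry, patrol round trips, kinetics."""

import math

import numpy as np
import pytest
from scipy import stats

from nkpatrol import bli_decay as bd
from nkpatrol import encounter_stats as es
from nkpatrol import synthetic, track_analysis as ta


def small_config(seed=0, **nk_overrides):
    cfg = synthetic.SimConfig(seed=seed, duration_min=60.0, n_movies=1)
    for key, value in nk_overrides.items():
        setattr(cfg.nk, key, value)
    return cfg


# ---------------------------------------------------------------------------
# configuration loading


class TestConfig:
    def test_unknown_top_level_key_named(self):
        with pytest.raises(ValueError, match="bogus"):
            synthetic.load_sim_config({"bogus": 1})

    def test_unknown_nested_key_named(self):
        with pytest.raises(ValueError, match="nk.bogus"):
            synthetic.load_sim_config({"nk": {"bogus": 1}})

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="p_erk_given_contact"):
            synthetic.load_sim_config({"outcomes": {"p_erk_given_contact": 1.5}})

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "duration_min: 45\nnk:\n  crawl_dwell_median_min: 2.5\nseed: 9\n"
        )
        cfg = synthetic.load_sim_config(path)
        assert cfg.duration_min == 45
        assert cfg.nk.crawl_dwell_median_min == 2.5
        assert cfg.outcomes.p_erk_given_contact == 0.68  # defaults retained


# ---------------------------------------------------------------------------
# capillary network


class TestNetwork:
    def test_deterministic_per_seed(self):
        cfg = small_config()
        g1 = synthetic.build_capillary_network(cfg, seed=7)
        g2 = synthetic.build_capillary_network(cfg, seed=7)
        assert sorted(g1.edges) == sorted(g2.edges)
        for n in g1.nodes:
            assert g1.nodes[n]["pos"] == pytest.approx(g2.nodes[n]["pos"])

    def test_degenerate_radius_raises(self):
        cfg = small_config()
        cfg.network.connection_radius_um = 1e-6
        with pytest.raises(ValueError, match="degenerate"):
            synthetic.build_capillary_network(cfg, seed=0)

    def test_no_dead_end_branches_by_default(self):
        g = synthetic.build_capillary_network(small_config(), seed=3)
        assert min(dict(g.degree).values()) >= 2

    def test_mean_total_length_matches_pair_sampling_expectation(self):
        """Monte-Carlo oracle: E[total edge length] of the unpruned graph is
        n(n-1)/2 * E[d * 1(d <= r)] over uniform point pairs in the slab."""
        cfg = small_config()
        cfg.network.n_nodes = 150
        cfg.network.connection_radius_um = 120.0
        rng = np.random.default_rng(99)
        box = np.array([cfg.fov_side_um, cfg.fov_side_um, cfg.slab_depth_um])
        a = rng.uniform(0, 1, size=(200_000, 3)) * box
        b = rng.uniform(0, 1, size=(200_000, 3)) * box
        d = np.linalg.norm(a - b, axis=1)
        n = cfg.network.n_nodes
        expected = n * (n - 1) / 2 * np.mean(
            np.where(d <= cfg.network.connection_radius_um, d, 0.0)
        )
        totals = [
            synthetic.total_edge_length(
                synthetic.build_capillary_network(cfg, seed=s, prune_dead_ends=False)
            )
            for s in range(100)
        ]
        assert np.mean(totals) == pytest.approx(expected, rel=0.10)


# ---------------------------------------------------------------------------
# patrol simulation


class TestPatrol:
    def test_bit_identical_outputs_per_seed(self):
        cfg = small_config(seed=5)
        net = synthetic.build_capillary_network(cfg, seed=5)
        r1 = synthetic.simulate_patrol(net, cfg, seed=11)
        r2 = synthetic.simulate_patrol(net, cfg, seed=11)
        assert len(r1.nk_tracks) == len(r2.nk_tracks)
        for a, b in zip(r1.nk_tracks, r2.nk_tracks):
            assert np.array_equal(a.positions, b.positions)
        assert [e.event_id for e in r1.events] == [e.event_id for e in r2.events]
        assert r1.ground_truth.survival_times_min == r2.ground_truth.survival_times_min

    def test_zero_activation_probability_no_deaths(self):
        cfg = small_config(seed=2)
        cfg.outcomes.p_erk_given_contact = 0.0
        net = synthetic.build_capillary_network(cfg, seed=2)
        res = synthetic.simulate_patrol(net, cfg, seed=3)
        assert not any(e.erk_activated or e.ca_influx or e.tumor_died
                       for e in res.events)
        assert all(v is None for v in res.ground_truth.survival_times_min.values())
        # all tumors observable for the whole movie
        assert all(tr.duration == pytest.approx(60.0) for tr in res.tumor_tracks)

    def test_ground_truth_consistent_with_emitted_events(self):
        cfg = small_config(seed=4)
        net = synthetic.build_capillary_network(cfg, seed=4)
        res = synthetic.simulate_patrol(net, cfg, seed=6)
        nk_ids = {t.track_id for t in res.nk_tracks}
        tumor_ids = {t.track_id for t in res.tumor_tracks}
        for ev in res.events:
            assert ev.nk_track_id in nk_ids
            assert ev.tumor_id in tumor_ids
        # every recorded death has a generating contact, and the tumor track
        # ends no later than the kill time (frame-snapped)
        killed = {c["tumor_id"] for c in res.ground_truth.contacts if c["death"]}
        for tr in res.tumor_tracks:
            death = res.ground_truth.survival_times_min[tr.track_id]
            if death is not None:
                assert tr.track_id in killed
                assert tr.times[-1] <= death + 1e-9

    def test_dwell_and_speed_recovery(self):
        """Crawl-dwell median (2.5 min preset) within 10% and mean crawl
        speed within 5% on over a thousand simulated crawl episodes."""
        tracks = []
        for s in range(2):
            cfg = small_config(seed=s, crawl_dwell_median_min=2.5)
            cfg.duration_min = 120.0
            cfg.outcomes.p_erk_given_contact = 0.0
            net = synthetic.build_capillary_network(cfg, seed=s)
            res = synthetic.simulate_patrol(net, cfg, seed=100 + s)
            tracks.extend(res.nk_tracks)
        assert len(tracks) >= 1000
        stats_ = ta.crawl_duration_stats(tracks, detection_floor=0.25)
        assert stats_.exp_median_min == pytest.approx(2.5, rel=0.10)
        speeds = np.concatenate(
            [ta.instantaneous_speed(t, 0.5) for t in tracks if t.n_samples > 2]
        )
        assert speeds.mean() == pytest.approx(4.8, rel=0.05)

    def test_crawl_durations_exponential(self):
        """Emitted ground-truth dwells pass a KS test against the
        configured exponential distribution."""
        cfg = small_config(seed=8, crawl_dwell_median_min=2.5)
        cfg.duration_min = 120.0
        net = synthetic.build_capillary_network(cfg, seed=8)
        res = synthetic.simulate_patrol(net, cfg, seed=9)
        dwells = np.asarray(res.ground_truth.crawl_dwell_true_min)
        scale = 2.5 / math.log(2)
        assert stats.kstest(dwells, "expon", args=(0, scale)).pvalue > 0.01


# ---------------------------------------------------------------------------
# killing kinetics


class TestKillingKinetics:
    def test_survival_matches_closed_form(self):
        """Pooled survival times over 20 seeds pass a KS test against the
        exponential law with rate contact_rate * p_death."""
        rate, p = 0.01, 0.34
        surv = []
        for s in range(20):
            _, _, times, censored = synthetic.simulate_killing_kinetics(
                rate, p, n_tumors=50, duration=3000.0, seed=100 + s
            )
            surv.extend(times[~censored])
        res = stats.kstest(surv, "expon", args=(0, 1.0 / (rate * p)))
        assert res.pvalue > 0.01

    def test_hit_rate_estimator_on_known_rate(self):
        events, tumors, _, _ = synthetic.simulate_killing_kinetics(
            0.01, 0.0, n_tumors=50, duration=120.0, seed=7
        )
        est = es.hit_rate(events, tumors)
        n = len(events)
        ci = 2.58 * math.sqrt(n) / (50 * 120.0)
        assert abs(est - 0.01) <= ci

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_killing_kinetics(0.0, 0.5, 5, 10.0, seed=1)
        with pytest.raises(ValueError):
            synthetic.simulate_killing_kinetics(0.01, 1.5, 5, 10.0, seed=1)


# ---------------------------------------------------------------------------
# fractional tracks


class TestFractionalTracks:
    def test_msd_follows_generator_exponent(self):
        tracks = synthetic.fractional_tracks(0.5, n_tracks=300, n_steps=60, seed=3)
        curve = ta.ensemble_msd(tracks, max_lag=20.0)
        mask = curve.lags > 0
        expected = 3.0 * (curve.lags[mask] / 0.5) ** 0.5
        assert curve.msd_values[mask] == pytest.approx(expected, rel=0.10)

    def test_brownian_case_is_independent_increments(self):
        tracks = synthetic.fractional_tracks(1.0, n_tracks=200, n_steps=40, seed=4)
        incs = np.diff(np.stack([t.positions for t in tracks]), axis=1)
        flat = incs[:, :, 0]
        corr = np.corrcoef(flat[:, :-1].ravel(), flat[:, 1:].ravel())[0, 1]
        assert abs(corr) < 0.05

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            synthetic.fractional_tracks(0.0, 10, 10)


# ---------------------------------------------------------------------------
# reporters


class TestReporters:
    def _event(self, erk_lag=1.5, activated=True):
        return es.ContactEvent(
            event_id="e0",
            nk_track_id="nk_0",
            tumor_id="t_0",
            start_time=10.0,
            end_time=12.0,
            erk_activated=activated,
            erk_lag=erk_lag if activated else None,
            ca_influx=activated,
            ca_lag=4.0 if activated else None,
        )

    def test_zero_noise_round_trip(self):
        cfg = small_config()
        cfg.outcomes.reporter_noise_cv = 0.0
        series = synthetic.generate_reporter_series([self._event()], cfg, seed=1)
        fret = next(s for s in series if s.channel == "fret_ratio")
        activated, lag = es.detect_activation(fret, contact_time=10.0)
        assert activated
        assert lag == pytest.approx(1.5)
        gcamp = next(s for s in series if s.channel == "gcamp")
        ca, ca_lag = es.detect_activation(gcamp, contact_time=10.0, window=8.0)
        assert ca and ca_lag == pytest.approx(4.0)

    def test_subthreshold_amplitude_not_detected(self):
        cfg = small_config()
        cfg.outcomes.reporter_noise_cv = 0.0
        cfg.outcomes.reporter_step_amplitude = 0.20  # below the 30% threshold
        series = synthetic.generate_reporter_series([self._event()], cfg, seed=1)
        fret = next(s for s in series if s.channel == "fret_ratio")
        activated, _ = es.detect_activation(fret, contact_time=10.0)
        assert not activated

    def test_inactive_cells_get_flat_series(self):
        cfg = small_config()
        cfg.outcomes.reporter_noise_cv = 0.0
        series = synthetic.generate_reporter_series(
            [self._event(activated=False)], cfg, seed=1
        )
        for s in series:
            assert s.values == pytest.approx(np.ones(len(s.values)))


# ---------------------------------------------------------------------------
# bioluminescence


class TestSimulatedBLI:
    def test_noiseless_round_trip(self):
        cfg = small_config()
        cfg.bli.noise_cv = 0.0
        series = synthetic.simulate_bli(cfg, seed=1)
        norm = bd.normalize_bli(series[0])
        assert bd.fit_decay_powerlaw(norm) == pytest.approx(1.45, abs=1e-9)
        assert bd.nadir_time(norm) == 24.0
        growth = bd.doubling_time(norm, window=(24.0, 96.0))
        assert growth == pytest.approx(24.0, rel=1e-9)

    def test_noisy_half_life_centred(self):
        """100 noisy replicates: the fitted half-life distribution centres
        within 5% of the noiseless value."""
        cfg = small_config()
        cfg.bli.noise_cv = 0.05
        cfg.bli.n_animals = 100
        series = synthetic.simulate_bli(cfg, seed=2)
        hl = [
            bd.half_life_at(bd.fit_decay_powerlaw(bd.normalize_bli(s)), 4.0)
            for s in series
        ]
        noiseless = bd.half_life_at(1.45, 4.0)
        assert np.mean(hl) == pytest.approx(noiseless, rel=0.05)

    def test_deterministic_per_seed(self):
        cfg = small_config()
        a = synthetic.simulate_bli(cfg, seed=5)
        b = synthetic.simulate_bli(cfg, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.intensities, y.intensities)
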