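"""Synthetic-experiment generator: contracts and planted ground truth."""

import numpy as np
import pytest

from gazeforge.clustering import gaze_cv
from gazeforge.salience import PHASES, ConfigError
from gazeforge.synth import (
    SynthConfig,
    frame_points_in,
    generate_dataset,
    generate_edge_truth,
    generate_frame_points,
    generate_gaze,
    generate_latents,
    generate_performance,
    generate_phase_track,
    generate_presses,
    generate_template,
)


class TestPhaseTrack:
    def test_degenerate_spec_labels_everything_one_phase(self):
        cfg = SynthConfig(phase_segment_spec={"core_move": (1.0, 5.0)})
        track = generate_phase_track(cfg)
        assert set(track.labels) == {"core_move"}

    def test_default_duration_is_1024_seconds(self):
        assert generate_phase_track(SynthConfig()).duration_s == 1024

    def test_same_seed_same_track(self):
        a = generate_phase_track(SynthConfig(seed=5))
        b = generate_phase_track(SynthConfig(seed=5))
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_labels_from_closed_vocabulary(self):
        track = generate_phase_track(SynthConfig(seed=2))
        assert set(track.labels) <= set(PHASES)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ConfigError, match="somersault"):
            generate_phase_track(
                SynthConfig(phase_segment_spec={"somersault": (1.0, 5.0)})
            )


class TestPresses:
    def test_certain_immediate_presses_sit_on_onsets(self):
        cfg = SynthConfig(
            n_subjects=4, video_duration_s=256, seed=1,
            press_response_prob=1.0, press_lag_mean_s=0.0, press_lag_sd_s=0.0,
            press_background_rate_hz=0.0,
        )
        track = generate_phase_track(cfg)
        onsets = track.onsets("core_move")
        for log in generate_presses(cfg, track):
            np.testing.assert_allclose(np.sort(log.latencies), np.sort(onsets))

    def test_no_response_no_background_gives_empty_logs(self):
        cfg = SynthConfig(
            n_subjects=3, video_duration_s=128, press_response_prob=0.0,
            press_background_rate_hz=0.0,
        )
        track = generate_phase_track(cfg)
        assert all(len(l.latencies) == 0 for l in generate_presses(cfg, track))

    def test_mean_responders_per_event_matches_binomial(self):
        """Empirical responders per salient event vs the binomial expectation
        p*S, within 3 standard errors over >= 500 events."""
        p, S = 0.6, 10
        cfg = SynthConfig(
            n_subjects=S, video_duration_s=1024, seed=9,
            press_response_prob=p, press_lag_sd_s=0.1,
            press_background_rate_hz=0.0,
            phase_segment_spec={"core_move": (0.5, 2.0), "grinding": (0.5, 2.0)},
        )
        track = generate_phase_track(cfg)
        onsets = track.onsets("core_move")
        logs = generate_presses(cfg, track)
        responders = []
        for session in cfg.session_labels:
            session_logs = [l for l in logs if l.session == session]
            for onset in onsets:
                # presses land at onset + lag (lag ~ N(1.0, 0.1)); neighbouring
                # onsets are >= 2 s away, so a +-0.45 s window is unambiguous
                responders.append(
                    sum(
                        np.any(np.abs(l.latencies - (onset + 1.0)) < 0.45)
                        for l in session_logs
                    )
                )
        n_events = len(responders)
        assert n_events >= 500
        se = np.sqrt(S * p * (1 - p) / n_events)
        assert abs(np.mean(responders) - p * S) < 3 * se

    def test_latencies_inside_video(self):
        cfg = SynthConfig(n_subjects=3, video_duration_s=128, seed=4)
        track = generate_phase_track(cfg)
        for log in generate_presses(cfg, track):
            assert ((log.latencies >= 0) & (log.latencies <= 128)).all()


class TestGaze:
    def test_noiseless_limit_tracks_edge_exactly(self):
        cfg = SynthConfig(
            n_subjects=1, video_duration_s=64, seed=3,
            gaze_jitter_sd=0.0,
            edge_offset_sd_by_session=(0.0, 0.0, 0.0),
            gaze_cv_by_session=(0.0, 0.0, 0.0),  # calibration yields no glances
            phase_segment_spec={"core_move": (1.0, 8.0)},
        )
        track = generate_phase_track(cfg)
        edge = generate_edge_truth(cfg, track)
        stream = generate_gaze(cfg, track, edge)[0]
        t = stream.samples["t_s"].to_numpy()
        expected = np.interp(t, edge["t_s"], edge["edge_x"])
        np.testing.assert_allclose(stream.samples["x"], expected, atol=1e-12)

    def test_fixation_jitter_sd_matches_configuration(self):
        sigma = 0.02
        cfg = SynthConfig(
            n_subjects=1, video_duration_s=200, seed=6,
            gaze_jitter_sd=sigma,
            edge_offset_sd_by_session=(0.0, 0.0, 0.0),
            gaze_cv_by_session=(0.0, 0.0, 0.0),
            edge_drift_amp=0.0, pose_sd=0.0,  # constant anchor
            phase_segment_spec={"core_move": (1.0, 8.0)},
        )
        track = generate_phase_track(cfg)
        edge = generate_edge_truth(cfg, track)
        stream = generate_gaze(cfg, track, edge)[0]
        x = stream.samples["x"].to_numpy()
        assert len(x) == 12000
        assert np.std(x, ddof=1) == pytest.approx(sigma, rel=0.10)

    def test_session_cv_profile_ordered_over_twenty_subjects(self):
        """With CV targets (0.30, 0.15, 0.15) the measured per-window CV is
        ordered Pre above both post-training sessions, which sit together."""
        cfg = SynthConfig(
            n_subjects=20, video_duration_s=512, seed=1,
            gaze_cv_by_session=(0.30, 0.15, 0.15),
        )
        track = generate_phase_track(cfg)
        edge = generate_edge_truth(cfg, track)
        streams = generate_gaze(cfg, track, edge)
        segs = [
            (s, e) for s, e, p in track.segments() if p == "core_move"
        ][:20]
        cv = {}
        for sess in cfg.session_labels:
            vals = [
                gaze_cv(st, seg).cv
                for st in streams if st.session == sess
                for seg in segs
            ]
            cv[sess] = np.mean(vals)
        assert cv["Pre"] > cv["Post1"]
        assert cv["Pre"] > cv["Post2"]
        assert abs(cv["Post1"] - cv["Post2"]) < 0.05

    def test_gaze_coordinates_clipped_to_unit_square(self, small_cfg):
        track = generate_phase_track(small_cfg)
        edge = generate_edge_truth(small_cfg, track)
        for stream in generate_gaze(small_cfg, track, edge)[:3]:
            s = stream.samples
            assert s["x"].between(0, 1).all() and s["y"].between(0, 1).all()


class TestPerformance:
    def test_zero_coupling_decorrelates_latents(self):
        cfg = SynthConfig(n_subjects=200, latent_coupling=0.0, seed=21)
        lat = generate_latents(cfg)
        r = np.corrcoef(lat["aptitude"], lat["gaze_param"])[0, 1]
        assert abs(r) < 0.2

    def test_planted_coupling_recovered(self):
        cfg = SynthConfig(n_subjects=200, latent_coupling=0.8, seed=22)
        lat = generate_latents(cfg)
        r = np.corrcoef(lat["aptitude"], lat["gaze_param"])[0, 1]
        assert 0.7 <= r <= 0.9

    def test_zero_rate_flat_scores(self):
        cfg = SynthConfig(n_subjects=5, perf_rate=0.0, perf_noise_sd=0.0, seed=2)
        perf = generate_performance(cfg)
        for _, grp in perf.groupby("subject"):
            assert grp["handaxe_score"].nunique() == 1

    def test_scores_rise_and_errors_fall_across_sessions(self):
        perf = generate_performance(SynthConfig(n_subjects=50, seed=8))
        means = perf.groupby("session", sort=False)[
            ["handaxe_score", "percussion_error"]
        ].mean()
        assert (
            means.loc["Pre", "handaxe_score"]
            < means.loc["Post1", "handaxe_score"]
            <= means.loc["Post2", "handaxe_score"] + 0.5
        )
        assert (
            means.loc["Pre", "percussion_error"]
            > means.loc["Post1", "percussion_error"]
            > means.loc["Post2", "percussion_error"]
        )


class TestEdgeTruthAndFrames:
    def test_edge_in_unit_interval_and_30fps(self, small_cfg):
        track = generate_phase_track(small_cfg)
        edge = generate_edge_truth(small_cfg, track)
        assert len(edge) == int(256 * 30)
        assert edge["edge_x"].between(0, 1).all()

    def test_template_box_xmax_lands_on_true_edge(self, small_cfg):
        track = generate_phase_track(small_cfg)
        edge = generate_edge_truth(small_cfg, track)
        tpl = generate_template(small_cfg)
        cfg = small_cfg
        cfg.feature_jitter_sd = 0.0
        pts = generate_frame_points(cfg, edge, tpl)
        n_tpl = tpl.points.shape[0]
        xmax_per_frame = pts[:, :n_tpl, 0].max(axis=1)
        np.testing.assert_allclose(
            xmax_per_frame, edge["edge_x"], atol=1e-12
        )

    def test_outlier_fraction_respected(self, small_cfg):
        track = generate_phase_track(small_cfg)
        edge = generate_edge_truth(small_cfg, track)
        tpl = generate_template(small_cfg)
        pts = generate_frame_points(small_cfg, edge, tpl)
        n_total = pts.shape[1]
        n_out = n_total - tpl.points.shape[0]
        assert n_out / n_total == pytest.approx(small_cfg.outlier_frac, abs=0.05)

    def test_frame_points_interval_restriction(self, small_cfg):
        track = generate_phase_track(small_cfg)
        edge = generate_edge_truth(small_cfg, track)
        tpl = generate_template(small_cfg)
        pts = generate_frame_points(small_cfg, edge, tpl)
        import pandas as pd

        intervals = pd.DataFrame({"start_s": [10.0], "end_s": [12.0]})
        frames = frame_points_in(pts, edge, intervals)
        assert len(frames) == 60
        assert all(10.0 <= f.t_s < 12.0 for f in frames)


class TestDatasetPurity:
    def test_same_seed_bit_identical_dataset(self):
        cfg = SynthConfig(n_subjects=3, video_duration_s=64, seed=17)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        np.testing.assert_array_equal(a.phase_track.labels, b.phase_track.labels)
        np.testing.assert_array_equal(a.frame_points, b.frame_points)
        for sa, sb in zip(a.gaze_streams, b.gaze_streams):
            np.testing.assert_array_equal(
                sa.samples.to_numpy(), sb.samples.to_numpy()
            )
        assert a.performance.equals(b.performance)
        for la, lb in zip(a.press_logs, b.press_logs):
            np.testing.assert_array_equal(la.latencies, lb.latencies)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            SynthConfig(press_response_prob=1.5).validate()

    def test_session_profile_length_mismatch_rejected(self):
        with pytest.raises(ConfigError, match="gaze_cv_by_session"):
            SynthConfig(gaze_cv_by_session=(0.3, 0.2)).validate()
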