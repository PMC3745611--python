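"""Synthetic session generator: schedules, kinematics, noise, closure."""

import numpy as np
import pytest

from gazekit import (
    CalibrationModel,
    CalibrationSample,
    DetectionParams,
    FilterSpec,
    SimConfig,
    detect_events,
    fit_calibration,
    make_schedule,
    read_recording,
    simulate_session,
    synth_feature_stream,
    synth_image_sequence,
    synth_trace,
    write_recording,
)
from gazekit.calibration import apply_calibration
from gazekit.imaging import ImagingConfig, RenderConfig, extract_features
from gazekit.simulator import Kinematics, grid_positions


class TestSchedule:
    def test_gapoverlap_block_balance(self):
        """Each of the 5 gap offsets appears 4 times in a 20-trial block."""
        cfg = SimConfig(seed=1, task="gapoverlap", n_blocks=1)
        sched = make_schedule(cfg)
        conds = [s.condition for s in sched]
        assert len(sched) == 20
        for g in (-200, -100, 0, 100, 200):
            assert conds.count(f"gap{g:+d}") == 4

    def test_antisaccade_direction_balance(self):
        """Each of the 4 directions appears 5 times within a block."""
        cfg = SimConfig(seed=2, task="antisaccade", n_blocks=2)
        sched = make_schedule(cfg)
        for block in (sched[:20], sched[20:]):
            axes = [tuple(np.sign(s.target_pos)) for s in block]
            for d in [(1, 0), (-1, 0), (0, 1), (0, -1)]:
                assert axes.count(d) == 5
        # anti blocks aim at the mirror position, pro blocks at the target
        for s in sched:
            expected = (
                (-s.target_pos[0], -s.target_pos[1])
                if s.condition == "anti"
                else s.target_pos
            )
            assert s.goal_pos == expected

    def test_same_seed_identical_schedule(self):
        a = make_schedule(SimConfig(seed=5))
        b = make_schedule(SimConfig(seed=5))
        assert a == b

    def test_grid_task_geometry(self):
        nodes = grid_positions(6, 2.7)
        assert len(nodes) == 36
        xs = sorted({p[0] for p in nodes})
        assert np.allclose(np.diff(xs), 2.7)
        assert np.isclose(np.mean([p[0] for p in nodes]), 0.0)
        sched = make_schedule(SimConfig(seed=3, task="grid", n_blocks=1))
        assert all(len(s.jumps) == 10 for s in sched)
        for s in sched:  # nodes in one trial never repeat
            visited = [s.target_pos] + [p for _, p in s.jumps]
            assert len(set(visited)) == len(visited)


class TestTrace:
    def _sched(self, cfg):
        return make_schedule(cfg)[0]

    def test_degenerate_config_is_exact(self):
        """No noise/jitter/drops: trace is piecewise-analytic, onset exact."""
        cfg = SimConfig(seed=7, fixation_noise_sd=0.0)
        sched = self._sched(cfg)
        trial, truth = synth_trace(sched, cfg, np.random.default_rng(0))
        pre = trial.t < truth.saccade_onset_ms
        post = trial.t > truth.saccade_offset_ms
        assert np.all(trial.x[pre] == 0.0) and np.all(trial.y[pre] == 0.0)
        assert np.allclose(
            np.hypot(trial.x[post] - sched.goal_pos[0], trial.y[post] - sched.goal_pos[1]),
            0.0,
            atol=1e-12,
        )

    def test_peak_velocity_closed_form(self):
        """Numeric peak speed of the profile matches 2·amp/D within 1%."""
        kin = Kinematics()
        amp = 4.2
        D = kin.duration_ms(amp)
        tau = np.linspace(0, 1, 20001)
        s = kin.displacement(amp, tau)
        v_num = np.max(np.diff(s) / np.diff(tau * D / 1000.0))
        assert v_num == pytest.approx(kin.peak_velocity(amp), rel=0.01)

    def test_frame_drop_rate(self):
        """Dropped fraction within 3 binomial SEs of the configured rate."""
        p = 0.01
        cfg = SimConfig(seed=9, task="grid", frame_drop_prob=p, n_blocks=1,
                        trials_per_block=20, fixation_noise_sd=0.0)
        rec, _ = simulate_session(cfg)
        dt = 1000.0 / cfg.nominal_rate
        n_emitted = sum(len(tr) for tr in rec.trials)
        n_planned = sum(int(np.round(tr.t[-1] / dt)) + 1 for tr in rec.trials)
        frac = 1 - n_emitted / n_planned
        se = np.sqrt(p * (1 - p) / n_planned)
        assert abs(frac - p) < 3 * se

    def test_tracking_loss_contiguous_gaps(self):
        cfg = SimConfig(seed=10, gap_prob=0.005, gap_dur_ms=80.0, n_blocks=1)
        rec, _ = simulate_session(cfg)
        all_valid = np.concatenate([tr.valid for tr in rec.trials])
        assert 0 < np.sum(~all_valid) < len(all_valid) * 0.5
        # invalid samples carry no position data
        for tr in rec.trials:
            assert np.all(np.isnan(tr.x[~tr.valid]))

    def test_latency_resampled_when_overlong(self):
        cfg = SimConfig(seed=11, trial_length_ms=900.0, fixation_noise_sd=0.0)
        assert cfg.latency is not None
        cfg.latency.means = {k: 850.0 for k in cfg.latency.means}
        cfg.latency.sd = 200.0
        sched = make_schedule(cfg)[0]
        trial, truth = synth_trace(sched, cfg, np.random.default_rng(1))
        assert truth.saccade_offset_ms <= sched.end_ms


class TestDeterminismAndClosure:
    def test_bit_identical_csv_under_seed(self, tmp_path):
        cfg = dict(seed=21, task="gapoverlap", n_blocks=1,
                   timestamp_jitter_sd=0.2, frame_drop_prob=0.005, gap_prob=0.002)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_recording(simulate_session(SimConfig(**cfg))[0], p1)
        write_recording(simulate_session(SimConfig(**cfg))[0], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_emitted_files_pass_validation(self, tmp_path):
        cfg = SimConfig(seed=22, n_blocks=1, timestamp_jitter_sd=0.3,
                        frame_drop_prob=0.01, gap_prob=0.001)
        rec, truths = simulate_session(cfg)
        path = tmp_path / "rec.csv"
        write_recording(rec, path)
        rec2 = read_recording(path)
        assert len(rec2.trials) == len(truths) == 20
        for tr, tr2 in zip(rec.trials, rec2.trials):
            assert tr.messages == tr2.messages

    def test_detection_recovers_injected_saccades(self):
        cfg = SimConfig(seed=23, task="antisaccade", n_blocks=1, nominal_rate=500.0)
        rec, truths = simulate_session(cfg)
        ok = 0
        for tr, truth in zip(rec.trials, truths):
            ev = detect_events(tr, DetectionParams(), filter_spec=FilterSpec(60.0))
            hits = [
                s for s in ev.saccades
                if abs(s.onset_ms - truth.saccade_onset_ms) <= 14.0
                and abs(s.amplitude_deg - truth.amplitude_deg) <= 0.3
            ]
            ok += bool(hits)
        assert ok >= 19  # at least 95% of 20 trials


class TestFeatureSpace:
    def test_identity_model_passthrough(self):
        cfg = SimConfig(seed=31, n_blocks=1, fixation_noise_sd=0.0)
        trial, _ = synth_trace(make_schedule(cfg)[0], cfg, np.random.default_rng(0))
        ident = CalibrationModel(1, 0, 0, 0, 1, 0)
        U, V = synth_feature_stream(trial, ident)
        np.testing.assert_allclose(U, trial.x, atol=1e-12)
        np.testing.assert_allclose(V, trial.y, atol=1e-12)

    def test_fit_apply_roundtrip(self):
        """Features from a random model, refit, reproduce the trace to 1e-6°."""
        rng = np.random.default_rng(32)
        cfg = SimConfig(seed=32, n_blocks=1)
        trial, _ = synth_trace(make_schedule(cfg)[0], cfg, rng)
        true = CalibrationModel(0.12, 0.015, -1.2, -0.01, 0.11, 0.8)
        U, V = synth_feature_stream(trial, true)
        v = trial.valid
        samples = [
            CalibrationSample(t, u, vv, (x, y))
            for t, u, vv, x, y in zip(trial.t[v], U[v], V[v], trial.x[v], trial.y[v])
        ]
        model, _ = fit_calibration(samples)
        X, Y = apply_calibration(model, U[v], V[v])
        assert np.max(np.hypot(X - trial.x[v], Y - trial.y[v])) < 1e-6

    def test_singular_model_rejected(self):
        cfg = SimConfig(seed=33, n_blocks=1)
        trial, _ = synth_trace(make_schedule(cfg)[0], cfg, np.random.default_rng(0))
        singular = CalibrationModel(1, 1, 0, 1, 1, 0)
        with pytest.raises(ValueError, match="singular"):
            synth_feature_stream(trial, singular)

    def test_noise_decreases_with_n(self):
        """Pixel noise: calibration error positive and shrinking with n."""
        from gazekit.calibration import calibration_error
        from gazekit.simulator import CALIBRATION_3X3, synth_calibration_stream

        true = CalibrationModel(0.1, 0.0, 0.0, 0.0, 0.1, 0.0)
        errs = []
        for rate in (30.0, 500.0):
            rng = np.random.default_rng(34)
            stream = synth_calibration_stream(
                CALIBRATION_3X3, true, rate, fixation_noise_sd=0.0,
                pixel_noise_sd=0.5, rng=rng,
            )
            model, _ = fit_calibration(stream)
            _, overall = calibration_error(model, stream)
            coef_err = sum(
                abs(getattr(model, k) - getattr(true, k))
                for k in ("a_x", "b_x", "c_x", "a_y", "b_y", "c_y")
            )
            errs.append((overall, coef_err))
        assert errs[0][0] > 0 and errs[1][0] > 0
        assert errs[1][1] < errs[0][1]


class TestImageSequence:
    def test_constant_features_identical_frames(self):
        frames = synth_image_sequence(np.full(3, 8.0), np.full(3, 4.0))
        assert np.array_equal(frames[0], frames[1])
        assert np.array_equal(frames[1], frames[2])

    def test_feature_sweep_recovered_monotone(self):
        u_true = np.linspace(-20, 20, 21)
        frames = synth_image_sequence(u_true, np.zeros_like(u_true))
        cfg = ImagingConfig()
        u_est = []
        for f in frames:
            feat = extract_features(f, cfg)
            assert feat.ok
            u_est.append(feat.U)
        u_est = np.array(u_est)
        assert np.max(np.abs(u_est - u_true)) < 0.5
        assert np.all(np.diff(u_est) > 0)

    def test_glint_dropout_marks_frames(self):
        off = [False] * 5 + [True] * 3 + [False] * 2
        frames = synth_image_sequence(np.full(10, 8.0), np.full(10, 4.0), glint_off=off)
        cfg = ImagingConfig()
        oks = [extract_features(f, cfg).ok for f in frames]
        assert oks == [not o for o in off]
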