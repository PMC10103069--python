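"""Generator-level tests: determinism, ground-truth bookkeeping, physics."""
import numpy as np
import pytest

from pseudopupil import synthetic as syn


class TestGenFrames:
    def test_constant_trajectory_no_noise_gives_identical_frames(self):
        times = np.arange(0.0, 0.05, 0.01)
        z = np.zeros_like(times)
        traj = syn.TrajectoryGT(times=times, x=z, y=z, smooth_x=z, smooth_y=z)
        stack, px = syn.gen_frames(
            traj, syn.SceneParams(noise_sigma=0.0, seed=0))
        assert np.array_equal(stack.frames[0], stack.frames[1])
        assert np.allclose(px, px[0])

    def test_step_trajectory_moves_pixel_truth_by_exact_step(self):
        # +12 px in x with spacing 12 px and 5 deg/spacing = +5 deg step
        times = np.array([0.0, 0.01])
        x = np.array([0.0, 5.0])
        z = np.zeros_like(x)
        traj = syn.TrajectoryGT(times=times, x=x, y=z, smooth_x=x, smooth_y=z)
        _, px = syn.gen_frames(traj, syn.SceneParams(dot_spacing_px=12.0),
                               deg_per_spacing=5.0)
        assert px[1, 0] - px[0, 0] == pytest.approx(12.0, abs=1e-12)
        assert px[1, 1] == pytest.approx(px[0, 1], abs=1e-12)

    def test_same_seed_bit_identical_different_seed_noise_only(self, sine_trajectory):
        s1a, _ = syn.gen_frames(sine_trajectory, syn.SceneParams(seed=1))
        s1b, _ = syn.gen_frames(sine_trajectory, syn.SceneParams(seed=1))
        s2, _ = syn.gen_frames(sine_trajectory, syn.SceneParams(seed=2))
        clean, _ = syn.gen_frames(sine_trajectory,
                                  syn.SceneParams(noise_sigma=0.0))
        assert np.array_equal(s1a.frames, s1b.frames)
        assert not np.array_equal(s1a.frames, s2.frames)
        # the two seeds differ only in the additive noise realization
        d1 = s1a.frames - clean.frames
        d2 = s2.frames - clean.frames
        assert abs(d1.mean()) < 0.05 and abs(d2.mean()) < 0.05
        assert np.std(d1 - d2) == pytest.approx(np.sqrt(2) * 2.0, rel=0.05)

    def test_trajectory_leaving_frame_names_first_bad_sample(self):
        times = np.arange(0.0, 0.03, 0.01)
        x = np.array([0.0, 0.0, 999.0])
        z = np.zeros_like(x)
        traj = syn.TrajectoryGT(times=times, x=x, y=z, smooth_x=x, smooth_y=z)
        with pytest.raises(ValueError, match="sample 2"):
            syn.gen_frames(traj, syn.SceneParams())


class TestGenOkrTrace:
    def test_null_dynamics_gives_flat_traces(self):
        p = syn.OkrParams(gain=0.0, nystagmus_rate=0.0, noise_sigma_deg=0.0)
        left, right = syn.gen_okr_trace(p, 5.0)
        assert np.all(left.x == 0) and np.all(right.x == 0)

    def test_smooth_slope_opposes_stimulus_exactly(self):
        # gain 0.2, 15 deg/s rightward -> smooth velocity -3 deg/s
        p = syn.OkrParams(gain=0.2, stimulus_speed=15.0, nystagmus_rate=0.0,
                          noise_sigma_deg=0.0)
        _, right = syn.gen_okr_trace(p, 10.0, direction=1)
        v = np.diff(right.smooth_x) / np.diff(right.times)
        assert np.max(np.abs(v - (-3.0))) < 1e-9

    def test_unilateral_right_stimulus_leaves_left_eye_flat(self):
        p = syn.OkrParams(gain=0.2, nystagmus_rate=0.5, noise_sigma_deg=0.0,
                          laterality="right", seed=3)
        left, right = syn.gen_okr_trace(p, 10.0)
        assert np.all(left.x == 0)
        assert np.ptp(right.x) > 0

    def test_ground_truth_conservation_and_additivity(self):
        p = syn.OkrParams(gain=0.2, nystagmus_rate=0.8, noise_sigma_deg=0.02,
                          seed=11)
        _, right = syn.gen_okr_trace(p, 30.0)
        # x = smooth + sum of saccade steps at every sample
        steps = np.zeros_like(right.x)
        for ev in right.saccade_events:
            steps += syn.minimum_jerk_step(right.times, ev.onset,
                                           ev.offset - ev.onset, ev.amplitude)
        assert np.allclose(right.x, right.smooth_x + steps, atol=1e-12)
        # every event lies inside the trace, once
        onsets = [ev.onset for ev in right.saccade_events]
        assert len(onsets) == len(set(onsets))
        assert all(0 <= t <= right.times[-1] for t in onsets)

    def test_counter_saccade_peak_velocity_follows_main_sequence(self):
        p = syn.OkrParams(gain=0.2, nystagmus_rate=0.8, noise_sigma_deg=0.0,
                          k=80.0, b=0.7, seed=4)
        _, right = syn.gen_okr_trace(p, 60.0)
        assert len(right.saccade_events) >= 3
        for ev in right.saccade_events:
            dur = ev.offset - ev.onset
            vpk = syn.MIN_JERK_PEAK * abs(ev.amplitude) / dur
            assert vpk == pytest.approx(80.0 * abs(ev.amplitude) ** 0.7,
                                        rel=1e-9)


class TestGenGapSession:
    def test_zero_crossings_flat_eyes(self):
        p = syn.GapSessionParams(n_crossings=0, noise_sigma_deg=0.0,
                                 wheel_noise=0.0, duration=30.0)
        session, t_gt = syn.gen_gap_session(p)
        assert t_gt.size == 0
        assert np.all(session.left.x == 0) and np.all(session.right.x == 0)

    def test_event_list_length_matches_n_crossings(self):
        session, t_gt = syn.gen_gap_session(
            syn.GapSessionParams(n_crossings=5, seed=1))
        assert t_gt.size == 5
        assert np.all(np.diff(t_gt) > 0)
        assert np.all((t_gt > 0) & (t_gt < session.times[-1]))

    def test_vergence_event_is_mirror_symmetric_convergent(self):
        p = syn.GapSessionParams(n_crossings=1, vergence_amplitude=1.0,
                                 noise_sigma_deg=0.0, seed=0)
        session, t_gt = syn.gen_gap_session(p)
        i = int(np.argmin(np.abs(session.times - t_gt[0])))
        # left +1, right -1 at the event peak: sign-inverted product +1
        assert session.left.x[i] == pytest.approx(1.0, abs=0.01)
        assert session.right.x[i] == pytest.approx(-1.0, abs=0.01)
        assert -session.left.x[i] * session.right.x[i] == pytest.approx(
            1.0, abs=0.02)

    def test_incompatible_duration_raises(self):
        with pytest.raises(ValueError, match="duration"):
            syn.gen_gap_session(syn.GapSessionParams(
                n_crossings=10, duration=30.0))

    def test_determinism(self):
        a, ta = syn.gen_gap_session(syn.GapSessionParams(seed=9))
        b, tb = syn.gen_gap_session(syn.GapSessionParams(seed=9))
        assert np.array_equal(a.wheel, b.wheel)
        assert np.array_equal(a.left.x, b.left.x)
        assert np.array_equal(ta, tb)


class TestGenBarSweep:
    def test_no_shift_no_latency_identical_pairs(self):
        s = syn.gen_bar_sweep(0.0, 0.0, noise_sigma_mV=0.0)
        assert np.allclose(s[("control", 1)].mean, s[("activated", 1)].mean)
        assert np.allclose(s[("control", -1)].mean, s[("activated", -1)].mean)

    def test_shift_moves_peaks_in_both_directions(self):
        s = syn.gen_bar_sweep(5.7, 0.0, noise_sigma_mV=0.0)
        for d in (1, -1):
            pc = s[("control", d)].positions[np.argmax(s[("control", d)].mean)]
            pa = s[("activated", d)].positions[np.argmax(s[("activated", d)].mean)]
            assert pa - pc == pytest.approx(5.7, abs=0.25)

    def test_latency_adds_direction_signed_offset(self):
        # 0.1 s latency at 21 deg/s -> +/-2.1 deg per direction
        s = syn.gen_bar_sweep(0.0, 0.1, bar_speed=21.0, noise_sigma_mV=0.0)
        for d in (1, -1):
            c = s[("control", d)]
            peak = c.positions[np.argmax(c.mean)]
            assert peak == pytest.approx(d * 2.1, abs=0.25)


class TestGenFlashGrid:
    def test_rf_peak_on_grid_node_is_max_response(self):
        rf = syn.GaussianRF(center_az=5.0, center_el=0.0, sigma=10.0)
        fl = syn.gen_flash_grid(rf, np.arange(-20, 21, 5.0))
        by_pos = fl.records[fl.records.time_s >= 0].groupby(
            "position_az")["vm_mV"].mean()
        assert by_pos.idxmax() == 5.0

    def test_zero_amplitude_rf_gives_baseline_everywhere(self):
        rf = syn.GaussianRF(amplitude=0.0, baseline=-70.0)
        fl = syn.gen_flash_grid(rf, [-5.0, 0.0, 5.0])
        assert np.allclose(fl.records.vm_mV, -70.0)

    def test_half_maximum_diameter_matches_closed_form(self):
        # FWHM of a Gaussian = 2*sigma*sqrt(2 ln 2); sigma 21.2 -> 49.9 deg
        rf = syn.GaussianRF(sigma=21.2)
        az = np.arange(-60.0, 60.05, 0.1)
        prof = rf.response(az)
        above = az[prof >= prof.max() / 2]
        width = above[-1] - above[0]
        assert width == pytest.approx(2 * 21.2 * np.sqrt(2 * np.log(2)),
                                      abs=1.0)


class TestGenCrossingTrajectories:
    def test_zero_sd_every_minimum_equals_group_mean(self):
        out = syn.gen_crossing_trajectories(-1.0, 0.0, n_flies=3,
                                            crossings_per_fly=4)
        for mins in out.minima:
            assert np.allclose(mins, -1.0)
        for paths in out.paths:
            for p in paths:
                assert p[:, 1].min() == pytest.approx(-1.0, abs=1e-12)

    def test_group_means_recover_targets_within_two_sem(self):
        for target in (-1.0, -1.4):
            out = syn.gen_crossing_trajectories(target, 0.3, 20, 10, seed=5)
            mins = np.concatenate(out.minima)
            sem = mins.std(ddof=1) / np.sqrt(mins.size)
            assert abs(mins.mean() - target) < 2 * sem + 1e-9

    def test_single_cross_median_equals_minimum(self):
        out = syn.gen_crossing_trajectories(-1.2, 0.3, n_flies=2,
                                            crossings_per_fly=1, seed=2)
        for paths, mins in zip(out.paths, out.minima):
            assert np.median(mins) == mins[0]
            assert paths[0][:, 1].min() == pytest.approx(mins[0], abs=1e-9)


class TestSaccadeTrain:
    def test_explicit_amplitudes_are_honored(self):
        gt = syn.gen_saccade_train(syn.OkrParams(noise_sigma_deg=0.0), 4.0,
                                   amplitudes=[1.0, -2.0])
        assert [e.amplitude for e in gt.saccade_events] == [1.0, -2.0]
        assert gt.x[-1] == pytest.approx(-1.0, abs=1e-9)

    def test_determinism_across_calls(self):
        p = syn.OkrParams(seed=21)
        a = syn.gen_saccade_train(p, 30.0)
        b = syn.gen_saccade_train(p, 30.0)
        assert np.array_equal(a.x_noisy, b.x_noisy)
        assert a.saccade_events == b.saccade_events
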