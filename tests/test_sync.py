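"""Synchronization: m-modes, period estimation, pooling, shifts."""

import numpy as np
import pytest

from oftflow import phantom, sync
from oftflow.sync import (
    BModeSequence,
    LineSpec,
    MMode,
    SyncError,
    estimate_period,
    extract_mmode,
    phase_shift,
    pool_cycle,
    refine_and_smooth,
    resequence,
    synchronize_dataset,
    validate_sync,
)


def _mmode_from(matrix, fps=140.0):
    return MMode(matrix=np.asarray(matrix, float),
                 line_spec=LineSpec("vertical", 0), fps=fps)


class TestExtractMMode:
    def test_columns_are_frame_lines(self):
        frames = np.arange(5 * 4 * 3, dtype=float).reshape(5, 4, 3)
        seq = BModeSequence(frames=frames, fps=100.0)
        mm = extract_mmode(seq, LineSpec("vertical", 1))
        assert mm.matrix.shape == (4, 5)
        assert np.array_equal(mm.matrix[:, 2], frames[2, :, 1])
        mh = extract_mmode(seq, LineSpec("horizontal", 3))
        assert mh.matrix.shape == (3, 5)
        assert np.array_equal(mh.matrix[:, 4], frames[4, 3, :])

    def test_constant_sequence_gives_constant_mmode(self):
        seq = BModeSequence(frames=np.full((6, 4, 4), 2.5), fps=10.0)
        mm = extract_mmode(seq, LineSpec("vertical", 0))
        assert np.all(mm.matrix == 2.5)

    def test_out_of_bounds_line_rejected(self):
        seq = BModeSequence(frames=np.zeros((3, 4, 4)), fps=10.0)
        with pytest.raises(IndexError):
            extract_mmode(seq, LineSpec("vertical", 9))

    def test_200_frame_sequence_yields_200_columns(self, small_phantom):
        mm = extract_mmode(small_phantom.cross_images[0],
                           LineSpec("vertical", 24))
        assert mm.n_columns == 200


class TestEstimatePeriod:
    def test_exact_tiling_recovers_period(self):
        rng = np.random.default_rng(0)
        cycle = rng.normal(size=(10, 25))
        mm = _mmode_from(np.tile(cycle, 8))
        assert estimate_period(mm, (10.0, 60.0)) == pytest.approx(25.0, abs=0.1)

    def test_phantom_period_within_half_frame(self, small_phantom):
        cfg = small_phantom.truth.config
        mm = extract_mmode(small_phantom.cross_images[4],
                           LineSpec("vertical", 24))
        est = estimate_period(mm, (30.0, 90.0))
        assert est == pytest.approx(cfg.frames_per_cycle, abs=0.5)

    def test_noisy_phantom_period_within_one_frame(self):
        cfg = phantom.PhantomConfig(n_slices=5, image_depth_px=48,
                                    image_width_px=48, speckle_noise_sd=0.15)
        ds = phantom.generate_phantom(cfg, seed=21)
        mm = extract_mmode(ds.cross_images[2], LineSpec("vertical", 24))
        est = estimate_period(mm, (30.0, 90.0))
        assert est == pytest.approx(cfg.frames_per_cycle, abs=1.0)

    def test_flat_mmode_is_flagged_not_a_number(self):
        mm = _mmode_from(np.ones((8, 100)))
        with pytest.raises(SyncError):
            estimate_period(mm, (10.0, 40.0))

    def test_affine_intensity_invariance(self, small_phantom):
        mm = extract_mmode(small_phantom.cross_images[2],
                           LineSpec("vertical", 24))
        p1 = estimate_period(mm, (30.0, 90.0))
        mm2 = _mmode_from(3.7 * mm.matrix - 12.0)
        p2 = estimate_period(mm2, (30.0, 90.0))
        assert p1 == pytest.approx(p2, abs=1e-9)


class TestPoolCycle:
    def test_pooled_has_exactly_200_columns(self, small_phantom):
        mm = extract_mmode(small_phantom.cross_images[0],
                           LineSpec("vertical", 24))
        pooled = pool_cycle(mm, 57.4, n_bins=200)
        assert pooled.matrix.shape[1] == 200

    def test_pooling_idempotent_at_full_period(self):
        rng = np.random.default_rng(1)
        pooled = _mmode_from(rng.normal(size=(6, 200)))
        again = pool_cycle(pooled, 200.0, n_bins=200)
        assert np.allclose(again.matrix, pooled.matrix)

    def test_pooled_matches_resampled_single_cycle(self):
        """Noiseless periodic m-mode pools to one true cycle."""
        n_pix, p, n_bins = 8, 57.3, 200
        t = np.arange(400)
        phase = (t % p) / p
        offsets = np.linspace(0, 1, n_pix)[:, None]
        mat = np.sin(2 * np.pi * (phase[None, :] + offsets))
        pooled = pool_cycle(_mmode_from(mat), p, n_bins=n_bins)
        bins = np.floor(phase * n_bins + 1e-9).astype(int) % n_bins
        for b in (0, 57, 123, 198):
            members = phase[bins == b]
            if members.size:  # populated: exact bin mean
                expected = np.sin(2 * np.pi * (members[None, :] + offsets)
                                  ).mean(axis=1)
                assert np.allclose(pooled.matrix[:, b], expected, atol=1e-12)
            else:  # empty: circular interpolation stays near the signal
                expected = np.sin(2 * np.pi * ((b + 0.5) / n_bins + offsets[:, 0]))
                assert np.allclose(pooled.matrix[:, b], expected, atol=0.05)

    def test_invalid_period_rejected(self):
        with pytest.raises(ValueError):
            pool_cycle(_mmode_from(np.zeros((4, 10))), -5.0)


class TestPhaseShift:
    def test_identical_images_give_zero(self):
        rng = np.random.default_rng(2)
        a = _mmode_from(rng.normal(size=(12, 200)))
        assert phase_shift(a, a) == pytest.approx(0.0, abs=1e-6)

    def test_constructed_rotation_recovered(self):
        rng = np.random.default_rng(3)
        mat = np.cumsum(rng.normal(size=(12, 200)), axis=1)  # smooth-ish
        a = _mmode_from(mat)
        # b lags a by 37 bins: b advanced 37 bins matches a
        b = _mmode_from(np.roll(mat, 37, axis=1))
        assert phase_shift(a, b) == pytest.approx(37.0, abs=0.5)

    def test_constant_input_flagged(self):
        a = _mmode_from(np.random.default_rng(0).normal(size=(4, 50)))
        b = _mmode_from(np.ones((4, 50)))
        with pytest.raises(SyncError):
            phase_shift(a, b)

    def test_phantom_injected_offsets_recovered(self, small_phantom):
        """Coarse alignment recovers per-slice phases within 2 bins."""
        ds = small_phantom
        cfg = ds.truth.config
        n_bins = 200
        period = cfg.frames_per_cycle
        for k in (0, 4, 8):
            lm = pool_cycle(
                extract_mmode(ds.longitudinal, LineSpec("vertical", k)),
                period, n_bins)
            cm = pool_cycle(
                extract_mmode(ds.cross_images[k], LineSpec("vertical", 24)),
                period, n_bins)
            s = phase_shift(lm, cm)
            true = (ds.truth.longitudinal_phase_offset
                    - ds.truth.slice_phase_offsets[k]) % 1.0
            err = (s / n_bins - true + 0.5) % 1.0 - 0.5
            assert abs(err) * n_bins < 2.0


class TestRefineAndSmooth:
    def _pooled_set(self, shifts_bins, n_bins=200, n_pix=10, seed=4):
        rng = np.random.default_rng(seed)
        base = np.cumsum(rng.normal(size=(n_pix, n_bins)), axis=1)
        base -= base.mean(axis=1, keepdims=True)
        return [
            _mmode_from(np.roll(base, int(s), axis=1))
            for s in np.cumsum(np.concatenate([[0], shifts_bins]))
        ]

    def test_zero_shifts_give_zero_curve(self):
        pooled = self._pooled_set([0, 0, 0])
        curve = refine_and_smooth(pooled)
        assert np.allclose(curve.raw, 0.0, atol=0.5)

    def test_constant_shift_telescopes(self):
        d = 7
        pooled = self._pooled_set([d] * 5)
        curve = refine_and_smooth(pooled)
        assert curve.raw[-1] == pytest.approx(5 * d, abs=1.0)

    def test_corrupted_slice_smoothed_to_trend(self):
        d = 4
        shifts = [d] * 9
        pooled = self._pooled_set(shifts)
        pooled[5] = _mmode_from(np.roll(pooled[5].matrix, -30, axis=1))
        curve = refine_and_smooth(pooled, outlier_bins=5.0)
        truth = d * np.arange(10)
        assert np.all(np.abs(curve.smoothed - truth) < 2.0)

    def test_near_half_cycle_shift_flagged(self):
        pooled = self._pooled_set([0, 95, 0], n_bins=200)
        curve = refine_and_smooth(pooled)
        assert len(curve.ambiguous_slices) >= 1


class TestResequence:
    def test_output_has_exactly_100_frames(self, small_phantom):
        out = resequence(small_phantom.cross_images[0], 57.4, 10.0, n_out=100)
        assert out.frames.shape[0] == 100

    def test_zero_shift_full_bins_is_pooling_identity(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(size=(200, 6, 5))
        seq = BModeSequence(frames=frames, fps=140.0)
        out = resequence(seq, 200.0, 0.0, n_out=200, n_bins=200)
        assert np.allclose(out.frames, frames)

    def test_type_preserved_for_doppler(self, small_phantom):
        out = resequence(small_phantom.cross_doppler[0], 57.4, 3.0)
        assert isinstance(out, sync.DopplerSequence)

    def test_resequencing_conserves_time_mean(self):
        """Per-pixel mean over the cycle survives resampling."""
        rng = np.random.default_rng(6)
        frames = rng.normal(size=(200, 4, 4)).cumsum(axis=0) / 10
        seq = BModeSequence(frames=frames, fps=140.0)
        pooled = resequence(seq, 50.0, 0.0, n_out=200, n_bins=200)
        shifted = resequence(seq, 50.0, 77.3, n_out=200, n_bins=200)
        assert np.allclose(pooled.frames.mean(axis=0),
                           shifted.frames.mean(axis=0), atol=1e-2)


class TestEndToEnd:
    def test_resequenced_slices_follow_traveling_wave(self):
        """Adjacent resequenced slices peak at the configured wave lag.

        Cushion-free phantom so the area waveform is a pure traveling
        wave (the cushion pulse has no longitudinal phase lag).
        """
        cfg = phantom.PhantomConfig(
            n_slices=9, image_depth_px=48, image_width_px=48,
            speckle_noise_sd=0.0, cushion_depth=0.0,
        )
        ds = phantom.generate_phantom(cfg, seed=11)
        sd = synchronize_dataset(ds.longitudinal, ds.cross_images,
                                 ds.cross_doppler)
        n_out = sd.volume.shape[0]
        # lumen area proxy per phase: count of dark pixels
        dark = (sd.volume < 0.15).reshape(n_out, -1, cfg.n_slices).sum(axis=1)
        lag_true = (1.0 / (cfg.n_slices - 1)) / cfg.wave_speed  # cycles/slice
        for k in (1, 4, 7):
            a = dark[:, k - 1] - dark[:, k - 1].mean()
            b = dark[:, k] - dark[:, k].mean()
            ncc = np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b),
                               n=n_out)
            lag = np.argmax(ncc)
            lag = lag - n_out if lag > n_out / 2 else lag
            assert abs(lag - lag_true * n_out) <= 1.0

    def test_self_comparison_validation_is_perfect(self, small_phantom):
        ds = small_phantom
        sd = synchronize_dataset(ds.longitudinal, ds.cross_images,
                                 ds.cross_doppler)
        reports = validate_sync(ds.longitudinal_doppler, sd)
        ok = [r for r in reports if not r.get("excluded")]
        assert len(ok) >= 3
        for r in ok:
            assert r["peak_correlation"] >= 0.99
            assert abs(r["lag_frames"]) <= 1.0

    def test_unsynchronized_negative_control_detected(self, small_phantom):
        """Zeroing the shifts leaves at least one clearly lagged point."""
        ds = small_phantom
        sd = synchronize_dataset(ds.longitudinal, ds.cross_images,
                                 ds.cross_doppler)
        broken = sync.SyncedDataset(
            volume=sd.volume,
            doppler=np.stack(
                [resequence(d, sd.schedule.period_frames, 0.0).frames
                 for d in ds.cross_doppler], axis=-1),
            schedule=sd.schedule,
            fps_equivalent=sd.fps_equivalent,
        )
        reports = validate_sync(ds.longitudinal_doppler, broken)
        lags = [abs(r["lag_frames"]) for r in reports if not r.get("excluded")]
        assert max(lags) > 2.0
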