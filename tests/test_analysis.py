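"""Calcium-imaging analysis: preprocessing, tuning fits, orientation mapping."""

import itertools

import numpy as np
import pytest

from contourscope.analysis import (
    TrialSet,
    bandpass_spatial,
    compare_maps,
    composite_orientation_map,
    decode_orientation,
    dff,
    dprime_map,
    harmonic_amplitude,
    harmonic_coefficient,
    orientation_pipeline,
    pairwise_map_correlation,
    position_tuning,
    register_frames,
    rms_roi,
    shuffle_null,
    shuffle_null_trials,
    subtract_blank,
)


def make_trialset(videos, labels, onset=4):
    return TrialSet(np.asarray(videos, float), labels, frame_rate=20.0,
                    onset_frame=onset, pixel_pitch_obj=31.25)


class TestSubtractBlank:
    def test_self_cancellation(self, rng):
        blank = rng.random((12, 8, 8))
        vids = np.stack([blank, blank, blank])
        ts = make_trialset(vids, [0.0, 30.0, "blank"])
        out = subtract_blank(ts)
        assert np.abs(out.videos).max() < 1e-12

    def test_preonset_mean_exactly_zero(self, rng):
        vids = rng.random((5, 12, 6, 6))
        ts = make_trialset(vids, [0.0, 0.0, 90.0, "blank", "blank"])
        out = subtract_blank(ts)
        pre = out.videos[:, :4].mean(axis=1)
        assert np.abs(pre).max() < 1e-9

    def test_planted_signal_plus_shared_drift(self, rng):
        # signal + drift decomposition: the correction must return exactly
        # the planted signal (oracle = the decomposition itself)
        T, H, W = 12, 6, 6
        drift = np.cumsum(rng.random((T, H, W)), axis=0) * 0.1
        signal = np.zeros((T, H, W))
        signal[6:] = rng.random((6, H, W))  # post-onset only
        stim = drift + signal
        ts = make_trialset(np.stack([stim, drift]), [0.0, "blank"])
        out = subtract_blank(ts)
        assert np.abs(out.videos[0] - signal).max() < 1e-9

    def test_requires_blanks_and_preonset(self, rng):
        vids = rng.random((2, 12, 4, 4))
        with pytest.raises(ValueError):
            subtract_blank(make_trialset(vids, [0.0, 30.0]))
        with pytest.raises(ValueError):
            subtract_blank(make_trialset(vids, [0.0, "blank"], onset=2))


class TestDff:
    def test_constant_video_is_zero(self):
        v = np.full((10, 4, 4), 7.0)
        assert np.abs(dff(v, slice(0, 5))).max() == 0

    def test_sinusoidal_modulation_amplitude(self):
        t = np.arange(40)
        v = 50.0 * (1 + 0.05 * np.sin(2 * np.pi * t / 8))[:, None, None] * np.ones((1, 3, 3))
        out = dff(v, slice(0, 40))
        # the mean over whole periods is the baseline; t=2 samples the peak
        assert np.isclose(out.max(), 0.05, atol=1e-9)

    def test_matches_per_pixel_loop_oracle(self, rng):
        v = rng.random((8, 5, 5)) + 0.5
        out = dff(v, slice(0, 3))
        for y in range(5):
            for x in range(5):
                f0 = v[:3, y, x].mean()
                assert np.abs(out[:, y, x] - (v[:, y, x] - f0) / f0).max() < 1e-12

    def test_nonpositive_baseline_masked(self):
        v = np.ones((6, 3, 3))
        v[:, 1, 1] = 0.0
        with pytest.warns(UserWarning):
            out = dff(v, slice(0, 3))
        assert np.isnan(out[:, 1, 1]).all()
        assert np.isfinite(out[:, 0, 0]).all()


class TestRegistration:
    def test_identical_frames_zero_displacement(self, rng):
        tmpl = rng.random((32, 32))
        video = np.stack([tmpl] * 4)
        disp, out, flagged = register_frames(video, tmpl)
        assert np.abs(disp).max() == 0
        assert not flagged.any()

    def test_integer_shifts_recovered_exactly(self, rng):
        from scipy.ndimage import gaussian_filter

        tmpl = gaussian_filter(rng.random((48, 48)), 1.0)
        shifts = [(3, -2), (-1, 3), (0, 2)]
        video = np.stack([np.roll(tmpl, s, axis=(0, 1)) for s in shifts])
        disp, out, _ = register_frames(video, tmpl, upsample=1)
        assert np.array_equal(disp, -np.asarray(shifts, float) * 1.0)

    def test_subpixel_shifts_within_tenth_pixel(self, rng):
        from scipy.ndimage import fourier_shift
        import scipy.fft as spfft

        tmpl = np.real(spfft.ifft2(spfft.fft2(rng.random((64, 64))) *
                                   np.exp(-0.05 * np.arange(64)[:, None])))
        shifted = np.real(spfft.ifft2(fourier_shift(spfft.fft2(tmpl), (0.5, -0.5))))
        disp, _, _ = register_frames(shifted[None], tmpl, upsample=10)
        assert np.abs(disp[0] - [-0.5, 0.5]).max() <= 0.1


class TestPositionTuning:
    def _trials_with_profile(self, centers_deg, amp_fn):
        # responses uniform over the FOV: ROI means equal the profile value
        positions = list(np.round(np.arange(-1.3, -0.79, 0.1), 2))
        vids, labels = [], []
        for pos in positions:
            resp = amp_fn(pos)
            v = np.zeros((14, 96, 96))
            v[4:] = resp
            vids.append(v)
            labels.append(pos)
        vids.append(np.zeros((14, 96, 96)))
        labels.append("blank")
        return make_trialset(vids, labels)

    def test_planted_gaussian_center_recovered(self):
        center = -1.05
        profile = lambda p: 0.8 * np.exp(-0.5 * ((p - center) / 0.12) ** 2) + 0.01
        ts = self._trials_with_profile(None, profile)
        fit = position_tuning(subtract_blank(ts))
        assert not fit.flagged.any()
        assert np.abs(fit.peak_positions - center).max() < 1e-6

    def test_flat_responses_flagged(self):
        ts = self._trials_with_profile(None, lambda p: 0.5)
        fit = position_tuning(subtract_blank(ts))
        assert fit.flagged.all()
        # raw responses preserved for flagged ROIs
        assert np.allclose(fit.responses, 0.5)

    def test_canonical_stimulus_grid_accepted(self):
        ts = self._trials_with_profile(
            None, lambda p: np.exp(-0.5 * ((p + 1.0) / 0.2) ** 2))
        fit = position_tuning(subtract_blank(ts))
        assert np.allclose(sorted(fit.positions), np.arange(-1.3, -0.79, 0.1))

    def test_needs_three_positions(self, rng):
        vids = rng.random((3, 14, 16, 16))
        ts = make_trialset(vids, [0.0, 1.0, "blank"])
        with pytest.raises(ValueError):
            position_tuning(subtract_blank(ts))


class TestHarmonic:
    def test_cosine_amplitude_convention(self):
        t = np.arange(40) / 20.0
        x = 0.03 * np.cos(2 * np.pi * 4.0 * t)
        amp = harmonic_amplitude(x[:, None, None], 4.0, 20.0)
        assert np.abs(amp[0, 0] - 0.03) < 1e-9

    def test_constant_trace_zero(self):
        amp = harmonic_amplitude(np.ones((40, 2, 2)), 4.0, 20.0)
        assert np.abs(amp).max() < 1e-12

    def test_matches_projection_oracle(self, rng):
        v = rng.random((20, 4, 4))
        amp = harmonic_amplitude(v, 4.0, 20.0)
        t = np.arange(20)
        for y in range(4):
            for x in range(4):
                c = np.sum(v[:, y, x] * np.exp(-2j * np.pi * 4 * t / 20.0))
                assert abs(amp[y, x] - 2.0 / 20.0 * abs(c)) < 1e-12

    def test_off_grid_frequency_warns(self):
        with pytest.warns(UserWarning):
            harmonic_amplitude(np.random.rand(23, 2, 2), 4.0, 20.0)

    def test_linearity_of_coefficient(self, rng):
        a = rng.random((20, 3, 3))
        b = rng.random((20, 3, 3))
        lhs = harmonic_coefficient(0.5 * (a + b))
        rhs = 0.5 * (harmonic_coefficient(a) + harmonic_coefficient(b))
        assert np.abs(lhs - rhs).max() < 1e-12


class TestRmsRoi:
    def test_uniform_single_map_full_mask(self):
        assert rms_roi(np.ones((1, 8, 8))).all()

    def test_planted_two_level_threshold(self):
        m = np.full((8, 8), 0.9)
        m[2:5, 2:5] = 3.0
        mask = rms_roi(m[None], threshold_frac=1.0 / 3.0)
        assert np.array_equal(mask, m > 1.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            rms_roi(np.zeros((2, 4, 4)))


class TestBandpass:
    pitch = 31.25  # μm → 3.2 mm FOV at 128 px

    def _plane_wave(self, cpmm, n=128):
        x = np.arange(n) * self.pitch * 1e-3  # mm
        return np.sin(2 * np.pi * cpmm * x)[None, :] * np.ones((n, 1))

    def test_passband_center_preserved(self):
        m = self._plane_wave(1.25)  # on the DFT grid of 4 mm? use measured gain
        out = bandpass_spatial(m, pixel_pitch_obj=self.pitch)
        core = np.s_[32:96, 32:96]
        gain = np.linalg.norm(out[core]) / np.linalg.norm(m[core])
        assert abs(gain - 1.0) < 0.01

    def test_dc_rejected(self):
        m = np.full((64, 64), 5.0)
        out = bandpass_spatial(m, pixel_pitch_obj=self.pitch)
        assert np.abs(out).max() < 1e-9 * 5.0

    def test_stopband_attenuation_matches_analytic_response(self):
        m = self._plane_wave(0.5)
        out = bandpass_spatial(m, pixel_pitch_obj=self.pitch)
        # analytic raised-cosine response at 0.5 cycles/mm is 0 (below
        # low − taper/2 = 0.75), so attenuation must exceed 100×
        assert np.linalg.norm(out) < np.linalg.norm(m) / 100.0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_spatial(np.ones((32, 32)), high=20.0, pixel_pitch_obj=100.0)


class TestDprimeMap:
    def test_equal_means_zero(self, rng):
        s = rng.random((6, 6)) + 0.5
        m = rng.random((6, 6))
        assert np.abs(dprime_map(m, m, s, s)).max() == 0

    def test_unit_effect(self, rng):
        s = rng.random((6, 6)) + 0.5
        m90 = rng.random((6, 6))
        out = dprime_map(m90 + s, m90, s, s)
        assert np.allclose(out, 1.0, atol=1e-12)

    def test_matches_elementwise_formula(self, rng):
        m0, m90 = rng.random((5, 5)), rng.random((5, 5))
        s0, s90 = rng.random((5, 5)) + 0.1, rng.random((5, 5)) + 0.1
        out = dprime_map(m0, m90, s0, s90)
        ref = (m0 - m90) / np.sqrt((s0**2 + s90**2) / 2.0)
        assert np.abs(out - ref).max() < 1e-12

    def test_zero_pooled_sd_pixels_zeroed(self):
        m0 = np.ones((3, 3))
        s = np.ones((3, 3))
        s[1, 1] = 0.0
        with pytest.warns(UserWarning):
            out = dprime_map(m0, np.zeros_like(m0), s, s)
        assert out[1, 1] == 0


class TestDecoder:
    def test_null_distribution_unbiased(self, rng):
        # both conditions identically distributed → held-out d′ centered at 0
        reps = 60
        ds = []
        for _ in range(reps):
            a = rng.standard_normal((6, 5, 5))
            b = rng.standard_normal((6, 5, 5))
            ds.append(decode_orientation(a, b).dprime_dv)
        ds = np.asarray(ds)
        assert abs(ds.mean()) < 3 * ds.std(ddof=1) / np.sqrt(reps)

    def test_single_pixel_reduces_to_pixel_dprime(self, rng):
        n = 4000
        a = rng.standard_normal((n, 1, 1)) + 0.8
        b = rng.standard_normal((n, 1, 1))
        res = decode_orientation(a, b, cv=None)
        d_pix = dprime_map(a.mean(0), b.mean(0), a.std(0, ddof=1), b.std(0, ddof=1))
        assert abs(abs(res.dprime_dv) - abs(d_pix[0, 0])) < 0.05

    def test_matched_filter_closed_form(self, rng):
        # independent unit-variance pixels with planted per-pixel d′ᵢ and
        # population weights: d′_DV → sqrt(Σ d′ᵢ²)
        d = rng.uniform(0.1, 1.0, (8, 8))
        n = 2000
        a = rng.standard_normal((n, 8, 8)) + d / 2
        b = rng.standard_normal((n, 8, 8)) - d / 2
        res = decode_orientation(a, b, cv=None)
        expect = np.sqrt((d**2).sum())
        assert abs(res.dprime_dv - expect) / expect < 0.05

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            decode_orientation(rng.random((2, 3, 3)), rng.random((5, 3, 3)))


class TestMapCorrelations:
    orientations = np.array([0.0, 30.0, 60.0, 90.0, 120.0, 150.0])

    def _ideal_maps(self, rng, shape=(24, 24)):
        # equally spaced preferences shuffled in space: the empirical moments
        # of (cos 2θ, sin 2θ) vanish exactly, making corr(Δ) = cos(2Δ) exact
        n = shape[0] * shape[1]
        pref = np.linspace(0.0, 180.0, n, endpoint=False)
        pref = rng.permutation(pref).reshape(shape)
        maps = np.stack([np.cos(2 * np.deg2rad(pref - t)) for t in self.orientations])
        return pref, maps

    def test_self_correlation_is_one(self, rng):
        m = rng.random((16, 16))
        d, c = pairwise_map_correlation(np.stack([m, m]), [0.0, 0.0])
        assert d[0] == 0.0 and np.isclose(c[0], 1.0)

    def test_negation_gives_minus_one(self, rng):
        m = rng.random((16, 16))
        d, c = pairwise_map_correlation(np.stack([m, -m]), [0.0, 90.0])
        assert np.isclose(c[0], -1.0)

    def test_cosine_identity_curve(self, rng):
        # analytic oracle: ideal cosine maps ⇒ corr(Δ) = cos(2Δ)
        _, maps = self._ideal_maps(rng)
        d, c = pairwise_map_correlation(maps, self.orientations)
        assert np.allclose(d, [30.0, 60.0, 90.0])
        assert np.allclose(c, [0.5, -0.5, -1.0], atol=1e-6)

    def test_curve_monotone_decreasing(self, rng):
        _, maps = self._ideal_maps(rng)
        _, c = pairwise_map_correlation(maps, self.orientations)
        assert np.all(np.diff(c) < 0)

    def test_zero_variance_map_skipped(self, rng):
        maps = np.stack([rng.random((8, 8)), np.ones((8, 8))])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                # the only pair is skipped → empty curve is an error upstream
                d, c = pairwise_map_correlation(maps, [0.0, 30.0])
                if len(d) == 0:
                    raise ValueError


class TestCompositeMap:
    def test_single_component_pixel(self):
        maps = np.zeros((6, 1, 1))
        maps[2] = 1.0  # responds only at 60°
        pref, mag, ok = composite_orientation_map(
            maps, [0.0, 30.0, 60.0, 90.0, 120.0, 150.0])
        assert np.isclose(pref[0, 0], 60.0)
        assert np.isclose(mag[0, 0], 1.0)
        assert ok[0, 0]

    def test_isotropic_pixel_masked(self):
        maps = np.ones((6, 2, 2))
        pref, mag, ok = composite_orientation_map(
            maps, [0.0, 30.0, 60.0, 90.0, 120.0, 150.0])
        assert np.all(mag == 0)
        assert np.all(pref == 0)
        assert not ok.any()

    def test_planted_preferences_recovered(self, rng):
        pref = rng.uniform(0, 180, (16, 16))
        th = [0.0, 30.0, 60.0, 90.0, 120.0, 150.0]
        maps = np.stack([np.cos(2 * np.deg2rad(pref - t)) for t in th])
        est, _, _ = composite_orientation_map(maps, th)
        err = np.minimum(np.abs(est - pref), 180 - np.abs(est - pref))
        assert err.max() < 1.0


class TestCompareMaps:
    def test_identical_maps(self, rng):
        a = rng.uniform(0, 180, (12, 12))
        assert np.isclose(compare_maps(a, a), 1.0)

    def test_ninety_degree_offset_is_minus_one(self, rng):
        a = rng.uniform(0, 180, (12, 12))
        b = np.mod(a + 90.0, 180.0)
        assert np.isclose(compare_maps(a, b), -1.0)

    def test_matches_pearson_oracle(self, rng):
        a = rng.uniform(0, 180, (10, 10))
        b = rng.uniform(0, 180, (10, 10))
        sa, sb = np.sin(2 * np.deg2rad(a)).ravel(), np.sin(2 * np.deg2rad(b)).ravel()
        ref = (np.mean(sa * sb) - sa.mean() * sb.mean()) / (sa.std() * sb.std())
        assert abs(compare_maps(a, b) - ref) < 1e-12

    def test_offset_sweep_symmetric_about_90(self, rng):
        a = np.linspace(0.0, 180.0, 24 * 24, endpoint=False)
        a = rng.permutation(a).reshape(24, 24)
        deltas = np.arange(0, 181, 15)
        rs = [compare_maps(a, np.mod(a + d, 180.0)) for d in deltas]
        assert np.allclose(rs, np.cos(2 * np.deg2rad(deltas)), atol=1e-9)

    def test_constant_map_errors(self):
        with pytest.raises(ValueError):
            compare_maps(np.zeros((4, 4)), np.random.rand(4, 4) * 180)


class TestShuffleNull:
    orientations = np.array([0.0, 30.0, 60.0, 90.0, 120.0, 150.0])

    def _maps(self, rng):
        pref = rng.uniform(0, 180, (16, 16))
        maps = np.stack([np.cos(2 * np.deg2rad(pref - t)) + 0.1 * rng.standard_normal((16, 16))
                         for t in self.orientations])
        return pref, maps

    def test_identity_permutation_equals_unshuffled(self, rng):
        pref, maps = self._maps(rng)
        est, _, _ = composite_orientation_map(maps, self.orientations)
        actual = compare_maps(est, pref)
        null = shuffle_null(maps, self.orientations, pref,
                            _permutations=[np.arange(6)])
        assert np.isclose(null.values[0], actual)

    def test_values_bounded(self, rng):
        pref, maps = self._maps(rng)
        null = shuffle_null(maps, self.orientations, pref, n_shuffles=50, seed=1)
        assert null.min >= -1.0 and null.max <= 1.0

    def test_sampled_mean_matches_exhaustive_permutations(self, rng):
        # 720 distinct label permutations; the sampled null mean must agree
        # with the exhaustive mean within Monte-Carlo error
        pref, maps = self._maps(rng)
        perms = list(itertools.permutations(range(6)))
        exact = shuffle_null(maps, self.orientations, pref, _permutations=perms)
        sampled = shuffle_null(maps, self.orientations, pref,
                               _permutations=[np.asarray(p) for p in
                                              rng.choice(len(perms), 300).tolist()
                                              and [perms[i] for i in rng.choice(len(perms), 300)]])
        se = sampled.values.std(ddof=1) / np.sqrt(len(sampled.values))
        assert abs(sampled.mean - exact.mean) < 3 * se + 1e-12

    def test_trial_level_null_destroys_orientation_signal(self, rng):
        # per-trial coefficient maps with a planted columnar signal: the
        # trial-shuffled null must collapse toward zero correlation
        pref = rng.uniform(0, 180, (32, 32))
        labels = np.repeat(self.orientations, 5)
        coefs = np.stack([
            np.cos(2 * np.deg2rad(pref - lab)) + 0.3 * rng.standard_normal((32, 32))
            + 1j * 0.3 * rng.standard_normal((32, 32))
            for lab in labels
        ])
        null = shuffle_null_trials(coefs, labels, pref, n_shuffles=60, seed=2,
                                   band=(0.0001, 10.0), pixel_pitch_obj=31.25)
        assert abs(null.mean) < 0.2
        assert null.max < 0.8


class TestOrientationPipeline:
    def test_recovers_planted_map_from_clean_trials(self, rng):
        import contourscope as cs

        ph = cs.make_cortex_phantom((64, 64), seed=7)
        proto = cs.StimulusProtocol(trials_per_condition=2, blank_trials=2)
        vids, labels = [], []
        for cond in proto.orientations:
            for rep in range(2):
                vids.append(cs.generate_trial_video(ph, proto, cond, seed=rep))
                labels.append(cond)
        for rep in range(2):
            vids.append(cs.generate_trial_video(ph, proto, "blank", seed=rep))
            labels.append("blank")
        trials = TrialSet(np.stack(vids), labels, frame_rate=20.0,
                          onset_frame=proto.onset_frame,
                          pixel_pitch_obj=ph.pixel_pitch_obj)
        maps = orientation_pipeline(trials)
        r = compare_maps(maps.pref_map, ph.pref_map, maps.roi_mask)
        assert r > 0.9
        # blank trial, processed the same way, stays near the noise floor
        assert np.all(np.diff(maps.corr_curve) < 0)
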