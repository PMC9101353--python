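"""Kymograph extraction, normalization chain, segments, landmarks."""

import numpy as np
import pytest

from sfmech.exceptions import (
    CorrectionFailureError,
    InvalidParameterError,
    KymographStateError,
    LandmarkAmbiguityWarning,
)
from sfmech.kymograph import (
    Kymograph,
    extract_kymograph,
    locate_landmarks,
    normalize_relative,
    photobleach_correct,
    segment_average,
    total_trace,
)
from sfmech.model import intensity_model
from sfmech.synthetic import default_config, generate_kymograph


def _raw(s, t, I, ds=0.2, dt=2.0):
    return Kymograph(s=s, t=t, I=I, state="raw", pixel_size=ds, dt=dt)


class TestExtraction:
    def test_uniform_image_gives_constant_kymograph(self):
        stack = np.full((5, 40, 60), 7.0)
        path = [(2.0, 5.0), (25.0, 5.0)]
        kym = extract_kymograph(stack, path, width=1.0, pixel_size=0.5, dt=2.0)
        assert np.allclose(kym.I, 7.0)
        assert kym.state == "raw"

    def test_zero_width_equals_line_sampling(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(1, 10, (3, 30, 30))
        path = [(3.0, 7.0), (12.0, 7.0)]
        k0 = extract_kymograph(stack, path, width=0.0, pixel_size=0.5, dt=1.0)
        k1 = extract_kymograph(stack, path, width=1e-9, pixel_size=0.5, dt=1.0)
        assert np.allclose(k0.I, k1.I, atol=1e-9)

    def test_out_of_bounds_path_lists_vertices(self):
        stack = np.zeros((2, 10, 10))
        with pytest.raises(InvalidParameterError, match="indices \\[1\\]"):
            extract_kymograph(stack, [(1.0, 1.0), (99.0, 1.0)],
                              width=1.0, pixel_size=0.5, dt=1.0)

    def test_bright_arc_profile_recovered(self):
        # synthetic stack with a known-profile arc: round-trip within 2% RMS
        from sfmech.synthetic import generate_arc_stack

        cfg = default_config(0.0, seed=3)
        proto = cfg.protocol
        import dataclasses

        cfg = dataclasses.replace(
            cfg, protocol=dataclasses.replace(proto, epsilon=0.0),
            sampling=dataclasses.replace(cfg.sampling, duration=8.0))
        sample = generate_arc_stack(cfg, noisy=False, pixel_size=0.25)
        px = sample.truth["pixel_size"]
        path = sample.edges[0][2:-2]  # drop the arc tips (mask cut-off)
        kym = extract_kymograph(sample.stack, path, width=0.0,
                                pixel_size=px, dt=cfg.sampling.dt)
        peak = sample.truth["amplitude"] + 20.0  # amplitude + background
        rms = np.sqrt(np.mean((kym.I - peak) ** 2)) / peak
        assert rms < 0.02


class TestBleachCorrection:
    def test_exact_inversion_of_exponential_decay(self):
        s = np.arange(0, 10, 0.5)
        t = np.arange(0, 400, 2.0)
        P = 1.0 + 0.3 * np.sin(s)[:, None]
        I = P * np.exp(-t / 1500.0)[None, :]
        kym = _raw(s, t, I)
        out = photobleach_correct(kym, (0.0, 400.0))
        assert np.allclose(out.I, P * np.ones_like(t)[None, :], rtol=1e-9)
        assert out.meta["tau_b_s"] == pytest.approx(1500.0, rel=1e-6)
        assert out.state == "bleach_corrected"

    def test_no_bleaching_is_identity(self):
        s = np.arange(0, 10, 0.5)
        t = np.arange(0, 100, 2.0)
        I = np.full((len(s), len(t)), 3.0)
        out = photobleach_correct(_raw(s, t, I), (0.0, 100.0))
        assert np.allclose(out.I, I)
        assert np.isinf(out.meta["tau_b_s"])

    def test_noisy_decay_constant_recovered(self, rng):
        s = np.arange(0, 36, 0.2)
        t = np.arange(0, 900, 2.0)
        I = np.exp(-t / 1500.0)[None, :] * np.ones((len(s), 1))
        I = I * (1 + 0.03 * rng.standard_normal(I.shape))
        out = photobleach_correct(_raw(s, t, np.clip(I, 0, None)), (0.0, 900.0))
        assert out.meta["tau_b_s"] == pytest.approx(1500.0, rel=0.10)

    def test_brightening_is_a_failure(self):
        s = np.arange(0, 10, 0.5)
        t = np.arange(0, 100, 2.0)
        I = np.exp(+t / 200.0)[None, :] * np.ones((len(s), 1))
        with pytest.raises(CorrectionFailureError):
            photobleach_correct(_raw(s, t, I), (0.0, 100.0))

    def test_reapplication_guarded(self):
        s = np.arange(0, 10, 0.5)
        t = np.arange(0, 100, 2.0)
        I = np.ones((len(s), len(t)))
        out = photobleach_correct(_raw(s, t, I), (0.0, 100.0))
        with pytest.raises(KymographStateError):
            photobleach_correct(out, (0.0, 100.0))


class TestRelativeNormalization:
    def _corrected(self, s, t, I):
        kym = _raw(s, t, I)
        return photobleach_correct(kym, (t[0], t[-1]))

    def test_baseline_equal_data_gives_zero(self):
        s = np.arange(0, 10, 0.5)
        t = np.arange(0, 100, 2.0)
        I = np.ones((len(s), len(t))) * 5.0
        out = normalize_relative(self._corrected(s, t, I), (0.0, 100.0))
        assert np.allclose(out.I, 0.0, atol=1e-12)
        assert out.state == "normalized_relative"

    def test_uniform_recruitment_matches_intensity_model(self):
        s = np.arange(0, 36, 0.2)
        t = np.arange(0, 900, 2.0)
        g = intensity_model(0.25, t, 0.64, 427.0)
        I = (1.0 + g)[None, :] * np.ones((len(s), 1))
        kym = Kymograph(s=s, t=t, I=I, state="bleach_corrected",
                        pixel_size=0.2, dt=2.0)
        out = normalize_relative(kym, (0.0, 0.0 + 1e-9))
        assert np.allclose(total_trace(out), g, atol=1e-9)

    def test_prestretch_plateau_stays_flat_through_compression(self):
        # intensity raised to I0 + DIp by prestretch, constant afterwards
        s = np.arange(0, 36, 0.2)
        t = np.arange(0, 900, 2.0)
        I = np.full((len(s), len(t)), 1.25)
        kym = Kymograph(s=s, t=t, I=I, state="bleach_corrected",
                        pixel_size=0.2, dt=2.0)
        out = normalize_relative(kym, (0.0, 100.0))
        assert np.allclose(total_trace(out), 0.0, atol=1e-12)

    def test_wrong_state_rejected(self):
        s = np.arange(0, 10, 0.5)
        t = np.arange(0, 100, 2.0)
        with pytest.raises(KymographStateError):
            normalize_relative(_raw(s, t, np.ones((len(s), len(t)))), (0, 50))


class TestSegmentAverage:
    def _kym(self, L=36.47, ds=0.2):
        s = np.arange(0.0, L + ds / 2, ds)
        t = np.arange(0, 10, 2.0)
        I = np.outer(s, np.ones(len(t)))
        return _raw(s, t, I, ds=ds)

    def test_study_bundle_tiles_into_seven_segments(self):
        out = segment_average(self._kym(), 5.0)
        assert out.I.shape[0] == 7  # 1.47 um remainder merged into the last

    def test_full_length_single_segment_is_global_mean(self):
        kym = self._kym()
        out = segment_average(kym, kym.length + kym.pixel_size)
        assert out.I.shape[0] == 1
        assert np.allclose(out.I[0], kym.I.mean(axis=0))

    def test_linear_profile_segment_means_at_midpoints(self):
        out = segment_average(self._kym(L=20.0, ds=0.1), 5.0)
        # linear in s: the mean over a segment equals its sample midpoint
        assert np.allclose(out.I[:, 0], out.s, atol=1e-9)

    def test_total_intensity_conserved(self):
        kym = self._kym()
        out = segment_average(kym, 5.0)
        counts = out.meta["segment_counts"]
        assert np.sum(out.I * counts[:, None]) == pytest.approx(
            np.sum(kym.I), rel=1e-9)

    def test_oversized_segment_rejected(self):
        with pytest.raises(InvalidParameterError):
            segment_average(self._kym(L=10.0), 50.0)


class TestLandmarks:
    def test_symmetric_double_peak_profile(self):
        s = np.linspace(0, 36, 181)
        prof = (np.exp(-((s - 2) ** 2) / 8) + np.exp(-((s - 34) ** 2) / 8)
                - 0.3 * np.exp(-((s - 18) ** 2) / 50) + 1.0)
        fa_l, msf, fa_r = locate_landmarks(prof, s)
        assert fa_l == pytest.approx(2.0, abs=0.5)
        assert fa_r == pytest.approx(34.0, abs=0.5)
        assert msf == pytest.approx(18.0, abs=0.5)

    def test_generator_template_round_trip(self):
        cfg = default_config(0.2, seed=7)
        sample = generate_kymograph(cfg, noisy=False, bleach=False)
        prof = sample.kym.I[:, 0]
        fa_l, msf, fa_r = locate_landmarks(prof, sample.kym.s)
        true = sample.truth["positions"]
        assert fa_l == pytest.approx(true["fa_left"], abs=5.0)
        assert fa_r == pytest.approx(true["fa_right"], abs=5.0)
        assert msf == pytest.approx(true["msf"], abs=5.0)

    def test_flat_profile_warns_and_centers(self):
        s = np.linspace(0, 10, 51)
        with pytest.warns(LandmarkAmbiguityWarning):
            fa_l, msf, fa_r = locate_landmarks(np.ones(51), s)
        assert msf == pytest.approx(5.0, abs=0.2)


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        s = np.arange(0, 10, 0.5)
        t = np.arange(0, 20, 2.0)
        kym = _raw(s, t, np.random.default_rng(0).uniform(1, 5, (len(s), len(t))))
        path = tmp_path / "kym.csv"
        kym.to_csv(path)
        back = Kymograph.from_csv(path)
        assert np.allclose(back.I, kym.I)
        assert back.state == "raw"
        assert back.pixel_size == kym.pixel_size
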