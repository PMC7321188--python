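"""Puncta detection, tracking, residence and fluctuation analysis."""

import numpy as np
import pytest

from flucty import puncta, simkit
from flucty.types import PunctaSimSpec, RasterScanStack, ScanGeometry


def _gauss_spot(shape, cx, cy, sigma_px, amp):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2))


class TestDetection:
    def test_blank_frame_no_detections(self):
        rng = np.random.default_rng(0)
        frame = rng.poisson(100.0, size=(64, 64)).astype(float)
        dets = puncta.detect_puncta(frame, pixel_size=0.1)
        assert dets == []

    def test_five_spots_detected_with_radii(self):
        """Known ground truth: 5 well-separated Gaussian spots, SNR ≈ 40;
        exactly 5 detections with radii within 20%."""
        rng = np.random.default_rng(1)
        truth_r = 0.25  # µm; sigma = r/sqrt(2)
        sigma_px = truth_r / np.sqrt(2) / 0.1
        img = np.full((96, 96), 10.0)
        centers = [(15, 20), (70, 15), (40, 50), (20, 75), (75, 70)]
        for cx, cy in centers:
            img += _gauss_spot((96, 96), cx, cy, sigma_px, 400.0)
        frame = rng.poisson(img).astype(float)
        dets = puncta.detect_puncta(frame, pixel_size=0.1, scale_range=(0.12, 0.6))
        assert len(dets) == 5
        for d in dets:
            assert d.radius == pytest.approx(truth_r, rel=0.2)
        # centroids match ground truth within one pixel
        found = {(round(d.x / 0.1), round(d.y / 0.1)) for d in dets}
        for cx, cy in centers:
            assert any(abs(fx - cx) <= 1 and abs(fy - cy) <= 1 for fx, fy in found)

    def test_translation_equivariance(self):
        """Shifting the image by whole pixels shifts centroids identically."""
        rng = np.random.default_rng(2)
        sigma_px = 2.0
        img = np.full((64, 64), 5.0)
        img += _gauss_spot((64, 64), 20, 24, sigma_px, 300.0)
        frame = rng.poisson(img).astype(float)
        shifted = np.roll(frame, (3, 5), axis=(0, 1))
        d0 = puncta.detect_puncta(frame, pixel_size=0.1, scale_range=(0.12, 0.6))
        d1 = puncta.detect_puncta(shifted, pixel_size=0.1, scale_range=(0.12, 0.6))
        assert len(d0) == len(d1) == 1
        assert d1[0].x - d0[0].x == pytest.approx(0.5, abs=0.02)
        assert d1[0].y - d0[0].y == pytest.approx(0.3, abs=0.02)

    def test_nonfinite_image_rejected(self):
        frame = np.full((16, 16), np.nan)
        with pytest.raises(ValueError):
            puncta.detect_puncta(frame, pixel_size=0.1)

    def test_fewer_but_larger_contrast(self):
        """Two conditions — many small spots vs few large spots — reproduce
        the fewer-but-larger contrast in counts and radii."""
        geom = ScanGeometry(nx=96, ny=96, pixel_size=0.1, pixel_dwell=1.0, n_frames=3, frame_time=0.1)
        many_small = simkit.simulate_tirf_series(
            PunctaSimSpec(n_puncta=20, radius=0.15, peak_brightness=400),
            geom, background=10, seed=5,
        )
        few_large = simkit.simulate_tirf_series(
            PunctaSimSpec(n_puncta=8, radius=0.30, peak_brightness=400),
            geom, background=10, seed=6,
        )
        d_small = puncta.detect_stack(many_small, scale_range=(0.1, 0.6))
        d_large = puncta.detect_stack(few_large, scale_range=(0.1, 0.6))
        n_small = np.mean([len(d) for d in d_small])
        n_large = np.mean([len(d) for d in d_large])
        r_small = np.mean([d.radius for dets in d_small for d in dets])
        r_large = np.mean([d.radius for dets in d_large for d in dets])
        assert n_small > n_large
        assert r_large > r_small


class TestTracking:
    def _det(self, f, x, y, r=0.2, peak=100.0):
        return puncta.PunctaDetection(
            frame_index=f, x=x, y=y, radius=r,
            peak_intensity=peak, integrated_intensity=peak * 10,
        )

    def test_static_spot_single_track(self):
        dets = [[self._det(f, 1.0, 1.0)] for f in range(100)]
        tracks = puncta.track_puncta(dets, max_link_distance=0.3, frame_time=0.1)
        assert len(tracks) == 1
        assert tracks[0].residence_time == pytest.approx(10.0)

    def test_crossing_spots_stay_separate(self):
        """Two spots on converging straight paths: with a link radius below
        their separation at closest approach, both tracks survive."""
        dets = []
        for f in range(20):
            x = 0.1 * f
            dets.append(
                [
                    self._det(f, x, 1.0, peak=100.0),
                    self._det(f, 2.0 - x, 2.0, peak=200.0),
                ]
            )
        tracks = puncta.track_puncta(dets, max_link_distance=0.3, frame_time=0.1)
        assert len(tracks) == 2
        assert all(len(t.detections) == 20 for t in tracks)

    def test_gap_closing(self):
        dets = [[self._det(f, 1.0, 1.0)] if f != 5 else [] for f in range(10)]
        tracks = puncta.track_puncta(
            dets, max_link_distance=0.3, max_gap=1, frame_time=0.1
        )
        assert len(tracks) == 1

    def test_gap_longer_than_tolerance_splits(self):
        dets = [[self._det(f, 1.0, 1.0)] if f not in (4, 5, 6) else []
                for f in range(10)]
        tracks = puncta.track_puncta(
            dets, max_link_distance=0.3, max_gap=1, frame_time=0.1
        )
        assert len(tracks) == 2


class TestResidence:
    def _track(self, f0, f1, frame_time=1.0):
        dets = [
            puncta.PunctaDetection(
                frame_index=f, x=1.0, y=1.0, radius=0.2,
                peak_intensity=10.0, integrated_intensity=100.0,
            )
            for f in range(f0, f1 + 1)
        ]
        return puncta.PunctaTrack(detections=dets, frame_time=frame_time)

    def test_single_uncensored_track(self):
        tracks = [self._track(5, 14)]
        stats = puncta.residence_stats(tracks, n_frames=100)
        assert stats["mean"] == pytest.approx(10.0)
        assert stats["sd"] == 0.0
        assert stats["n"] == 1

    def test_censored_tracks_excluded(self):
        tracks = [self._track(0, 10), self._track(90, 99), self._track(20, 29)]
        stats = puncta.residence_stats(tracks, n_frames=100)
        assert stats["n"] == 1
        assert stats["n_censored"] == 2

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            puncta.residence_stats([self._track(0, 10)], n_frames=11)

    def test_exponential_lifetime_recovery(self):
        """Mean-25 s movie: recovered mean within 15% (truncation-debiased
        by a long observation window)."""
        geom = ScanGeometry(
            nx=64, ny=64, pixel_size=0.1, pixel_dwell=12.5,
            n_frames=1600, frame_time=0.5,
        )
        spec = PunctaSimSpec(
            n_puncta=150, radius=0.25, peak_brightness=400, mean_residence=25.0
        )
        st = simkit.simulate_tirf_series(spec, geom, background=10, seed=7)
        dets = puncta.detect_stack(st, scale_range=(0.12, 0.6))
        tracks = puncta.track_puncta(
            dets, max_link_distance=0.4, max_gap=1, frame_time=0.5
        )
        stats = puncta.residence_stats(tracks, geom.n_frames)
        assert stats["mean"] == pytest.approx(25.0, rel=0.15)

    def test_censoring_unbiased_under_movie_extension(self):
        """Doubling the movie length moves the uncensored mean by < 10%."""
        means = []
        for n_frames in (1600, 3200):
            geom = ScanGeometry(
                nx=64, ny=64, pixel_size=0.1, pixel_dwell=12.5,
                n_frames=n_frames, frame_time=0.5,
            )
            spec = PunctaSimSpec(
                n_puncta=60, radius=0.25, peak_brightness=400, mean_residence=25.0
            )
            st = simkit.simulate_tirf_series(spec, geom, background=10, seed=9)
            dets = puncta.detect_stack(st, scale_range=(0.12, 0.6))
            tracks = puncta.track_puncta(
                dets, max_link_distance=0.4, max_gap=1, frame_time=0.5
            )
            means.append(puncta.residence_stats(tracks, n_frames)["mean"])
        assert abs(means[1] - means[0]) / means[0] < 0.10


class TestLargestComponent:
    def _stack(self, frames):
        geom = ScanGeometry(
            nx=frames.shape[2], ny=frames.shape[1],
            pixel_size=0.1, n_frames=frames.shape[0], frame_time=0.1,
        )
        return RasterScanStack(
            frames=frames, geometry=geom, detector_mode="camera"
        )

    def test_uniform_image_empty_flag(self):
        rng = np.random.default_rng(3)
        st = self._stack(rng.poisson(20.0, (5, 32, 32)).astype(float))
        assert puncta.largest_component(st, threshold_sd=5.0) is None

    def test_argmax_by_integrated_intensity(self):
        frames = np.full((4, 64, 64), 10.0)
        frames[:, 10:14, 10:14] += 80.0     # small dim blob
        frames[:, 40:48, 40:48] += 200.0    # large bright blob
        st = self._stack(frames)
        res = puncta.largest_component(st, threshold_sd=5.0)
        assert res is not None
        assert res["size_px"] == 64
        assert res["peak_brightness"] == pytest.approx(200.0, rel=0.01)

    def test_radius_ordering_tracks_cluster_size(self):
        sizes = []
        for radius, seed in ((0.2, 11), (0.4, 12)):
            geom = ScanGeometry(
                nx=64, ny=64, pixel_size=0.1, n_frames=10, frame_time=0.1
            )
            spec = PunctaSimSpec(n_puncta=1, radius=radius, peak_brightness=500)
            st = simkit.simulate_tirf_series(spec, geom, background=10, seed=seed)
            res = puncta.largest_component(st, threshold_sd=5.0)
            sizes.append(res["radius_um"])
        assert sizes[1] > sizes[0]


class TestFluctuationEvents:
    def _track_from_trace(self, trace):
        dets = [
            puncta.PunctaDetection(
                frame_index=f, x=0.0, y=0.0, radius=0.2,
                peak_intensity=float(v), integrated_intensity=float(v),
            )
            for f, v in enumerate(trace)
        ]
        return puncta.PunctaTrack(detections=dets, frame_time=0.1)

    def test_constant_trace_no_events(self):
        res = puncta.intensity_fluctuation_trace(
            self._track_from_trace([5.0] * 10), min_change=1.0
        )
        assert res["n_events"] == 0

    def test_triangle_wave_one_rise_one_fall_per_period(self):
        period = np.concatenate([np.linspace(0, 10, 6), np.linspace(10, 0, 6)[1:]])
        trace = np.concatenate([period, period[1:]])
        res = puncta.intensity_fluctuation_trace(
            self._track_from_trace(trace), min_change=5.0
        )
        rises = [e for e in res["events"] if e.direction == "rise"]
        falls = [e for e in res["events"] if e.direction == "fall"]
        assert len(rises) == 2
        assert len(falls) == 2

    def test_spiky_trace_more_events_and_variance_than_smooth(self):
        """Smooth build-up/decline vs abrupt spiky dynamics: the spiky
        trace yields more suprathreshold events and larger variance."""
        n = 100
        t = np.arange(n)
        smooth = 50 * np.sin(np.pi * t / n)  # one rise, one fall
        rng = np.random.default_rng(8)
        spiky = np.zeros(n)
        for start in range(5, n - 10, 12):
            spiky[start : start + 6] += rng.uniform(40, 120)
        res_smooth = puncta.intensity_fluctuation_trace(
            self._track_from_trace(smooth), min_change=30.0
        )
        res_spiky = puncta.intensity_fluctuation_trace(
            self._track_from_trace(spiky), min_change=30.0
        )
        assert res_spiky["n_events"] > res_smooth["n_events"]
        assert res_spiky["variance"] > 0

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            puncta.intensity_fluctuation_trace(
                self._track_from_trace([1.0, 2.0]), min_change=0.5
            )
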