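"""Simulator correctness: seed determinism, photon statistics, kinematics."""

import numpy as np
import pytest

from flucty import simkit
from flucty.types import BeamProfile, PunctaSimSpec, ScanGeometry, SpeciesSpec


class TestPointTrace:
    def test_zero_concentration_gives_all_zero_counts(self, beam):
        sp = SpeciesSpec(D=5.0, epsilon=35_000, concentration=0.0)
        tr = simkit.simulate_point_trace([sp], beam, 1e-4, 0.1, seed=1)
        assert tr.counts.sum() == 0

    def test_empty_species_list_rejected(self, beam):
        with pytest.raises(ValueError):
            simkit.simulate_point_trace([], beam, 1e-4, 0.1, seed=1)

    def test_non_integer_bin_count_rejected(self, beam):
        sp = SpeciesSpec(D=5.0, epsilon=1000, concentration=10)
        with pytest.raises(ValueError):
            simkit.simulate_point_trace([sp], beam, 3e-4, 0.1, seed=1)

    def test_pinned_immobile_particle_is_poisson_at_peak_rate(self, beam):
        """One molecule at the focus with ε·bin_time = 0.7: Poisson mean 0.7."""
        bin_time = 1e-5
        eps = 0.7 / bin_time
        # one particle per box volume, pinned at the origin
        box = simkit._box_dims(beam, None)
        conc = 1.0 / (np.prod(box) * 0.602214076)
        sp = SpeciesSpec(D=0.0, epsilon=eps, concentration=conc, motion="immobile")
        n_bins = 10**6
        # force exactly one particle at the focus
        tr = None
        for seed in range(20):
            pos0 = np.zeros((1, 3))
            try:
                tr = simkit.simulate_point_trace(
                    [sp], beam, bin_time, n_bins * bin_time, seed=seed,
                    initial_positions=pos0,
                )
                break
            except ValueError:
                continue  # seed drew 0 or >1 particles
        assert tr is not None
        se = np.sqrt(0.7 / n_bins)
        assert abs(tr.counts.mean() - 0.7) < 3 * se

    def test_seed_determinism(self, beam, mgfp_species):
        a = simkit.simulate_point_trace([mgfp_species], beam, 1e-4, 0.5, seed=7)
        b = simkit.simulate_point_trace([mgfp_species], beam, 1e-4, 0.5, seed=7)
        c = simkit.simulate_point_trace([mgfp_species], beam, 1e-4, 0.5, seed=8)
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_photon_conservation_across_seeds(self, beam, mgfp_species):
        """Mean detected rate matches c·ε·(π/2)^{3/2}ω0²ωz within 3 SE."""
        expected = simkit.expected_mean_rate([mgfp_species], beam)
        rates = [
            simkit.simulate_point_trace(
                [mgfp_species], beam, 1e-4, 0.5, seed=s
            ).mean_rate
            for s in range(20)
        ]
        rates = np.array(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - expected) < 3 * se + 0.01 * expected


class TestRasterStack:
    def test_immobile_scene_frames_identical_up_to_shot_noise(self, beam):
        geom = ScanGeometry(nx=32, ny=32, n_frames=30)
        sp = SpeciesSpec(D=0.0, epsilon=200_000, concentration=100, motion="immobile")
        st = simkit.simulate_raster_stack([sp], beam, geom, seed=3)
        means = st.frames.mean(axis=(1, 2))
        # frame means fluctuate only through shot noise: CV ≈ 1/sqrt(total counts)
        cv = means.std(ddof=1) / means.mean()
        expected_cv = 1.0 / np.sqrt(means.mean() * 32 * 32)
        assert cv < 3 * expected_cv

    def test_directed_particle_moves_one_pixel_per_frame(self, beam):
        """Kinematics oracle: v = pixel_size/frame_time shifts the centroid
        by exactly one pixel between consecutive frames."""
        geom = ScanGeometry(nx=32, ny=32, pixel_size=0.1, pixel_dwell=2.0, n_frames=2)
        v = geom.pixel_size / geom.frame_time_s
        box = simkit._box_dims(beam, geom.field_of_view)
        conc = 1.0 / (np.prod(box) * 0.602214076)  # ~one particle
        sp = SpeciesSpec(
            D=0.0, epsilon=5e6, concentration=conc, motion="directed", velocity=v
        )
        st = None
        for seed in range(30):
            cand = simkit.simulate_raster_stack([sp], beam, geom, seed=seed)
            if cand.ground_truth["n_particles"] == 1:
                # pin the particle at the field centre, moving along +x
                st = simkit.simulate_raster_stack(
                    [sp], beam, geom, seed=seed,
                    initial_positions=np.zeros((1, 3)),
                )
                break
        assert st is not None
        def centroid_x(frame):
            total = frame.sum()
            xs = np.arange(frame.shape[1])
            return (frame.sum(axis=0) * xs).sum() / total
        shift = centroid_x(st.frames[1]) - centroid_x(st.frames[0])
        assert shift == pytest.approx(1.0, abs=0.3)

    def test_seed_determinism(self, beam, small_geom, mgfp_species):
        geom = ScanGeometry(nx=32, ny=32, n_frames=5)
        a = simkit.simulate_raster_stack([mgfp_species], beam, geom, seed=5)
        b = simkit.simulate_raster_stack([mgfp_species], beam, geom, seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_mean_pixel_rate_matches_theory(self, beam, mgfp_species):
        geom = ScanGeometry(nx=64, ny=64, n_frames=10)
        st = simkit.simulate_raster_stack([mgfp_species], beam, geom, seed=9)
        expected = simkit.expected_mean_rate([mgfp_species], beam) * geom.pixel_dwell_s
        # single Poisson draw of particle number dominates the error budget
        assert st.frames.mean() == pytest.approx(expected, rel=0.15)


class TestBrownianStatistics:
    def test_displacement_variance_fits_2dt(self):
        """Per-axis displacement variance grows as 2·D·t with R² > 0.99."""
        rng = np.random.default_rng(11)
        d_true, dt, n_steps, n_particles = 3.0, 1e-3, 100, 100
        steps = rng.normal(0, np.sqrt(2 * d_true * dt), size=(n_steps, n_particles))
        # oracle for the simulator's step law: cumulative sums
        paths = np.cumsum(steps, axis=0)
        lags = np.arange(1, 21)
        var = np.array([np.mean((paths[k:] - paths[:-k]) ** 2) for k in lags])
        t = lags * dt
        slope, intercept = np.polyfit(t, var, 1)
        r2 = 1 - np.sum((var - (slope * t + intercept)) ** 2) / np.sum(
            (var - var.mean()) ** 2
        )
        assert r2 > 0.99
        assert slope == pytest.approx(2 * d_true, rel=0.1)

    def test_occupancy_matches_concentration(self, beam, mgfp_species):
        """Ergodicity: mean rate / (ε·γ) equals c·V_eff within 5%."""
        tr = simkit.simulate_point_trace([mgfp_species], beam, 1e-4, 20.0, seed=21)
        n_eff = tr.mean_rate / (mgfp_species.epsilon * beam.gamma)
        expected = mgfp_species.number_density * beam.effective_volume
        assert n_eff == pytest.approx(expected, rel=0.05)


class TestTwoChannel:
    def test_bound_fraction_range_validated(self, beam, small_geom):
        g = SpeciesSpec(D=4, epsilon=1000, concentration=10)
        with pytest.raises(ValueError):
            simkit.simulate_two_channel_stack(g, g, 1.5, beam, small_geom, seed=1)

    def test_channels_share_geometry_and_complex_count(self, beam):
        geom = ScanGeometry(nx=32, ny=32, n_frames=5)
        g = SpeciesSpec(D=4, epsilon=35_000, concentration=30)
        sg, sr = simkit.simulate_two_channel_stack(g, g, 0.5, beam, geom, seed=2)
        assert sg.geometry == sr.geometry
        t = sg.ground_truth
        assert t["n_complex"] == round(0.5 * t["n_green"])


class TestTirf:
    def test_no_puncta_is_pure_background(self):
        geom = ScanGeometry(nx=32, ny=32, pixel_size=0.1, n_frames=5, frame_time=0.1)
        spec = PunctaSimSpec(n_puncta=0, radius=0.2)
        st = simkit.simulate_tirf_series(spec, geom, background=5.0, seed=1)
        photons = st.photon_frames()
        assert photons.mean() == pytest.approx(5.0, rel=0.05)
        assert st.detector_mode == "camera"

    def test_unresolvable_radius_rejected(self):
        geom = ScanGeometry(nx=32, ny=32, pixel_size=0.1, n_frames=2, frame_time=0.1)
        with pytest.raises(ValueError):
            simkit.simulate_tirf_series(
                PunctaSimSpec(n_puncta=1, radius=0.04), geom, 5.0, seed=1
            )

    def test_persistent_puncta_present_every_frame(self):
        geom = ScanGeometry(nx=64, ny=64, pixel_size=0.1, n_frames=10, frame_time=0.1)
        spec = PunctaSimSpec(n_puncta=3, radius=0.25, peak_brightness=300)
        st = simkit.simulate_tirf_series(spec, geom, background=10.0, seed=4)
        assert len(st.ground_truth["centers_um"]) == 3
        # bright pixels in every frame
        assert (st.photon_frames().max(axis=(1, 2)) > 100).all()


class TestDecay:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            simkit.simulate_decay([1.0, 4.0], [0.6, 0.6], 80e6, 1000, seed=1)

    def test_long_lifetime_warns(self):
        with pytest.warns(UserWarning):
            simkit.simulate_decay([200.0], [1.0], 80e6, 1000, seed=1)

    def test_ideal_histogram_is_normalized_and_periodic(self):
        d = simkit.ideal_decay_histogram([2.95], [1.0], 80e6, n_bins=512,
                                         total_counts=1e6)
        assert d.total_counts == pytest.approx(1e6)
        assert d.period_ns == pytest.approx(12.5)

    def test_monte_carlo_matches_ideal_shape(self):
        ideal = simkit.ideal_decay_histogram([2.0], [1.0], 80e6, n_bins=64)
        mc = simkit.simulate_decay([2.0], [1.0], 80e6, 200_000, seed=6, n_bins=64)
        p = ideal.counts / ideal.counts.sum()
        expected = p * mc.total_counts
        chi2 = ((mc.counts - expected) ** 2 / expected).sum()
        # chi2 ~ 63 dof; 3 sigma
        assert chi2 < 63 + 3 * np.sqrt(2 * 63)
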