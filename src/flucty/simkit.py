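"""Synthetic-data generation with known ground truth.

This module stands in for the microscope: it produces point traces, raster
stacks, two-channel stacks, TIRF movies and fluorescence decays from
explicit physical ground truth (diffusion coefficients, molecular
brightness, concentrations, lifetimes), so that every analysis stage of the
toolkit can be validated by parameter recovery.

The emission model is a 3D Gaussian PSF; molecules perform Brownian motion
(optionally with drift) in a periodic box that encloses the imaged field,
and detected counts are Poisson samples of the instantaneous summed rate.
Photobleaching, triplet blinking and detector dead time are deliberately
not simulated.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from . import _kernels
from .types import (
    BeamProfile,
    DecayHistogram,
    PointTrace,
    PunctaSimSpec,
    RasterScanStack,
    ScanGeometry,
    SpeciesSpec,
    species_list,
)

__all__ = [
    "simulate_point_trace",
    "simulate_raster_stack",
    "simulate_two_channel_stack",
    "simulate_tirf_series",
    "simulate_decay",
    "ideal_decay_histogram",
    "expected_mean_rate",
]

#: default axial extent of the simulation box, in units of omega_z
AXIAL_EXTENT_FACTOR = 5.0


def _split_seed(seed: int, n: int = 2) -> list[int]:
    """Derive independent sub-seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _box_dims(beam: BeamProfile, fov: tuple[float, float] | None) -> np.ndarray:
    """Periodic-box extents (µm): lateral >= max(8·ω0, FOV + 2·ω0)."""
    lat_min = 8.0 * beam.omega0
    if fov is None:
        lx = ly = lat_min
    else:
        lx = max(lat_min, fov[0] + 2.0 * beam.omega0)
        ly = max(lat_min, fov[1] + 2.0 * beam.omega0)
    lz = AXIAL_EXTENT_FACTOR * beam.omega_z
    return np.array([lx, ly, lz])


def _populate(
    species: Sequence[SpeciesSpec],
    box: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw particle numbers, positions and per-particle kinetic parameters.

    Particle counts are Poisson-distributed around concentration × box
    volume, matching the open-system statistics the correlation analyses
    assume.  Returns (pos, D, eps_cpsm, vx, species_index).
    """
    v_box = float(np.prod(box))
    pos_list, d_list, e_list, v_list, s_list = [], [], [], [], []
    for si, sp in enumerate(species):
        n = int(rng.poisson(sp.number_density * v_box))
        p = rng.uniform(-0.5, 0.5, size=(n, 3)) * box
        pos_list.append(p)
        d = 0.0 if sp.motion == "immobile" else sp.D
        d_list.append(np.full(n, d))
        e_list.append(np.full(n, sp.effective_epsilon))
        v_list.append(np.full(n, sp.velocity if sp.motion == "directed" else 0.0))
        s_list.append(np.full(n, si, dtype=np.int64))
    pos = np.concatenate(pos_list) if pos_list else np.empty((0, 3))
    return (
        np.ascontiguousarray(pos),
        np.concatenate(d_list) if d_list else np.empty(0),
        np.concatenate(e_list) if e_list else np.empty(0),
        np.concatenate(v_list) if v_list else np.empty(0),
        np.concatenate(s_list) if s_list else np.empty(0, dtype=np.int64),
    )


def expected_mean_rate(species: Sequence[SpeciesSpec], beam: BeamProfile) -> float:
    """Expected detected count rate (counts/s) for a species mixture.

    The PSF volume integral of the 3D Gaussian is (π/2)^{3/2}·ω0²·ωz, so
    the ensemble-average rate is Σ c_i·ε_i·(π/2)^{3/2}·ω0²·ωz.
    """
    psf_integral = (np.pi / 2.0) ** 1.5 * beam.omega0**2 * beam.omega_z
    return float(
        sum(sp.number_density * sp.effective_epsilon for sp in species) * psf_integral
    )


def simulate_point_trace(
    species: Sequence[SpeciesSpec],
    beam: BeamProfile,
    bin_time: float,
    duration: float,
    seed: int,
    *,
    position_update: float | None = None,
    initial_positions: np.ndarray | None = None,
) -> PointTrace:
    """Simulate a binned photon-count trace at a fixed confocal spot.

    Parameters
    ----------
    species
        Fluorescent species; molecule numbers are drawn from their
        concentrations.
    bin_time, duration
        Sampling bin (s) and total duration (s); duration must be an
        integer number of bins.
    position_update
        Interval (s) at which particle positions are re-drawn.  ``None``
        picks the finest of ``bin_time`` and the interval at which the RMS
        Brownian step is ω0/4.  Positions at update boundaries are exact
        equilibrium Brownian samples, so count-distribution statistics
        (PCH, mean rate) are unbiased for any update interval; only
        sub-interval temporal correlation is coarsened.
    initial_positions
        Override starting positions (testing hook, e.g. a molecule pinned
        at the focus).
    """
    species = species_list(species)
    n_bins_f = duration / bin_time
    n_bins = round(n_bins_f)
    if abs(n_bins_f - n_bins) > 1e-9 * max(1.0, n_bins_f) or n_bins < 1:
        raise ValueError("duration must be an integer number of bins")

    seed_pop, seed_kernel = _split_seed(seed)
    rng = np.random.default_rng(seed_pop)
    box = _box_dims(beam, None)
    pos, d_arr, e_arr, v_arr, _ = _populate(species, box, rng)
    if initial_positions is not None:
        pos = np.ascontiguousarray(np.asarray(initial_positions, dtype=float))
        if pos.shape != (len(d_arr), 3):
            raise ValueError("initial_positions shape must be (n_particles, 3)")

    d_max = float(d_arr.max()) if len(d_arr) else 0.0
    v_max = float(v_arr.max()) if len(v_arr) else 0.0
    if position_update is None:
        dt = np.inf
        if d_max > 0:
            dt = beam.omega0**2 / (32.0 * d_max)  # RMS step ω0/4
        if v_max > 0:
            dt = min(dt, beam.omega0 / (8.0 * v_max))
        position_update = max(bin_time, dt)
    if not np.isfinite(position_update):  # nothing moves: one static block
        position_update = duration
    upd = max(1, min(n_bins, round(position_update / bin_time)))
    block_dt = upd * bin_time
    sigma_blk = np.sqrt(2.0 * d_arr * block_dt)

    counts = _kernels.trace_kernel(
        seed_kernel,
        n_bins,
        upd,
        pos,
        sigma_blk,
        v_arr * block_dt,  # drift per block, µm
        e_arr * bin_time,
        beam.omega0,
        beam.omega_z,
        box,
    )
    return PointTrace(counts=counts, bin_time=bin_time)


def _run_raster(
    species: Sequence[SpeciesSpec],
    eps_channels: np.ndarray,
    pos: np.ndarray,
    d_arr: np.ndarray,
    v_arr: np.ndarray,
    beam: BeamProfile,
    geom: ScanGeometry,
    box: np.ndarray,
    seed_kernel: int,
    pixels_per_update: int,
) -> np.ndarray:
    line_t = geom.line_time_s
    sigma_line = np.sqrt(2.0 * d_arr * line_t)
    sig_max = float(sigma_line.max()) if len(sigma_line) else 0.0
    v_max = float(np.abs(v_arr).max()) if len(v_arr) else 0.0
    near_margin = 2.0 * sig_max + v_max * line_t
    # kernel advances with dt_frac relative to one line; express drift per line
    vx_line = v_arr * line_t
    return _kernels.raster_kernel(
        seed_kernel,
        pos,
        sigma_line,
        vx_line,
        np.ascontiguousarray(eps_channels * geom.pixel_dwell_s),
        eps_channels.shape[1],
        geom.n_frames,
        geom.ny,
        geom.nx,
        geom.pixel_size,
        geom.pixel_dwell_s,
        line_t,
        geom.frame_time_s,
        beam.omega0,
        beam.omega_z,
        box,
        pixels_per_update,
        near_margin,
    )


def simulate_raster_stack(
    species: Sequence[SpeciesSpec],
    beam: BeamProfile,
    geom: ScanGeometry,
    seed: int,
    *,
    pixels_per_update: int = 8,
    initial_positions: np.ndarray | None = None,
) -> RasterScanStack:
    """Simulate a raster-scanned photon-counting image stack.

    Each pixel's expected rate is evaluated at that pixel's acquisition
    time (pixel index × dwell + line index × line time + frame index ×
    frame time), so diffusion decorrelates the image along the slow axis
    exactly as the RICS model assumes.  Particle positions are integrated
    in sub-line steps of ``pixels_per_update`` pixels.
    """
    species = species_list(species)
    seed_pop, seed_kernel = _split_seed(seed)
    rng = np.random.default_rng(seed_pop)
    box = _box_dims(beam, geom.field_of_view)
    pos, d_arr, e_arr, v_arr, _ = _populate(species, box, rng)
    if initial_positions is not None:
        pos = np.ascontiguousarray(np.asarray(initial_positions, dtype=float))
        if pos.shape != (len(d_arr), 3):
            raise ValueError("initial_positions shape must be (n_particles, 3)")
    eps = e_arr[:, None]  # one channel
    frames = _run_raster(
        species, eps, pos, d_arr, v_arr, beam, geom, box, seed_kernel,
        pixels_per_update,
    )[0]
    truth = {
        "species": [vars(sp) | {"effective_epsilon": sp.effective_epsilon} for sp in species],
        "omega0": beam.omega0,
        "axial_ratio": beam.axial_ratio,
        "n_particles": int(len(d_arr)),
        "box_um": box.tolist(),
    }
    return RasterScanStack(
        frames=frames, geometry=geom, detector_mode="photon_counting",
        ground_truth=truth,
    )


def simulate_two_channel_stack(
    green: SpeciesSpec,
    red: SpeciesSpec,
    bound_fraction: float,
    beam: BeamProfile,
    geom: ScanGeometry,
    seed: int,
    *,
    pixels_per_update: int = 8,
) -> tuple[RasterScanStack, RasterScanStack]:
    """Simulate co-diffusion of a bound fraction across two channels.

    A fraction ``bound_fraction`` of the green molecules is placed in
    complexes that share a trajectory with a red molecule (correlated
    emission in both channels); the rest of each species diffuses
    independently.  Complexes move with the slower of the two partners'
    diffusion coefficients.
    """
    if not (0.0 <= bound_fraction <= 1.0):
        raise ValueError("bound_fraction must lie in [0, 1]")
    seed_pop, seed_kernel = _split_seed(seed)
    rng = np.random.default_rng(seed_pop)
    box = _box_dims(beam, geom.field_of_view)
    v_box = float(np.prod(box))
    n_g = int(rng.poisson(green.number_density * v_box))
    n_r = int(rng.poisson(red.number_density * v_box))
    n_c = min(int(round(bound_fraction * n_g)), n_r)
    groups = [
        # (count, eps_green, eps_red, D)
        (n_c, green.effective_epsilon, red.effective_epsilon, min(green.D, red.D)),
        (n_g - n_c, green.effective_epsilon, 0.0, green.D),
        (n_r - n_c, 0.0, red.effective_epsilon, red.D),
    ]
    pos = rng.uniform(-0.5, 0.5, size=(n_g + n_r - n_c, 3)) * box
    eps = np.zeros((len(pos), 2))
    d_arr = np.zeros(len(pos))
    k = 0
    for count, eg, er, d in groups:
        eps[k : k + count, 0] = eg
        eps[k : k + count, 1] = er
        d_arr[k : k + count] = d
        k += count
    v_arr = np.zeros(len(pos))
    out = _run_raster(
        [green, red], eps, np.ascontiguousarray(pos), d_arr, v_arr, beam,
        geom, box, seed_kernel, pixels_per_update,
    )
    truth = {
        "bound_fraction": bound_fraction,
        "n_green": n_g,
        "n_red": n_r,
        "n_complex": n_c,
        "omega0": beam.omega0,
        "axial_ratio": beam.axial_ratio,
    }
    mk = lambda fr: RasterScanStack(
        frames=fr, geometry=geom, detector_mode="photon_counting",
        ground_truth=truth,
    )
    return mk(out[0]), mk(out[1])


def simulate_tirf_series(
    spec: PunctaSimSpec,
    geom: ScanGeometry,
    background: float,
    seed: int,
    *,
    camera_offset: float = 100.0,
    camera_scale: float = 1.0,
    read_noise_sd: float = 0.0,
) -> RasterScanStack:
    """Simulate a TIRF movie of membrane puncta recorded on a camera.

    Puncta are 2D Gaussian spots (the evanescent-field axial profile is
    collapsed into the 2D amplitude).  Each punctum appears at a uniformly
    random time, persists for an exponentially distributed residence time
    of mean ``spec.mean_residence`` (forever if ``None``), and is rendered
    with peak photon rate ``spec.peak_brightness`` per frame.  Camera
    counts are ``offset + scale × Poisson(signal)`` plus optional Gaussian
    read noise.
    """
    if spec.radius < 0.5 * geom.pixel_size:
        raise ValueError(
            f"puncta radius {spec.radius} µm is below half a pixel "
            f"({0.5 * geom.pixel_size} µm) and cannot be resolved"
        )
    rng = np.random.default_rng(_split_seed(seed, 1)[0])
    n_frames, ny, nx = geom.n_frames, geom.ny, geom.nx
    frame_time = geom.frame_time_s
    duration = n_frames * frame_time
    # spot Gaussian sigma chosen so a LoG detector reports spec.radius
    sigma_um = spec.radius / np.sqrt(2.0)
    margin = 3.0 * spec.radius
    fov_x, fov_y = geom.field_of_view
    xc = rng.uniform(margin, fov_x - margin, size=spec.n_puncta)
    yc = rng.uniform(margin, fov_y - margin, size=spec.n_puncta)
    if spec.mean_residence is None or np.isinf(spec.mean_residence):
        birth = np.zeros(spec.n_puncta)
        death = np.full(spec.n_puncta, np.inf)
    else:
        birth = rng.uniform(0.0, duration, size=spec.n_puncta)
        death = birth + rng.exponential(spec.mean_residence, size=spec.n_puncta)
    if spec.motion == "directed" and spec.n_puncta:
        theta = rng.uniform(0, 2 * np.pi, size=spec.n_puncta)
        vx, vy = spec.velocity * np.cos(theta), spec.velocity * np.sin(theta)
    else:
        vx = vy = np.zeros(spec.n_puncta)

    yy, xx = np.mgrid[0:ny, 0:nx]
    xx = xx * geom.pixel_size
    yy = yy * geom.pixel_size
    frames = np.empty((n_frames, ny, nx), dtype=float)
    two_sig2 = 2.0 * sigma_um**2
    for f in range(n_frames):
        t = f * frame_time
        signal = np.full((ny, nx), float(background))
        active = np.nonzero((birth <= t) & (t < death))[0]
        for i in active:
            px = xc[i] + vx[i] * (t - birth[i])
            py = yc[i] + vy[i] * (t - birth[i])
            signal += spec.peak_brightness * np.exp(
                -((xx - px) ** 2 + (yy - py) ** 2) / two_sig2
            )
        counts = camera_offset + camera_scale * rng.poisson(signal)
        if read_noise_sd > 0:
            counts = counts + rng.normal(0.0, read_noise_sd, size=counts.shape)
        frames[f] = counts
    truth = {
        "n_puncta": spec.n_puncta,
        "radius_um": spec.radius,
        "mean_residence_s": spec.mean_residence,
        "centers_um": np.column_stack([xc, yc]).tolist(),
        "birth_s": birth.tolist(),
        "death_s": np.minimum(death, duration).tolist(),
    }
    return RasterScanStack(
        frames=frames,
        geometry=geom,
        detector_mode="camera",
        camera_offset=camera_offset,
        camera_scale=camera_scale,
        ground_truth=truth,
    )


def _check_decay_args(lifetimes, fractions, rep_rate):
    lifetimes = np.asarray(lifetimes, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if lifetimes.ndim != 1 or lifetimes.size == 0:
        raise ValueError("lifetimes must be a non-empty 1D sequence")
    if np.any(lifetimes <= 0):
        raise ValueError("lifetimes must be positive")
    if fractions.shape != lifetimes.shape:
        raise ValueError("fractions must match lifetimes in length")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if np.any(fractions < 0):
        raise ValueError("fractions must be non-negative")
    period_ns = 1e9 / rep_rate
    if np.any(lifetimes >= 10.0 * period_ns):
        warnings.warn(
            "lifetime >= 10x the excitation period: phasor lies near the "
            "origin and the inversion is ill-conditioned",
            stacklevel=3,
        )
    return lifetimes, fractions, period_ns


def simulate_decay(
    lifetimes: Sequence[float],
    fractions: Sequence[float],
    rep_rate: float,
    n_photons: int,
    seed: int,
    *,
    n_bins: int = 256,
) -> DecayHistogram:
    """Monte-Carlo TCSPC histogram under periodic pulsed excitation.

    Photon delays are drawn from an intensity-weighted mixture of
    exponentials and folded modulo one excitation period (incomplete decay
    re-excitation), then binned into ``n_bins`` channels.
    """
    lifetimes, fractions, period_ns = _check_decay_args(lifetimes, fractions, rep_rate)
    rng = np.random.default_rng(_split_seed(seed, 1)[0])
    comp = rng.choice(len(lifetimes), size=int(n_photons), p=fractions)
    t = rng.exponential(lifetimes[comp]) % period_ns
    counts, edges = np.histogram(t, bins=n_bins, range=(0.0, period_ns))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DecayHistogram(bin_centers=centers, counts=counts, rep_rate=rep_rate)


def ideal_decay_histogram(
    lifetimes: Sequence[float],
    fractions: Sequence[float],
    rep_rate: float,
    *,
    n_bins: int = 4096,
    total_counts: float = 1.0,
) -> DecayHistogram:
    """Noiseless bin-integrated decay histogram (the n_photons→∞ limit).

    Each channel holds the exact integral of the folded exponential
    mixture over the bin, scaled to ``total_counts`` photons.
    """
    lifetimes, fractions, period_ns = _check_decay_args(lifetimes, fractions, rep_rate)
    edges = np.linspace(0.0, period_ns, n_bins + 1)
    counts = np.zeros(n_bins)
    for tau, frac in zip(lifetimes, fractions):
        # folded decay e^{-t/τ}/(τ(1-e^{-T/τ})) integrates to 1 over a period
        cdf = -np.expm1(-edges / tau) / -np.expm1(-period_ns / tau)
        counts += frac * np.diff(cdf)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DecayHistogram(
        bin_centers=centers, counts=counts * total_counts, rep_rate=rep_rate
    )
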