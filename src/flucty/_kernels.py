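"""Numba-compiled Brownian-dynamics / photon-sampling kernels.

All kernels are single-threaded and seed their own RNG, so identical inputs
and seed give bit-identical output.  Positions are in µm inside a periodic
box centred on the origin; the PSF is a 3D Gaussian
``exp(-2(x²+y²)/ω0² - 2z²/ωz²)``.

Particles farther than ``2·ω0`` laterally (or ``2·ωz`` axially) from the
beam contribute < 4e-4 of their peak rate — a < 1e-4 relative truncation of
the collected signal — and are skipped.  The per-line near-set carries a
motion margin so particles can diffuse into range mid-line.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# PSF truncation radius in units of omega0 / omega_z.
CUT_SIGMAS = 2.0


@njit(cache=True)
def _wrap(delta: float, box: float) -> float:
    """Minimum-image displacement for a periodic box of extent ``box``."""
    if delta > 0.5 * box:
        delta -= box
    elif delta < -0.5 * box:
        delta += box
    return delta


@njit(cache=True)
def _advance(pos, idx, sigma, vx, dt_frac, box):
    """Advance selected particles by one Brownian(+drift) step.

    ``sigma`` is the per-particle step SD for a full reference step;
    ``dt_frac`` scales the variance (step time / reference time).
    """
    s = np.sqrt(dt_frac)
    for j in range(idx.shape[0]):
        i = idx[j]
        if sigma[i] > 0.0:
            pos[i, 0] += sigma[i] * s * np.random.normal()
            pos[i, 1] += sigma[i] * s * np.random.normal()
            pos[i, 2] += sigma[i] * s * np.random.normal()
        if vx[i] != 0.0:
            pos[i, 0] += vx[i] * dt_frac
        for a in range(3):
            half = 0.5 * box[a]
            if pos[i, a] >= half:
                pos[i, a] -= box[a]
            elif pos[i, a] < -half:
                pos[i, a] += box[a]
    return pos


@njit(cache=True)
def trace_kernel(seed, n_bins, upd, pos, sigma_blk, vx, eps_bin,
                 omega0, omega_z, box):
    """Simulate a photon-count trace at a fixed confocal spot (origin).

    Particle positions are updated every ``upd`` bins (one "block"); the
    emission rate is constant within a block.  ``sigma_blk`` is the step SD
    per block, ``vx`` the drift per block (µm), ``eps_bin`` the
    per-particle peak counts per bin.

    Returns int64 counts of length ``n_bins``.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    counts = np.zeros(n_bins, dtype=np.int64)
    lat2 = (CUT_SIGMAS * omega0) ** 2
    zcut = CUT_SIGMAS * omega_z
    inv_w2 = 2.0 / (omega0 * omega0)
    inv_z2 = 2.0 / (omega_z * omega_z)
    all_idx = np.arange(n)
    b = 0
    while b < n_bins:
        nb = min(upd, n_bins - b)
        rate = 0.0
        for i in range(n):
            z = pos[i, 2]
            if np.abs(z) > zcut:
                continue
            x = pos[i, 0]
            y = pos[i, 1]
            r2 = x * x + y * y
            if r2 > lat2:
                continue
            rate += eps_bin[i] * np.exp(-r2 * inv_w2 - z * z * inv_z2)
        for k in range(nb):
            counts[b + k] = np.random.poisson(rate)
        _advance(pos, all_idx, sigma_blk, vx, nb / upd, box)
        b += nb
    return counts


@njit(cache=True)
def raster_kernel(seed, pos, sigma_line, vx, eps_dwell,
                  n_channels, n_frames, ny, nx, pixel_size,
                  dwell_s, line_time_s, frame_time_s,
                  omega0, omega_z, box, chunk, near_margin):
    """Simulate a raster-scanned photon-counting stack (1 or 2 channels).

    The beam visits pixel (frame f, line j, pixel i) at time
    ``f*frame_time + j*line_time + i*dwell``.  Particles within emission
    range of the current line (PSF truncation radius plus the
    ``near_margin`` motion allowance) are stepped every ``chunk`` pixels
    and their PSF is scattered into the pixels within the lateral
    truncation radius; remaining particles are stepped once per line (an
    excursion past the margin would still leave them at a negligible PSF
    weight for the rest of the line).

    ``eps_dwell`` has shape (n, n_channels): per-particle peak counts per
    pixel dwell in each detection channel.  ``sigma_line`` / ``vx`` are the
    Brownian step SD and drift per full line time.  Returns an int64 array
    of shape (n_channels, n_frames, ny, nx).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    out = np.zeros((n_channels, n_frames, ny, nx), dtype=np.int64)
    lat_cut = CUT_SIGMAS * omega0
    zcut = CUT_SIGMAS * omega_z
    inv_w2 = 2.0 / (omega0 * omega0)
    inv_z2 = 2.0 / (omega_z * omega_z)
    # image physical coords: pixel centres at i*pixel_size, origin top-left,
    # field centred in the box
    x0 = -0.5 * (nx - 1) * pixel_size
    y0 = -0.5 * (ny - 1) * pixel_size
    near = np.empty(n, dtype=np.int64)
    far = np.empty(n, dtype=np.int64)
    rate = np.empty((n_channels, chunk), dtype=np.float64)
    y_cut = lat_cut + near_margin
    z_near = zcut + near_margin
    retrace = line_time_s - nx * dwell_s
    frame_gap = frame_time_s - ny * line_time_s
    all_idx = np.arange(n)
    for f in range(n_frames):
        for j in range(ny):
            y_line = y0 + j * pixel_size
            n_near = 0
            n_far = 0
            for i in range(n):
                dy = _wrap(pos[i, 1] - y_line, box[1])
                if np.abs(dy) < y_cut and np.abs(pos[i, 2]) < z_near:
                    near[n_near] = i
                    n_near += 1
                else:
                    far[n_far] = i
                    n_far += 1
            nearv = near[:n_near]
            i_px = 0
            while i_px < nx:
                npx = min(chunk, nx - i_px)
                x_start = x0 + i_px * pixel_size
                for c in range(n_channels):
                    for k in range(npx):
                        rate[c, k] = 0.0
                for m in range(n_near):
                    i = nearv[m]
                    dy = _wrap(pos[i, 1] - y_line, box[1])
                    z = pos[i, 2]
                    if np.abs(dy) >= lat_cut or np.abs(z) >= zcut:
                        continue
                    amp = np.exp(-dy * dy * inv_w2 - z * z * inv_z2)
                    # particle x relative to the chunk start (nearest image)
                    dxc = _wrap(pos[i, 0] - x_start, box[0])
                    k_lo = int(np.ceil((dxc - lat_cut) / pixel_size))
                    k_hi = int(np.floor((dxc + lat_cut) / pixel_size))
                    if k_lo < 0:
                        k_lo = 0
                    if k_hi > npx - 1:
                        k_hi = npx - 1
                    for k in range(k_lo, k_hi + 1):
                        dx = dxc - k * pixel_size
                        q = amp * np.exp(-dx * dx * inv_w2)
                        for c in range(n_channels):
                            rate[c, k] += eps_dwell[i, c] * q
                for k in range(npx):
                    for c in range(n_channels):
                        out[c, f, j, i_px + k] = np.random.poisson(rate[c, k])
                _advance(pos, nearv, sigma_line, vx, npx * dwell_s / line_time_s, box)
                i_px += npx
            if retrace > 0.0:
                _advance(pos, nearv, sigma_line, vx, retrace / line_time_s, box)
            _advance(pos, far[:n_far], sigma_line, vx, 1.0, box)
        if frame_gap > 0.0:
            _advance(pos, all_idx, sigma_line, vx, frame_gap / line_time_s, box)
    return out
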