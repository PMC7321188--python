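"""Raster image correlation spectroscopy (RICS).

RICS extracts diffusion coefficients from the *spatial* autocorrelation of
raster-scanned images by exploiting the scan timing: adjacent pixels along
the fast axis are ~µs apart, adjacent lines are ~ms apart, so the
correlation surface G(ξ,ψ) decays with both the PSF profile and the motion
that happened between pixel visits.

The fitted model for a freely diffusing species is

    G(ξ,ψ) = G0 · S(ξ,ψ;D) · T(ξ,ψ;D) + offset
    T = (1 + 4Dτ/ω0²)^-1 · (1 + 4Dτ/ωz²)^-1/2,     τ = |τ_p·ξ + τ_l·ψ|
    S = exp[ -(δr²(ξ²+ψ²)/ω0²) / (1 + 4Dτ/ω0²) ]

with pixel dwell τ_p, line time τ_l and pixel size δr.  The zero-lag point
carries the shot-noise variance and is excluded from fits.  The amplitude
gives the mean number of molecules in the focal volume, N = γ/G0, hence
the concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import fft as spfft
from scipy.ndimage import uniform_filter1d

import lmfit

from .types import BeamProfile, RasterScanStack, ScanGeometry, MOLECULES_PER_UM3_PER_NM

__all__ = [
    "ACFSurface",
    "DiffusionFit",
    "ConcentrationEstimate",
    "compute_spatial_acf",
    "average_acfs",
    "fit_diffusion",
    "concentration_from_amplitude",
    "roi_modular_analysis",
    "rics_model",
]

#: minimum ROI edge for modular analysis, pixels
MIN_ROI_EDGE = 32

#: fixed seed for fit-restart jitter (optimizer detail, not a data seed)
_JITTER_SEED = 20200531


@dataclass
class ACFSurface:
    """2D spatial (auto- or cross-) correlation surface on pixel-lag axes.

    ``values[j, i]`` is the correlation at slow-axis lag ``psi_lags[j]``
    and fast-axis lag ``xi_lags[i]``; lags run symmetrically through 0.
    """

    xi_lags: np.ndarray
    psi_lags: np.ndarray
    values: np.ndarray
    n_frames_averaged: int
    detrend_window: int
    #: standard error of each lag point from frame-to-frame scatter (optional)
    se: np.ndarray | None = None

    def at(self, xi: int, psi: int) -> float:
        """Correlation value at integer lag (ξ, ψ)."""
        i = int(np.searchsorted(self.xi_lags, xi))
        j = int(np.searchsorted(self.psi_lags, psi))
        if self.xi_lags[i] != xi or self.psi_lags[j] != psi:
            raise KeyError(f"lag ({xi}, {psi}) not on this surface")
        return float(self.values[j, i])

    @property
    def zero_lag(self) -> float:
        return self.at(0, 0)


@dataclass
class DiffusionFit:
    """Result of a one- or two-component RICS diffusion fit.

    ``components`` is sorted by descending D; each entry is ``(D, G0)``.
    A fit that hit the optimizer bounds is flagged ``boundary``; a fit
    that failed to converge is flagged ``success=False`` (never silent).
    """

    components: list[tuple[float, float]]
    offset: float
    chi2_reduced: float
    se: dict[str, float | None] = field(default_factory=dict)
    success: bool = True
    boundary: bool = False
    message: str = ""

    @property
    def D(self) -> float:
        """Fastest-component diffusion coefficient, µm²/s."""
        return self.components[0][0]

    @property
    def G0(self) -> float:
        """Fastest-component amplitude."""
        return self.components[0][1]


@dataclass
class ConcentrationEstimate:
    """Concentration from a correlation amplitude: N = γ/G0, c = N/(N_A·V_eff)."""

    value: float          # nM
    n_in_volume: float    # molecules
    v_eff: float          # µm³


def _detrended_fluctuations(
    frames: np.ndarray, detrend_window: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Remove immobile structure, return (δI per frame, frame means, bias factor).

    Subtracts a per-pixel boxcar moving average over ``detrend_window``
    frames and adds back the grand mean.  Because the window contains the
    frame itself, fluctuation power is attenuated by (1 - 1/W); the
    returned factor W/(W-1) undoes this in the averaged surface.
    """
    frames = frames.astype(float)
    if detrend_window and detrend_window > 1:
        moving = uniform_filter1d(frames, size=detrend_window, axis=0, mode="nearest")
        detr = frames - moving + frames.mean()
        bias = detrend_window / (detrend_window - 1.0)
    else:
        detr = frames
        bias = 1.0
    means = detr.mean(axis=(1, 2))
    delta = detr - means[:, None, None]
    return delta, means, bias


def _xcorr_surface(
    delta_a: np.ndarray,
    delta_b: np.ndarray,
    norm: np.ndarray,
    max_lag: int,
) -> np.ndarray:
    """Frame-averaged non-periodic (zero-padded) correlation surface.

    G(ξ,ψ) = <δa(x,y)·δb(x+ξ,y+ψ)> / norm, with the average over the
    overlapping pixels at each lag (per-lag overlap normalization).
    """
    n_frames, ny, nx = delta_a.shape
    shape = (2 * ny, 2 * nx)
    fa = spfft.rfft2(delta_a, s=shape)
    fb = spfft.rfft2(delta_b, s=shape)
    corr = spfft.irfft2(np.conj(fa) * fb, s=shape)
    # corr[.., psi % 2ny, xi % 2nx] = sum_xy a(x,y) b(x+xi, y+psi)
    max_xi, max_psi = max_lag
    xi_lags = np.arange(-max_xi, max_xi + 1)
    psi_lags = np.arange(-max_psi, max_psi + 1)
    overlap = (ny - np.abs(psi_lags))[:, None] * (nx - np.abs(xi_lags))[None, :]
    surf = corr[:, psi_lags[:, None], xi_lags[None, :]] / overlap
    return surf / norm[:, None, None]


def _check_acf_args(
    stack: RasterScanStack, detrend_window: int, max_lag
) -> tuple[int, int]:
    """Validate and normalize the lag window to (max_xi, max_psi)."""
    geom = stack.geometry
    if max_lag is None:
        max_lag = min(16, min(geom.nx, geom.ny) // 2 - 1)
    if np.isscalar(max_lag):
        max_xi = max_psi = int(max_lag)
    else:
        max_xi, max_psi = (int(v) for v in max_lag)
    if not (0 < max_xi < geom.nx / 2 and 0 < max_psi < geom.ny / 2):
        raise ValueError("max_lag must be positive and below half the field")
    if detrend_window < 0:
        raise ValueError("detrend_window must be >= 0")
    if detrend_window > stack.n_frames:
        raise ValueError(
            f"detrend_window ({detrend_window}) exceeds n_frames ({stack.n_frames})"
        )
    return max_xi, max_psi


def compute_spatial_acf(
    stack: RasterScanStack,
    detrend_window: int = 10,
    max_lag: int | tuple[int, int] | None = None,
) -> ACFSurface:
    """Spatial autocorrelation surface of a raster stack.

    Per frame, G(ξ,ψ) = <δI(x,y)·δI(x+ξ,y+ψ)> / <I>² with δI the
    mean-subtracted intensity after immobile-structure removal (boxcar
    detrend over ``detrend_window`` frames); surfaces are averaged over
    frames.  The estimator is non-periodic: shifted frames are compared
    only on their overlap (no wrap-around).  ``max_lag`` may be one
    integer or ``(max_xi, max_psi)``; slow species need a wide slow-axis
    window because their temporal decay spans many line times.
    """
    max_xi, max_psi = _check_acf_args(stack, detrend_window, max_lag)
    frames = stack.photon_frames().astype(float)
    if np.allclose(frames.mean(axis=(1, 2)), 0.0):
        raise ValueError("zero-mean image: normalization undefined")
    delta, means, bias = _detrended_fluctuations(frames, detrend_window)
    per_frame = bias * _xcorr_surface(delta, delta, means**2, (max_xi, max_psi))
    values = per_frame.mean(axis=0)
    n = per_frame.shape[0]
    se = per_frame.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else None
    return ACFSurface(
        xi_lags=np.arange(-max_xi, max_xi + 1),
        psi_lags=np.arange(-max_psi, max_psi + 1),
        values=values,
        n_frames_averaged=stack.n_frames,
        detrend_window=detrend_window,
        se=se,
    )


def average_acfs(surfaces: Sequence[ACFSurface]) -> ACFSurface:
    """Pool correlation surfaces from repeated acquisitions of one condition.

    Component decomposition is noise-limited on a single desk-scale stack;
    averaging the surfaces of N independent acquisitions before fitting
    (√N noise reduction, same expectation) is the standard way to resolve
    a two-component mixture.  Lag axes must match.
    """
    if not surfaces:
        raise ValueError("no surfaces to average")
    first = surfaces[0]
    for s in surfaces[1:]:
        if not (
            np.array_equal(s.xi_lags, first.xi_lags)
            and np.array_equal(s.psi_lags, first.psi_lags)
        ):
            raise ValueError("surfaces have mismatched lag axes")
    values = np.mean([s.values for s in surfaces], axis=0)
    if all(s.se is not None for s in surfaces):
        se = np.sqrt(np.mean([s.se**2 for s in surfaces], axis=0) / len(surfaces))
    else:
        se = None
    return ACFSurface(
        xi_lags=first.xi_lags.copy(),
        psi_lags=first.psi_lags.copy(),
        values=values,
        n_frames_averaged=sum(s.n_frames_averaged for s in surfaces),
        detrend_window=first.detrend_window,
        se=se,
    )


def rics_model(
    xi: np.ndarray,
    psi: np.ndarray,
    D: float,
    G0: float,
    beam: BeamProfile,
    geom: ScanGeometry,
) -> np.ndarray:
    """Single-species RICS correlation model G0·S·T at pixel lags (ξ, ψ)."""
    xi = np.asarray(xi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    tau = np.abs(geom.pixel_dwell_s * xi + geom.line_time_s * psi)
    w2 = beam.omega0**2
    denom_xy = 1.0 + 4.0 * D * tau / w2
    denom_z = 1.0 + 4.0 * D * tau / beam.omega_z**2
    spatial = np.exp(-(geom.pixel_size**2) * (xi**2 + psi**2) / w2 / denom_xy)
    return G0 * spatial / (denom_xy * np.sqrt(denom_z))


def _fit_points(
    acf: ACFSurface,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    xi, psi = np.meshgrid(acf.xi_lags, acf.psi_lags)
    keep = ~((xi == 0) & (psi == 0))  # shot-noise point excluded
    se = None
    if acf.se is not None:
        se = acf.se[keep].ravel()
        floor = np.median(se[se > 0]) * 1e-3 if np.any(se > 0) else 1.0
        se = np.maximum(se, floor)
    return xi[keep].ravel(), psi[keep].ravel(), acf.values[keep].ravel(), se


def fit_diffusion(
    acf: ACFSurface,
    beam: BeamProfile,
    geom: ScanGeometry,
    n_components: int = 1,
    init: dict | None = None,
    max_restarts: int = 5,
) -> DiffusionFit:
    """Least-squares fit of a 1- or 2-component diffusion model to an ACF.

    Two components are parameterized as (D_fast, ratio = D_slow/D_fast ∈
    (0,1)) so the labels cannot swap during optimisation; results are
    re-expressed as components sorted by descending D.  Bounded
    least-squares with up to ``max_restarts`` restarts from jittered
    initial values (fixed jitter seed); non-convergence is reported in the
    result flags, never silently.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    xi, psi, g, se = _fit_points(acf)
    if not np.all(np.isfinite(g)):
        raise ValueError("ACF surface contains non-finite values")
    g_scale = max(float(np.nanmax(np.abs(g))), 1e-12)

    init = dict(init or {})
    d0 = init.get("D", 5.0 if n_components == 1 else (5.0, 0.5))
    params = lmfit.Parameters()
    if n_components == 1:
        params.add("D", value=float(np.atleast_1d(d0)[0]), min=1e-4, max=500.0)
        params.add("G0", value=init.get("G0", g_scale), min=0.0)
    else:
        d_fast0, d_slow0 = np.atleast_1d(d0)[:2]
        params.add("D_fast", value=float(d_fast0), min=1e-4, max=500.0)
        params.add("ratio", value=float(d_slow0 / d_fast0), min=1e-4, max=0.999)
        params.add("G0_fast", value=init.get("G0_fast", 0.5 * g_scale), min=0.0)
        params.add("G0_slow", value=init.get("G0_slow", 0.5 * g_scale), min=0.0)
    params.add("offset", value=init.get("offset", 0.0))

    def model_values(p: lmfit.Parameters) -> np.ndarray:
        v = p.valuesdict()
        if n_components == 1:
            m = rics_model(xi, psi, v["D"], v["G0"], beam, geom)
        else:
            m = rics_model(xi, psi, v["D_fast"], v["G0_fast"], beam, geom)
            m = m + rics_model(
                xi, psi, v["D_fast"] * v["ratio"], v["G0_slow"], beam, geom
            )
        return m + v["offset"]

    def residual(p):
        r = model_values(p) - g
        return r / se if se is not None else r

    rng = np.random.default_rng(_JITTER_SEED)
    best = None
    for attempt in range(max_restarts + 1):
        p = lmfit.Parameters()
        for name, par in params.items():
            val = par.value
            if attempt > 0 and name != "offset":
                val = val * np.exp(rng.normal(0.0, 0.5))
                val = np.clip(val, par.min + 1e-12 if np.isfinite(par.min) else val,
                              par.max - 1e-12 if np.isfinite(par.max) else val)
            p.add(name, value=val, min=par.min, max=par.max)
        try:
            res = lmfit.minimize(residual, p, method="least_squares", xtol=1e-8,
                                 ftol=1e-8, gtol=1e-8)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res

    if best is None:
        return DiffusionFit(
            components=[(np.nan, np.nan)] * n_components, offset=np.nan,
            chi2_reduced=np.nan, success=False, message="optimizer failed",
        )

    v = best.params.valuesdict()
    se = {k: best.params[k].stderr for k in best.params}
    if n_components == 1:
        comps = [(v["D"], v["G0"])]
    else:
        comps = [
            (v["D_fast"], v["G0_fast"]),
            (v["D_fast"] * v["ratio"], v["G0_slow"]),
        ]
    comps.sort(key=lambda c: -c[0])
    boundary = any(
        np.isfinite(par.min) and abs(par.value - par.min) < 1e-10
        or np.isfinite(par.max) and abs(par.value - par.max) < 1e-10
        for name, par in best.params.items()
        if name != "offset"
    )
    dof = max(len(g) - len(best.params), 1)
    return DiffusionFit(
        components=comps,
        offset=float(v["offset"]),
        chi2_reduced=float(best.chisqr / dof),
        se=se,
        success=bool(best.success),
        boundary=boundary,
        message=str(best.message),
    )


def concentration_from_amplitude(
    fit: DiffusionFit,
    beam: BeamProfile,
    component: int = 0,
) -> ConcentrationEstimate:
    """Concentration from a fitted zero-lag amplitude.

    The apparent number of molecules is N = γ/G0, which for a 3D Gaussian
    PSF is the mean number inside the PSF volume integral
    V_eff = ∫PSF dV = γ·π^{3/2}·ω0²·ωz (so that G0 = 1/(c·π^{3/2}ω0²ωz)
    exactly); the concentration is N/(N_A·V_eff) expressed in nM.
    """
    g0 = fit.components[component][1]
    if not (g0 > 0):
        raise ValueError("amplitude G0 must be positive")
    n = beam.gamma / g0
    v_eff = beam.gamma * beam.effective_volume
    conc = n / (MOLECULES_PER_UM3_PER_NM * v_eff)
    return ConcentrationEstimate(value=float(conc), n_in_volume=float(n), v_eff=v_eff)


def roi_modular_analysis(
    stack: RasterScanStack,
    rois: Sequence[tuple[int, int, int, int]],
    n_components: int = 1,
    detrend_window: int = 10,
    max_lag: int | None = None,
    beam: BeamProfile | None = None,
) -> list[dict]:
    """Independent RICS analysis of rectangular cytosolic regions.

    Each ROI is ``(x0, y0, w, h)`` in pixel coordinates; the scan timing of
    the parent stack is preserved (an ROI row still takes one full line
    time).  Returns one record per ROI with the ROI, its ACF and its fit.
    """
    beam = beam or BeamProfile()
    geom = stack.geometry
    results = []
    for roi in rois:
        x0, y0, w, h = roi
        if min(w, h) < MIN_ROI_EDGE:
            raise ValueError(
                f"ROI {roi} is too small: minimum edge is {MIN_ROI_EDGE} pixels"
            )
        if x0 < 0 or y0 < 0 or x0 + w > geom.nx or y0 + h > geom.ny:
            raise ValueError(f"ROI {roi} falls outside the {geom.nx}x{geom.ny} field")
        sub_geom = ScanGeometry(
            nx=w,
            ny=h,
            pixel_size=geom.pixel_size,
            pixel_dwell=geom.pixel_dwell,
            line_time=geom.line_time_s * 1e3,
            frame_time=geom.frame_time_s,
            n_frames=geom.n_frames,
        )
        sub = RasterScanStack(
            frames=stack.frames[:, y0 : y0 + h, x0 : x0 + w],
            geometry=sub_geom,
            detector_mode=stack.detector_mode,
            camera_offset=stack.camera_offset,
            camera_scale=stack.camera_scale,
        )
        acf = compute_spatial_acf(sub, detrend_window=detrend_window, max_lag=max_lag)
        fit = fit_diffusion(acf, beam, sub_geom, n_components=n_components)
        results.append({"roi": tuple(roi), "acf": acf, "fit": fit})
    return results
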