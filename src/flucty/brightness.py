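"""Number & Brightness (N&B) mapping and photon counting histogram (PCH).

N&B turns a stack of raster frames into per-pixel moment maps: the ratio
B = σ²/⟨k⟩ exceeds the shot-noise value of 1 in proportion to the
molecular brightness, so oligomerization shows up as pixels whose
brightness is a multiple of the monomer standard.  PCH instead uses the
full photon-count distribution of a stationary-point trace: diffusion
through the inhomogeneous PSF makes the distribution super-Poissonian in a
way that separates the molecular brightness ε from the mean occupancy N̄.

Brightness is reported in counts per second per molecule (cpsm) using the
peak-brightness convention (count rate of a molecule at the PSF maximum),
the same convention used by the simulator and the PCH model, so N&B, PCH
and RICS amplitudes are mutually consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .types import BeamProfile, PointTrace, RasterScanStack

__all__ = [
    "BrightnessMap",
    "ClassificationResult",
    "PCHistogram",
    "PCHFit",
    "nb_maps",
    "deadtime_correct",
    "classify_pixels",
    "pch_histogram",
    "pch_fit",
    "pch_single_molecule_pmf",
    "pch_pmf",
]


@dataclass
class BrightnessMap:
    """Per-pixel N&B statistics of a raster stack."""

    mean_map: np.ndarray
    var_map: np.ndarray
    B_map: np.ndarray
    epsilon_map: np.ndarray  # cpsm
    n_map: np.ndarray        # apparent number; NaN where B <= 1
    mode: str
    pixel_dwell_s: float
    gamma: float
    n_frames: int = 0

    def positive_mask(self, threshold: float | None = None) -> np.ndarray:
        """Pixels with a positive fluorophore signal.

        Photon-counting default: mean count > 0.1 per dwell.  Camera mode
        (``mean_map`` is offset-subtracted photons): mean above 2× the
        shot-noise SD of the per-pixel mean.
        """
        if threshold is not None:
            return self.mean_map > threshold
        if self.mode == "photon_counting":
            return self.mean_map > 0.1
        n = max(self.n_frames, 1)
        shot_sd = np.sqrt(np.maximum(self.mean_map, 0.0) / n)
        return self.mean_map > 2.0 * shot_sd

    def summary_epsilon(self, threshold: float | None = None) -> float:
        """Mean ε (cpsm) over positive-signal pixels — the map's headline value."""
        mask = self.positive_mask(threshold)
        if not mask.any():
            return float("nan")
        return float(np.nanmean(self.epsilon_map[mask]))


@dataclass
class ClassificationResult:
    """Oligomer-class labels and pixel percentages (of positive pixels)."""

    class_map: np.ndarray  # strings: background/monomer/dimer/higher
    pct_monomer: float
    pct_dimer: float
    pct_higher: float
    n_positive: int


@dataclass
class PCHistogram:
    """Photon-count frequency histogram of a point trace."""

    k_values: np.ndarray
    frequencies: np.ndarray
    bin_time: float

    @property
    def n_bins_total(self) -> int:
        return int(self.frequencies.sum())


@dataclass
class PCHFit:
    """Single-species PCH maximum-likelihood estimate."""

    epsilon: float       # cpsm
    n_bar: float         # mean molecules in the focal volume (c·V_eff)
    chi2_reduced: float
    success: bool = True
    degenerate: bool = False   # histogram indistinguishable from pure Poisson
    message: str = ""


def deadtime_correct(rate: float | np.ndarray, dead_time: float) -> float | np.ndarray:
    """Non-paralyzable detector dead-time correction of an observed rate.

    true = observed / (1 - observed·τ_dead).  Identity at τ_dead = 0,
    monotone increasing in the observed rate, and undefined at saturation
    (observed·τ_dead ≥ 1).
    """
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    rate = np.asarray(rate, dtype=float)
    loss = rate * dead_time
    if np.any(loss >= 1.0):
        raise ValueError("observed rate × dead time >= 1: detector saturated")
    out = rate / (1.0 - loss)
    return float(out) if out.ndim == 0 else out


def nb_maps(
    stack: RasterScanStack,
    dead_time: float | None = None,
    beam: BeamProfile | None = None,
) -> BrightnessMap:
    """Per-pixel Number & Brightness maps of a raster stack.

    Photon-counting mode: B = σ²/⟨k⟩; the apparent single-molecule
    brightness per dwell is (B − 1)/γ (the PSF shape factor γ converts
    the fluctuation-weighted brightness to the peak-brightness
    convention), and ε_cpsm = (B − 1)/(γ·τ_dwell) after dead-time
    correction of the rate.  Camera mode: photon statistics are recovered
    through the offset/scale calibration first.  N = ⟨k⟩/(B − 1), marked
    NaN where B ≤ 1.
    """
    beam = beam or BeamProfile()
    if stack.n_frames < 20:
        warnings.warn(
            f"only {stack.n_frames} frames: N&B moment estimates will be noisy",
            stacklevel=2,
        )
    if stack.detector_mode == "camera" and dead_time is not None:
        raise ValueError("dead-time correction applies to photon-counting data only")

    if stack.detector_mode == "photon_counting":
        frames = stack.frames.astype(float)
        mean = frames.mean(axis=0)
        var = frames.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(mean > 0, var / mean, 0.0)
    else:
        frames = stack.frames.astype(float)
        mean_raw = frames.mean(axis=0)
        var = frames.var(axis=0, ddof=1)
        mean = (mean_raw - stack.camera_offset) / stack.camera_scale
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(mean > 0, var / (stack.camera_scale**2 * mean), 0.0)
    b = np.maximum(b, 0.0)

    dwell = stack.geometry.pixel_dwell_s
    excess = b - 1.0
    # negative excess is pure estimator noise; keep it so that spatial
    # averages stay unbiased (clipping would rectify noise upward)
    eps_map = excess / (beam.gamma * dwell)
    if dead_time:
        rate = mean / dwell
        factor = deadtime_correct(rate, dead_time) / np.where(rate > 0, rate, 1.0)
        eps_map = eps_map * factor
    with np.errstate(divide="ignore", invalid="ignore"):
        n_map = np.where(excess > 0, mean / excess, np.nan)
    return BrightnessMap(
        mean_map=mean,
        var_map=var,
        B_map=b,
        epsilon_map=eps_map,
        n_map=n_map,
        mode=stack.detector_mode,
        pixel_dwell_s=dwell,
        gamma=beam.gamma,
        n_frames=stack.n_frames,
    )


def classify_pixels(
    bmap: BrightnessMap,
    epsilon_mono: float,
    band_half_width: float = 0.5,
) -> ClassificationResult:
    """Label pixels as monomer/dimer/higher relative to a monomer standard.

    With half-width w, the monomer band is [(1−w)·ε_mono, (1+w)·ε_mono],
    the dimer band ((1+w)·ε_mono, (2+w)·ε_mono], anything above is
    "higher"; background pixels carry no positive signal.  Percentages are
    computed over positive-signal pixels only.
    """
    if epsilon_mono <= 0:
        raise ValueError("epsilon_mono must be positive")
    w = band_half_width
    pos = bmap.positive_mask()
    eps = bmap.epsilon_map
    cls = np.full(bmap.epsilon_map.shape, "background", dtype=object)
    mono = pos & (eps >= (1 - w) * epsilon_mono) & (eps <= (1 + w) * epsilon_mono)
    dim = pos & (eps > (1 + w) * epsilon_mono) & (eps <= (2 + w) * epsilon_mono)
    high = pos & (eps > (2 + w) * epsilon_mono)
    cls[mono] = "monomer"
    cls[dim] = "dimer"
    cls[high] = "higher"
    n_pos = int(pos.sum())
    pct = lambda m: 100.0 * m.sum() / n_pos if n_pos else 0.0
    return ClassificationResult(
        class_map=cls,
        pct_monomer=pct(mono),
        pct_dimer=pct(dim),
        pct_higher=pct(high),
        n_positive=n_pos,
    )


def pch_histogram(trace: PointTrace) -> PCHistogram:
    """Photon counting histogram: frequency of each integer count per bin."""
    if len(trace.counts) == 0:
        raise ValueError("empty trace")
    kmax = int(trace.counts.max())
    freq = np.bincount(trace.counts, minlength=kmax + 1)
    return PCHistogram(
        k_values=np.arange(kmax + 1),
        frequencies=freq,
        bin_time=trace.bin_time,
    )


def pch_single_molecule_pmf(
    k_max: int,
    eps_counts: float,
    beam: BeamProfile,
    v_ref_factor: float = 30.0,
    n_quad: int = 256,
) -> tuple[np.ndarray, float]:
    """p₁(k): count distribution of ONE molecule diffusing in V_ref.

    For the 3D Gaussian PSF the volume with intensity above u = e^{-t} has
    dV/dt = (π/√2)·ω0²·ωz·√t, so

        p₁(k≥1) = (C/V_ref) ∫₀^∞ √t · Poisson(k; ε·e^{-t}) dt,

    with p₁(0) absorbing the (huge) rest of the reference volume.
    ``eps_counts`` is the peak count ε·bin_time.  Returns (pmf over
    0..k_max, n_ref_per_molecule_volume = V_ref in units of V_eff).
    """
    v_psf = (np.pi / 2.0) ** 1.5 * beam.omega0**2 * beam.omega_z  # ∫PSF
    v_ref = v_ref_factor * np.pi**1.5 * beam.omega0**2 * beam.omega_z
    c_geom = np.pi / np.sqrt(2.0) * beam.omega0**2 * beam.omega_z
    # composite Gauss-Legendre: fine panel near t=0 (integrand varies on a
    # 1/k scale there), coarse panel for the exponential tail
    nodes, weights = np.polynomial.legendre.leggauss(n_quad // 2)
    t_list, w_list = [], []
    for a, b in ((0.0, 2.0), (2.0, 40.0)):
        t_list.append(0.5 * (b - a) * (nodes + 1.0) + a)
        w_list.append(0.5 * (b - a) * weights)
    t = np.concatenate(t_list)
    wt = np.concatenate(w_list)
    lam = eps_counts * np.exp(-t)
    k = np.arange(1, k_max + 1)
    logpois = (
        k[:, None] * np.log(np.maximum(lam[None, :], 1e-300))
        - lam[None, :]
        - gammaln(k + 1)[:, None]
    )
    integrand = np.sqrt(t)[None, :] * np.exp(logpois)
    pk = (c_geom / v_ref) * (integrand @ wt)
    p0 = 1.0 - pk.sum()
    pmf = np.concatenate([[p0], pk])
    return pmf, v_ref / v_psf


def pch_pmf(
    k_max: int,
    eps_counts: float,
    n_bar: float,
    beam: BeamProfile,
    v_ref_factor: float = 30.0,
) -> np.ndarray:
    """Full PCH P(k) for a Poisson number of identical diffusing molecules.

    The count distribution is the compound-Poisson convolution of p₁ with
    the Poisson-distributed number of molecules in V_ref (mean
    n_ref = n_bar·V_ref/V_eff); computed exactly in Fourier space.
    ``n_bar`` is the mean number in V_eff = π^{3/2}ω0²ωz.
    """
    p1, _ = pch_single_molecule_pmf(k_max, eps_counts, beam, v_ref_factor)
    n_ref = n_bar * v_ref_factor  # V_ref = factor × V_eff
    # pad to avoid circular aliasing of the compound distribution
    m = 1
    while m < 4 * (k_max + 1):
        m *= 2
    phi = np.fft.rfft(p1, n=m)
    pk = np.fft.irfft(np.exp(n_ref * (phi - 1.0)), n=m)[: k_max + 1]
    return np.maximum(pk, 0.0)


def pch_fit(
    hist: PCHistogram,
    beam: BeamProfile,
    v_ref_factor: float = 30.0,
    min_total_bins: int = 10_000,
) -> PCHFit:
    """Maximum-likelihood single-species PCH fit → (ε in cpsm, N̄).

    Fits the 3D-Gaussian PCH model by multinomial likelihood over the
    observed count histogram.  A histogram statistically consistent with a
    pure Poisson (no super-Poissonian excess) cannot constrain ε and is
    returned with ``degenerate=True`` and ε = 0.
    """
    if hist.n_bins_total < min_total_bins:
        raise ValueError(
            f"PCH needs at least {min_total_bins} bins, got {hist.n_bins_total}"
        )
    k = hist.k_values
    freq = hist.frequencies.astype(float)
    n_tot = freq.sum()
    mean_k = float((k * freq).sum() / n_tot)
    var_k = float(((k - mean_k) ** 2 * freq).sum() / (n_tot - 1))
    k_max = int(k.max()) + 5

    # Mandel Q = γ·ε_counts decides whether there is any excess to fit
    q = var_k / mean_k - 1.0 if mean_k > 0 else 0.0
    q_se = np.sqrt(2.0 / n_tot)  # SD of var/mean for Poisson, relative
    if q < 3.0 * q_se:
        return PCHFit(
            epsilon=0.0,
            n_bar=np.nan,
            chi2_reduced=np.nan,
            degenerate=True,
            message="histogram consistent with pure Poisson; ε unresolved",
        )

    def nll(theta: np.ndarray) -> float:
        log_eps, log_n = theta
        pk = pch_pmf(k_max, np.exp(log_eps), np.exp(log_n), beam, v_ref_factor)
        pk = np.maximum(pk[: len(k)], 1e-300)
        return -float((freq * np.log(pk)).sum())

    # moment-based starting point: Q = γ·ε_counts, mean = ε_counts·γ·n_bar
    eps0 = max(q / beam.gamma, 1e-3)
    n0 = max(mean_k / max(q, 1e-6), 1e-3)
    res = optimize.minimize(
        nll,
        x0=[np.log(eps0), np.log(n0)],
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
    )
    eps_counts, n_bar = np.exp(res.x)
    pk = pch_pmf(k_max, eps_counts, n_bar, beam, v_ref_factor)[: len(k)]
    expected = n_tot * np.maximum(pk, 1e-300)
    good = expected > 5
    chi2 = float(((freq[good] - expected[good]) ** 2 / expected[good]).sum())
    dof = max(int(good.sum()) - 2, 1)
    return PCHFit(
        epsilon=float(eps_counts / hist.bin_time),
        n_bar=float(n_bar),
        chi2_reduced=chi2 / dof,
        success=bool(res.success),
        message=str(res.message),
    )
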