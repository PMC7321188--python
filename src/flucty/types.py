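"""Core domain types shared across the fluctuation-imaging toolkit.

Units are µm for lengths and seconds for times throughout, except where a
field name says otherwise (``pixel_dwell`` in µs, ``line_time`` in ms, decay
bins in ns).  Molecular brightness ``epsilon`` is expressed in counts per
second per molecule (cpsm), the conventional unit of fluorescence
fluctuation spectroscopy, and converted to counts per bin/dwell internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "BeamProfile",
    "SpeciesSpec",
    "ScanGeometry",
    "RasterScanStack",
    "PointTrace",
    "DecayHistogram",
    "PunctaSimSpec",
    "GAMMA_3DG",
]

#: PSF shape factor for a 3D Gaussian observation volume, gamma = 2^(-3/2).
GAMMA_3DG = 2.0 ** -1.5


@dataclass(frozen=True)
class BeamProfile:
    """Two-photon / confocal excitation volume modelled as a 3D Gaussian.

    Parameters
    ----------
    omega0
        Lateral 1/e² beam-waist radius in µm.  Daily GFP-standard
        calibrations of the instrument modelled here give 0.35–0.4 µm.
    axial_ratio
        ωz/ω0, the elongation of the focal volume along the optical axis.
    gamma
        Dimensionless shape factor relating the zero-lag correlation
        amplitude to the mean number of molecules (``N = gamma / G0``);
        2^(-3/2) for the 3D Gaussian PSF.
    """

    omega0: float = 0.4
    axial_ratio: float = 3.0
    gamma: float = GAMMA_3DG

    def __post_init__(self) -> None:
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")
        if self.axial_ratio < 1:
            raise ValueError("axial_ratio must be >= 1")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must lie in (0, 1]")

    @property
    def omega_z(self) -> float:
        """Axial 1/e² radius in µm."""
        return self.omega0 * self.axial_ratio

    @property
    def effective_volume(self) -> float:
        """FCS effective volume π^{3/2}·ω0²·ωz in µm³."""
        return float(np.pi ** 1.5 * self.omega0 ** 2 * self.omega_z)


#: Avogadro constant, molecules per mole.
N_AVOGADRO = 6.02214076e23

#: molecules per µm³ for a 1 nM solution (1e-9 mol/L × N_A × 1e-15 L/µm³)
MOLECULES_PER_UM3_PER_NM = N_AVOGADRO * 1e-24


@dataclass(frozen=True)
class SpeciesSpec:
    """One fluorescent species in a simulated scene.

    ``epsilon`` is the peak molecular brightness: the detected count rate of
    a single molecule at the centre of the PSF, in cpsm.  ``oligomer``
    multiplies a monomer brightness, so ``SpeciesSpec(epsilon=35_000,
    oligomer=2)`` emits like a dimer of 35 000-cpsm monomers.
    """

    D: float
    epsilon: float
    concentration: float
    motion: Literal["diffusive", "directed", "immobile"] = "diffusive"
    velocity: float = 0.0
    oligomer: int = 1

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")
        if self.oligomer < 1:
            raise ValueError("oligomer must be a positive integer")
        if self.motion == "directed" and self.velocity == 0:
            raise ValueError("directed motion requires a positive velocity")
        if self.motion not in ("diffusive", "directed", "immobile"):
            raise ValueError(f"unknown motion kind {self.motion!r}")

    @property
    def effective_epsilon(self) -> float:
        """Brightness including the oligomer multiplier, cpsm."""
        return self.epsilon * self.oligomer

    @property
    def number_density(self) -> float:
        """Molecules per µm³ at this concentration."""
        return self.concentration * MOLECULES_PER_UM3_PER_NM


@dataclass(frozen=True)
class ScanGeometry:
    """Raster-scan timing and sampling metadata.

    Defaults mirror a typical 2P RICS acquisition: 256×256 px at
    50 nm/pixel, 12.5 µs pixel dwell, 100 frames.
    """

    nx: int = 256
    ny: int = 256
    pixel_size: float = 0.05        # µm
    pixel_dwell: float = 12.5       # µs
    line_time: float | None = None  # ms; None -> nx * pixel_dwell (no retrace)
    frame_time: float | None = None  # s; None -> ny * line_time
    n_frames: int = 100

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.n_frames) <= 0:
            raise ValueError("nx, ny and n_frames must be positive")
        if self.pixel_size <= 0 or self.pixel_dwell <= 0:
            raise ValueError("pixel_size and pixel_dwell must be positive")
        if self.line_time is not None and self.line_time_s < self.nx * self.pixel_dwell_s:
            raise ValueError("line_time must cover nx * pixel_dwell")
        if self.frame_time is not None and self.frame_time < self.ny * self.line_time_s:
            raise ValueError("frame_time must cover ny * line_time")

    @property
    def pixel_dwell_s(self) -> float:
        return self.pixel_dwell * 1e-6

    @property
    def line_time_s(self) -> float:
        if self.line_time is None:
            return self.nx * self.pixel_dwell_s
        return self.line_time * 1e-3

    @property
    def frame_time_s(self) -> float:
        if self.frame_time is None:
            return self.ny * self.line_time_s
        return float(self.frame_time)

    @property
    def field_of_view(self) -> tuple[float, float]:
        """(width, height) of the scanned field in µm."""
        return (self.nx * self.pixel_size, self.ny * self.pixel_size)


@dataclass
class RasterScanStack:
    """A time-ordered stack of raster-scanned intensity frames.

    ``frames`` has shape ``(n_frames, ny, nx)``.  In ``photon_counting``
    mode pixel values are integer photon counts; in ``camera`` mode they are
    EMCCD counts related to photons by ``counts = offset + scale * photons``.
    """

    frames: np.ndarray
    geometry: ScanGeometry
    detector_mode: Literal["photon_counting", "camera"] = "photon_counting"
    camera_offset: float = 0.0
    camera_scale: float = 1.0
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        expected = (self.geometry.n_frames, self.geometry.ny, self.geometry.nx)
        if self.frames.shape != expected:
            raise ValueError(
                f"frame array shape {self.frames.shape} does not match geometry {expected}"
            )
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.detector_mode == "photon_counting" and not np.issubdtype(
            self.frames.dtype, np.integer
        ):
            raise ValueError("photon_counting frames must be integer-typed")
        if self.detector_mode not in ("photon_counting", "camera"):
            raise ValueError(f"unknown detector_mode {self.detector_mode!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def photon_frames(self) -> np.ndarray:
        """Frames converted back to (estimated) photon counts."""
        if self.detector_mode == "photon_counting":
            return self.frames
        return (self.frames - self.camera_offset) / self.camera_scale


@dataclass
class PointTrace:
    """Binned photon counts collected at a single confocal spot."""

    counts: np.ndarray
    bin_time: float  # s

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.bin_time <= 0:
            raise ValueError("bin_time must be positive")

    @property
    def duration(self) -> float:
        return len(self.counts) * self.bin_time

    @property
    def mean_rate(self) -> float:
        """Mean detected count rate, counts/s."""
        return float(self.counts.mean() / self.bin_time)


@dataclass
class DecayHistogram:
    """A TCSPC-style fluorescence decay folded into one excitation period."""

    bin_centers: np.ndarray  # ns
    counts: np.ndarray
    rep_rate: float  # Hz

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_centers.shape != self.counts.shape:
            raise ValueError("bin_centers and counts must have the same shape")
        if self.rep_rate <= 0:
            raise ValueError("rep_rate must be positive")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        period = self.period_ns
        width = self.bin_centers[1] - self.bin_centers[0] if len(self.bin_centers) > 1 else period
        span = self.bin_centers[-1] - self.bin_centers[0] + width
        if not np.isclose(span, period, rtol=1e-6):
            raise ValueError(
                f"bins span {span:.4f} ns but one period is {period:.4f} ns"
            )

    @property
    def period_ns(self) -> float:
        return 1e9 / self.rep_rate

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class PunctaSimSpec:
    """Ground truth for a simulated population of membrane puncta.

    ``mean_residence`` is the mean of the exponential lifetime a punctum
    spends on the membrane; ``None`` (or ``inf``) makes every punctum
    persist for the whole movie.
    """

    n_puncta: int = 10
    radius: float = 0.2          # µm (Gaussian sigma-equivalent: see simkit)
    peak_brightness: float = 100.0  # photons/frame at the spot centre
    mean_residence: float | None = None  # s
    motion: Literal["static", "directed"] = "static"
    velocity: float = 0.0        # µm/s

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.peak_brightness < 0:
            raise ValueError("peak_brightness must be >= 0")
        if self.mean_residence is not None and self.mean_residence <= 0:
            raise ValueError("mean_residence must be positive (or None)")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")
        if self.motion == "directed" and self.velocity == 0:
            raise ValueError("directed motion requires a positive velocity")


def species_list(species: Sequence[SpeciesSpec]) -> list[SpeciesSpec]:
    """Validate a species list (non-empty, correct type)."""
    out = list(species)
    if not out:
        raise ValueError("at least one species is required")
    for s in out:
        if not isinstance(s, SpeciesSpec):
            raise TypeError("species must be SpeciesSpec instances")
    return out
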