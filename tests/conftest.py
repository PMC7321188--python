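import numpy as np
import pytest

from flucty.types import BeamProfile, ScanGeometry, SpeciesSpec


@pytest.fixture(scope="session")
def beam() -> BeamProfile:
    """GFP-calibration beam: ω0 = 0.4 µm, ωz/ω0 = 3."""
    return BeamProfile(omega0=0.4, axial_ratio=3.0)


@pytest.fixture(scope="session")
def small_geom() -> ScanGeometry:
    """Desk-scale raster geometry that keeps simulations fast."""
    return ScanGeometry(nx=64, ny=64, pixel_size=0.05, pixel_dwell=12.5, n_frames=40)


@pytest.fixture(scope="session")
def mgfp_species() -> SpeciesSpec:
    """Cytosolic monomeric GFP: D = 9 µm²/s, ε = 35 000 cpsm, 30 nM."""
    return SpeciesSpec(D=9.0, epsilon=35_000, concentration=30.0)


def acf_direct(frame: np.ndarray, max_lag: int) -> np.ndarray:
    """Brute-force nested-loop spatial correlation of one frame.

    Independent oracle for the FFT estimator: non-periodic, per-lag
    overlap-normalized, G = <δI δI> / <I>² with δI = I − mean(I).
    """
    frame = frame.astype(float)
    ny, nx = frame.shape
    mean = frame.mean()
    delta = frame - mean
    lags = range(-max_lag, max_lag + 1)
    out = np.zeros((2 * max_lag + 1, 2 * max_lag + 1))
    for j, psi in enumerate(lags):
        for i, xi in enumerate(lags):
            acc = 0.0
            n = 0
            for y in range(ny):
                for x in range(nx):
                    yy, xx = y + psi, x + xi
                    if 0 <= yy < ny and 0 <= xx < nx:
                        acc += delta[y, x] * delta[yy, xx]
                        n += 1
            out[j, i] = acc / n / mean**2
    return out
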