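# Methods

`flucty` implements the fluctuation-imaging analysis chain used to
characterize protein dynamics in live cells — raster image correlation
spectroscopy (RICS), Number & Brightness (N&B), photon counting histogram
(PCH) analysis, phasor FLIM/FRET, two-channel cross-correlation RICS
(ccRICS), and TIRF puncta dynamics — together with a Brownian-dynamics
photon simulator that plays the role of the microscope, so that every
stage can be validated by recovering known ground truth.

## Simulation model

**Emission.** The excitation/detection volume is a 3D Gaussian,
PSF(r) = exp(−2(x²+y²)/ω0² − 2z²/ωz²), with lateral waist ω0 (default
0.4 µm, the GFP-standard calibration value) and axial ratio ωz/ω0
(default 3; the axial waist is rarely published and is configurable). A
molecule's peak brightness ε (cpsm) is its detected count rate at the PSF
maximum; this peak convention is used consistently by the simulator, the
PCH model and the N&B conversion, and sets the PSF shape factor
γ = 2^{−3/2} relating fluctuation amplitudes to molecule numbers.

**Motion.** Molecules diffuse with per-axis Gaussian steps of variance
2DΔt (plus optional uniform drift, or immobility) in a periodic box.
Lateral box extent is max(8ω0, field of view + 2ω0) so that the imaged
field never feels the boundary; axial extent is 5ωz. Molecule numbers
are Poisson-drawn from concentration × box volume, matching the
open-system number statistics the correlation analyses assume.

**Detection.** Counts are Poisson samples of the summed instantaneous
rate; raster scans evaluate each pixel's rate at that pixel's acquisition
time (pixel index × dwell + line index × line time + frame index × frame
time), including idle retrace time, so diffusion decorrelates the image
along the slow axis exactly as the RICS model assumes. Camera-mode TIRF
movies add offset/scale calibration and optional Gaussian read noise.
Photobleaching, triplet blinking, detector afterpulsing and dead time are
deliberately not simulated.

**Numerical integration granularity.** Exact per-photon dynamics are
unnecessary and unaffordable; positions are advanced in blocks — every 8
scanned pixels for particles within emission range of the current line
(once per line for the rest, which stay below the PSF truncation level of
2ω0/2ωz ≈ 4·10⁻⁴ of peak for the whole line), and for point traces at
the interval where the RMS Brownian step is ω0/4. Block-boundary
positions are exact equilibrium Brownian samples, so count-distribution
statistics (PCH, N&B moments, mean rates) are unbiased for any block
size; only temporal correlation inside a block is coarsened, an effect
bounded by 4D·t_block/ω0² ≈ 1% of the correlation decay at the default
settings.

## RICS

The spatial correlation surface is estimated per frame as
G(ξ,ψ) = ⟨δI(x,y)·δI(x+ξ,y+ψ)⟩/⟨I⟩² with zero-padded FFT correlation and
per-lag overlap normalization — cells are not periodic, so wrap-around is
explicitly not used (a brute-force nested-loop estimator in the test
suite pins the convention). Immobile structure can be removed by
subtracting a per-pixel boxcar moving average over `detrend_window`
frames (default 10) and adding back the grand mean; because the window
contains the frame itself this attenuates fluctuation power by 1 − 1/W,
which the estimator corrects by W/(W−1). The correction assumes
frame-to-frame decorrelation; for species slow enough to correlate
across the window the detrend removes genuine signal, so analyses of
simulated scenes (which contain no immobile structure) use
`detrend_window=0`.

The fitted model is G = offset + Σᵢ G0ᵢ·S(ξ,ψ;Dᵢ)·T(ξ,ψ;Dᵢ) with
T = (1+4Dτ/ω0²)⁻¹(1+4Dτ/ωz²)^{−1/2}, S = exp[−δr²(ξ²+ψ²)/ω0² /
(1+4Dτ/ω0²)], τ = |τ_p ξ + τ_l ψ|. The zero-lag point carries shot noise
and is excluded (the ξ = ±1 neighbours are kept). Points are weighted by
the frame-to-frame standard error of the surface. The free offset is
required: subtracting the per-frame spatial mean leaves a small uniform
negative pedestal in the estimator. Two components are parameterized as
(D_fast, ratio = D_slow/D_fast ∈ (0,1)) to forbid label swapping; fits
use bounded least squares with up to 5 restarts from jittered starting
values (fixed jitter seed), tolerance 1e-8, default starts D = 5 µm²/s
(one component) or (5, 0.5) µm²/s. Non-convergence and bound-pinned
solutions are flagged, never silent.

Concentration follows from the amplitude: N = γ/G0 is the mean number of
molecules in the PSF volume integral V = γ·π^{3/2}ω0²ωz (equivalently
G0 = 1/(c·π^{3/2}ω0²ωz)), giving c = N/(N_A·V).

**Two-component decomposition needs pooling.** On a single desk-scale
stack the component split is noise-limited: per-stack fits of an
equal-amplitude 4.1/1.2 µm²/s mixture scatter strongly (the fast
component has a heavy right tail, the slow one occasionally collapses to
the bound). Averaging the correlation surfaces of repeated acquisitions
of the same condition before fitting (`average_acfs`) restores stable
recovery; the package treats pooling as the standard protocol for
mixtures, mirroring how multiple cells are averaged in practice. A wide
slow-axis lag range matters for the slowest components, whose temporal
term has decayed by only ~50% at ψ = 16 lines.

## Number & Brightness

Photon-counting mode: B = σ²/⟨k⟩ per pixel over frames; apparent
brightness per dwell is (B − 1)/γ, converted to ε in cpsm by dividing by
the pixel dwell after non-paralyzable dead-time correction of the rate
(true = observed/(1 − observed·τ_dead)). Camera mode recovers photon
statistics through the offset/scale calibration first; dead-time
correction is a photon-counting concept and is rejected there. Negative
per-pixel excesses are kept so spatial averages stay unbiased. Two
estimator properties worth knowing: with a finite number of frames the
variance of slowly-moving species is shrunk (low-frequency truncation; a
few per cent at the default settings, ~20% for D ≲ 0.5 µm²/s at small
fields), and with a fixed total molecule number in the periodic box the
excess is reduced by (∫PSF)²/(V_box·∫PSF²) ≈ 1–2%. Both cancel in
normalized brightness (sample/monomer-standard ratio), which is the
quantity used for oligomer classification.

Pixel classification against a monomer standard ε_mono uses bands with
half-width w (default 0.5): monomer [(1−w), (1+w)]·ε_mono, dimer
((1+w), (2+w)]·ε_mono, higher above; the published analysis does not
define its band edges, so they are configurable. Percentages are taken
over pixels with positive signal (mean > 0.1 counts/dwell in photon
mode; > 2 shot-noise SDs of the mean above offset in camera mode).

## PCH

The single-species PCH uses the 3D-Gaussian single-molecule distribution
p₁(k ≥ 1) = (C/V_ref)∫₀^∞ √t·Poisson(k; ε·bin_time·e^{−t}) dt with
C = π ω0² ωz/√2 (the closed-form volume density of PSF iso-surfaces),
evaluated by composite Gauss–Legendre quadrature, and compounds it over a
Poisson-distributed number of molecules in a reference volume of 30
effective volumes via an FFT of the characteristic function. Parameters
(ε, N̄) are fitted by multinomial maximum likelihood (Nelder–Mead in log
space, moment-based start). A histogram whose variance/mean ratio is
within 3 SE of 1 carries no brightness information and is returned with
ε = 0 and a degeneracy flag. No first-order out-of-focus correction is
applied; at the simulated signal levels the plain 3D-Gaussian model
recovers ε within a few per cent (a documented limitation for real 2P
data with aberrated PSFs). Bin times must stay well below the diffusion
time so molecules are quasi-static within a bin (20 µs vs ~4 ms here).

## Phasor FLIM

g = Σ I cos(nωt)/Σ I, s = Σ I sin(nωt)/Σ I at bin centres, ω = 2π × the
80 MHz repetition rate, harmonic n = 1 by default. Because bin
integration multiplies both Fourier sums by the same sinc factor, the
phase lifetime τ_phase = s/(gω) is insensitive to binning; τ_mod picks up
an O((ωΔt)²/24) attenuation, negligible at ≥ 256 bins. Mono-exponential
decays land on the universal circle (g−½)² + s² = ¼; mixtures lie inside
at the intensity-weighted combination of component phasors, and then
τ_phase < τ_mod. The instrument response is treated as ideal by default;
single-reference calibration against a known-lifetime standard (the
purified-GFP 2.95 ns convention) is implemented as complex division.
FRET efficiency is E = 1 − τ_DA/τ_D from donor-lifetime shortening.

## ccRICS and interaction fractions

Cross-correlation surfaces share the autocorrelation estimator and
detrend. Zero-lag amplitudes come from diffusion-model fits, so
uncorrelated shot noise and background do not contribute. The bound
fraction of green-labelled molecules is the amplitude ratio
100·G×(0)/G_r(0) (= N_complex/N_green); the symmetric red fraction swaps
the denominators. Values outside [0, 100] are clipped and flagged; the
Cauchy–Schwarz bound |G×(0)| ≤ √(G_g(0)·G_r(0)) is exposed as a sanity
check. In the simulator a bound fraction shares trajectories between one
green and one red molecule per complex; complexes move with the slower
partner's D. Scan asymmetry along the fast axis (directed transport) is
quantified as a normalized forward/backward difference of G(±ξ, 0) and
reported as a diagnostic only, not fitted to a transport model.
Channel registration is assumed perfect and spectral bleed-through zero.

## Puncta

Detection is multi-scale Laplacian-of-Gaussian with radius = √2 × the
best LoG scale, a robust threshold (background median + `threshold_sd` ×
1.4826·MAD, default 5), intensity-weighted sub-pixel centroids, and
brightest-first suppression of duplicate shoulder detections closer than
0.75×(r₁+r₂). Tracking is greedy nearest-neighbour linking (closest
pair first, ties by intensity difference) within `max_link_distance`
(default 3 pixels) and gap closing up to `max_gap` (default 1) missing
frames. Residence statistics exclude censored tracks (touching the first
or last frame) and tracks shorter than 2 detections (single-frame tracks
are dominated by spurious detections). Excluding censored tracks in a
finite movie still truncates the longest lifetimes, biasing the mean
down by roughly μ/T_movie; recovery simulations therefore observe for
≥ 15 mean lifetimes. The published TIRF series pairs 1000 frames with a
100 s examination window, so the default frame interval is 0.1 s
(configurable); membrane "puncta variance" tables report the mean
residence time, and the package follows that meaning. The
largest-component summary thresholds the time-averaged image, labels
8-connected components and reports the one with the greatest integrated
intensity (equivalent-disk radius). Intensity-fluctuation events on a
track are maximal monotone runs whose net change exceeds the inclusion
line `min_change`.

## Problem sizes in the recovery suite

The validation suite and `scripts/acceptance.py` run the full chain at
desk scale as the package's own standard problem sizes: 128² px (50
nm/pixel, 12.5 µs dwell) one-component stacks of 50 frames; 64² px
concentration stacks; 40 s point traces at 50 kHz; 13–27 min TIRF movies
at 0.5 s frames with 150 puncta events. Two-component mixtures use a
slow-scan acquisition designed for the slow population — 64×96 px,
12.5 µs dwell, 8 ms line time (long retrace), 60 frames, bright labels —
with a ξ ≤ 16 / ψ ≤ 32 lag window; several pools of ~10 repeated
acquisitions are each ACF-averaged and fitted, and the pooled estimates
averaged. Validation ensembles at these settings recover the slow
component without detectable bias (grand mean 0.67 µm²/s over 7
independent pools at truth 0.67) with a per-pool SD near 15%, so a
4-pool average carries a ~7–8% standard error. Tolerances follow the
recovery targets (10–25% stochastic, exact for the deterministic phasor
inversion).

## Known limitations

- No photobleaching/blinking in the simulator, so detrending paths are
  validated only structurally, not against bleaching-like truth.
- The PCH model is single-species; mixtures bias ε toward an
  intensity-weighted average.
- Greedy tracking can swap identities when puncta pass within the link
  radius; the residence statistics are insensitive to swaps.
- Absolute N&B ε inherits a small negative bias for slow species at
  finite frame counts (see above); normalized brightness does not.
- Camera-mode normalized brightness depends on an instrument
  normalization constant that published tables do not always state; it
  is left configurable rather than guessed.
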