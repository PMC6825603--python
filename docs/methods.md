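# Methods

This note describes the models implemented in `aostedfcs`, the choices
made where the design was genuinely open, and what the simulation-based
tests do and do not demonstrate about real measurements.

## Focal fields

Pupil fields are propagated with a **scalar Debye integral**: each sample
of the uniformly filled unit pupil contributes a plane wave with
transverse wavevector `k0·NA·ρ` and axial wavevector
`k0·sqrt(n² − NA²ρ²)`; components beyond the propagating aperture
(`NA·ρ > n`) are discarded. Polarization (Richards–Wolf) effects are not
modelled. The scalar model reproduces the quantities this package needs —
null position, tip/tilt/defocus shifts, qualitative null degradation and
the axial compression of the effective volume — but it underestimates
null filling for some aberration modes, because a coherent scalar focus
preserves deep field zeros more readily than a vectorial one. This is a
known fidelity limit.

Aberrations are expanded in **Noll-indexed Zernike modes**; a coefficient
is the rms phase in radians over the pupil disk. The instrument's
repositioning modes are tip (j=2), tilt (j=3) and the **high-NA defocus**
phase `a·sqrt(1 − (NA·ρ/n)²)`, which refocuses without the spherical-term
mixing of Zernike j=4. Its amplitude unit is not Zernike-normalized; we
calibrate it so that **one unit shifts the focus axially by 339 nm**
(equivalently `scale = 2π·n·339 nm/λ`), which makes the tabulated
shift-per-radian conversions (172 nm tip/tilt, 339 nm defocus at
λ=755 nm, NA=1.4) exact by construction for defocus and exact to the
printed rounding (λ/(π·NA) = 171.66 nm) for tip/tilt.

The z-STED "bottle beam" uses a central π phase step of radius `1/√2`
(pupil-area balance), the standard choice producing a true on-axis null
(< 10⁻³ of the pattern maximum on our default grids; the small residual
is pupil-pixelation ripple, which also sets the ~1 nm noise floor of the
null localization). Null tracking descends on a lightly smoothed field
from the nominal focus and refines per axis with a multi-point parabola,
which is robust against that ripple.

**Depth aberration.** Focusing a depth `d` through an index step
`n_i → n_s` adds the pupil phase
`(2π/λ)·d·(sqrt(n_s² − NA²ρ²) − sqrt(n_i² − NA²ρ²))` on the transmitted
sub-aperture `ρ ≤ n_s/NA`. The package reports its Noll coefficients
after removing piston/tip/tilt/defocus by least squares (Zernike j=4 by
default; the instrument's high-NA defocus profile optionally). For
d=3 µm, oil (1.518) into 1:1 water:glycerol (1.398), λ=755 nm, NA=1.4
this projection gives |c₁₁| ≈ 0.80 rad rms (≈0.63 with high-NA-defocus
removal) — the full scalar-theory mismatch aberration. Sensorless systems
often measure substantially smaller correction amplitudes than this
full-theory value (for example when the depletion beam underfills the
physical pupil, or when partial correction already restores the metric
optimum); the package reports the theoretical projection and leaves such
instrument factors to the user.

## Effective observation volume

The confocal excitation–detection profile is the product of the
excitation focus (640 nm) and the pinhole-filtered detection focus
(685 nm), both diffraction-limited; this folds the pinhole into a single
3-D profile whose volume integrals converge. Depletion follows the
standard saturated-depletion approximation: survival `exp(−ζ·S)` where S
is the depletion intensity normalized to the *unaberrated* pattern's
focal peak and ζ is the dimensionless saturation (the stand-in for STED
laser power; the mW↔ζ mapping is instrument-specific and out of scope).
Scaling ζ by the aberrated pattern's raw peak-intensity ratio models a
fixed laser power: an aberrated pattern both deforms *and weakens*, which
is what makes the molecule-number metric convex around zero aberration.
Effective volumes are **not** re-normalized, so aberrations and
misalignment cost detected signal, as on the instrument.

Volumes are summarized by 1-D Gaussian fits through the peak: 1/e² radii
ω_xy, ω_z (FWHM = √(2 ln 2)·ω), aspect ratio K = ω_z/ω_xy, the
Gaussian-equivalent volume V_eff = π^{3/2}·ω_xy²·ω_z, and the occupancy
volume V_occ = (∫W)²/∫W² (these coincide exactly for a 3-D Gaussian).
The **lateral-shrinking calibration** is
`ω_norm(K) = w_inf + (1 − w_inf)·exp((K − K_conf)/κ)`, constrained to 1
at the confocal aspect ratio; the functional form is recorded in the
calibration's metadata so alternatives can be swapped. Its inversion maps
a lateral transit-time ratio to K via the anomalous transit scaling
τ ∝ ω^{2/α} (ω² for Brownian). At very strong simulated depletion the
volume becomes oblate (K < 1); the inversion's lower clamp is therefore a
parameter (default 1).

## Photon-count simulation

A fixed number of molecules diffuses in a periodic box (canonical
ensemble; occupancy fluctuations of the much smaller observation volume
are Poisson-like). Brownian paths use i.i.d. Gaussian increments with
per-axis variance 2·D·dt; anomalous subdiffusion uses fractional Brownian
motion with Hurst H = α/2, generated exactly by Davies–Harte circulant
embedding, with per-axis MSD = 2·Γ·t^α. Triplet blinking is a two-state
continuous-time Markov chain (rates k_dark = T/τ_T, k_bright = (1−T)/τ_T,
so the stationary dark fraction is T and the relaxation time τ_T),
realized as exponential dwells rasterized onto the bin grid. Detection is
Poisson per 1 µs bin with rate
`Σ_mol brightness0·dt·W(r)·bright + background·dt`; an optional
exponential decay of brightness emulates photobleaching. Every molecule
consumes its own child of `SeedSequence(seed)`, so traces are bit-exactly
reproducible and independent of internal batching.

Default physical conditions: λ_dep 755 nm / λ_exc 640 nm, NA 1.4 oil
(n 1.518); triplet τ_T 12 µs (solution) or 5 µs (cells), T ≈ 0.15;
α = 1 in solution, α = 0.75 as the cell-like preset; 1 MHz sampling.
Brightness (counts/s per molecule at the volume centre), diffusion
coefficients and concentrations are set per experiment; the worked
configurations in the tests use dye-like values (D of tens of µm²/s,
peak brightness 150–300 kHz, background a few hundred counts/s).

What the generator does *not* emulate: detector afterpulsing and dead
time, excitation saturation, dye photophysics beyond one dark state,
chromatic or vectorial focal effects, and spatially varying specimen
aberrations. Passing tests therefore demonstrate the correctness and
statistical behaviour of the estimators and the control loop under the
stated model, not instrument performance.

## Correlation and fitting

The ACF estimator is the normalized time average
`G(τ) = <δI(t)·δI(t+τ)>/<I>²` with population statistics. The
multiple-tau scheme evaluates lags 1..m (m = 16) on the raw trace, then
repeatedly halves the time resolution by pairwise averaging and evaluates
lags m/2+1..m per level; each level is normalized by the coarsened
trace's own mean, making every value exactly equal to the direct
estimator applied to the binned trace (the property the oracle tests
assert). Sub-trace splitting (default 5 parts) provides per-lag
dispersion used as fit weights. Bleaching is corrected by local
averaging: `I_c = I/√(f/f₀) + f₀(1 − √(f/f₀))` with f a moving-window
mean and f₀ its first interior value; a long-lag QC flags curves whose
tail does not return to ~0 (default threshold 10% of the amplitude over
the last decade).

The fit model is `G = G_T·G_D` with
`G_T = 1 + T/(1−T)·exp(−τ/τ_T)` and
`G_D = (1/N)·(1+(τ/τ_xy)^α)^{-1}·(1+(τ/τ_xy)^α/K²)^{-1/2} + δ`.
Fits are least squares on linear G (log-spaced lags give natural
short-lag emphasis), weighted by sub-trace dispersion when available,
with lmfit/Levenberg–Marquardt. Deterministic initialization: N from the
inverse short-lag amplitude, τ_xy from the half-amplitude lag. δ is
bounded to ±20% of the amplitude to avoid degeneracy with the tail — the
free offset is what absorbs the finite-trace negative bias of the ACF
estimator. Confocal fits pin K (conventionally 4 on instruments whose
excitation path is uncorrected; tests against simulated volumes pin K to
the volume's true aspect ratio) and τ_T. The coupled STED fit frees
(N, τ_xy, T, δ) and derives K from τ_xy/τ_xy,confocal through the
calibration at every evaluation; when the calibration is the identity
(no lateral shrinking) the coupling carries no information and the fit
falls back to the legacy fixed-lateral model, making the two variants
coincide exactly in that limit. τ_z is reported as K^{2/α}·τ_xy (K²·τ_xy
for Brownian; the α-generalization is a convention, flagged in output).
Concentration is N/(N_A·V_eff).

## Moment metrics and the AO loop

N and ε come from count moments: `N = <Φ>²/(var(Φ) − <Φ>)`,
`ε = (var(Φ) − <Φ>)/<Φ>` (population statistics). Shot noise is removed
by the −<Φ> term, but triplet blinking biases both at fine binning —
hence the default **20 µs re-binning** before metric evaluation (the
choice is empirical and exposed in `MetricConfig`). A non-positive
denominator (shot-noise-limited trace) yields an invalid value that
propagates as +inf so the quadratic fit excludes the point.

The sensorless loop applies, per mode, a uniform symmetric 7-point bias
grid (±0.8 rad by default, ±0.6 for the refinement rounds of the solution
preset), computes the N metric on 5 sub-traces per bias, fits a parabola
and moves to its vertex. Safeguards: concave fits and vertices clamped to
the scan edge apply **no** correction (extrapolating such fits is how
sensorless loops run away to spurious optima); modes with fewer than four
valid points are skipped. The solution preset runs one round over
tip/tilt/astigmatism/coma, three rounds over defocus + both sphericals at
0.8 rad, then two refinement rounds at 0.6 rad. The cell preset drops
astigmatism (negligible in the cytosol) and secondary spherical (its
cross-talk with primary spherical costs more acquisitions than it
returns) and runs **two passes** over the remaining modes: around a large
aberration the metric curve is strongly asymmetric, so one quadratic scan
under-corrects and the second pass, operating near the optimum, completes
the correction. Only the depletion path is aberrated by default
(single-adaptive-element instrument); static excitation-path aberrations
can be added to emulate uncorrected signal loss.

## Problem sizes used in the tests

The Monte-Carlo tests run at reduced scales chosen to keep the full suite
in the tens of minutes on one CPU while leaving clear statistical
margins: recovery tests use 0.4–0.8 s traces of 90–280 molecules;
closed-loop tests use 0.2 s acquisitions at 10 µs sampling, 128 molecules
in a 1.6 µm box, saturation ζ = 8, and focal grids of 48² pupil samples /
25–50 nm voxels; the analytic shift and depth computations use 192²
pupils and ≤10 nm lateral voxels. Tolerances in the tests are the
method-level ones (e.g. 10% parameter recovery, 0.1 rad residual
aberration, 15% axial-ratio recovery), not functions of these sizes.

## Known limitations

* Scalar (non-vectorial) focal fields; no polarization or chromatic
  effects; null filling under some modes is weaker than on instruments.
* The exponential depletion law is the standard approximation; no
  pulse-timing or re-excitation effects.
* The moment metrics are not triplet- or shot-noise-corrected beyond the
  Mandel −<Φ> term; re-binning is the mitigation.
* The coupled-K inversion is ill-conditioned when the simulated lateral
  shrink is small (low ζ); the tests use saturation levels where the
  calibration carries real information.
* The depth-aberration projection is full scalar theory; measured
  sensorless correction amplitudes on real systems can be several-fold
  smaller (see the depth-aberration section).
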