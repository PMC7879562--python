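# Methods

## Motion model

The molecule position follows the linear SDE `dX = (V + F X) dt + G dB`
with constant coefficient matrices; time-varying coefficients are out of
scope since every supported study uses constants. The discrete-time
solution at arbitrary times is the exact Gauss–Markov recursion with
transition matrix `phi(dt) = expm(F dt)`, drift increment
`a(dt) = (∫₀^dt expm(F s) ds) V` and noise covariance
`Q(dt) = ∫₀^dt expm(F s) G Gᵀ expm(Fᵀ s) ds`. For the scalar family
`F = f I` (the common Ornstein–Uhlenbeck case) all three have closed
forms; `a` for general invertible `F` uses `F⁻¹(phi − I)V` guarded by a
condition-number limit of 1e8, beyond which (and for non-commuting
`F, G Gᵀ`) the defining integrals are evaluated by adaptive quadrature
rather than Lyapunov solves, so the implementation matches the definition
it claims to compute. Units are μm and seconds everywhere internally;
configuration files accept milliseconds for times and convert on load.

The initial state is a fixed point by default. The studies never state a
random initial law, so a fixed `x(t0)` is assumed; a Gaussian initial law
is supported for generality.

## Optics

Three image functions are provided: the Airy profile
`q(u) = J₁²(α|u|)/(π|u|²)` with `α = 2π n_a/λ` (removable singularity at
the origin filled with `α²/4π`), the isotropic Gaussian approximation with
width σ, and the Born–Wolf defocus model (complex ρ-integral on [0,1],
64-node Gauss–Legendre; at `z0 = 0` it reduces to Airy, which the tests
verify to 1e-6). The magnification defaults to `M = 100·I` when a
configuration omits it — the standard objective magnification in the
localization-accuracy literature, and the value that makes 6.5 μm pixels
comparable to a σ = 0.1 μm PSF.

Pixel integrals `I_C(x)` use the error-function product for Gaussian PSFs
with diagonal `M`, and fixed-order tensor Gauss–Legendre quadrature
(default 16 nodes per axis, deterministic given the configuration)
otherwise. Two performance layers matter for the Monte Carlo likelihood,
which evaluates millions of pixel integrals: radial image functions are
tabulated and interpolated for bulk quadrature (`density_approx`), and
`OpticalMap(pixel_table=True)` caches the pixel integral as a bilinear
table over the emitter-to-pixel-center offset (step 8 nm; measured error
≤ 7e-5 absolute, ~1% relative where the integral is below 1e-3 — well
under the Monte Carlo noise floor). Detector-coverage integrals over large
rectangles use the exact angular form `(1/2π)∫ P(R(φ)) dφ` of the radial
cumulative mass `P`, which handles the Airy profile's heavy `~2/(παr)`
tail that defeats naive quadrature.

A note on the Airy↔Gaussian correspondence: `α = 13.23` is conventionally
paired with σ = 0.1 μm, but pixel integrals of those two profiles differ
by ~12%; the Gaussian matching the Airy peak intensity (σ = √2/α ≈ 0.107
μm) agrees to 0.01% and is what the correspondence test asserts.

## Photon arrivals

Detections are a Poisson process with non-negative piecewise-continuous
intensity; constant, piecewise-constant and callable intensities are
supported. Conditional on `L` detections in the exposure, the ordered
arrival times are the order statistics of `L` i.i.d. draws from the
normalized intensity (joint density `L! ΠΛ(τ_l)/Λ̄^L` on the ordered
simplex); sampling uses this representation directly — exact and
`O(L log L)` — rather than rejection on full Poisson paths. The benchmark
studies fix small exact photon counts (1–4); the constant rate is set to
`n_photons / exposure` since only photon totals are specified.

## Likelihoods

Four data models share the same three stochastic layers:

* **fundamental** — exact impact points, arrival times marginalized;
* **infinite practical** — per-pixel counts, the pixel array assumed to
  tile the plane;
* **finite practical** — counts on a finite array with an explicit
  complement region; the number of missed photons is summed out, truncated
  at 20 terms or when a term falls below 1e-8 of the running sum
  (convergence is factorial in the missed count);
* **noisy practical** — real-valued intensities `i_k = z_k + Poisson(β_k) +
  N(η_k, σ_k²)`; the count-configuration sum is truncated per pixel to
  counts within 6 readout sigmas of `i_k` and to totals inside the Poisson
  bulk, and the Poisson–Gaussian convolution series is truncated at a tail
  mass of 1e-12.

The count likelihood's label-vector sum is enumerated exactly (lexicographic
multiset permutations) under a hard cap of 1e6 vectors; exceeding the cap
raises a typed error, and a uniform label-vector subsampler is available as
an explicitly approximate fallback. Per-photon pixel integrals are computed
once per (trajectory sample, occupied pixel) and reused across all label
vectors.

Monte Carlo estimation draws `N` conditional arrival-time sequences and
`M_c` trajectories per sequence. All random draws derive from a fixed seed
stream independent of the motion parameters (common random numbers), so
the likelihood surface seen by an optimizer is a fixed smooth function of
θ. The estimator is unbiased for the likelihood, not its logarithm; the
log of the averaged estimate carries an `O(variance/2)` downward bias that
shrinks with `N·M_c`, and evaluation reports include the per-sequence
standard error. Within a batch fit, each image gets its own seed stream so
surface errors stay independent across images.

Stationary emitters short-circuit all of this: the infinite model becomes
the exact multinomial `p_L · L!/(Πz_k!) · Π p_k^{z_k}` and the finite
model the thinned-Poisson product `Π_k Poisson(z_k; Λ̄ p_k)` — both exact,
deterministic, and used as oracles for the Monte Carlo paths in the tests.

## Estimation

Free parameters are any subset of `x0, y0, D, F, Vx, Vy`; `D` is
optimized in log space. Initial guesses: the count-weighted pixel centroid
mapped through `M⁻¹` for the location, and mid-range defaults (`D = 1`
μm²/s, `F = −5`/s, `V = 0`) for the dynamics — the studies state no
initialization, so these are this package's choices. Optimization is
bounded Nelder–Mead on the CRN-smoothed objective (no gradient formulas
are assumed), with optional multi-start (3 perturbed starts by default in
the API; the batch studies use a single start for runtime).

A caveat documented here because it shapes what the benchmark studies can
show: the joint per-image MLE at very low photon counts (L ≈ 4) with free
`(x0, y0, D, F)` places substantial probability on the `D → 0` boundary.
With `D = 0` the trajectory is the deterministic relaxation curve
`x0 e^{F τ}`; choosing `x0` and `F` to thread that curve through the
photon positions, with the PSF absorbing residuals, often yields a
strictly higher exact likelihood than the true diffusive parameters (this
was verified with closed-form, Monte-Carlo-free likelihood evaluations,
while the expected log-likelihood across many images is still maximized
at the truth, confirming the likelihood itself). The consequence is a
negative small-sample bias in `D̂` and a correlated bias in `F̂` at L = 4 —
a genuine boundary-estimate property of maximum likelihood in this regime,
not an artifact of the Monte Carlo approximation (larger `M_c` sharpens
the collapse). The bias and pixel-size-trend studies therefore fail their
idealized no-bias expectations at this photon count, and their tests
record that outcome.

## Fisher information and CRLB

For stationary emitters the practical-model information is the multinomial
closed form `I = n_eff Σ_k (∂p_k/∂θ)ᵀ(∂p_k/∂θ)/p_k` over pixels plus the
complement cell, with analytic error-function derivatives for Gaussian
optics (finite differences, step 1e-3 in transformed units, otherwise);
`n_eff` is the fixed photon count `L` when conditioning on it, or the
Poisson mean when averaging. The benchmark 3-photon configuration gives a
localization accuracy of 58.74 nm per coordinate (insensitive to the
sub-pixel emitter position at this pixel-to-PSF ratio), conditioning on
exactly L = 3 detected photons.

Moving molecules use the score-based Monte Carlo estimator: simulate
images at θ, form scores by central finite differences of the CRN
log-likelihood, and average the outer products — positive semidefinite by
construction. The literal definition-form sum over count vectors with
finite-difference derivatives is implemented for tiny systems (K ≤ 4,
L ≤ 3) as an exact oracle only; the full nested-integral expression over
label-vector pairs is exponentially large and is not a production path.
The noisy model additionally offers a direct 1D quadrature for the
single-pixel case. The information ordering fundamental ≥ practical ≥
noisy (CRLB non-decreasing along the chain) is asserted in the tests.

## Synthetic studies and their scope

`run_example` packages four studies: Monte Carlo convergence of a
pixel-hit probability; joint-estimation bias at 4 photons (Gaussian and
Airy); stationary localization spread vs the CRLB at 3 photons; and the
pixel-size dependence of drift-coefficient estimates (widths 4–11.5 μm).
The `scale` factor multiplies image counts and Monte Carlo sizes; the
default study sizes used by the test suite are 100 images with
`(N, M_c) = (16, 128)` (Gaussian) and `(12, 96)` (Airy) for the bias
study, and 20–50 images per width at `(8, 64)` for the pixel sweep.

The generator emulates exactly the model the likelihood assumes —
Markovian linear-SDE motion, Poisson arrivals, independent photon impacts,
ideal binning, optional Poisson+Gaussian camera noise. It does not emulate
fluorophore photophysics (blinking, bleaching), dipole-orientation
effects, sCMOS/EMCCD gain chains, drift of the optical system, or
location-dependent detection efficiency; passing tests therefore certify
the estimator under the stated model, not robustness to those real-data
effects.

## Numerical conventions

Pixels are half-open rectangles `[lo, hi)`, labeled row-major and 1-based,
with the grid origin at the low corner (none of this is standardized in
the literature; it is fixed here and honored by simulator and likelihood
alike). Boundary impacts resolve to the higher-coordinate pixel.
Degenerate inputs raise typed errors: singular transition covariances
(`DegenerateDensityError`), label sets over the cap
(`TooManyConfigurationsError`), intensities outside any count's readout
support (`DegenerateDataError`). All sampling goes through explicitly
passed seeded generators; batch outputs are byte-identical given the same
configuration and seed.
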