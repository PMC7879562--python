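# pixtraj

Parameter estimation for single-molecule trajectories imaged by pixelated
detectors.

In single-molecule fluorescence microscopy, a moving, fluorescently labeled
molecule emits photons that a camera collects during an exposure interval.
The camera does not record when each photon arrived or where exactly it
struck the detector — only how many photons accumulated in each pixel. Most
analysis methods paper over this by adding a "localization noise" term to
the motion model. `pixtraj` instead implements the exact stochastic forward
model and its likelihood, for researchers in biophysics and quantitative
microscopy who want estimates and accuracy bounds that account for
pixelation, photon statistics and motion blur without approximation.

## The model

The molecule position `X(t)` (μm) follows a linear stochastic differential
equation

    dX(t) = (V + F X(t)) dt + G dB(t),       G = sqrt(2 D) I,

with drift matrix `F` (1/s), zero-order drift `V` (μm/s) and diffusion
coefficient `D` (μm²/s). Photon detections form a Poisson process with
intensity `Λ(t)` on the exposure `[t0, t]`; a photon emitted while the
molecule is at `x` lands on the detector at `r` with density

    f_x(r) = q(M⁻¹ r − x) / |det M|,

where `q` is the image function (Airy, Gaussian, or Born–Wolf PSF) and `M`
the lateral magnification. A pixel array `C_1 … C_K` then reduces the data
to counts `z_k`. The likelihood of an image with `L = Σ z_k` photons is

    Pr[S = z] = p_L · E[ Σ_{v ∈ A(z)} Π_l I_{C_{v_l}}(X(τ_l)) ],

where `p_L` is the Poisson photon-number probability, `A(z)` is the set of
`L!/(z_1!…z_K!)` assignments of chronologically ordered photons to pixels,
`I_C(x) = ∫_C f_x(r) dr`, and the expectation runs over the conditional
arrival times `τ_1 < … < τ_L` and the trajectory. The package evaluates
this by nested Monte Carlo (N arrival-time sequences × M_c trajectories),
with exact closed forms for stationary emitters; maximizes it over motion
parameters (`x0`, `y0`, `D`, `F`, `V`); and computes the Fisher information
and Cramér–Rao lower bound (CRLB) — the best achievable estimator standard
deviation — for all three data models (exact impact points, pixel counts,
and counts corrupted by Poisson background plus Gaussian readout noise).

## Worked example

Localize a stationary molecule from 100 simulated images, three photons
each (Gaussian PSF σ = 0.1 μm, 6.5 μm pixels, 60×60 detector, 100×
magnification):

```python
import pixtraj as px

report = px.run_example("ex53", scale=1.0, seed=1)
print(report)
```

prints (seed 1):

```
sample sd of x0_hat:  51.0 nm
sample sd of y0_hat:  55.2 nm
CRLB (localization):  58.74 nm per coordinate
```

Three photons pin the location down to about 58 nm at best — the
unpixelated bound is σ/√3 = 57.7 nm and the 6.5 μm pixels cost ≈1 nm more.
The sample spreads of the maximum-likelihood estimates scatter around that
bound, i.e. the estimator is essentially efficient. The `examples/`
directory walks through each capability (trajectory simulation, image
formation, likelihood evaluation, fitting, CRLB-vs-pixel-size sweeps), and
the `pixtraj` command line exposes `simulate`, `fit`, `crlb` and
`run-example` for shell use.

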