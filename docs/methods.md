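# Methods

## Pupil models

All pupils live on an even N×N grid, centred at the 0-based pixel
(N/2, N/2). A pixel belongs to a region when its integer centre satisfies
the closed inequality (≤), which makes every mask bit-reproducible.

* **Circular**: binary disc of radius ρ₀ (pixels).
* **Spiky**: the disc united with `n_spikes` wedge-shaped protrusions of
  angular half-width `spike_halfwidth_deg` (default 6°). The spike is a
  parameterized wedge, not a traced silhouette. Regular mode places spikes
  at equal angles starting at 0° with radial extent εr; irregular mode
  draws per-spike lengths from U(0.5 εr, 1.5 εr) and jitters angles by
  U(−pitch/4, +pitch/4) from a seeded `numpy` Generator, so the maximum
  radial support is ρ₀ + 1.5 εr. The internal/external radius ratio is
  α = ρ₀/(ρ₀ + εr).
* **Modulated**: rim-weighted transmission t(ρ) = ρ/ρ₀ (linear) or
  (ρ/ρ₀)² (quadratic) inside the disc, zero outside, optional spikes at
  amplitude 1. Rim-weighted (increasing) profiles are the ones whose
  cutoffs fall below the circular value; centre-weighted profiles would
  move it the other way.

The εr ≪ ρ₀ regime is the modelling assumption behind the thin-annulus
approximation below; only ρ₀ + max extent < N/2 is enforced.

## Analytic amplitude PSFs

For a circularly symmetric transmission t(s), s = ρ/ρ₀ ∈ [0,1], the radial
amplitude PSF is the Hankel-type integral h(w) ∝ ∫₀¹ t(s) J₀(ws) s ds in
the reduced coordinate w = 2πρ₀r/(fλ). Closed forms:

* Airy (uniform disc): h = 2J₁(w)/w.
* Spiky, thin-annulus approximation: h = 2J₁(w)/w + β J₀(w), β ∈ [0,1),
  default β = 0.5. β weights the annular fringe contribution.
* Exact two-radius form: h = 2J₁(w)/w + 2/(1−α²) [J₁(w₁)/w₁ − α J₁(w)/w]
  with w₁ = w(1 + εr/ρ₀). This is implemented exactly as written even
  though its annular term is not the textbook annular-pupil expression
  (α appears where α² would be expected, and J₁(w₁)/w₁ lacks a factor 2);
  its physical consistency is not asserted anywhere.
* Confocal effective profile: h_eff = [2J₁(w)/w]² + β J₀(w)·2J₁(w)/w.

Values at w = 0 are taken by series limit below |w| < 1e-8
(2J₁(w)/w → 1 − w²/8). Arbitrary t(s) goes through adaptive quadrature
(`scipy.integrate.quad`, tolerance 1e-10, error-checked) with the result
normalized to h(0) = 1.

## The cutoff W_c

W_c is defined as the w-location of the **first local minimum of the
normalized amplitude profile after the central lobe** (not the first
zero). Under this definition the circular pupil's W_c is the first
positive root of J₂, 5.1356, and the β = 0.5 spiky profile's is 4.4390.
The solver scans a grid (default step 0.005 on (0, 4π]) for the first sign
change of the discrete derivative from negative to non-negative, then
refines inside the bracket: by Brent root-finding on the closed-form
derivative where one exists (d/dw[2J₁/w] = −2J₂/w, dJ₀/dw = −J₁), by a
central difference (step 1e-4) of a supplied profile function otherwise,
or — with samples only — by the parabola through the three bracketing
points (accurate to O(step²)). Tolerance 1e-6. A profile with no
post-lobe minimum on the grid raises `CutoffNotFoundError`.

Measured cutoffs: circular 5.1356, linear 4.8067, quadratic 4.6126, spiky
4.4390 — strictly ordered spiky < quadratic < linear < circular.

## FFT diffraction and pixel conventions

The amplitude impulse response of a pupil is its centred 2-D DFT:
`fftshift(fft2(ifftshift(a)))`, so a pupil centred at (N/2, N/2) yields a
PSF whose zero-frequency peak lands on the same pixel. Reporting is
1-based, which places the N = 2048 peak at pixel 1025 and hence at
position 36 of the window [990, 1058], and the N = 512 peak at pixel 257,
position 22 of [236, 296]. Intensity is the squared modulus, max
normalized; windowed line profiles are re-normalized to the window
maximum. No zero-padding is applied by default (the full frame is
transformed); a pad factor is available for finer PSF sampling. The pupil
autocorrelation is computed transform-based on the doubled (2N−1) support,
clipping FFT round-off below zero.

## Confocal image formation

Amplitude PSFs (complex fields, not intensities) enter the product
h_eff = h₁·h₂; intensity is taken only at detection. The object amplitude
is the grayscale value on [0,1], with no phase. Convolution is full
zero-padded linear convolution cropped to the object size with the kernel
centre (index N/2 for even kernels) aligned — chosen so a centred unit
impulse object reproduces h_eff pixel-for-pixel, which also fixes the
one-pixel bias a (N−1)/2-centred crop would introduce for even kernels.
Zero padding avoids wrap-around artifacts. The detected intensity is
globally max-normalized; it is invariant to any global phase on h_eff, and
the two pupils commute.

## Synthetic virus phantom

`make_virus_phantom` emulates a grayscale coronavirus micrograph: a
340-px-diameter body disc in a 512² frame carrying smoothed seeded speckle
(Gaussian-filtered white noise, σ = max(2, r_body/20), scaled to the
requested contrast) and stalk-and-knob protrusions (stalk 60 % of the
spike length and ±2 px wide, knob radius 20 %) at seeded angles. Defaults:
24 spikes of length 40 px, contrast 0.5 — chosen once as a realistic
peplomer morphology within the constraint that the phantom fits the frame.
The phantom is deterministic per seed and its support stays within
body radius + spike length.

What it does not emulate: optical blur or noise of a real micrograph,
staining variation, partial-volume effects, or any phase structure.
Passing tests therefore demonstrate the correctness of the imaging chain
on a clean amplitude object, not performance on real micrographs.

## Problem sizes and numerical choices

Cutoffs use grid step 0.005 over (0, 4π] with 1e-6 refinement; diffraction
experiments use the full 2048² and 512² frames of the reference
geometries; oracle cross-checks run on deliberately tiny inputs (16×16
autocorrelation against the O(N⁴) sliding dot product, 8×8 objects against
nested-loop convolution) where brute force is exact and fast. Peak-finding
ties break toward the smallest index. Degenerate inputs (all-zero masks,
empty objects, zero-peak profiles) raise rather than return silent
defaults.

## Known limitations

* Scalar, paraxial Fourier optics only: no vectorial/high-NA model, no
  defocus or 3-D PSF, no pupil phase, no Fresnel propagation.
* The confocal model assumes an ideal point detector and coherent
  amplitude imaging; finite pinholes and fluorescence (incoherent) mode
  are out of scope.
* Spike geometry is a parameterized wedge model; hand-drawn or measured
  pupil silhouettes can be supplied as images instead.
* The exact two-radius profile is reproduced as printed in its source
  formula; it should not be used as a validated annular-pupil reference.
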