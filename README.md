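# spikyoptics

Coronavirus-inspired pupil engineering for confocal scanning laser
microscopy (CSLM): generators for spiky and radially modulated aperture
masks, analytic Bessel-function PSF models, FFT diffraction, a cutoff
resolution metric, pupil autocorrelation, and coherent confocal image
formation.

## The problem

A microscope's resolution is set by the shape of its pupil. A uniform
circular pupil yields the Airy amplitude PSF `h(w) = 2 J1(w)/w` in the
reduced image-plane coordinate `w = 2π ρ₀ r / (fλ)`. Fringing the pupil
with wedge-shaped spikes — a pupil that looks like a coronavirus virion —
adds a thin-annulus contribution, and in the thin-annulus approximation the
amplitude PSF becomes

```
h(w) = 2 J1(w)/w + β J0(w),      β < 1  (default β = 0.5),
```

whose central lobe is narrower than the Airy lobe. The package quantifies
this with the cutoff `W_c`, the reduced coordinate of the first local
minimum of the normalized amplitude PSF after the central lobe. For the
circular pupil `W_c` is the first positive root of `J2` (5.1356); for the
spiky pupil with β = 0.5 it drops to 4.439; rim-weighted linear
(`t(ρ) = ρ/ρ₀`) and quadratic (`t = (ρ/ρ₀)²`) pupil modulations fall in
between. A smaller `W_c` means a sharper PSF, hence better two-point
resolution.

For the CSLM with a point detector, imaging is coherent with effective PSF
`h_eff = h₁ · h₂` (illumination × detection amplitude PSFs), scanned image
amplitude `C = h_eff ⊛ g` and detected intensity `I = |C|²`. The reference
configuration pairs an 8-spike illumination pupil with a circular detection
pupil, both of radius 128 px in a 512² frame, applied to a synthetic
spiky-virus phantom object.

## Worked example

Cutoffs for the spiky and circular pupils:

```sh
$ spikyoptics psf cutoff --model spiky
{"model": "spiky", "W_c": 4.439034}
$ spikyoptics psf cutoff --model airy
{"model": "airy", "W_c": 5.135622}
```

The spiky pupil's first PSF minimum sits at 4.439 versus the circular
5.136 — about a 14 % narrower central lobe, the resolution improvement the
spiky aperture buys.

Numeric route — build the 8-spike radius-128 pupil, diffract it, and read
the windowed peak position:

```sh
$ spikyoptics aperture make --n 512 --radius 128 --spikes 8 \
      --mode regular --spike-length 24 --out pupil.png
wrote pupil.png and pupil.json
$ spikyoptics psf fft --spec pupil.json --window 236 296 --axis row --fixed 257
wrote profile.csv; peak at position 22 within window [236, 296]
```

Position 22 is the centre pixel (1-based 257) of the 512-frame landing in
the 1-based window [236, 296] — the convention used throughout for line
plots. The same library call with a 2048² frame and a diameter-900
irregular spiky pupil puts the peak at position 36 of window [990, 1058].

The full confocal chain:

```python
import spikyoptics as so

illum = so.ApertureSpec(grid_size=512, inner_radius=128, spike_length=24,
                        n_spikes=8, spike_mode="regular")
detect = so.ApertureSpec(grid_size=512, inner_radius=128)
phantom = so.make_virus_phantom(so.VirusPhantomSpec(seed=1))
image = so.simulate_cslm(phantom, illum, detect)   # detected intensity in image.intensity
```

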