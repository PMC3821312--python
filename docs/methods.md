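# Methods

## Conventions

All public angles are in degrees, measured counter-clockwise from the
horizontal axis viewed against the propagation direction; retardances are in
radians.  Stokes vectors are `(s0, s1, s2, s3)` with `s3 > 0` defined as
right-circular.  The circular sign is a bookkeeping convention: no observable
in the package depends on a global flip of `s3`, and tests only constrain
`|s3|`.  The package works entirely in Mueller (intensity) calculus; every
modelled observable is an incoherent intensity, so Jones (field) calculus is
unnecessary.  This is also the model's main limitation: coherent effects —
edge diffraction at the retarder's sector boundaries, interference, the
vectorial structure of a tightly focused beam — are outside its scope.

## Segmented retarder (SVR)

The device is modelled as `n` half-wave-plate sectors (default 8) tiling a
circular aperture.  Sector `k` is centred on azimuth `φ_k = k·360°/n` and
spans `±180°/n` around it, minus half an inter-sector gap on each side (the
symmetric layout; the physical device's exact cut is not public).  The fast
axis of sector `k` is `(φ_k + input_axis)/2`, so a half-wave plate maps the
input linear polarization onto the local radial direction `φ_k`.  Gap pixels
transmit the input beam unchanged — reproducing the main noise mechanism of
the real device — while edge diffraction is deliberately not modelled.
Per-sector fast-axis jitter (cutting/mounting error) is available as an
optional parameter, default 0, to generate imperfect maps for robustness
tests.  For linear input the model conserves `s0` pixel-wise and produces no
circular component (assertable to machine precision), because ideal half-wave
plates are lossless and map linear states to linear states.

## Polarimeter

The analyzer is a rigid quarter-wave plate + linear polarizer with axes 45°
apart.  Facing the light with the wave plate ("normal") it analyzes circular
content — detected intensity `(S0 − S3)/2` independent of the unit's rotation
— and flipped by 180° it is a plain linear analyzer at the rotated polarizer
axis.  The default protocol is flipped at {0°, 45°, 90°, 135°} plus one
normal setting; any protocol with ≥ 3 distinct flipped angles and one normal
setting is full rank, and rank is checked with an error naming the
unconstrained Stokes component.  The rotation angles themselves are a
package default (they are not dictated by the physics; any full-rank set
works) and are configurable.

Inversion is per-pixel ordinary least squares on `I = a(setting)·S`
(homoscedastic averaged noise justifies the unweighted fit), followed by a
minimal-change physicality projection: if the polarized part exceeds `s0` the
vector `(s1, s2, s3)` is radially clipped to `dop = 1`, preserving its
direction.  Noise-free reconstruction is exact to 1e−10 for any physical
truth map.

The camera chain: ideal intensities are auto-exposed so the brightest pixel
sits at 90 % of the 8-bit full scale (avoids saturation; the real exposure
setting is an instrument detail), then per frame Poisson shot noise at unit
gain, additive Gaussian read noise (default sd 1 count), clipping to
[0, 255], rounding to integer counts, and averaging of 256 frames per
setting.  Averaging suppresses per-pixel noise by ≈ 1/√N (verified ≈ 1/16 for
N = 256).

**Accuracy metric.** Reported per-component accuracy is
`100·(1 − ⟨|ΔS_i|/S0_ref⟩)` averaged over valid pixels, plus a worst-pixel
variant.  This is the simplest pointwise metric consistent with per-pixel
evaluation; with the default camera it yields ≈ 99.5–99.8 % for homogeneous
calibration beams, comfortably above the 98 % working threshold used in the
acceptance checks.

## Confocal forward model

A cylindrical fiber of diameter 80 μm (typical terminal scalp hair; the
diameter is a scene parameter) lies in the image plane at angle ψ.  Per
pixel, the optical path through the birefringent cortex is
`min(focus_depth, chord)` where the chord is the vertical extent of the
circular cross-section at the pixel's lateral offset.  On that path the model
evaluates the retardation `d = 2π δ x / λ` (δ = n_e − n_o = 0.007,
λ = 0.83 μm) and the surviving degree of polarization `p = exp(−x/ℓ_p)`.

The exponential depolarization law and its default length ℓ_p = 100 μm are
the package's phenomenological choice for the observed monotone loss of
polarization with depth; ℓ_p is exposed in the scene configuration.
Similarly, the retardation is accumulated over a single pass by default; a
`double_pass` flag doubles both the retardation path and the depolarization
path for a reflection-geometry reading.  Fresnel reflection at the fiber
surface and photon-transport scattering are not modelled.

**Crossed detection.** The detected signal is a Mueller chain — input state →
`depolarizer(p)` → fiber retarder `(d, ψ)` → crossed analyzer (orthogonal
linear for linear light, opposite-handed circular for circular, per-azimuth
crossed linear for radial) — applied to the *polarized* component of the
light.  The depolarized share is treated as rejected by the confocal pinhole
(it is multiply-scattered, hence spatially incoherent with the focal volume);
whatever depolarized light does reach the detector is part of the empirical
background level `b`.  This choice makes the chain agree exactly with the
closed forms listed in the README; retaining the depolarized term instead
would add a uniform `½(1−p)·I₀` offset to every mode and depth, which the
ratio statistic would largely cancel but which double-counts the background.

**Radial illumination** is an incoherent average of the linear response over
pupil azimuths — the discrete output azimuths of a sectored retarder, or an
equally spaced azimuth grid for the ideal beam.  Because `sin²` averages to
½ over any balanced azimuth set, both give exactly half the crossed
throughput of the best linear orientation, mirroring the lower focal
intensity observed with radial beams; the average is ψ-independent, which is
the entire point of radial illumination.  The true vectorial focal field of
a high-NA radial beam (longitudinal component, side lobes) is not modelled.

**Background.** Air is a small constant floor (default 0.001·I₀ — a strictly
positive level so the contrast ratio is always defined).  Skin is a constant
level (default 0.05·I₀) times mean-one log-normal speckle (default σ = 0.2);
any positive heterogeneous field serves the purpose of exercising the ROI
statistics.  The fiber occludes the textured background: under the footprint
only the constant floor remains.  The speckle seed depends on the depth
index but not on the illumination orientation, so orientation arms compare
the same background realisation — the paired-arm assumption of the ratio
statistic below.

## Contrast ratio R

`R = (I_B/I_N)|_P1 ÷ (I_B/I_N)|_P2` from pooled means over three randomly
placed, non-overlapping 25 × 25 μm ROIs (35 × 30 px at the default
450 × 400 μm / 630 × 480 px sampling) on the fiber and on the background.
Placement is uniform over feasible positions with overlap rejection (the
layout restarts when greedy placement dead-ends), deterministic per seed.
ROIs are re-drawn per depth with a seed offset; the same ROI set is used in
both orientation arms whenever the masks coincide, making the comparison
paired.  When the fiber itself is rotated between arms (circular/radial
studies), each arm gets its own fiber-core mask and the background mask is
the region clear of the fiber at *every* orientation.  Fiber ROIs are
restricted to the central band of the footprint (|offset| ≤ 0.35·diameter),
where the chord exceeds the shallow probing depths and the signal is
laterally uniform.

Because eq-style ratios are orientation-ambiguous, the reported `R` takes P1
as the higher-contrast orientation (so `R ≥ 1`), and the raw signed ratio is
reported alongside.  The quoted uncertainty is first-order (delta-method)
propagation of the four ROI-mean standard errors; the error-bar definition
is a package choice.

Noise-free model predictions: linear illumination at (45°, 0°) relative to
the fiber gives `R = 1 + I₀·p·sin²(d/2)/b > 1`; circular and radial give
exactly `R = 1` at every depth.  With strong depolarization (ℓ_p well below
the probed depths) the linear-light `|R − 1|` decays towards 0 — note the
decay is monotone only once the exponential dominates the `sin²(d/2)` growth
(for the defaults, from roughly 3·ℓ_p onwards), which is where the package's
monotonicity checks probe it.

## Synthetic data and what passing tests show

The generator reproduces the study conditions: 6 μm polarimeter pixels,
8-bit frames, 256-frame averaging, read noise 1 count, shot noise on;
830 nm, 450 × 400 μm field of view, 80 μm fiber, δ = 0.007, orientations 45°
apart, depths of tens of μm.  Fixtures are byte-reproducible given a seed.
They emulate the *statistical structure* the analysis assumes — quantization,
averaging, speckle, orientation geometry — not real instrument physics:
no scanning distortion, no real VivaScope noise spectra, no hair cuticle or
medulla, no subject variability.  Passing tests therefore validate the
computational chain and its internal consistency, not the instrument.

## Problem sizes

Default test and reproduction sizes — 256 × 256 polarimeter maps with 20
noise realisations, 630 × 480 confocal frames, 1000-tuple oracle sweeps —
were chosen so the full suite and the reproduction script each complete in a
few minutes while keeping Monte-Carlo scatter well below the tolerances they
are compared against.
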