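# polbiref

Polarization-resolved birefringence contrast in cross-polarized confocal
microscopy, simulated end to end.

## The problem

Cross-polarized confocal laser scanning microscopy images birefringent tissue
structures (hair cortex, collagen, muscle) by detecting only the light whose
polarization changed inside the sample.  With **linearly** polarized
illumination the detected signal depends strongly on the angle between the
polarization and the structure's optical axis: a hair illuminated along or
across its axis looks dark, the same hair at 45° looks bright.  Quantitative
birefringence assessment of wavy structures is therefore orientation-biased.
**Circularly** and **radially** polarized illumination have no preferred
transverse direction and remove this bias.  This package provides the
complete computational chain needed to study that effect in simulation:

* **`polarization_core`** — Stokes vectors and Mueller matrices (rotators,
  retarders, polarizers, depolarizers), broadcasting over image grids.
* **`svr_model`** — the segmented spatially variable retarder: eight
  half-wave-plate sectors whose fast axes turn a homogeneous linear beam into
  a near-radial vector beam, including inter-sector air gaps.
* **`polarimetry`** — a spatially resolved Stokes polarimeter built from a
  rotatable, flippable circular polarizer (quarter-wave plate + polarizer at
  45°) and an 8-bit CCD with shot/read noise and 256-frame averaging; per-pixel
  least-squares Stokes reconstruction.
* **`confocal_model`** — forward model of crossed-polarization confocal images
  of a birefringent cylindrical fiber (cortex indices n_o = 1.541,
  n_e = 1.548, δ = 0.007) in air or on skin, under linear, circular or radial
  illumination, at arbitrary fiber orientations and focusing depths.
* **`contrast_analysis`** — the orientation-contrast ratio
  **R = (I_B/I_N)|_P1 ÷ (I_B/I_N)|_P2** between two illumination orientations
  45° apart, evaluated from three randomly placed 25 × 25 μm ROIs on the fiber
  (I_B) and background (I_N), power-normalized, with delta-method error bars
  and depth profiles.  R = 1 means orientation-independent contrast.
* **`synthetic_data`** — seeded, byte-reproducible fixture generation for all
  of the above (calibration beams, sectored radial beams, fiber-in-air and
  fiber-on-skin image series).

The physics core is the crossed-detected intensity of a fiber at angle ψ with
retardation d = 2π·δ·x/λ over path x and surviving degree of polarization
p = exp(−x/ℓ_p):

    linear(θ):  I = I₀ · p · sin²(2(θ−ψ)) · sin²(d/2) + b
    circular:   I = I₀ · p · sin²(d/2) + b
    radial:     I = I₀ · p · ½ · sin²(d/2) + b

computed internally as a Mueller-matrix chain and verified against these
closed forms to 1e−10.

## Worked example

```python
import polbiref as pb
from polbiref.synthetic_data import FixtureSpec, make_confocal_fixture

for mode, orients in [("linear", (45.0, 0.0)), ("circular", (0.0, 45.0))]:
    spec = FixtureSpec("fiber_in_skin", illumination_mode=mode,
                       orientations=orients, depths=(20.0,), seed=1)
    fx = make_confocal_fixture(spec)
    curve = pb.contrast_depth_curve(
        [fx["images"][(orients[0], 20.0)]], [fx["images"][(orients[1], 20.0)]],
        (fx["fiber_masks"][orients[0]], fx["fiber_masks"][orients[1]]),
        fx["bg_mask"], seed=7)
    r = curve[0]
    print(f"{mode:9s}  R = {r.R:.4f}")
```

prints

```
linear     R = 5.1834
circular   R = 1.0000
```

With linear light the hair-to-skin contrast at 45° to the fiber is ~5× the
contrast with the illumination along the fiber (R ≈ 5.2 at 20 μm depth); with
circular light both orientations give identical contrast, R = 1.  The
polarimeter side of the package recovers homogeneous calibration states from
noisy 8-bit, 256-frame-averaged stacks with per-component accuracy around
99.5–99.8 %:

```python
import numpy as np
truth = pb.PolarizationMap(np.broadcast_to(
    pb.StokesVector.linear(-45).as_array(), (256, 256, 4)).copy())
stack = pb.simulate_stack(truth, camera=pb.CameraModel(), n_averaged=256, seed=1)
rec, _ = pb.reconstruct(stack)
print(pb.accuracy_report(rec, truth)["mean"])   # [99.771 99.671 99.599 99.478]
```

A thin CLI mirrors the pipeline: `polbiref fixtures make`, `polbiref
polarimetry reconstruct|accuracy`, `polbiref confocal`, `polbiref contrast`.

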