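# chromatie

Single-shot quantitative phase imaging (QPI) through a chromatically
dispersive metalens, in silico: a forward optical simulator (hyperboloid
metalens + color sensor + optional coherent fiber bundle) and the spectral
transport-of-intensity solver that recovers quantitative phase and height
maps from one RGB intensity capture.

## The idea

A hyperboloid metalens focuses each wavelength at a different distance —
λ·f is conserved, so δf/f = −δλ/λ. Behind such a lens, the red, green and
blue planes of a single color-camera exposure are three *defocus*
measurements of the same scene: the Fresnel diffraction pattern depends
only on ζ = λz, making spectrum and defocus interchangeable. The
transport of intensity equation (TIE)

    dI/dz = −(λ/2π) ∇·(I∇φ)

links the axial intensity derivative to the transverse phase, so with the
channel difference standing in for dI (λdz = −zdλ), a double FFT-Poisson
inversion with Tikhonov regularizers ε, ε′ (via the Helmholtz substitution
I∇φ = ∇ψ) yields the unwrapped phase φ, refined by forward-propagating the
candidate field and re-inverting the residual. Physical height follows as
h = φ·λ/(2π·δn) for a sample of index contrast δn. Because the phase is
encoded in per-channel *intensities* before any fiber, the method survives
transmission through a coherent fiber bundle that scrambles optical phase,
and the differential between channels cancels the shared honeycomb
artifact.

For whom: anyone prototyping propagation-based phase retrieval — the
package gives exactly known pure-phase targets (Siemens star, random
diffuser screens, filamentous-algae-like ribbons), a faithful partially
coherent chromatic capture model, and the full inverse pipeline with its
diagnostics.

## Worked example

Simulate the classic validation experiment — a 250 nm tall Siemens star in
n = 1.52 material, imaged in one shot through a 1 mm metalens — and
recover its height:

```python
import numpy as np
from chromatie import (OpticalTrain, SampledGrid, SolverParams,
                       iterative_refine, siemens_star, simulate_capture)
from chromatie.metrics import plateau_height
from chromatie.phantoms import spoke_masks

grid = SampledGrid(512, 512, pixel_pitch=1.0)            # 512 µm field
train = OpticalTrain.two_f(1000.0, 250.0)                # f = 1 mm, NA 0.25
star = siemens_star(grid, n_spokes=12, height=0.25,      # 250 nm step
                    index_contrast=0.52, radius=200.0)

capture = simulate_capture(star, train)                  # one RGB exposure
for c in capture.channels:
    print(f"{c.name}: λ = {c.center_wavelength:.0f} nm, "
          f"defocus = {c.equivalent_defocus:+.1f} µm")

result = iterative_refine(capture, SolverParams(), index_contrast=0.52)
spoke, gap = spoke_masks(star, 80.0, 180.0)
print(f"recovered plateau: {1e3 * plateau_height(result.height, spoke, gap):.1f} nm")
```

Output:

```
R: λ = 625 nm, defocus = +179.2 µm
G: λ = 530 nm, defocus = +0.0 µm
B: λ = 455 nm, defocus = -141.5 µm
recovered plateau: 229.9 nm
```

The red channel is recorded 179 µm past its focus and blue 142 µm before
it — the chromatic focal law turned into a through-focus stack — and the
median recovered step height lands within 10 % of the fabricated 250 nm,
with no per-target tuning.

The same pipeline is scriptable from the shell:

```bash
chromatie simulate --config run.yaml --out out/
chromatie retrieve --capture out/capture.tif --out out/
chromatie validate --config run.yaml --out out/   # exits 1 on failure
chromatie refocus  --capture out/capture.tif --phase out/phase.tif \
                   --targets "530:100,578:91.7,625:84.8" --out stack.tif
```

`docs/methods.md` describes the model, the solver's regularization and
update shaping, and the validity domain (caustic onset, strong-phase
saturation, coherence band) in detail.

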