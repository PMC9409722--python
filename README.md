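# speckleflow

Laser speckle contrast imaging (LSCI) turns the blurring of laser speckle
during a camera exposure into a dye-free, full-field map of tissue
perfusion. During intestinal surgery this lets a surgeon see, in real
time, which parts of a bowel segment or anastomosis are well, marginally,
or poorly perfused. `speckleflow` implements the complete laparoscopic
LSCI processing chain — raw speckle frames → spatial speckle contrast →
laser speckle perfusion units (LSPU) → masked, Viridis false-colored 2D
perfusion maps with relative-perfusion classification — together with a
physics-based dynamic speckle simulator that provides ground-truth
phantoms, so every stage is testable at desk scale without an animal
acquisition.

## The statistic at the core

Within a sliding window (default 7 × 7 pixels) the spatial speckle
contrast is

```
K = σ / ⟨I⟩
```

the ratio of the (population) standard deviation to the mean of the pixel
intensities in the window. Moving red blood cells decorrelate the speckle
field during the exposure *T* (default 20 ms at 20 fps), blurring the
pattern and lowering K. Perfusion is reported in laser speckle perfusion
units, LSPU = 1/K² (saturated where K ≈ 0); higher LSPU means better
perfusion.

For a Lorentzian field correlation g₁(t) = exp(−t/τc), where τc is the
per-pixel decorrelation time (inversely related to blood flow), the
contrast at exposure *T* has the closed form

```
K(T, τc) = sqrt( β · [ τc/T + τc²/(2T²) · (e^(−2T/τc) − 1) ] )
```

with β ≤ 1 the coherence/sampling factor. The simulator evolves a
band-limited complex Gaussian speckle field with a first-order
autoregressive update whose per-pixel correlation is exp(−Δt/τc), so this
closed form is an independent oracle for the whole chain, and measured
contrast can be inverted to recover τc.

## Worked example

Simulate a three-tier phantom (well-perfused background τc = 1 ms, a
marginal ellipse at 2.5 ms, a poorly perfused rectangle at 50 ms, 20 ms
exposure, 20 fps) and run the full pipeline:

```python
import json
import speckleflow as sf

scene = sf.default_scene(seed=11)
phantom = sf.make_phantom(scene)
stack = sf.generate_dynamic_stack(phantom, sf.AcquisitionParams(n_frames=20),
                                  sf.NoiseParams(seed=12))
sf.write_stack(stack, "demo/stack.tiff")
summary = sf.run_pipeline(sf.PipelineConfig(), "demo/stack.tiff", "demo/out")
print(json.dumps({"reference_value_lspu": summary["reference_value_lspu"],
                  "label_fractions": summary["label_fractions"]}, indent=2))
```

prints

```json
{
  "reference_value_lspu": 26.454932,
  "label_fractions": {
    "poor": 0.23996,
    "marginal": 0.080307,
    "well": 0.633408,
    "invalid": 0.046326
  }
}
```

The reference value (26.5 LSPU) is the 95th percentile of valid perfusion
— the "maximum perfusion in healthy tissue" against which every pixel is
expressed as a percentage. The label fractions recover the phantom
geometry: the poor rectangle covers 22.4 % of the frame by construction
and is classified on 24.0 % (its demarcation sits at the blurred
boundary), the marginal ellipse 7.0 % vs 8.0 %, and the 4.6 % invalid rim
is the 3-pixel border where the 7 × 7 window overlaps the frame edge.
`demo/out/` also contains the contrast, LSPU and relative-percent maps
(32-bit TIFF), the Viridis rendering with underexposed pixels in black,
the side-by-side surgeon's view, the label map, and the extracted
demarcation contours (JSON).

The same chain is available from the shell:

```
speckleflow simulate --out demo/stack.tiff --seed 11
speckleflow process --in demo/stack.tiff --out demo/lspu.tiff
speckleflow pipeline --in demo/stack.tiff --out-dir demo/out
```

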