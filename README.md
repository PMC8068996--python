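# acnsim

Simulation of **augmented capillary network (ACN)** image data: volumetric,
OCT-like images of human-skin capillaries paired voxel-for-voxel with binary
ground truth, plus the binarization schemes and confusion-matrix metrics
used to evaluate capillary segmentations.

Annotating capillaries in full-field optical coherence tomography (FF-OCT)
volumes by hand is slow, expensive and subjective — capillaries are thin,
low-contrast, and visible only in the instants when red blood cells pass,
so they appear fragmented from frame to frame.  `acnsim` sidesteps the
annotation bottleneck by *generating* realistic training data together with
its ground truth, and ships a 3D U-Net (pure numpy, CPU-reproducible) plus
the evaluation pipeline to close the loop.  It is aimed at researchers in
biomedical image analysis who need paired vascular image data on demand.

## The model in brief

**Pathway growth.**  Capillary pathways grow on a 2D working domain like a
river basin flowing to a sink.  A boundary *root point* contributes the
potential `U_root = α·[(x−x₀)² + (y−y₀)²]^¼` (α > 0), and every existing
pathway *i* adds a shallow valley `U_i = β·Σ_j [(x−x_ij)² + (y−y_ij)²]^(γ/2)`
(β, γ < 0; defaults α = 100, β = −20, γ = −1).  Each pathway descends the
total potential from a random interior end point until it reaches the root
or is captured by — and attaches to — an earlier pathway, forming branches.
Grown polylines are smoothed with third-order polynomials through four
control points.

**Rendering.**  Gaussian spots `f = I_c·exp(−r²/2σ_c²)` are pasted along the
curves (I_c ∈ [0.05, 0.08], σ_c ∈ [5, 8] px); ground truth is the set of
pixels within σ_c of a curve.  Curves are randomly fragmented per frame,
bright speckle patches of width 8·σ_c mimic granular tissue speckle, and
Gaussian background noise realises a target SNR = 10·log₁₀(I_c²/σ_noise²)
∈ [1, 10] dB.  About 20 frames of one network form a sub-volume; one or two
sub-volumes are embedded, well separated, into a 128×128×64 8-bit target
volume.

**Evaluation.**  Predictions are binarized with the threshold
`p_thresd = p_mode + c·p_std` (c = 2), either after averaging frames or by
counting how often a pixel is foreground across frames (≥ N of them), and
scored with accuracy, precision P, recall R, and F1 = 2PR/(P+R).

## Worked example

```python
import numpy as np
import acnsim as a

# grow and render one network
net = a.build_network(a.WorkingDomain(128, 128), n_endpoints=4, seed=3)
print([(p.label, p.terminus[0], len(p.points)) for p in net.pathways])

# one full paired volume, then score a (here: perfect) prediction
vol = a.generate_volume(seed=42)
print(vol.dims, vol.placements)

gt_enface = (vol.gt_volume > 0).any(axis=0)
m = a.metrics(a.confusion(gt_enface, gt_enface))
print(m.f1, m.precision, m.recall)
```

prints

```
[(1, 'root', 99), (2, 'attached', 86), (3, 'attached', 62), (4, 'attached', 17)]
(128, 128, 64) [(16, 36)]
1.0 1.0 1.0
```

— a four-end-point network whose first pathway reached the root while the
other three attached to earlier pathways as branches; a 128×128×64 volume
with one 20-layer sub-volume placed at slices 16–36; and the sanity check
that a prediction identical to its ground truth scores F1 = 1.

From the shell, the same pipeline is available as:

```bash
acn generate --out data/ --count 10 --seed 0     # paired TIFF volumes + manifest
acn evaluate --pred pred.tif --gt gt.tif --scheme repeat --n-repeat 2
acn train --data data/ --out run/                # desk-scale numpy U-Net
acn selfcheck                                    # worked examples + invariants
```

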