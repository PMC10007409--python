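# smpcnn

Fusion of registered **ToF-confidence / visible-light image pairs** in the
non-subsampled shearlet domain, with a **saliency-guided pulse coupled neural
network (PCNN)** segmenting the ToF low-frequency band and a
**momentum-driven multi-objective artificial bee colony** tuning the PCNN
parameters.

The target application is orchard robotics: a time-of-flight camera renders
near, reflective fruit as bright, approximately normally distributed regions
regardless of ambient light, while the visible camera carries the texture and
edges the ToF image lacks. Fusing the two yields a single image in which the
fruit foreground stays highlighted and the scene detail survives — useful as
the front end of a fruit-detection pipeline under harsh, changing
illumination.

## Method

1. **NSST decomposition.** Both images are decomposed with a non-subsampled
   shearlet transform: an à-trous maxflat pyramid (u levels) followed by
   Fourier-domain angular wedge filters (2^v directions per level). All
   sub-bands keep the source resolution; the transform is exactly invertible
   and, with periodic boundaries, exactly shift invariant.
2. **Saliency-guided PCNN.** The ToF low band drives a PCNN
   (`F = I`, `L(n) = e^{-α_L} L(n-1) + V_L (W*Y)`, `U = F(1+βL)`,
   fire when `U > θ`, `θ(n) = e^{-α_θ} θ(n-1) + V_θ Y(n)`), producing binary
   ignition maps. Two maps at lag 2 are treated as successive states of a
   first-order Markov chain; their mutual information `I(U;V)` (bits) is the
   *significance* of the iteration, and the loop runs while `I > δ`. The
   threshold recharge `V_θ` is set each iteration to the KL divergence
   between the two maps' firing-state distributions, so firing calms down as
   the segmentation stabilizes.
3. **Parameter search.** `(α_L, β, α_θ)` can be tuned by a bi-objective
   artificial bee colony (cross entropy and mutual information of the fused
   result against the sources) with heavy-ball momentum for employed bees,
   Nesterov-style momentum for onlookers, and a grid-density Pareto archive.
4. **Fusion rules.** Low bands: pixelwise weighted average
   `0.5·ToF + 0.5·RGB` (the final ignition map is exported as a diagnostic
   mask and can optionally boost the ToF weight inside fired regions). Each
   directional high-band pair: a ToF-steered bilateral rule — visible-band
   values in a window are averaged with a spatial Gaussian times a Gaussian
   similarity to the ToF coefficient at the centre. Inverse NSST gives the
   fused image.
5. **Scoring.** Ten indicators: AG, ES, IE, SD, PSNR, SF, IC, MI, SSI and CE
   (see `smpcnn.metrics` for the exact conventions).

No external data are needed: `smpcnn.data_io` generates registered synthetic
ToF/visible pairs with ground-truth fruit masks.

## Worked example

```python
import numpy as np
from smpcnn import data_io, fusion, metrics

scene = data_io.generate_scene(data_io.SyntheticSceneConfig(seed=1))
result = fusion.fuse_images(scene.tof, scene.visible)
print(f"PCNN iterations: {len(result.ignition_maps)}")
report = metrics.evaluate(result.fused, scene.tof, scene.visible)
for name, value in report.as_dict().items():
    print(f"{name:5s} {value:8.3f}")
inside = result.fused[scene.mask].mean()
outside = result.fused[~scene.mask].mean()
print(f"mean intensity inside fruit mask {inside:.3f} vs outside {outside:.3f}")
```

prints

```
PCNN iterations: 3
AG       3.482
ES      38.089
IE       7.043
SD      34.301
PSNR    30.493
SF       6.370
IC       4.011
MI       4.238
SSI      0.634
CE       6.325
mean intensity inside fruit mask 0.691 vs outside 0.380
```

The PCNN stops after three iterations (the significance between lag-2
ignition maps fell to the δ = 0.2 bit floor); the fused image keeps 7.0 bits
of grey-level entropy, shares 4.2 bits of histogram information with its two
sources combined, and the fruit regions stay almost twice as bright as the
background — the foreground-highlighting behaviour the low-frequency rule is
designed for.

The same pipeline is available from the shell:

```sh
smpcnn-fuse synth --out scene/ --seed 1
smpcnn-fuse run --tof scene/tof.png --rgb scene/visible.png --out fused.png --optimize --seed 1
smpcnn-fuse score --fused fused.png --src-a scene/tof.png --src-b scene/visible.png
```

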