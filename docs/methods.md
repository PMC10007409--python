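# Methods

## Scope and conventions

All images live on the unit grey scale: floats in [0, 1], row-major, origin
top-left. Colour visible images are reduced to Rec.601 luminance before
decomposition; the fused luminance is re-attached to the chroma as a clipped
additive shift (`fuse-luminance` mode), or each channel is fused
independently (`per-channel`). Registration is assumed: the two inputs must
share their spatial shape, and nothing in the package attempts alignment.

## Shearlet decomposition

The non-subsampled pyramid is the à-trous scheme with the maxflat B3-spline
kernel `(1,4,6,4,1)/16`, upsampled by `2^level` between levels; the detail
band at each level is defined as the residual between successive
approximations, so synthesis is a plain sum and reconstruction is exact to
machine precision for *any* boundary handling. The directional stage
multiplies each detail band's FFT by raised-cosine angular windows of width
`π/2^v` (angle taken modulo π so the filtered bands stay real); the windows
are normalized to a partition of unity, making the directional split exactly
invertible too. With `boundary_mode="periodic"` (default) the pyramid is
evaluated as a product of zero-phase frequency responses, so the whole
transform commutes exactly with integer circular shifts; `"symmetric"`
trades that exactness for mirror-padded behaviour at the borders.

Defaults `u = 2` levels, `v = 2` (4 directions/level) keep desk-scale runs
cheap while giving the bilateral high-band rule distinct orientations to
work with. The minimum image side is the support of the largest pyramid
kernel, `4·2^(u−1) + 1`.

## PCNN

Stimuli are min-max normalized to [0, 1] (a constant band is clipped instead
— there is nothing to normalize), which makes the initial threshold
`θ0 = 1.0` mean "nobody fires until the threshold has decayed below the
brightest pixel" and keeps `V_θ` scale-free. The circular definition of
`θ(n)` and `Y(n)` is resolved the standard way: fire against the decayed
threshold, then recharge. The link kernel is the 3×3 inverse-distance matrix
with zero centre; the link correlation uses zero padding. `n_max = 50`
bounds every run.

## Termination and adaptive recharge

The two ignition maps at lag 2 define an empirical joint distribution over
per-pixel firing states. `significance` is the mutual information of that
joint in bits, computed as `H(p_u) + H(p_v) − H(p_joint)`; this is the only
reading under which the quantity is non-negative with the claimed maximum,
and it coincides with the source-entropy-minus-conditional-entropy
composition when the source entropy is read as the joint entropy (both
compositions are exposed and tested against brute-force histogram sums).
The iteration continues while significance exceeds `δ = 0.2` bits (the
inverted convention is available as a config switch), with `n_max` as the
safety stop. In practice the loop can only terminate once the history is
`lag + 1` long, so a run always produces at least three maps.

`V_θ` for the next iteration is the KL divergence `D(p_v ‖ p_u)` between the
two maps' marginal firing distributions, ε-smoothed (`ε = 1e−12`) and
renormalized so disjoint supports stay finite, and floored at `1e−3` inside
the pipeline so that firing always raises the threshold. The raw function
returns exactly 0 for identical distributions.

## Bee colony

Employed bees: `a_new = r(x_j − x_partner,j) + γ a_j`, `x_j += a_new`;
onlookers: `b_new = r(x_j − x_partner,j − γ b_j) + γ b_j`; `γ = 0.9`,
`r ~ U[−1, 1]`, candidates clipped to the per-dimension bounds
(`α_L ∈ [0.01, 3]`, `β ∈ [0.01, 1]`, `α_θ ∈ [0.01, 3]`). Momentum memories
travel with accepted candidates only; a rejected move leaves the incumbent's
memory untouched, so stored step sizes always describe accepted evolution.
Greedy replacement uses Pareto dominance; with one objective and `γ = 0`
the colony reduces exactly to classical ABC (verified step-for-step against
an independent reference under a shared RNG stream). Scouts follow the
classical rule: once per cycle, the most-stagnant source past `limit` is
redrawn uniformly with zeroed momenta.

Onlooker roulette weights are `mean_i(0.9 f_i / max f_i + 0.1)` per source;
objective columns are shifted positive (min subtracted, `1e−9` added) only
when needed, so the ratio form is preserved for well-behaved fitness.

The archive keeps mutually nondominated sources (exact-duplicate fitness
vectors are not stored twice). Grid bins per objective place `nGrid − 1`
finite edges across the archive's fitness range with ±inf sentinels; the
isolation score of a member is the summed absolute grid-index distance to
every other member, and pruning removes members sampled with probability
proportional to `1/(poss+1)` until the archive fits `Rep`. The returned
triplet is the most isolated member (ties: lowest index) — a
diversity-favouring choice, since nothing canonical selects a single point
from a front.

Both objectives (CE, MI) are *maximized* by default, matching the fitness
definition `max{CE, MI}`; `senses` allows the conventional minimize-CE
reading. Note that with the default `mask_boost = 0` the fused image does
not depend on `(α_L, β, α_θ)` at all — the printed low-frequency rule is a
plain average and the high-frequency rule never sees the PCNN — so the
objectives are flat and the archive collapses to a single representative.
The search becomes meaningful when `mask_boost > 0` routes the segmentation
into the low-band weights; the flat default case is kept because it is the
literal reading of the fusion rules.

## Fusion rules

Low bands: `w·ToF + (1−w)·RGB`, `w = 0.5` by default, optionally
`w + η·mask` inside fired pixels. High bands (per level and direction):

```
out(m,n) = Σ_(t,s)∈window RGB(t,s) · wN · wS / Σ wN · wS
wN = exp(−((m−t)² + (n−s)²) / 2σ_s²),  wS = exp(−(ToF(m,n) − RGB(t,s))² / 2σ_r²)
```

with window radius 2 (5×5), `σ_s = σ_r = 1.0` on normalized bands — two
independent sigmas because bilateral filtering needs distinct spatial and
range scales; setting them equal recovers the shared-σ reading. Windows are
truncated at the border; all weights are strictly positive, so the output is
a convex combination of the visible band over the window. A consequence
worth stating: fusing an image with itself is *not* the identity near
edges — the bilateral average smooths edge-adjacent high-band
coefficients — and the self-fusion test therefore asserts identity (1e−4)
on constant regions away from boundaries, plus exactness for a globally
constant image.

## Quality indicators

All metrics quantize to 8 bits first (half-to-even; unit-scale inference
tolerates the slight overshoot reconstruction can add). Formula choices for
the nine named indicators plus CE are listed in `smpcnn/metrics.py`; where
the literature varies (AG vs IC difference stencils, MI summed over both
sources rather than averaged, CE as source-vs-fused relative entropy,
symmetric-averaged in the optimizer objective) the convention is fixed,
documented and mirrored by naive double-loop oracles in the tests. SSI is
implemented in-package (11×11 Gaussian window, σ = 1.5, symmetric padding,
standard stabilizers) so the windowing convention is fully specified even
for images smaller than the window. PSNR is taken against the mean of the
two sources and capped at 100 dB.

## Synthetic scenes

The generator emulates the statistical structure of the target scenes, not
the optics: fruit = random ellipses (radii 6–12% of the image side, centres
kept clear of the border) whose ToF grey is N(0.85, 0.05) clipped to [0, 1]
over a 0.2 background with 1% additive noise; visible = Gaussian-smoothed
seeded noise (correlation length 6 px; a finer, slightly brighter texture
inside fruit) under a multiplicative illumination field (linear sweep plus a
broad blob, 30% amplitude). It does not model ToF multipath, flying pixels,
specular highlights or parallax, so passing tests demonstrate the pipeline's
contracts and determinism on this scene family, not detection performance on
real orchard data. All randomness flows from one seeded generator; a seed
reproduces every artifact bit-identically.

## Problem sizes

Unit and acceptance tests run on 2×2–128×128 arrays; the end-to-end check
and `scripts/acceptance.py` use a 128×128 3-fruit scene with the colony at
NP = 10 for 10 cycles — sizes chosen so a full suite run stays in seconds
while still exercising every branch (zero-fruit, overlapping-fruit and
strong-illumination fixtures included).

## Known limitations

- The directional stage is Fourier-domain even in `symmetric` mode, so only
  the periodic mode is exactly shift invariant.
- With the default flat objectives the Pareto archive is degenerate (see
  above); parameter search results are only informative with
  `mask_boost > 0` or a custom objective closure.
- `per-channel` colour mode triples the cost and can introduce small
  channel-wise hue shifts; `fuse-luminance` is the default for that reason.
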