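"""End-to-end ToF/visible fusion in the shearlet domain.

Pipeline: decompose both registered images with the non-subsampled shearlet
transform; segment the ToF low-frequency band with the saliency-guided PCNN
(KL-divergence-adaptive threshold recharge, mutual-information termination);
optionally tune the three free PCNN parameters with the momentum-driven
multi-objective bee colony; fuse the low bands by weighted average, fuse
each directional high-band pair with a ToF-steered bilateral rule (the ToF
high band selects which visible-band neighbours are similar enough to
average); reconstruct.

The low-frequency rule is a plain 0.5/0.5 weighted average.  The final
ignition map is returned as a diagnostic and can optionally shift weight
toward the ToF band inside fired regions (``mask_boost``); by default it
does not alter the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import mmoabc, metrics, nsst, pcnn, saliency

__all__ = ["FusionConfig", "FusionResult", "fuse_low", "fuse_high",
           "segment_low_band", "fuse_images"]


@dataclass
class FusionConfig:
    decomposition: nsst.DecompositionConfig = field(default_factory=nsst.DecompositionConfig)
    saliency: saliency.SaliencyConfig = field(default_factory=saliency.SaliencyConfig)
    pcnn: pcnn.PCNNParams = field(default_factory=pcnn.PCNNParams)
    optimizer: mmoabc.OptimizerConfig = field(default_factory=mmoabc.OptimizerConfig)
    optimize: bool = False
    bilateral_radius: int = 2
    sigma_spatial: float = 1.0
    sigma_range: float = 1.0
    low_weights: tuple = (0.5, 0.5)
    mask_boost: float = 0.0   # extra ToF weight inside fired regions
    color_mode: str = "fuse-luminance"

    def __post_init__(self) -> None:
        if abs(sum(self.low_weights) - 1.0) > 1e-12:
            raise ValueError("low-frequency weights must sum to 1")
        if self.bilateral_radius < 0:
            raise ValueError("bilateral window radius must be >= 0")
        if self.sigma_spatial <= 0 or self.sigma_range <= 0:
            raise ValueError("bilateral sigmas must be > 0")
        if self.color_mode not in ("fuse-luminance", "per-channel"):
            raise ValueError(f"unknown color mode {self.color_mode!r}")


@dataclass
class FusionResult:
    fused: np.ndarray
    ignition_maps: list
    params: pcnn.PCNNParams
    mask: np.ndarray | None = None          # final ignition map
    archive: mmoabc.ParetoArchive | None = None
    saliency_trace: list = field(default_factory=list)  # (n, significance, V_theta)


def fuse_low(tof_low: np.ndarray, rgb_low: np.ndarray, weights=(0.5, 0.5),
             mask: np.ndarray | None = None, mask_boost: float = 0.0) -> np.ndarray:
    """Pixelwise weighted average of the two low-frequency bands.

    With a segmentation mask and a positive ``mask_boost`` eta, fired pixels
    use weights (w1 + eta, w2 - eta), highlighting the ToF foreground.
    """
    tof_low = np.asarray(tof_low, dtype=float)
    rgb_low = np.asarray(rgb_low, dtype=float)
    if tof_low.shape != rgb_low.shape:
        raise ValueError(f"band shapes differ: {tof_low.shape} vs {rgb_low.shape}")
    w1 = np.full(tof_low.shape, float(weights[0]))
    if mask is not None and mask_boost != 0.0:
        w1 = w1 + mask_boost * np.asarray(mask, dtype=float)
    return w1 * tof_low + (1.0 - w1) * rgb_low


def fuse_high(tof_high: np.ndarray, rgb_high: np.ndarray, radius: int = 2,
              sigma_spatial: float = 1.0, sigma_range: float = 1.0) -> np.ndarray:
    """ToF-steered bilateral fusion of one directional high-band pair.

    Output(m, n) is the normalized sum over the window of visible-band
    values, weighted by a spatial Gaussian and by the similarity between the
    visible value at (t, s) and the ToF value at the centre (m, n).  Windows
    are truncated at the image border; all weights are strictly positive so
    the denominator never vanishes, and the output is a convex combination
    of the visible band over the window.
    """
    tof_high = np.asarray(tof_high, dtype=float)
    rgb_high = np.asarray(rgb_high, dtype=float)
    if tof_high.shape != rgb_high.shape:
        raise ValueError(f"band shapes differ: {tof_high.shape} vs {rgb_high.shape}")
    if not (np.all(np.isfinite(tof_high)) and np.all(np.isfinite(rgb_high))):
        raise ValueError("high bands must be finite")
    m, n = tof_high.shape
    num = np.zeros((m, n))
    den = np.zeros((m, n))
    inv2ss = 1.0 / (2.0 * sigma_spatial ** 2)
    inv2sr = 1.0 / (2.0 * sigma_range ** 2)
    for dt in range(-radius, radius + 1):
        for ds in range(-radius, radius + 1):
            w_spatial = np.exp(-(dt * dt + ds * ds) * inv2ss)
            # centre rows m with t = m + dt inside the image
            c0, c1 = max(0, -dt), min(m, m - dt)
            d0, d1 = max(0, -ds), min(n, n - ds)
            centre = (slice(c0, c1), slice(d0, d1))
            shifted = (slice(c0 + dt, c1 + dt), slice(d0 + ds, d1 + ds))
            values = rgb_high[shifted]
            w = w_spatial * np.exp(-((tof_high[centre] - values) ** 2) * inv2sr)
            num[centre] += values * w
            den[centre] += w
    return num / den


def segment_low_band(low_band: np.ndarray, params: pcnn.PCNNParams,
                     saliency_config: saliency.SaliencyConfig | None = None) -> tuple:
    """Saliency-guided PCNN segmentation of a low-frequency band.

    Runs the network on the min-max-normalized band; after each iteration
    the threshold recharge V_theta is replaced by the KL divergence between
    the firing-state distributions of the maps ``lag`` iterations apart
    (floored to stay positive), and iteration stops when the significance
    between those maps drops to the configured delta (or n_max is hit).

    Returns (ignition maps, trace) with trace entries
    (iteration, significance, V_theta used next).
    """
    if saliency_config is None:
        saliency_config = saliency.SaliencyConfig()
    trace: list = []

    def termination(maps):
        return saliency.should_continue(maps, saliency_config)

    def adapt(maps, current):
        lag = saliency_config.lag
        if len(maps) < lag + 1:
            return None
        a, b = maps[-1 - lag], maps[-1]
        v_theta = saliency.compute_v_theta(a, b, floor=saliency.V_THETA_FLOOR)
        model = saliency.estimate_model(a, b, lag)
        trace.append((len(maps), saliency.significance(model), v_theta))
        return current.with_v_theta(v_theta)

    result = pcnn.run(low_band, params, termination=termination, adapt=adapt)
    return result.maps, trace


def _luminance(image: np.ndarray) -> np.ndarray:
    return 0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    return _luminance(image) if image.ndim == 3 else image


def _fuse_gray(tof: np.ndarray, visible: np.ndarray, config: FusionConfig) -> FusionResult:
    dec = config.decomposition
    tof_pyr = nsst.decompose(tof, dec)
    vis_pyr = nsst.decompose(visible, dec)

    # high-band fusion does not depend on the PCNN parameters: do it once
    fused_high = [
        [
            fuse_high(tof_pyr.high[lev][k], vis_pyr.high[lev][k],
                      radius=config.bilateral_radius,
                      sigma_spatial=config.sigma_spatial,
                      sigma_range=config.sigma_range)
            for k in range(dec.n_directions)
        ]
        for lev in range(dec.levels)
    ]

    def assemble(params):
        maps, trace = segment_low_band(tof_pyr.low, params, config.saliency)
        mask = maps[-1] if maps else None
        low = fuse_low(tof_pyr.low, vis_pyr.low, config.low_weights,
                       mask=mask, mask_boost=config.mask_boost)
        pyramid = nsst.SubbandPyramid(low=low, high=fused_high, config=dec)
        return nsst.reconstruct(pyramid), maps, trace, mask

    archive = None
    params = config.pcnn
    if config.optimize:
        def objective(x):
            candidate = replace(params, alpha_L=float(x[0]), beta=float(x[1]),
                                alpha_theta=float(x[2]), W=params.W.copy())
            fused, _, _, _ = assemble(candidate)
            ce = 0.5 * (metrics.cross_entropy(fused, tof) + metrics.cross_entropy(fused, visible))
            mi = metrics.mutual_information(fused, tof) + metrics.mutual_information(fused, visible)
            return (ce, mi)

        archive, triplet = mmoabc.optimize(config.optimizer, objective)
        params = replace(params, alpha_L=float(triplet[0]), beta=float(triplet[1]),
                         alpha_theta=float(triplet[2]), W=params.W.copy())

    fused, maps, trace, mask = assemble(params)
    return FusionResult(fused=fused, ignition_maps=maps, params=params,
                        mask=mask, archive=archive, saliency_trace=trace)


def fuse_images(tof: np.ndarray, visible: np.ndarray, config: FusionConfig | None = None) -> FusionResult:
    """Fuse a registered ToF-confidence / visible image pair.

    A color visible image is either reduced to luminance (fused luminance is
    re-attached to the chroma as an additive shift) or fused channel by
    channel, per ``config.color_mode``.  Returns the fused raster with the
    ignition-map history, the PCNN parameters used, and (when the optimizer
    ran) the Pareto archive.
    """
    if config is None:
        config = FusionConfig()
    tof = np.asarray(tof, dtype=float)
    visible = np.asarray(visible, dtype=float)
    if tof.shape[:2] != visible.shape[:2]:
        raise ValueError(
            f"images are not registered: {tof.shape[:2]} vs {visible.shape[:2]}"
        )
    tof_gray = _to_gray(tof)

    if visible.ndim == 2:
        return _fuse_gray(tof_gray, visible, config)

    if config.color_mode == "per-channel":
        results = [_fuse_gray(tof_gray, visible[..., c], config) for c in range(visible.shape[2])]
        fused = np.stack([r.fused for r in results], axis=-1)
        first = results[0]
        return FusionResult(fused=fused, ignition_maps=first.ignition_maps,
                            params=first.params, mask=first.mask,
                            archive=first.archive, saliency_trace=first.saliency_trace)

    luma = _luminance(visible)
    result = _fuse_gray(tof_gray, luma, config)
    shift = result.fused - luma
    fused_color = np.clip(visible + shift[..., None], 0.0, 1.0)
    return FusionResult(fused=fused_color, ignition_maps=result.ignition_maps,
                        params=result.params, mask=result.mask,
                        archive=result.archive, saliency_trace=result.saliency_trace)
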