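"""Objective fusion-quality indicators.

All metrics operate on 8-bit-quantized copies of the images (values in
[0, 1] are scaled by 255 and rounded half-to-even), which makes histogram
quantities well defined and results deterministic.  The report carries the
nine standard indicators — average gradient (AG), edge strength (ES),
information entropy (IE), standard deviation (SD), peak signal-to-noise
ratio (PSNR), spatial frequency (SF), image clarity (IC), mutual information
(MI), structural similarity (SSI) — plus the cross entropy (CE) that the
parameter optimizer uses as its second objective.  For all of them, larger
values indicate a better fusion except CE, whose sense is configurable in
the optimizer.

Conventions (the named indicators are standard but their formulas vary
across the literature; the exact readings used here):

AG   mean of sqrt((dx^2 + dy^2) / 2) over forward differences.
ES   mean Sobel gradient magnitude (symmetric boundary).
IE   Shannon entropy of the 256-bin histogram, bits.
SD   population standard deviation.
PSNR against the mean of the two sources, peak 255, capped at 100 dB.
SF   sqrt(row-frequency^2 + column-frequency^2) from adjacent differences.
IC   diagonal-corrected mean gradient: sqrt((dx^2 + dy^2 + (dd^2 + da^2)/2) / 3).
MI   256-bin histogram mutual information, summed over the two sources, bits.
SSI  structural similarity, 11x11 Gaussian window (sigma 1.5), symmetric
     padding, standard stabilizers; averaged over the two sources.
CE   relative entropy of the source histogram vs the fused histogram
     (epsilon-smoothed), summed over the two sources, bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MetricReport", "evaluate", "cross_entropy", "mutual_information",
           "entropy", "psnr", "ssim", "quantize"]

PSNR_CAP = 100.0
_CE_EPS = 1e-12


def quantize(image: np.ndarray) -> np.ndarray:
    """8-bit quantized copy (float array of integers in 0..255).

    Inputs on the unit scale are multiplied by 255; inputs already on the
    0..255 scale are rounded in place.  Unit scale is inferred from
    ``max <= 1.5`` — the margin tolerates the slight overshoot that
    band-limited reconstruction can add to a [0, 1] image.  Rounding is
    numpy's half-to-even.
    """
    image = np.asarray(image, dtype=float)
    if image.max(initial=0.0) <= 1.5:
        image = image * 255.0
    return np.clip(np.round(image), 0.0, 255.0)


def _hist(q: np.ndarray) -> np.ndarray:
    return np.bincount(q.astype(np.int64).ravel(), minlength=256).astype(float) / q.size


def entropy(image: np.ndarray) -> float:
    """IE: Shannon entropy (bits) of the 256-bin grey-level histogram."""
    p = _hist(quantize(image))
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def average_gradient(image: np.ndarray) -> float:
    q = quantize(image)
    dx = q[1:, :-1] - q[:-1, :-1]
    dy = q[:-1, 1:] - q[:-1, :-1]
    return float(np.mean(np.sqrt((dx ** 2 + dy ** 2) / 2.0)))


def edge_strength(image: np.ndarray) -> float:
    q = quantize(image)
    gx = ndimage.sobel(q, axis=0, mode="reflect")
    gy = ndimage.sobel(q, axis=1, mode="reflect")
    return float(np.mean(np.sqrt(gx ** 2 + gy ** 2)))


def spatial_frequency(image: np.ndarray) -> float:
    q = quantize(image)
    rf = np.mean((q[:, 1:] - q[:, :-1]) ** 2)
    cf = np.mean((q[1:, :] - q[:-1, :]) ** 2)
    return float(np.sqrt(rf + cf))


def image_clarity(image: np.ndarray) -> float:
    q = quantize(image)
    dx = q[1:, :-1] - q[:-1, :-1]
    dy = q[:-1, 1:] - q[:-1, :-1]
    dd = q[1:, 1:] - q[:-1, :-1]
    da = q[1:, :-1] - q[:-1, 1:]
    return float(np.mean(np.sqrt((dx ** 2 + dy ** 2 + 0.5 * dd ** 2 + 0.5 * da ** 2) / 3.0)))


def psnr(image: np.ndarray, reference: np.ndarray) -> float:
    """PSNR (dB) with peak 255, capped at ``PSNR_CAP`` for zero MSE."""
    q = quantize(image)
    r = np.asarray(reference, dtype=float)
    if q.shape != r.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((q - r) ** 2))
    if mse == 0.0:
        return PSNR_CAP
    return float(min(10.0 * np.log10(255.0 ** 2 / mse), PSNR_CAP))


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (bits) between the 256-bin grey-level histograms of two images."""
    qa = quantize(a).astype(np.int64)
    qb = quantize(b).astype(np.int64)
    if qa.shape != qb.shape:
        raise ValueError("shape mismatch")
    joint = np.bincount(qa.ravel() * 256 + qb.ravel(), minlength=256 * 256).astype(float)
    joint = joint.reshape(256, 256) / qa.size
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)

    def h(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    return max(h(pa) + h(pb) - h(joint.ravel()), 0.0)


def cross_entropy(fused: np.ndarray, source: np.ndarray) -> float:
    """CE (bits): relative entropy of the source grey-level histogram with
    respect to the fused histogram, after epsilon smoothing."""
    qf = quantize(fused)
    qs = quantize(source)
    if qf.shape != qs.shape:
        raise ValueError("shape mismatch")
    pf = _hist(qf) + _CE_EPS
    ps = _hist(qs) + _CE_EPS
    pf /= pf.sum()
    ps /= ps.sum()
    return float((ps * (np.log2(ps) - np.log2(pf))).sum())


def _gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    half = size // 2
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(a: np.ndarray, b: np.ndarray, size: int = 11, sigma: float = 1.5) -> float:
    """Mean structural similarity with a Gaussian window and symmetric
    padding; stabilizers C1 = (0.01*255)^2, C2 = (0.03*255)^2."""
    qa = quantize(a)
    qb = quantize(b)
    if qa.shape != qb.shape:
        raise ValueError("shape mismatch")
    k = _gaussian_kernel(size, sigma)

    def smooth(img):
        return ndimage.correlate(img, k, mode="reflect")

    c1 = (0.01 * 255.0) ** 2
    c2 = (0.03 * 255.0) ** 2
    mu_a = smooth(qa)
    mu_b = smooth(qb)
    var_a = smooth(qa * qa) - mu_a ** 2
    var_b = smooth(qb * qb) - mu_b ** 2
    cov = smooth(qa * qb) - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


@dataclass
class MetricReport:
    AG: float
    ES: float
    IE: float
    SD: float
    PSNR: float
    SF: float
    IC: float
    MI: float
    SSI: float
    CE: float

    COLUMNS = ("AG", "ES", "IE", "SD", "PSNR", "SF", "IC", "MI", "SSI", "CE")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.COLUMNS}


def evaluate(fused: np.ndarray, src_a: np.ndarray, src_b: np.ndarray) -> MetricReport:
    """Score a fused image against its two sources.

    MI and CE are the sums of the fused-vs-src_a and fused-vs-src_b terms;
    SSI is the mean of the two pairwise values; PSNR is taken against the
    pixelwise mean of the two quantized sources.
    """
    fused = np.asarray(fused, dtype=float)
    if fused.shape != np.shape(src_a) or fused.shape != np.shape(src_b):
        raise ValueError("fused and source shapes differ")
    q = quantize(fused)
    reference = (quantize(src_a) + quantize(src_b)) / 2.0
    return MetricReport(
        AG=average_gradient(fused),
        ES=edge_strength(fused),
        IE=entropy(fused),
        SD=float(np.std(q)),
        PSNR=psnr(fused, reference),
        SF=spatial_frequency(fused),
        IC=image_clarity(fused),
        MI=mutual_information(fused, src_a) + mutual_information(fused, src_b),
        SSI=0.5 * (ssim(fused, src_a) + ssim(fused, src_b)),
        CE=cross_entropy(fused, src_a) + cross_entropy(fused, src_b),
    )
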