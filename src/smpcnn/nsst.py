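"""Non-subsampled shearlet transform: shift-invariant multiscale, multidirectional
decomposition into full-resolution sub-bands, and its inverse.

The pyramid stage is an a-trous (holes) scheme built on the maxflat B3-spline
kernel ``(1, 4, 6, 4, 1)/16``, upsampled by ``2**level`` between levels; each
detail band is the residual between successive approximations, so synthesis is
a plain sum and reconstruction is exact to machine precision.  The directional
stage splits every detail band into ``2**v`` wedge-shaped frequency bands with
raised-cosine angular windows that form a partition of unity modulo pi, so the
directional split is also exactly invertible.  With periodic boundaries every
operator is a circular convolution, which makes the transform exactly
equivariant under integer circular shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import pathlib

import numpy as np

__all__ = [
    "DecompositionConfig",
    "SubbandPyramid",
    "decompose",
    "reconstruct",
    "save_pyramid",
    "load_pyramid",
]

# maxflat B3-spline low-pass kernel of the a-trous scheme
_ATROUS_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class DecompositionConfig:
    """Settings of one pyramid/directional decomposition.

    Parameters
    ----------
    levels : int
        Number of pyramid levels ``u`` (>= 1).
    direction_power : int
        ``v``; each level is split into ``2**v`` directional bands.
    pyramid_filter : str
        Filter family of the non-subsampled pyramid. Only ``"maxflat"``
        (B3-spline) is provided.
    boundary_mode : str
        ``"periodic"`` (circular convolution; exactly shift invariant) or
        ``"symmetric"`` (mirror padding in the pyramid stage).
    """

    levels: int = 2
    direction_power: int = 2
    pyramid_filter: str = "maxflat"
    boundary_mode: str = "periodic"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels (u) must be >= 1")
        if self.direction_power < 0:
            raise ValueError("direction_power (v) must be >= 0")
        if self.pyramid_filter != "maxflat":
            raise ValueError(f"unknown pyramid filter {self.pyramid_filter!r}")
        if self.boundary_mode not in ("periodic", "symmetric"):
            raise ValueError(f"unknown boundary mode {self.boundary_mode!r}")

    @property
    def n_directions(self) -> int:
        return 2 ** self.direction_power

    def filter_support(self) -> int:
        """Spatial support of the largest (most upsampled) pyramid kernel."""
        return 4 * 2 ** (self.levels - 1) + 1


@dataclass
class SubbandPyramid:
    """One low-frequency band plus ``u`` levels of ``2**v`` directional
    high-frequency bands, all the size of the source image."""

    low: np.ndarray
    high: list  # high[level][direction] -> M x N array
    config: DecompositionConfig = field(default_factory=DecompositionConfig)

    @property
    def shape(self) -> tuple:
        return self.low.shape

    def validate(self) -> None:
        shape = self.low.shape
        if len(self.high) != self.config.levels:
            raise ValueError(
                f"pyramid has {len(self.high)} levels, config says {self.config.levels}"
            )
        for lev, bands in enumerate(self.high):
            if len(bands) != self.config.n_directions:
                raise ValueError(
                    f"level {lev} has {len(bands)} directional bands, "
                    f"expected {self.config.n_directions}"
                )
            for band in bands:
                if band.shape != shape:
                    raise ValueError("band shapes are inconsistent")


def _kernel_response_1d(n: int, step: int) -> np.ndarray:
    """Frequency response of the a-trous kernel upsampled by ``step`` on a
    length-``n`` periodic axis.  Symmetric kernel -> real, zero-phase."""
    w = 2.0 * np.pi * np.fft.fftfreq(n)
    return 6.0 / 16.0 + (8.0 / 16.0) * np.cos(w * step) + (2.0 / 16.0) * np.cos(2.0 * w * step)


def _upsampled_kernel_2d(step: int) -> np.ndarray:
    """Spatial 2-D separable kernel with ``step - 1`` holes between taps."""
    size = 4 * step + 1
    k1 = np.zeros(size)
    k1[::step] = _ATROUS_KERNEL
    return np.outer(k1, k1)


def direction_windows(shape: tuple, n_dir: int) -> list:
    """Angular raised-cosine windows on the FFT grid, a partition of unity.

    Directions are wedges of width pi / n_dir in frequency angle modulo pi
    (opposite frequencies belong to the same direction, keeping the filtered
    bands real-valued).
    """
    if n_dir == 1:
        return [np.ones(shape)]
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    theta = np.arctan2(fy, fx) % np.pi
    delta = np.pi / n_dir
    windows = []
    for k in range(n_dir):
        center = (k + 0.5) * delta
        # signed angular distance modulo pi, folded to [0, pi/2]
        dist = np.abs(((theta - center + np.pi / 2) % np.pi) - np.pi / 2)
        t = np.clip(dist / delta, 0.0, 1.0)
        windows.append(np.cos(0.5 * np.pi * t) ** 2)
    total = np.sum(windows, axis=0)
    return [w / total for w in windows]


def _check_image(image: np.ndarray, config: DecompositionConfig) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got ndim={image.ndim}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    support = config.filter_support()
    if min(image.shape) < support:
        raise ValueError(
            f"image of shape {image.shape} is smaller than the filter support "
            f"({support}) for {config.levels} levels"
        )
    return image


def decompose(image: np.ndarray, config: DecompositionConfig | None = None) -> SubbandPyramid:
    """Decompose an image into a low band and ``u * 2**v`` directional bands.

    All bands have the source shape (non-subsampled); the transform is linear
    and, with periodic boundaries, commutes with integer circular shifts.
    """
    if config is None:
        config = DecompositionConfig()
    image = _check_image(image, config)

    if config.boundary_mode == "periodic":
        approximations = _pyramid_periodic(image, config)
    else:
        approximations = _pyramid_symmetric(image, config)

    windows = direction_windows(image.shape, config.n_directions)
    high: list = []
    for level in range(config.levels):
        detail = approximations[level] - approximations[level + 1]
        if config.n_directions == 1:
            high.append([detail])
        else:
            spec = np.fft.fft2(detail)
            high.append([np.fft.ifft2(spec * w).real for w in windows])
    return SubbandPyramid(low=approximations[-1], high=high, config=config)


def _pyramid_periodic(image: np.ndarray, config: DecompositionConfig) -> list:
    out = [image]
    spec = np.fft.fft2(image)
    m, n = image.shape
    running = np.ones((m, n))
    for level in range(config.levels):
        step = 2 ** level
        running = running * np.outer(_kernel_response_1d(m, step), _kernel_response_1d(n, step))
        out.append(np.fft.ifft2(spec * running).real)
    return out


def _pyramid_symmetric(image: np.ndarray, config: DecompositionConfig) -> list:
    from scipy import ndimage

    out = [image]
    current = image
    for level in range(config.levels):
        kernel = _upsampled_kernel_2d(2 ** level)
        current = ndimage.convolve(current, kernel, mode="reflect")
        out.append(current)
    return out


def reconstruct(pyramid: SubbandPyramid) -> np.ndarray:
    """Invert :func:`decompose`.

    The analysis bands tile the identity (details are residuals; directional
    windows sum to one), so synthesis is the sum of every band.
    """
    pyramid.validate()
    out = pyramid.low.copy()
    for bands in pyramid.high:
        for band in bands:
            out += band
    return out


def save_pyramid(pyramid: SubbandPyramid, directory: str | pathlib.Path) -> None:
    """Serialize bands as 32-bit float TIFFs plus a JSON config sidecar."""
    import tifffile

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "low.tif", pyramid.low.astype(np.float32))
    for lev, bands in enumerate(pyramid.high):
        for k, band in enumerate(bands):
            tifffile.imwrite(directory / f"high_l{lev}_d{k}.tif", band.astype(np.float32))
    cfg = pyramid.config
    (directory / "config.json").write_text(
        json.dumps(
            {
                "levels": cfg.levels,
                "direction_power": cfg.direction_power,
                "pyramid_filter": cfg.pyramid_filter,
                "boundary_mode": cfg.boundary_mode,
            },
            indent=2,
        )
    )


def load_pyramid(directory: str | pathlib.Path) -> SubbandPyramid:
    import tifffile

    directory = pathlib.Path(directory)
    cfg = DecompositionConfig(**json.loads((directory / "config.json").read_text()))
    low = tifffile.imread(directory / "low.tif").astype(float)
    high = [
        [
            tifffile.imread(directory / f"high_l{lev}_d{k}.tif").astype(float)
            for k in range(cfg.n_directions)
        ]
        for lev in range(cfg.levels)
    ]
    pyramid = SubbandPyramid(low=low, high=high, config=cfg)
    pyramid.validate()
    return pyramid
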