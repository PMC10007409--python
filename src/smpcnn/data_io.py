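"""Raster I/O and the synthetic registered ToF/visible pair generator.

Internal image convention: float arrays in [0, 1], row-major, origin at the
top-left, 0-based indices.  Every module in the package works on this scale.

The generator emulates the structure of orchard ToF-confidence / visible
pairs: on the ToF image, fruit targets are bright elliptical regions whose
grey values are approximately normally distributed over a dark background;
the visible image is a textured scene (smoothed seeded noise) under a
smoothly varying illumination field, with the fruit regions given their own
texture.  The two images share the same geometry, i.e. they are registered
by construction, and the ground-truth fruit mask is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import pathlib

import numpy as np
from scipy import ndimage

__all__ = ["SyntheticSceneConfig", "Scene", "generate_scene", "generate_pair",
           "read_image", "write_image"]

_INT_SCALE = {np.uint8: 255.0, np.uint16: 65535.0}


@dataclass(frozen=True)
class SyntheticSceneConfig:
    """Scene parameters (grey values on the unit scale).

    The defaults model a handful of fruit targets filling a few percent of a
    128 x 128 frame: bright (0.85) and tight (sd 0.05) on the ToF confidence
    image over a dark (0.2) background, a mid-grey visible texture with a
    correlation length of ~6 px, a 30% illumination sweep and 1% sensor
    noise.
    """

    size: tuple = (128, 128)
    n_fruits: int = 3
    fruit_mean_gray: float = 0.85
    fruit_gray_sd: float = 0.05
    background_gray: float = 0.2
    radius_range: tuple = (0.06, 0.12)  # fraction of min(M, N)
    texture_scale: float = 6.0
    illumination_gradient: float = 0.3
    noise_sd: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        m, n = self.size
        if m < 32 or n < 32:
            raise ValueError("image size must be at least 32 x 32")
        if self.n_fruits < 0:
            raise ValueError("n_fruits must be >= 0")
        for name in ("fruit_mean_gray", "fruit_gray_sd", "background_gray"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.radius_range[1] * min(self.size) >= min(self.size) / 2:
            raise ValueError("fruits would be larger than the image")


@dataclass
class Scene:
    tof: np.ndarray
    visible: np.ndarray
    mask: np.ndarray          # boolean fruit mask
    fruits: list = field(default_factory=list)  # (cy, cx, ry, rx, angle)


def _ellipse_mask(shape, cy, cx, ry, rx, angle) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    y = yy - cy
    x = xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _texture(rng, shape, scale, mean, contrast) -> np.ndarray:
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), scale, mode="wrap")
    sd = noise.std()
    if sd > 0:
        noise = noise / sd
    return mean + contrast * noise


def generate_scene(config: SyntheticSceneConfig) -> Scene:
    """Draw one registered (tof, visible, mask) scene from the config."""
    rng = np.random.default_rng(config.seed)
    m, n = config.size
    shape = (m, n)
    rmin = config.radius_range[0] * min(shape)
    rmax = config.radius_range[1] * min(shape)

    mask = np.zeros(shape, dtype=bool)
    fruits = []
    for _ in range(config.n_fruits):
        ry = rng.uniform(rmin, rmax)
        rx = rng.uniform(rmin, rmax)
        margin = max(ry, rx) + 1
        cy = rng.uniform(margin, m - margin)
        cx = rng.uniform(margin, n - margin)
        angle = rng.uniform(0.0, np.pi)
        fruits.append((cy, cx, ry, rx, angle))
        mask |= _ellipse_mask(shape, cy, cx, ry, rx, angle)

    tof = np.full(shape, config.background_gray)
    fruit_gray = rng.normal(config.fruit_mean_gray, config.fruit_gray_sd, size=shape)
    tof[mask] = fruit_gray[mask]
    tof = tof + rng.normal(0.0, config.noise_sd, size=shape)
    tof = np.clip(tof, 0.0, 1.0)

    background = _texture(rng, shape, config.texture_scale, 0.5, 0.15)
    fruit_tex = _texture(rng, shape, max(config.texture_scale / 2.0, 1.0), 0.55, 0.12)
    visible = np.where(mask, fruit_tex, background)
    # smooth multiplicative light field: linear sweep plus a broad blob
    yy, xx = np.mgrid[0:m, 0:n]
    direction = rng.uniform(0.0, 2.0 * np.pi)
    ramp = (np.cos(direction) * xx / n + np.sin(direction) * yy / m)
    ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-12)
    blob = ndimage.gaussian_filter(rng.standard_normal(shape), min(m, n) / 4.0, mode="wrap")
    if blob.std() > 0:
        blob = blob / (4.0 * blob.std())
    light = 1.0 + config.illumination_gradient * (ramp - 0.5 + blob)
    visible = visible * light + rng.normal(0.0, config.noise_sd, size=shape)
    visible = np.clip(visible, 0.0, 1.0)

    return Scene(tof=tof, visible=visible, mask=mask, fruits=fruits)


def generate_pair(config: SyntheticSceneConfig) -> tuple:
    """(tof, visible, mask) triple; see :func:`generate_scene`."""
    scene = generate_scene(config)
    return scene.tof, scene.visible, scene.mask


def read_image(path: str | pathlib.Path) -> np.ndarray:
    """Read a PNG/TIFF/PGM raster as floats in [0, 1].

    Integer images are divided by their type's full scale; float TIFFs are
    taken as already being on the unit scale.
    """
    path = pathlib.Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".png", ".tif", ".tiff", ".pgm"):
        raise ValueError(f"unsupported image format {suffix!r}")
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"could not read image {path}") from exc
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        return arr.astype(float) / scale
    return arr.astype(float)


def write_image(path: str | pathlib.Path, image: np.ndarray) -> None:
    """Write a [0, 1] float raster: 8-bit for PNG/PGM, float32 for TIFF."""
    path = pathlib.Path(path)
    suffix = path.suffix.lower()
    image = np.asarray(image, dtype=float)
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.astype(np.float32))
    elif suffix in (".png", ".pgm"):
        import imageio.v3 as iio

        data = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(path, data)
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
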