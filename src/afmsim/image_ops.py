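"""Post-processing and comparison of AFM rasters.

Covers Gaussian blurring (to mimic experimental image averaging), bilinear
resampling onto a new pixel size, AFM-style rendering with height-encoded
colors, background cleaning of regions of interest, and the Pearson image
correlation score used to compare simulated and experimental images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import IO, Optional, Tuple, Union

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .exceptions import UndefinedCorrelationError, ValidationError
from .tip_scan import HeightMap, load_heightmap

__all__ = [
    "AFMRaster",
    "raster_from_heightmap",
    "load_raster",
    "gaussian_blur",
    "resample",
    "clean_background",
    "correlation",
    "render",
]

_BLUR_TRUNCATE = 4.0  # kernel support in units of sigma, fixed for reproducibility


@dataclass
class AFMRaster:
    """Grayscale image with a physical pixel size.

    ``pixels`` holds heights in nm for simulated data or arbitrary intensity
    units for experimental data; ``mask`` is an optional boolean region of
    interest of the same shape (True = inside ROI).
    """

    pixels: np.ndarray
    pixel_size: float
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2:
            raise ValidationError(f"pixels must be 2-D, got shape {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValidationError("pixels must be finite")
        if not (self.pixel_size > 0):
            raise ValidationError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != p.shape:
                raise ValidationError("mask shape must match pixels")
            self.mask = m
        self.pixels = p

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def effective_mask(self) -> np.ndarray:
        return np.ones(self.shape, dtype=bool) if self.mask is None else self.mask


def raster_from_heightmap(hmap: HeightMap) -> AFMRaster:
    """View a simulated height map as a raster (pixel size = grid step)."""
    return AFMRaster(pixels=hmap.heights.copy(), pixel_size=hmap.grid.step)


def load_raster(
    source: Union[str, os.PathLike, IO],
    pixel_size: Optional[float] = None,
) -> AFMRaster:
    """Load a raster from a height-map text matrix or a grayscale image file.

    Text matrices carry their own pixel size; for PNG/TIFF inputs
    ``pixel_size`` (nm/pixel) must be supplied.  RGB images are converted to
    grayscale by luminance; intensities are used as-is (the correlation score
    is invariant under affine intensity calibration).
    """
    path = os.fspath(source) if isinstance(source, (str, os.PathLike)) else None
    if path is not None and path.lower().endswith((".txt", ".tsv", ".dat", ".csv")):
        hmap = load_heightmap(path)
        return raster_from_heightmap(hmap)
    if path is not None:
        from PIL import Image

        with Image.open(path) as img:
            gray = img.convert("F") if img.mode in ("F", "I", "I;16") else img.convert("L")
            pixels = np.asarray(gray, dtype=float)[::-1]  # +y up convention
        if pixel_size is None:
            raise ValidationError("pixel_size is required for image-file rasters")
        return AFMRaster(pixels=pixels, pixel_size=pixel_size)
    # file-like: assume text matrix
    hmap = load_heightmap(source)
    return raster_from_heightmap(hmap)


def gaussian_blur(raster: AFMRaster, sigma: float) -> AFMRaster:
    """Isotropic Gaussian blur with standard deviation ``sigma`` in nm.

    The kernel is truncated at 4 sigma with reflect boundary handling;
    ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise ValidationError(f"blur sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return AFMRaster(raster.pixels.copy(), raster.pixel_size, raster.mask)
    blurred = ndimage.gaussian_filter(
        raster.pixels,
        sigma=sigma / raster.pixel_size,
        mode="reflect",
        truncate=_BLUR_TRUNCATE,
    )
    return AFMRaster(blurred, raster.pixel_size, raster.mask)


def resample(raster: AFMRaster, new_pixel_size: float) -> AFMRaster:
    """Bilinear resampling onto a new pixel size over the same physical area.

    Pixel centres of the target grid are interpolated from the source grid;
    linear extrapolation at the edges keeps affine intensity fields exact.
    """
    if not (new_pixel_size > 0):
        raise ValidationError(f"new_pixel_size must be positive, got {new_pixel_size}")
    ny, nx = raster.shape
    extent_y = ny * raster.pixel_size
    extent_x = nx * raster.pixel_size
    new_ny = int(round(extent_y / new_pixel_size))
    new_nx = int(round(extent_x / new_pixel_size))
    if new_ny < 2 or new_nx < 2:
        raise ValidationError(
            f"target raster degenerate: {new_ny}x{new_nx} pixels (need >=2 per axis)"
        )
    interp = RegularGridInterpolator(
        (np.arange(ny, dtype=float), np.arange(nx, dtype=float)),
        raster.pixels,
        method="linear",
        bounds_error=False,
        fill_value=None,  # linear extrapolation at edges
    )
    scale = new_pixel_size / raster.pixel_size
    yc = (np.arange(new_ny) + 0.5) * scale - 0.5
    xc = (np.arange(new_nx) + 0.5) * scale - 0.5
    jj, ii = np.meshgrid(yc, xc, indexing="ij")
    pixels = interp(np.stack([jj.ravel(), ii.ravel()], axis=1)).reshape(new_ny, new_nx)
    return AFMRaster(pixels=pixels, pixel_size=new_pixel_size)


def resample_to_shape(raster: AFMRaster, shape: Tuple[int, int]) -> AFMRaster:
    """Bilinear resampling to an explicit (ny, nx) shape (co-registration aid)."""
    ny, nx = raster.shape
    tny, tnx = shape
    if tny < 2 or tnx < 2:
        raise ValidationError("target shape must be at least 2x2")
    interp = RegularGridInterpolator(
        (np.arange(ny, dtype=float), np.arange(nx, dtype=float)),
        raster.pixels,
        method="linear",
        bounds_error=False,
        fill_value=None,
    )
    yc = (np.arange(tny) + 0.5) * (ny / tny) - 0.5
    xc = (np.arange(tnx) + 0.5) * (nx / tnx) - 0.5
    jj, ii = np.meshgrid(yc, xc, indexing="ij")
    pixels = interp(np.stack([jj.ravel(), ii.ravel()], axis=1)).reshape(tny, tnx)
    return AFMRaster(pixels=pixels, pixel_size=raster.pixel_size * ny / tny)


def clean_background(raster: AFMRaster, threshold: float) -> AFMRaster:
    """Zero out pixels strictly below ``threshold * max(pixels)`` and drop
    them from the ROI mask; other pixels are unchanged.  Idempotent at fixed
    threshold."""
    if not (0 <= threshold < 1):
        raise ValidationError(f"threshold must lie in [0, 1), got {threshold}")
    pixels = raster.pixels.copy()
    if threshold == 0:  # documented boundary: identity, full ROI
        return AFMRaster(pixels, raster.pixel_size, raster.effective_mask())
    cut = threshold * float(pixels.max())
    keep = pixels >= cut
    pixels[~keep] = 0.0
    mask = keep & raster.effective_mask()
    return AFMRaster(pixels=pixels, pixel_size=raster.pixel_size, mask=mask)


def correlation(sim: AFMRaster, exp: AFMRaster, method: str = "pearson") -> float:
    """Similarity score between two co-registered rasters over the joint ROI.

    ``method='pearson'`` (default) gives the Pearson correlation coefficient
    of pixel intensities — symmetric, bounded in [-1, 1] and invariant under
    affine intensity rescaling of either image.  ``method='cosine'`` gives
    the (uncentred) cosine similarity as an alternative.
    """
    if sim.shape != exp.shape:
        raise ValidationError(f"raster shapes differ: {sim.shape} vs {exp.shape}")
    roi = sim.effective_mask() & exp.effective_mask()
    n = int(roi.sum())
    if n < 3:
        raise UndefinedCorrelationError(f"joint ROI has only {n} pixels (need >= 3)")
    a = sim.pixels[roi].astype(float)
    b = exp.pixels[roi].astype(float)
    if method == "pearson":
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise UndefinedCorrelationError("zero intensity variance inside the ROI")
        a = a - a.mean()
        b = b - b.mean()
        return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    if method == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise UndefinedCorrelationError("zero intensity norm inside the ROI")
        return float(np.dot(a, b) / (na * nb))
    raise ValidationError(f"unknown correlation method: {method!r}")


def render(
    source: Union[HeightMap, AFMRaster],
    path: Union[str, os.PathLike],
    colormap: str = "afmhot",
    scalebar: bool = False,
    zrange: Optional[Tuple[float, float]] = None,
) -> str:
    """Render a height map (or raster) to a PNG/TIFF image file.

    Heights map linearly onto the palette between 0 and the map maximum, or
    a user-fixed ``zrange``.  Row orientation is +y up.  With
    ``scalebar=True`` a colorbar annotated in nm is added (figure-style
    output); otherwise the image is written pixel-per-cell.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = source.heights if isinstance(source, HeightMap) else source.pixels
    if zrange is None:
        vmin, vmax = 0.0, float(data.max())
        if vmax <= vmin:
            vmax = vmin + 1.0
    else:
        vmin, vmax = float(zrange[0]), float(zrange[1])

    path = os.fspath(path)
    if scalebar:
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(data, cmap=colormap, vmin=vmin, vmax=vmax, origin="lower")
        fig.colorbar(im, ax=ax, label="height (nm)")
        ax.set_xticks([])
        ax.set_yticks([])
        fig.savefig(path, dpi=150)
        plt.close(fig)
    else:
        plt.imsave(path, data, cmap=colormap, vmin=vmin, vmax=vmax, origin="lower")
    return path


def parse_roi(spec: str, shape: Tuple[int, int]) -> np.ndarray:
    """Boolean mask from a rectangle spec ``"x0:x1,y0:y1"`` in pixel coords."""
    try:
        xs, ys = spec.split(",")
        x0, x1 = (int(v) for v in xs.split(":"))
        y0, y1 = (int(v) for v in ys.split(":"))
    except Exception as exc:
        raise ValidationError(f"malformed ROI spec {spec!r} (want 'x0:x1,y0:y1')") from exc
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = True
    return mask


def load_mask(path: Union[str, os.PathLike], shape: Tuple[int, int]) -> np.ndarray:
    """Boolean ROI from a same-shape 0/1 whitespace-separated text file."""
    mask = np.loadtxt(path) != 0
    if mask.shape != shape:
        raise ValidationError(f"mask shape {mask.shape} does not match raster {shape}")
    return mask
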