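"""Preprocessing of two-channel multiphoton images.

A multiphoton acquisition yields two coregistered 8-bit channels: the
second-harmonic-generation (SHG) channel, specific to fibrillar collagen
("red", R), and the two-photon autofluorescence channel showing overall
tissue morphology ("green", G). This module normalizes such images:
morphological background subtraction, affine registration between
modalities, channel thresholding, tissue-mask construction, and
rectangular region-of-interest extraction.

Conventions shared by the whole package: coordinates are (row, col),
0-based, with pixel centers at integer positions; intensities live on the
0-255 scale; physical distances are micrometres with a known pixel pitch
(default 0.497 um/pixel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

DEFAULT_PIXEL_SIZE_UM = 0.497
DEFAULT_ROI_SIZE_UM = 500.0
DEFAULT_BACKGROUND_RADIUS_PX = 50
TISSUE_CLOSING_RADIUS_PX = 3
TISSUE_MIN_OBJECT_PX = 50


@dataclass
class MPMImage:
    """A coregistered two-channel multiphoton image.

    Attributes
    ----------
    channel_r : ndarray
        SHG (collagen) channel, values in [0, 255].
    channel_g : ndarray
        Two-photon autofluorescence (tissue) channel, same shape as
        ``channel_r``, values in [0, 255].
    pixel_size_um : float
        Physical pixel pitch in micrometres per pixel.
    label : str
        Optional free-text label (e.g. ROI tag) carried through crops.
    """

    channel_r: np.ndarray
    channel_g: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    label: str = ""

    def __post_init__(self) -> None:
        self.channel_r = np.asarray(self.channel_r)
        self.channel_g = np.asarray(self.channel_g)
        if self.channel_r.shape != self.channel_g.shape:
            raise ValueError("channel shapes differ: "
                             f"{self.channel_r.shape} vs {self.channel_g.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channel_r.shape

    def to_tiff(self, path) -> None:
        """Write as a 2-page 8-bit grayscale TIFF (page 1 = SHG, page 2 = 2PAF)."""
        stack = np.stack([
            np.clip(np.rint(self.channel_r), 0, 255).astype(np.uint8),
            np.clip(np.rint(self.channel_g), 0, 255).astype(np.uint8),
        ])
        tifffile.imwrite(path, stack, metadata={
            "pixel_size_um": self.pixel_size_um, "label": self.label})

    @classmethod
    def from_pair(cls, path_r, path_g,
                  pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> "MPMImage":
        """Read a pair of single-channel TIFFs (SHG file, 2PAF file)."""
        return cls(channel_r=tifffile.imread(path_r),
                   channel_g=tifffile.imread(path_g),
                   pixel_size_um=pixel_size_um)

    @classmethod
    def from_tiff(cls, path, pixel_size_um: float | None = None) -> "MPMImage":
        """Read a 2-page TIFF written by :meth:`to_tiff` (or any 2-page stack)."""
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        if stack.ndim != 3 or stack.shape[0] < 2:
            raise ValueError(f"{path}: expected a 2-page grayscale TIFF")
        if pixel_size_um is None:
            pixel_size_um = float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM))
        return cls(channel_r=stack[0], channel_g=stack[1],
                   pixel_size_um=pixel_size_um, label=str(meta.get("label", "")))


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangular region of interest, in pixel coordinates."""

    origin: tuple[int, int]
    size_px: tuple[int, int]
    label: str = ""


@dataclass(frozen=True)
class AffineTransform:
    """2-D affine map from moving to fixed pixel coordinates.

    ``fixed = linear @ moving + translation`` in (row, col) coordinates.
    """

    linear: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        lin = np.asarray(self.linear, dtype=float).reshape(2, 2)
        if abs(np.linalg.det(lin)) < 1e-12:
            raise ValueError("linear part is singular")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float).reshape(2))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()


def roi_size_px(roi_size_um: float = DEFAULT_ROI_SIZE_UM,
                pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> int:
    """Side length in pixels of a square ROI of the given physical size.

    Rounded to the nearest integer pixel count; 500 um at 0.497 um/pixel
    gives 1006 px.
    """
    return int(round(roi_size_um / pixel_size_um))


def subtract_background(channel: np.ndarray, radius_px: int = DEFAULT_BACKGROUND_RADIUS_PX
                        ) -> np.ndarray:
    """Rolling-ball-style background subtraction.

    The background is estimated by grayscale morphological opening with a
    disk of the given radius and subtracted; the result is clipped at 0.
    A flat image maps to all zeros, and isolated peaks narrower than the
    disk are preserved.
    """
    channel = np.asarray(channel, dtype=float)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if 2 * radius_px + 1 > min(channel.shape):
        raise ValueError(
            f"background radius {radius_px} px exceeds image extent {channel.shape}")
    background = ndimage.grey_opening(channel, footprint=disk(radius_px))
    return np.clip(channel - background, 0.0, None)


def threshold_channel(channel: np.ndarray, method: str = "otsu",
                      value: float | None = None,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Binarize a channel; pixels strictly above the threshold are foreground.

    ``method`` is ``"otsu"`` (threshold computed from the in-mask histogram)
    or ``"fixed"`` (uses ``value``). A constant channel has no Otsu
    threshold and raises.
    """
    channel = np.asarray(channel, dtype=float)
    pixels = channel if mask is None else channel[np.asarray(mask, dtype=bool)]
    if method == "otsu":
        if pixels.size == 0 or np.ptp(pixels) == 0:
            raise ValueError("degenerate histogram: channel is constant in mask")
        thr = threshold_otsu(pixels)
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        thr = float(value)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    fg = channel > thr
    if mask is not None:
        fg &= np.asarray(mask, dtype=bool)
    return fg


def tissue_mask(channel_g: np.ndarray, method: str = "otsu",
                value: float | None = None) -> np.ndarray:
    """Tissue mask from the autofluorescence channel.

    Threshold, then morphological closing (disk r=3) and removal of
    connected components smaller than 50 px so noise pixels do not count
    as tissue.
    """
    mask = threshold_channel(channel_g, method=method, value=value)
    mask = ndimage.binary_closing(mask, structure=disk(TISSUE_CLOSING_RADIUS_PX))
    return _remove_small(mask, TISSUE_MIN_OBJECT_PX)


def _remove_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop connected components with fewer than ``min_size`` pixels."""
    labeled, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labeled.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labeled]


def read_roi_csv(path, default_size_px: int | None = None) -> dict[str, list[ROI]]:
    """Read an ROI list CSV with columns (label, row, col[, rows, cols]).

    An optional ``file`` column scopes each ROI to one image; ROIs without
    it apply to every image (returned under the key ``"*"``). When the
    size columns are absent, ``default_size_px`` supplies a square size
    (e.g. the 500 um default via :func:`roi_size_px`).
    """
    import pandas as pd

    frame = pd.read_csv(path)
    missing = {"label", "row", "col"} - set(frame.columns)
    if missing:
        raise ValueError(f"ROI CSV missing columns: {sorted(missing)}")
    has_size = {"rows", "cols"} <= set(frame.columns)
    if not has_size and default_size_px is None:
        raise ValueError("ROI CSV has no rows/cols columns and no default "
                         "ROI size was given")
    out: dict[str, list[ROI]] = {}
    for _, r in frame.iterrows():
        key = (str(r["file"]) if "file" in frame.columns
               and pd.notna(r.get("file")) else "*")
        size = ((int(r["rows"]), int(r["cols"])) if has_size
                else (default_size_px, default_size_px))
        out.setdefault(key, []).append(ROI(
            origin=(int(r["row"]), int(r["col"])), size_px=size,
            label=str(r["label"])))
    return out


def extract_rois(image: MPMImage, rois: list[ROI]) -> list[MPMImage]:
    """Crop a list of rectangular ROIs, carrying pixel size and labels."""
    crops = []
    nrows, ncols = image.shape
    for roi in rois:
        r0, c0 = roi.origin
        dr, dc = roi.size_px
        if r0 < 0 or c0 < 0 or r0 + dr > nrows or c0 + dc > ncols:
            raise ValueError(
                f"ROI {roi.label or roi.origin} out of bounds for image {image.shape}")
        crops.append(MPMImage(
            channel_r=image.channel_r[r0:r0 + dr, c0:c0 + dc],
            channel_g=image.channel_g[r0:r0 + dr, c0:c0 + dc],
            pixel_size_um=image.pixel_size_um,
            label=roi.label))
    return crops


def _params_to_transform(params: np.ndarray, center: np.ndarray) -> AffineTransform:
    """Build an affine about the image center from (t_r, t_c, theta, log_sr, log_sc, shear)."""
    tr, tc, theta, log_sr, log_sc, shear = params
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    scale = np.diag([np.exp(log_sr), np.exp(log_sc)])
    sh = np.array([[1.0, shear], [0.0, 1.0]])
    lin = rot @ scale @ sh
    trans = center - lin @ center + np.array([tr, tc])
    return AffineTransform(linear=lin, translation=trans)


def warp(moving: np.ndarray, transform: AffineTransform,
         output_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Resample ``moving`` onto the fixed grid under ``transform`` (bilinear)."""
    inv = np.linalg.inv(transform.linear)
    offset = -inv @ transform.translation
    return ndimage.affine_transform(
        np.asarray(moving, dtype=float), inv, offset=offset,
        output_shape=output_shape, order=1, mode="constant", cval=0.0)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    valid = (a > 0) | (b > 0)
    if valid.sum() < 16:
        return -1.0
    a, b = a[valid], b[valid]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return -1.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def register_affine(moving: np.ndarray, fixed: np.ndarray,
                    init: AffineTransform | None = None
                    ) -> tuple[AffineTransform, np.ndarray, bool]:
    """Register ``moving`` onto ``fixed`` with a 6-parameter affine.

    Maximizes normalized cross-correlation by local optimization (Powell)
    starting from ``init``; when no ``init`` is supplied, the translation
    is first initialized by phase correlation. Returns the transform, the
    warped moving image, and a success flag. On optimizer failure the
    initial transform is returned with ``success=False`` and a warning.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    center = (np.array(fixed.shape, dtype=float) - 1) / 2.0

    x0 = np.zeros(6)
    if init is not None:
        # translation-only inits are supported exactly; general linear parts
        # seed the translation component and leave the rest to the optimizer
        x0[:2] = init.translation + (init.linear - np.eye(2)) @ center
    else:
        shift, _, _ = phase_cross_correlation(fixed, moving, upsample_factor=10,
                                              normalization=None)
        x0[:2] = shift

    def neg_score(params):
        t = _params_to_transform(params, center)
        return -_ncc(warp(moving, t, fixed.shape), fixed)

    scales = np.array([1.0, 1.0, 0.01, 0.01, 0.01, 0.01])
    res = optimize.minimize(lambda z: neg_score(z * scales), x0 / scales,
                            method="Powell",
                            options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 4000})
    best = _params_to_transform(res.x * scales, center)
    success = bool(res.success) and -res.fun > _ncc(warp(moving,
                   _params_to_transform(x0, center), fixed.shape), fixed) - 1e-9
    if not res.success:
        warnings.warn("affine registration did not converge; returning initial "
                      "transform", RuntimeWarning, stacklevel=2)
        best = init if init is not None else _params_to_transform(x0, center)
        success = False
    return best, warp(moving, best, fixed.shape), success
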