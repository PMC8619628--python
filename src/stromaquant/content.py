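"""Collagen-content quantifiers of a stromal region of interest.

Four content features summarize how much collagen an ROI holds and how
bright it is relative to the surrounding tissue:

* ``af`` — collagen area fraction: SHG-foreground pixels divided by tissue
  pixels (reported x100 as a percentage in clinical tables);
* ``i_r`` — mean SHG intensity over SHG-foreground pixels;
* ``i_g`` — mean autofluorescence intensity over tissue pixels;
* ``norm_intensity`` — the normalized stromal intensity ratio
  i_r / (i_r + i_g), near 1 when bright collagen dominates the stroma.

The remaining fields of :class:`FeatureVector` (coherence and the fiber
morphometrics) are filled by :mod:`stromaquant.fibers`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

from .prep import MPMImage, threshold_channel, tissue_mask

#: The seven collagen quantifiers entering the recurrence screen, in the
#: fixed reporting order used by results tables.
SCREEN_FEATURES: tuple[str, ...] = (
    "af", "i_r", "norm_intensity", "fiber_length_um",
    "fiber_width_um", "fiber_angle_deg", "coherence",
)

FEATURE_COLUMNS: tuple[str, ...] = (
    "af", "i_r", "i_g", "norm_intensity", "coherence", "fiber_width_um",
    "fiber_length_um", "fiber_straightness", "fiber_angle_deg",
)


@dataclass(frozen=True)
class FeatureVector:
    """Collagen quantifiers for one ROI; missing values are NaN."""

    af: float = math.nan
    i_r: float = math.nan
    i_g: float = math.nan
    norm_intensity: float = math.nan
    coherence: float = math.nan
    fiber_width_um: float = math.nan
    fiber_length_um: float = math.nan
    fiber_straightness: float = math.nan
    fiber_angle_deg: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def merged(self, **kwargs) -> "FeatureVector":
        return replace(self, **kwargs)

    @classmethod
    def mean(cls, vectors: list["FeatureVector"]) -> "FeatureVector":
        """Field-wise arithmetic mean, ignoring missing (NaN) values.

        A field missing in every vector stays missing.
        """
        if not vectors:
            raise ValueError("cannot average an empty list of feature vectors")
        out = {}
        for f in fields(cls):
            vals = [getattr(v, f.name) for v in vectors
                    if not math.isnan(getattr(v, f.name))]
            out[f.name] = float(np.mean(vals)) if vals else math.nan
        return cls(**out)


def compute_area_fraction(shg_mask: np.ndarray, tissue: np.ndarray) -> float:
    """Fraction of tissue pixels occupied by SHG-emitting collagen."""
    shg_mask = np.asarray(shg_mask, dtype=bool)
    tissue = np.asarray(tissue, dtype=bool)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("no tissue")
    return float((shg_mask & tissue).sum() / n_tissue)


def compute_channel_intensity(channel: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of a channel over the mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(np.mean(np.asarray(channel, dtype=float)[mask]))


def compute_normalized_intensity(i_r: float, i_g: float) -> float:
    """Normalized stromal intensity ratio i_r / (i_r + i_g)."""
    if i_r < 0 or i_g < 0:
        raise ValueError("intensities must be nonnegative")
    if i_r + i_g == 0:
        raise ValueError("no signal")
    return i_r / (i_r + i_g)


@dataclass(frozen=True)
class ContentConfig:
    """Thresholding choices for content features.

    The SHG threshold is computed per image within the analysis region;
    ``fixed`` values provide a cohort-wide escape hatch.
    """

    shg_method: str = "otsu"
    shg_value: float | None = None
    tissue_method: str = "otsu"
    tissue_value: float | None = None


def compute_content_features(image: MPMImage,
                             stroma_mask: np.ndarray | None = None,
                             config: ContentConfig = ContentConfig(),
                             ) -> tuple[FeatureVector, dict[str, np.ndarray]]:
    """Threshold both channels and fill the content fields of a FeatureVector.

    The SHG channel is thresholded within the analysis region (the stroma
    mask intersected with tissue, or all tissue when no stroma mask is
    given); the green channel yields the tissue mask. If no SHG pixel
    survives thresholding — genuinely collagen-free stroma — the limit
    values ``af = 0, i_r = 0, norm_intensity = 0`` are returned rather
    than an error.

    Returns the partial feature vector and the masks used (keys
    ``tissue``, ``shg``, ``analysis``), so fiber-level analysis can reuse
    them.
    """
    tissue = tissue_mask(image.channel_g, method=config.tissue_method,
                         value=config.tissue_value)
    analysis = tissue if stroma_mask is None else (tissue & np.asarray(stroma_mask, bool))
    if not analysis.any():
        raise ValueError("no tissue in the analysis region")

    try:
        shg_fg = threshold_channel(image.channel_r, method=config.shg_method,
                                   value=config.shg_value, mask=analysis)
    except ValueError:
        shg_fg = np.zeros_like(analysis)  # constant (typically zero) SHG channel
    shg_fg &= analysis

    i_g = compute_channel_intensity(image.channel_g, analysis)
    if shg_fg.any():
        af = compute_area_fraction(shg_fg, analysis)
        i_r = compute_channel_intensity(image.channel_r, shg_fg)
        norm = compute_normalized_intensity(i_r, i_g)
    else:
        af, i_r, norm = 0.0, 0.0, 0.0
    fv = FeatureVector(af=af, i_r=i_r, i_g=i_g, norm_intensity=norm)
    return fv, {"tissue": tissue, "shg": shg_fg, "analysis": analysis}
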