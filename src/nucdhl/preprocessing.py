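"""Image conditioning chain and tabular standard scaling.

The chain mirrors how real lamin micrographs are conditioned before entering
the deep pipeline: an HSV-value segmentation mask controlled by a sensitivity
factor, morphological closing with an elliptical (discrete-disk) structuring
element, unsharp-mask sharpening via a Gaussian blur, grayscale conversion,
background zeroing outside the mask, and min-max normalisation of the
foreground — the background carries no information afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing, gaussian_filter
from skimage.morphology import disk
from sklearn.preprocessing import StandardScaler

from .exceptions import ArgumentError, ScalingError, SegmentationError, ShapeError
from .types import NucleusImage


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the conditioning chain.

    ``sensitivity`` sets the value-channel threshold at
    ``(1 - sensitivity) * V_max``: higher sensitivity keeps dimmer pixels.
    The sharpening weights form a classic unsharp mask and must sum to 1 so
    that flat regions keep their brightness. ``closing_kernel`` selects the
    structuring element shape; the elliptical (disk) kernel follows the shape
    of the nuclei, the rectangular one is exposed for ablations.
    """

    sensitivity: float = 0.5
    closing_kernel_radius: int = 2
    blur_sigma: float = 2.0
    sharpen_weight_original: float = 1.5
    sharpen_weight_blurred: float = -0.5
    closing_kernel: str = "ellipse"

    def __post_init__(self) -> None:
        if not (0.0 < self.sensitivity <= 1.0):
            raise ArgumentError(f"sensitivity must lie in (0, 1], got {self.sensitivity}")
        if self.closing_kernel_radius < 1:
            raise ArgumentError("closing_kernel_radius must be >= 1")
        if self.blur_sigma <= 0:
            raise ArgumentError("blur_sigma must be > 0")
        if abs(self.sharpen_weight_original + self.sharpen_weight_blurred - 1.0) > 1e-9:
            raise ArgumentError("sharpening weights must sum to 1 (brightness-preserving)")
        if self.closing_kernel not in ("ellipse", "rectangle"):
            raise ArgumentError("closing_kernel must be 'ellipse' or 'rectangle'")


def _structuring_element(params: PreprocessParams) -> np.ndarray:
    r = params.closing_kernel_radius
    if params.closing_kernel == "ellipse":
        return disk(r)
    return np.ones((2 * r + 1, 2 * r + 1), dtype=bool)


def build_segmentation_mask(image: NucleusImage,
                            params: PreprocessParams | None = None) -> np.ndarray:
    """Binary {0,1} nucleus mask from the HSV value channel.

    The value channel is the per-pixel maximum over channels (for a grayscale
    image, the image itself). Pixels with ``V >= (1 - sensitivity) * V_max``
    are foreground; the mask is then closed with the configured structuring
    element. An all-zero image yields an empty mask.
    """
    if params is None:
        params = PreprocessParams()
    pixels = np.asarray(image.pixels, dtype=np.float64)
    if pixels.ndim not in (2, 3):
        raise ShapeError("image must be (H, W) or (H, W, C)")
    value = pixels if pixels.ndim == 2 else pixels.max(axis=2)
    v_max = float(value.max())
    if v_max <= 0.0:
        return np.zeros(value.shape, dtype=np.uint8)
    mask = value >= (1.0 - params.sensitivity) * v_max
    mask = binary_closing(mask, structure=_structuring_element(params))
    return mask.astype(np.uint8)


def sharpen(image: NucleusImage, params: PreprocessParams | None = None) -> NucleusImage:
    """Unsharp-mask sharpening, ``w_orig * I + w_blur * blur(I)``, clipped to [0, 1]."""
    if params is None:
        params = PreprocessParams()
    pixels = np.asarray(image.pixels, dtype=np.float64)
    sigma = (params.blur_sigma, params.blur_sigma) + (0,) * (pixels.ndim - 2)
    blurred = gaussian_filter(pixels, sigma)
    out = params.sharpen_weight_original * pixels + params.sharpen_weight_blurred * blurred
    out = np.clip(out, 0.0, 1.0)
    result = replace_pixels(image, out)
    return result


def replace_pixels(image: NucleusImage, pixels: np.ndarray,
                   provenance: str | None = None) -> NucleusImage:
    """Copy of ``image`` with new pixel data (metadata preserved)."""
    return NucleusImage(pixels=pixels, pixel_size=image.pixel_size,
                        label=image.label, stain=image.stain,
                        provenance=provenance or image.provenance)


def preprocess(image: NucleusImage,
               params: PreprocessParams | None = None) -> NucleusImage:
    """Full conditioning chain: mask, sharpen, grayscale, background removal,
    foreground min-max normalisation.

    Every pixel outside the closed segmentation mask is exactly zero in the
    output; foreground intensities span [0, 1] (for non-degenerate input).
    Deterministic. Raises :class:`SegmentationError` when the mask is empty.
    """
    if params is None:
        params = PreprocessParams()
    mask = build_segmentation_mask(image, params).astype(bool)
    if not mask.any():
        raise SegmentationError("segmentation produced an empty mask; image rejected")
    sharp = sharpen(image, params)
    gray = sharp.plane().astype(np.float64).copy()
    gray[~mask] = 0.0
    fg = gray[mask]
    lo, hi = float(fg.min()), float(fg.max())
    if hi > lo:
        gray[mask] = (fg - lo) / (hi - lo)
    else:
        gray[mask] = 1.0
    return replace_pixels(image, gray.astype(np.float32), provenance="preprocessed")


@dataclass
class FittedScaler:
    """Per-column standardisation fitted on a training table only.

    Wraps scikit-learn's ``StandardScaler`` (population-SD convention) and
    remembers the column names so held-out rows can be transformed or
    inverted without leakage.
    """

    columns: list[str]
    scaler: StandardScaler

    @property
    def means(self) -> np.ndarray:
        return self.scaler.mean_

    @property
    def sds(self) -> np.ndarray:
        return self.scaler.scale_

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        values = self.scaler.transform(table[self.columns].to_numpy(dtype=float))
        return pd.DataFrame(values, columns=self.columns, index=table.index)

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        values = self.scaler.inverse_transform(table[self.columns].to_numpy(dtype=float))
        return pd.DataFrame(values, columns=self.columns, index=table.index)


def standard_scale(table: pd.DataFrame) -> tuple[pd.DataFrame, FittedScaler]:
    """Standardise every numeric column to mean 0, SD 1 (population SD).

    Returns the scaled table and the fitted scaler for held-out rows.
    Raises :class:`ScalingError` naming the first zero-variance column.
    """
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[1] == 0:
        raise ArgumentError("table has no numeric columns")
    if len(numeric) < 2:
        raise ArgumentError("need at least 2 rows to standardise")
    sds = numeric.to_numpy(dtype=float).std(axis=0)
    for col, sd in zip(numeric.columns, sds):
        if sd == 0.0:
            raise ScalingError(f"column {col!r} has zero variance")
    scaler = StandardScaler().fit(numeric.to_numpy(dtype=float))
    fitted = FittedScaler(columns=list(numeric.columns), scaler=scaler)
    return fitted.transform(numeric), fitted
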