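"""Label-preserving, on-the-fly augmentation of training images.

Each augmented sample receives one random transform per category — rotation,
isotropic zoom, width/height shift, horizontal/vertical flip — each drawn
uniformly within its configured range. Ranges default to the controlled
regime used for training the encoder: rotation up to 40 degrees, zoom and
shifts by a factor of 0.2, both mirrorings enabled. Interpolation is bilinear
and off-canvas regions are filled with 0, matching background-removed images.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import affine_transform

from .exceptions import ArgumentError
from .types import NucleusImage


@dataclass(frozen=True)
class AugmentParams:
    rotation_range: float = 40.0     # degrees, +/-
    zoom_range: float = 0.2          # zoom drawn from [1 - z, 1 + z]
    width_shift: float = 0.2         # fraction of width, +/-
    height_shift: float = 0.2        # fraction of height, +/-
    horizontal_flip: bool = True
    vertical_flip: bool = True

    def __post_init__(self) -> None:
        for name in ("rotation_range", "zoom_range", "width_shift", "height_shift"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be >= 0")
        if self.zoom_range >= 1:
            raise ArgumentError("zoom_range must be < 1")

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(rotation_range=0.0, zoom_range=0.0, width_shift=0.0,
                   height_shift=0.0, horizontal_flip=False, vertical_flip=False)


@dataclass(frozen=True)
class Transform:
    """One concrete draw of the per-category augmentation parameters."""

    rotation_deg: float = 0.0
    zoom: float = 1.0
    shift_x: float = 0.0  # pixels
    shift_y: float = 0.0  # pixels
    flip_h: bool = False
    flip_v: bool = False

    def is_identity(self) -> bool:
        return (self.rotation_deg == 0.0 and self.zoom == 1.0
                and self.shift_x == 0.0 and self.shift_y == 0.0
                and not self.flip_h and not self.flip_v)

    def as_log(self) -> dict:
        return asdict(self)


def draw_transform(shape: tuple[int, int], params: AugmentParams,
                   rng: np.random.Generator) -> Transform:
    """Draw one transform for an image of the given (height, width)."""
    h, w = shape
    return Transform(
        rotation_deg=float(rng.uniform(-params.rotation_range, params.rotation_range)),
        zoom=float(rng.uniform(1.0 - params.zoom_range, 1.0 + params.zoom_range)),
        shift_x=float(rng.uniform(-params.width_shift, params.width_shift) * w),
        shift_y=float(rng.uniform(-params.height_shift, params.height_shift) * h),
        flip_h=bool(params.horizontal_flip and rng.random() < 0.5),
        flip_v=bool(params.vertical_flip and rng.random() < 0.5),
    )


def apply_transform(plane: np.ndarray, transform: Transform) -> np.ndarray:
    """Apply one transform to a single-channel image plane.

    Identity transforms return the input bit-exactly; otherwise the flips are
    applied first and the rotation/zoom/shift are composed into a single
    bilinear resampling about the image centre with zero fill.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ArgumentError("augmentation expects a single-channel image plane")
    if transform.is_identity():
        return plane
    out = plane
    if transform.flip_h:
        out = out[:, ::-1]
    if transform.flip_v:
        out = out[::-1, :]
    alpha = math.radians(transform.rotation_deg)
    inv_zoom = 1.0 / transform.zoom
    # matrix maps output (row, col) displacements to input displacements
    matrix = inv_zoom * np.array(
        [[math.cos(alpha), -math.sin(alpha)],
         [math.sin(alpha), math.cos(alpha)]])
    center = (np.array(out.shape, dtype=float) - 1.0) / 2.0
    shift = np.array([transform.shift_y, transform.shift_x])
    offset = center - matrix @ (center + shift)
    out = affine_transform(out.astype(np.float64), matrix, offset=offset,
                           order=1, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0).astype(plane.dtype)


def augment(image: NucleusImage, params: AugmentParams,
            rng: np.random.Generator) -> tuple[NucleusImage, Transform]:
    """Augment one preprocessed image; returns the image and the drawn transform.

    The label, stain, shape and intensity range are preserved; the transform
    is returned so callers can log it per sample.
    """
    plane = image.plane()
    transform = draw_transform(plane.shape, params, rng)
    out = apply_transform(plane, transform)
    return (
        NucleusImage(pixels=out, pixel_size=image.pixel_size, label=image.label,
                     stain=image.stain, provenance=image.provenance),
        transform,
    )


def augmented_stream(images: np.ndarray, labels: np.ndarray,
                     params: AugmentParams | None = None, batch: int = 32,
                     seed: int | None = None, augment_samples: bool = True,
                     transform_log: list | None = None):
    """Infinite shuffled epoch stream of (image batch, label batch).

    ``images`` is ``(N, H, W)``; every epoch is a fresh permutation covering
    each index exactly once, so label proportions per epoch equal the source
    proportions. Augmentation applies only when ``augment_samples`` is true —
    validation/test streams use ``augment_samples=False`` and then reproduce
    the raw pixels bit-exactly. With ``transform_log`` given, one transform
    record per emitted sample is appended.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ArgumentError("augmented_stream needs a non-empty image list")
    if batch < 1:
        raise ArgumentError("batch must be >= 1")
    if params is None:
        params = AugmentParams()
    # separate shuffle and transform streams: disabling augmentation then
    # reproduces the raw stream bit-exactly
    shuffle_ss, transform_ss = np.random.SeedSequence(seed).spawn(2)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    rng = np.random.default_rng(transform_ss)
    n = len(images)
    while True:
        order = shuffle_rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            if augment_samples:
                out = np.empty_like(images[idx])
                for k, i in enumerate(idx):
                    transform = draw_transform(images[i].shape, params, rng)
                    out[k] = apply_transform(images[i], transform)
                    if transform_log is not None:
                        transform_log.append(transform.as_log())
                yield out, labels[idx]
            else:
                yield images[idx], labels[idx]


def steps_per_epoch(n_samples: int, batch: int) -> int:
    return math.ceil(n_samples / batch)
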