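"""Core domain types.

The package models every nucleus as an ellipse with semi-axes ``a >= b``.
All geometric quantities are carried in micrometres (areas in square
micrometres, curvatures in inverse micrometres); images additionally carry a
``pixel_size`` in micrometres per pixel so raster and physical coordinates can
be converted without unit strings in the tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import ArgumentError

#: Closed vocabulary of class labels. Normal is encoded 0 and cancer 1 in every
#: numeric context (confusion matrices, probability outputs).
LABELS = ("normal", "cancer")

#: Closed vocabulary of stain channels (nuclear lamina markers).
STAINS = ("laminA", "laminB")

#: The eight ellipse-based shape descriptors, in canonical column order.
DESCRIPTORS = (
    "area",
    "perimeter",
    "circularity",
    "eccentricity",
    "foci_distance",
    "loop_length",
    "max_curvature",
    "normalized_curvature",
)


def _check_label(label: str) -> None:
    if label not in LABELS:
        raise ArgumentError(f"unknown label {label!r}; expected one of {LABELS}")


def _check_stain(stain: str) -> None:
    if stain not in STAINS:
        raise ArgumentError(f"unknown stain {stain!r}; expected one of {STAINS}")


def label_code(label: str) -> int:
    """Numeric class code: normal -> 0, cancer -> 1."""
    _check_label(label)
    return LABELS.index(label)


@dataclass(frozen=True)
class EllipseNucleus:
    """Ground-truth or fitted ellipse geometry of a single nucleus.

    Parameters
    ----------
    a, b
        Semi-major and semi-minor axes in micrometres; ``a >= b > 0``.
    cx, cy
        Centre coordinates in micrometres.
    theta
        Orientation of the major axis in radians, normalised to ``[0, pi)``.
    label, stain
        Class label and stain channel from the closed vocabularies.
    """

    a: float
    b: float
    cx: float = 0.0
    cy: float = 0.0
    theta: float = 0.0
    label: str = "normal"
    stain: str = "laminA"

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.a >= self.b):
            raise ArgumentError(
                f"degenerate ellipse: need a >= b > 0, got a={self.a}, b={self.b}"
            )
        if not (0.0 <= self.theta < math.pi):
            object.__setattr__(self, "theta", self.theta % math.pi)
        _check_label(self.label)
        _check_stain(self.stain)

    @property
    def focal_half_distance(self) -> float:
        """c = sqrt(a^2 - b^2), distance from the centre to either focus."""
        return math.sqrt(self.a**2 - self.b**2)


@dataclass(frozen=True)
class GroupStats:
    """Population statistics of one descriptor for one (group, stain) cell.

    ``n`` is the sample size inferred from the printed statistics via
    ``SEM = SD / sqrt(n)``, i.e. ``n = round((sd / sem)^2)``. When constructed
    from data (see :func:`nucdhl.morphometry.population_stats`) the observed
    ``n`` is stored directly.
    """

    parameter: str
    group: str
    stain: str
    mean: float
    sem: float
    sd: float
    n: int = field(default=0)

    def __post_init__(self) -> None:
        if self.sem <= 0 or self.sd <= 0:
            raise ArgumentError("GroupStats requires sem > 0 and sd > 0")
        _check_label(self.group)
        _check_stain(self.stain)
        if self.n == 0:
            object.__setattr__(self, "n", int(round((self.sd / self.sem) ** 2)))
        if self.n < 1:
            raise ArgumentError("GroupStats requires n >= 1")


@dataclass(frozen=True)
class MorphometricRecord:
    """The eight shape descriptors of one nucleus plus its label and stain."""

    area: float
    perimeter: float
    circularity: float
    eccentricity: float
    foci_distance: float
    loop_length: float
    max_curvature: float
    normalized_curvature: float
    label: str = "normal"
    stain: str = "laminA"

    def __post_init__(self) -> None:
        _check_label(self.label)
        _check_stain(self.stain)
        for name in ("area", "perimeter", "foci_distance", "loop_length", "max_curvature"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be non-negative")
        if not (0.0 < self.circularity <= 1.0 + 1e-9):
            raise ArgumentError(f"circularity must lie in (0, 1], got {self.circularity}")
        if not (0.0 <= self.eccentricity < 1.0):
            raise ArgumentError(f"eccentricity must lie in [0, 1), got {self.eccentricity}")

    def values(self) -> tuple[float, ...]:
        """Descriptor values in canonical :data:`DESCRIPTORS` order."""
        return tuple(getattr(self, name) for name in DESCRIPTORS)


@dataclass(frozen=True)
class RenderStyle:
    """Appearance parameters of the synthetic confocal renderer.

    The renderer emulates the look of lamin-immunostained nuclei: a bright
    peripheral rim (the nuclear lamina) of ``rim_width`` micrometres over a
    dimmer nucleoplasmic fill (emulating a DNA counterstain such as propidium
    iodide), blurred by a Gaussian point-spread function, with additive sensor
    noise and a linear background illumination gradient standing in for the
    non-uniform lighting of real micrographs.
    """

    image_size: int = 64
    pixel_size: float = 0.35
    rim_width: float = 0.8
    rim_intensity: float = 0.9
    fill_intensity: float = 0.5
    psf_sigma: float = 1.0
    noise_sd: float = 0.02
    background_gradient_amplitude: float = 0.05

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ArgumentError("image_size must be >= 32")
        for name in ("rim_intensity", "fill_intensity", "noise_sd",
                     "background_gradient_amplitude"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ArgumentError(f"{name} must lie in [0, 1], got {v}")
        if self.psf_sigma < 0:
            raise ArgumentError("psf_sigma must be >= 0")
        if self.pixel_size <= 0:
            raise ArgumentError("pixel_size must be > 0")
        if self.rim_width <= 0:
            raise ArgumentError("rim_width must be > 0")


@dataclass
class NucleusImage:
    """A single-nucleus pixel grid with physical-size metadata.

    ``pixels`` is ``(H, W)`` for single-channel images or ``(H, W, C)`` for
    multi-channel ones, with intensities in ``[0, 1]``. ``provenance`` is
    ``"raw"`` straight out of the renderer/reader and ``"preprocessed"`` after
    the conditioning chain (which always yields a single channel).
    """

    pixels: np.ndarray
    pixel_size: float
    label: Optional[str] = None
    stain: Optional[str] = None
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ArgumentError("pixels must be (H, W) or (H, W, C)")
        if self.width < 32 or self.height < 32:
            raise ArgumentError("images must be at least 32 x 32 pixels")
        if self.label is not None:
            _check_label(self.label)
        if self.stain is not None:
            _check_stain(self.stain)
        if self.provenance not in ("raw", "preprocessed"):
            raise ArgumentError(f"unknown provenance {self.provenance!r}")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else int(self.pixels.shape[2])

    def plane(self) -> np.ndarray:
        """Channel-mean 2-D view (fluorescence channels are averaged, not
        luma-weighted, since they are not RGB photography)."""
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels.mean(axis=2)


@dataclass(frozen=True)
class ProbPair:
    """Per-sample cancer probabilities from the two pipelines."""

    p_ada: float
    p_deep: float
    sample_id: object = None

    def __post_init__(self) -> None:
        for name in ("p_ada", "p_deep"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ArgumentError(f"{name} must be a finite probability in [0, 1], got {v}")


@dataclass(frozen=True)
class Decision:
    """Fused verdict for one sample: the larger of the two pipeline scores."""

    fused_probability: float
    predicted_label: str
    source: str

    def __post_init__(self) -> None:
        _check_label(self.predicted_label)
        if self.source not in ("pipeline1", "pipeline2"):
            raise ArgumentError(f"unknown source {self.source!r}")
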