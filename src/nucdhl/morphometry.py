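"""Ellipse-based nuclear shape descriptors.

Each nucleus is modelled as an ellipse with semi-major axis ``a``, semi-minor
axis ``b`` and focal half-distance ``c = sqrt(a^2 - b^2)``. The eight
descriptors are:

========================  =====================================================
area                      ``pi * a * b``
perimeter                 Ramanujan's second approximation (relative error
                          below 1e-4 for aspect ratios up to ~10)
circularity               ``4 * pi * area / perimeter^2`` (1 for a circle)
eccentricity              ``c / a``
foci_distance             ``2 * c`` (distance between the two foci)
loop_length               ``2a + 2c`` — the taut string of the gardener's
                          (string) construction of the ellipse; grows with
                          both size and focal distance
max_curvature             ``a / b^2`` — curvature at the major-axis vertices,
                          the sharpest point of the boundary
normalized_curvature      ``max_curvature * sqrt(a * b)`` — curvature relative
                          to the equal-area circle (radius ``sqrt(area/pi)``),
                          dimensionless
========================  =====================================================

The loop-length and curvature conventions are this package's documented
defaults; each formula is isolated in its own function so an alternative
convention can be swapped in one place.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict

import numpy as np
import pandas as pd
from skimage import measure

from .exceptions import ArgumentError, EmptyInputError
from .types import DESCRIPTORS, EllipseNucleus, GroupStats, MorphometricRecord

logger = logging.getLogger(__name__)

#: CSV header of the morphometric table, shared with the synthetic generator.
TABLE_COLUMNS = ["id", "stain", "label", *DESCRIPTORS]


def ramanujan_perimeter(a, b):
    """Ellipse perimeter by Ramanujan's second approximation.

    ``P = pi (a+b) (1 + 3h / (10 + sqrt(4 - 3h)))`` with
    ``h = ((a-b)/(a+b))^2``. Accepts scalars or arrays.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))


def loop_length(a, b):
    """String-construction loop of the ellipse, ``2a + 2c``."""
    c = np.sqrt(np.asarray(a, dtype=float) ** 2 - np.asarray(b, dtype=float) ** 2)
    return 2.0 * np.asarray(a, dtype=float) + 2.0 * c


def max_curvature(a, b):
    """Boundary curvature at the major-axis vertex, ``a / b^2``."""
    return np.asarray(a, dtype=float) / np.asarray(b, dtype=float) ** 2


def normalized_curvature(a, b):
    """Maximum curvature scaled by the equal-area-circle radius ``sqrt(ab)``."""
    return max_curvature(a, b) * np.sqrt(np.asarray(a, float) * np.asarray(b, float))


def compute_morphometrics(geom: EllipseNucleus) -> MorphometricRecord:
    """Compute all eight descriptors analytically from ellipse geometry."""
    a, b = geom.a, geom.b
    if not (b > 0 and a >= b):
        raise ArgumentError(f"degenerate ellipse: a={a}, b={b}")
    c = math.sqrt(a * a - b * b)
    area = math.pi * a * b
    perimeter = float(ramanujan_perimeter(a, b))
    return MorphometricRecord(
        area=area,
        perimeter=perimeter,
        circularity=min(4.0 * math.pi * area / perimeter**2, 1.0),
        eccentricity=c / a,
        foci_distance=2.0 * c,
        loop_length=2.0 * a + 2.0 * c,
        max_curvature=a / b**2,
        normalized_curvature=(a / b**2) * math.sqrt(a * b),
        label=geom.label,
        stain=geom.stain,
    )


def fit_ellipse(mask: np.ndarray, pixel_size: float, min_pixels: int = 16,
                label: str = "normal", stain: str = "laminA") -> EllipseNucleus:
    """Moment-equivalent ellipse of the largest foreground region of a mask.

    The centre comes from the first image moments and the axes/orientation
    from the second central moments, converted to micrometres via
    ``pixel_size``. Raises :class:`EmptyInputError` on an empty mask and
    :class:`ArgumentError` when the largest region has fewer than
    ``min_pixels`` pixels.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ArgumentError("mask must be a 2-D binary grid")
    if not mask.any():
        raise EmptyInputError("mask contains no foreground pixels")
    labelled = measure.label(mask)
    regions = measure.regionprops(labelled)
    region = max(regions, key=lambda r: r.area)
    if region.area < min_pixels:
        raise ArgumentError(
            f"largest region has {region.area} px, below the minimum of {min_pixels}"
        )
    a_px = region.axis_major_length / 2.0
    b_px = region.axis_minor_length / 2.0
    # regionprops orientation is the angle between the major axis and the
    # vertical (row) axis in (-pi/2, pi/2]; convert to the x-axis convention.
    theta = (math.pi / 2.0 - region.orientation) % math.pi
    cy, cx = region.centroid
    b_px = max(b_px, 1e-6)
    a_px = max(a_px, b_px)
    return EllipseNucleus(
        a=a_px * pixel_size, b=b_px * pixel_size,
        cx=cx * pixel_size, cy=cy * pixel_size,
        theta=theta, label=label, stain=stain,
    )


def population_stats(records: list[MorphometricRecord]) -> list[GroupStats]:
    """Per-descriptor, per-(group, stain) mean, SD (n-1), SEM and n.

    Cells with fewer than two records are omitted with a warning (SD is
    undefined there).
    """
    cells: dict[tuple[str, str], list[MorphometricRecord]] = defaultdict(list)
    for rec in records:
        cells[(rec.label, rec.stain)].append(rec)
    out: list[GroupStats] = []
    for (group, stain), recs in sorted(cells.items()):
        if len(recs) < 2:
            logger.warning(
                "omitting (%s, %s): %d record(s), need >= 2", group, stain, len(recs)
            )
            continue
        values = np.array([rec.values() for rec in recs], dtype=float)
        n = len(recs)
        sds = values.std(axis=0, ddof=1)
        means = values.mean(axis=0)
        for j, parameter in enumerate(DESCRIPTORS):
            sd = float(sds[j])
            if sd == 0.0:
                logger.warning("omitting (%s, %s, %s): zero variance", parameter, group, stain)
                continue
            out.append(GroupStats(parameter=parameter, group=group, stain=stain,
                                  mean=float(means[j]), sem=sd / math.sqrt(n),
                                  sd=sd, n=n))
    return out


def stats_to_frame(stats: list[GroupStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.parameter, s.group, s.stain, s.mean, s.sem, s.sd, s.n) for s in stats],
        columns=["parameter", "group", "stain", "mean", "sem", "sd", "n"],
    )


def records_to_frame(records: list[MorphometricRecord],
                     ids: list | None = None) -> pd.DataFrame:
    """Morphometric records as a DataFrame in the canonical table layout."""
    if ids is None:
        ids = list(range(len(records)))
    rows = [
        (i, rec.stain, rec.label, *rec.values()) for i, rec in zip(ids, records)
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[MorphometricRecord]:
    records = []
    for _, row in frame.iterrows():
        records.append(MorphometricRecord(
            label=row["label"], stain=row["stain"],
            **{name: float(row[name]) for name in DESCRIPTORS},
        ))
    return records


def write_table(records: list[MorphometricRecord], path, ids=None) -> None:
    records_to_frame(records, ids).to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ArgumentError(f"morphometric table missing columns: {sorted(missing)}")
    return frame
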