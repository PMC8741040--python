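"""Synthetic nucleus generator calibrated to published population statistics.

No image data were deposited with the source study, so this module stands in
for them: it draws ellipse geometries whose population moments reproduce the
printed group statistics (see :mod:`nucdhl.calibration`) and renders them as
single-nucleus fluorescence micrographs with the appearance of lamin-stained
confocal images (peripheral rim + nucleoplasmic fill, point-spread blur,
sensor noise, uneven illumination).

Sampling model
--------------
An ellipse has only two shape degrees of freedom, so the generator samples
exactly two coordinates per nucleus and derives everything else analytically,
preserving the geometric correlations among the eight descriptors:

* area ``A`` ~ log-normal, moment-matched to the printed (mean, SD);
* eccentricity ``e`` ~ normal truncated to [0, 1), moment-matched to the
  printed (mean, SD);
* ``(A, e)`` are joined by a Gaussian copula whose correlation is solved
  (deterministically, by quadrature) so that the implied mean perimeter
  equals the printed perimeter mean for that (group, stain) — perimeter is
  the third printed moment the populations are calibrated against.

Semi-axes follow as ``a = sqrt(A / (pi * sqrt(1 - e^2)))``, ``b = A/(pi a)``.
Orientation is uniform on [0, pi) and the centre is jittered uniformly.
Remaining descriptors (loop length, curvatures, foci distance, circularity)
are deterministic functions of (a, b); their generated means are reported but
not independently calibrated.
"""

from __future__ import annotations

import logging
import math
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter

from . import morphometry
from .calibration import get_stats, inferred_population_size
from .exceptions import ArgumentError
from .types import EllipseNucleus, MorphometricRecord, NucleusImage, RenderStyle

logger = logging.getLogger(__name__)

#: Upper truncation bound for eccentricity (must stay strictly below 1).
ECC_MAX = 0.999

#: Magnitude cap on the area-eccentricity copula correlation. An uncapped
#: solve can run to +/-1, collapsing (area, eccentricity) onto a curve — a
#: degenerate population no real tissue shows, which would let classifiers
#: separate the groups by manifold membership instead of morphology. 0.9
#: keeps the coupling non-degenerate; the residual perimeter offsets stay
#: well inside the printed 3-SEM bands.
RHO_MAX = 0.9

#: Centre jitter half-range in micrometres.
CENTER_JITTER = 1.5

#: Fraction of the half-field the ellipse (centre offset + semi-major axis)
#: may occupy before the renderer rescales to fit.
FIT_MARGIN = 0.95


# ---------------------------------------------------------------------------
# moment matching

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given mean and SD."""
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


@lru_cache(maxsize=None)
def _truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """(loc, scale) of the [0, ECC_MAX]-truncated normal matching mean and SD."""

    def residual(p):
        loc, scale = p
        scale = abs(scale)
        a, b = (0.0 - loc) / scale, (ECC_MAX - loc) / scale
        d = stats.truncnorm(a, b, loc=loc, scale=scale)
        return [d.mean() - mean, d.std() - sd]

    sol, info, ier, msg = optimize.fsolve(residual, [mean, sd], full_output=True)
    if ier != 1:  # pragma: no cover - all calibration cells converge
        raise ArgumentError(f"truncated-normal moment match failed: {msg}")
    return float(sol[0]), float(abs(sol[1]))


def _sample_quantiles(group: str, stain: str, u_area: np.ndarray,
                      u_ecc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map uniform quantiles to (area, eccentricity) via the matched marginals."""
    area_stats = get_stats("area", group, stain)
    ecc_stats = get_stats("eccentricity", group, stain)
    mu, sigma = _lognormal_params(area_stats.mean, area_stats.sd)
    loc, scale = _truncnorm_params(ecc_stats.mean, ecc_stats.sd)
    eps = 1e-14  # keep quantiles strictly inside (0, 1) for the ppf maps
    u_area = np.clip(u_area, eps, 1.0 - eps)
    u_ecc = np.clip(u_ecc, eps, 1.0 - eps)
    area = np.exp(mu + sigma * stats.norm.ppf(u_area))
    lo, hi = (0.0 - loc) / scale, (ECC_MAX - loc) / scale
    ecc = stats.truncnorm(lo, hi, loc=loc, scale=scale).ppf(u_ecc)
    return area, np.clip(ecc, 0.0, ECC_MAX)


def _mean_perimeter(group: str, stain: str, rho: float, order: int = 48) -> float:
    """E[perimeter] under the copula model, by Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(order)
    weights = weights / math.sqrt(2.0 * math.pi)
    z1 = nodes[:, None]
    z2 = nodes[None, :]
    z_ecc = rho * z1 + math.sqrt(max(1.0 - rho * rho, 0.0)) * z2
    u1 = stats.norm.cdf(np.broadcast_to(z1, z_ecc.shape).ravel())
    u2 = stats.norm.cdf(z_ecc.ravel())
    area, ecc = _sample_quantiles(group, stain, u1, u2)
    a = np.sqrt(area / (np.pi * np.sqrt(1.0 - ecc**2)))
    b = area / (np.pi * a)
    per = morphometry.ramanujan_perimeter(a, b).reshape(z_ecc.shape)
    w2d = weights[:, None] * weights[None, :]
    return float(np.sum(w2d * per))


@lru_cache(maxsize=None)
def copula_correlation(group: str, stain: str) -> float:
    """Area-eccentricity copula correlation matching the printed perimeter mean.

    Solved once per (group, stain) with Brent's method on the quadrature
    estimate of E[perimeter]; clamped to +/-RHO_MAX when the printed mean is
    outside the achievable range (the residual offset is then well inside the
    printed 3-SEM band).
    """
    target = get_stats("perimeter", group, stain).mean

    def f(rho: float) -> float:
        return _mean_perimeter(group, stain, rho) - target

    lo, hi = -RHO_MAX, RHO_MAX
    flo, fhi = f(lo), f(hi)
    if flo >= 0.0:
        logger.info("copula correlation clamped at %.3f for (%s, %s); "
                    "residual perimeter offset %.3f um", lo, group, stain, flo)
        return lo
    if fhi <= 0.0:
        logger.info("copula correlation clamped at %.3f for (%s, %s); "
                    "residual perimeter offset %.3f um", hi, group, stain, fhi)
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-4))


# ---------------------------------------------------------------------------
# population and image generation

def generate_population(group: str, stain: str, n: int, seed: int | None = None,
                        rng: np.random.Generator | None = None) -> list[EllipseNucleus]:
    """Draw ``n`` calibrated ellipse nuclei for one (group, stain) population.

    ``group``/``stain`` must exist in the calibration table; ``n`` may be 0.
    Either a ``seed`` or an existing ``rng`` may be supplied; the same seed
    always reproduces the same population.
    """
    get_stats("area", group, stain)  # validates group/stain (ConfigurationError)
    if n < 0:
        raise ArgumentError(f"n must be >= 0, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n == 0:
        return []
    rho = copula_correlation(group, stain)
    z = rng.standard_normal((n, 2))
    z_ecc = rho * z[:, 0] + math.sqrt(1.0 - rho * rho) * z[:, 1]
    area, ecc = _sample_quantiles(group, stain,
                                  stats.norm.cdf(z[:, 0]), stats.norm.cdf(z_ecc))
    a = np.sqrt(area / (np.pi * np.sqrt(1.0 - ecc**2)))
    b = area / (np.pi * a)
    theta = rng.uniform(0.0, math.pi, size=n)
    centers = rng.uniform(-CENTER_JITTER, CENTER_JITTER, size=(n, 2))
    return [
        EllipseNucleus(a=float(a[i]), b=float(b[i]),
                       cx=float(centers[i, 0]), cy=float(centers[i, 1]),
                       theta=float(theta[i]), label=group, stain=stain)
        for i in range(n)
    ]


def render_nucleus(geom: EllipseNucleus, style: RenderStyle,
                   seed: int | None = None) -> NucleusImage:
    """Render one nucleus as a two-channel micrograph.

    Channel 0 is the nucleoplasmic fill (DNA counterstain), channel 1 the
    peripheral lamin rim. Both are blurred by a Gaussian point-spread
    function, overlaid with additive Gaussian noise and a random linear
    illumination gradient. Deterministic for a fixed seed. If the ellipse
    (centre offset included) does not fit in the frame, the effective pixel
    size is enlarged so it does; the returned image records it.
    """
    if geom.b <= 0:  # defensive; EllipseNucleus enforces this already
        raise ArgumentError("degenerate geometry: b must be > 0")
    rng = np.random.default_rng(seed)
    size = style.image_size
    half_field = size * style.pixel_size / 2.0
    required = math.hypot(geom.cx, geom.cy) + geom.a
    pixel_size = style.pixel_size
    if required > FIT_MARGIN * half_field:
        pixel_size = style.pixel_size * required / (FIT_MARGIN * half_field)
        half_field = size * pixel_size / 2.0

    coords = (np.arange(size) + 0.5) * pixel_size - half_field
    x, y = np.meshgrid(coords, coords)
    ct, st = math.cos(geom.theta), math.sin(geom.theta)
    xr = ct * (x - geom.cx) + st * (y - geom.cy)
    yr = -st * (x - geom.cx) + ct * (y - geom.cy)

    inside = (xr / geom.a) ** 2 + (yr / geom.b) ** 2 <= 1.0
    a_in = max(geom.a - style.rim_width, 0.1 * geom.a)
    b_in = max(geom.b - style.rim_width, 0.1 * geom.b)
    inner = (xr / a_in) ** 2 + (yr / b_in) ** 2 <= 1.0
    rim = inside & ~inner

    fill_ch = style.fill_intensity * inside.astype(np.float64)
    rim_ch = style.rim_intensity * rim.astype(np.float64)
    channels = []
    phi = rng.uniform(0.0, 2.0 * math.pi)
    grid = np.linspace(-1.0, 1.0, size)
    gx, gy = np.meshgrid(grid, grid)
    gradient = style.background_gradient_amplitude * (
        (math.cos(phi) * gx + math.sin(phi) * gy) + 1.0) / 2.0
    for ch in (fill_ch, rim_ch):
        if style.psf_sigma > 0:
            ch = gaussian_filter(ch, style.psf_sigma)
        ch = ch + gradient
        if style.noise_sd > 0:
            ch = ch + rng.normal(0.0, style.noise_sd, size=ch.shape)
        channels.append(np.clip(ch, 0.0, 1.0))
    pixels = np.stack(channels, axis=-1).astype(np.float32)
    return NucleusImage(pixels=pixels, pixel_size=pixel_size,
                        label=geom.label, stain=geom.stain, provenance="raw")


def generate_dataset(n_per_group: int, stain: str,
                     style: RenderStyle | None = None, seed: int | None = None,
                     out_dir=None):
    """Generate a balanced labelled dataset of images, records and geometries.

    Returns ``(images, table, truths)`` — three index-aligned lists with
    normal nuclei first, then cancer. Morphometric records are computed
    analytically from the ground-truth ellipses. One master seed fans out to
    per-population and per-nucleus rendering substreams, so the dataset is
    reproducible even if rendering is parallelised. With ``out_dir`` set, the
    dataset is also written to disk (see :func:`write_dataset`).
    """
    if n_per_group < 1:
        raise ArgumentError(f"n_per_group must be >= 1, got {n_per_group}")
    if style is None:
        style = RenderStyle()
    master = np.random.SeedSequence(seed)
    ss_normal, ss_cancer, ss_render = master.spawn(3)
    truths: list[EllipseNucleus] = []
    truths += generate_population("normal", stain, n_per_group,
                                  rng=np.random.default_rng(ss_normal))
    truths += generate_population("cancer", stain, n_per_group,
                                  rng=np.random.default_rng(ss_cancer))
    table: list[MorphometricRecord] = [morphometry.compute_morphometrics(g)
                                       for g in truths]
    render_seeds = [int(child.generate_state(1)[0])
                    for child in ss_render.spawn(len(truths))]
    images = [render_nucleus(g, style, s) for g, s in zip(truths, render_seeds)]
    if out_dir is not None:
        write_dataset(out_dir, images, table, truths)
    return images, table, truths


def default_study_dataset(stain: str = "laminA", style: RenderStyle | None = None,
                          seed: int | None = None):
    """Dataset at the inferred study sizes for each group (e.g. 338 normal and
    393 cancer nuclei for lamin A), without rendered images.

    Returns ``(table, truths)``; use :func:`generate_dataset` when images are
    needed (that path keeps the groups balanced instead).
    """
    master = np.random.SeedSequence(seed)
    truths: list[EllipseNucleus] = []
    for group, child in zip(("normal", "cancer"), master.spawn(2)):
        n = inferred_population_size(group, stain)
        truths += generate_population(group, stain, n, rng=np.random.default_rng(child))
    table = [morphometry.compute_morphometrics(g) for g in truths]
    return table, truths


# ---------------------------------------------------------------------------
# disk output

def write_dataset(out_dir, images, table, truths) -> None:
    """Write images (16-bit TIFF + 8-bit PNG), the morphometric table and the
    ground-truth geometry CSV under ``out_dir``.

    Filenames follow ``{stain}_{label}_{index}.tif`` / ``.png``.
    Raises ``OSError`` with the offending path on I/O failure.
    """
    import imageio.v3 as iio
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for idx, img in enumerate(images):
        stem = f"{img.stain}_{img.label}_{idx}"
        arr16 = np.clip(np.asarray(img.pixels, dtype=np.float64), 0, 1)
        # TIFF as (C, H, W) planes, 16-bit
        planes = (np.moveaxis(np.atleast_3d(arr16), -1, 0) * 65535).astype(np.uint16)
        tifffile.imwrite(out_dir / f"{stem}.tif", planes,
                         metadata={"pixel_size_um": img.pixel_size,
                                   "label": img.label, "stain": img.stain})
        png8 = (img.plane() * 255).astype(np.uint8)
        iio.imwrite(out_dir / f"{stem}.png", png8)
    morphometry.write_table(table, out_dir / "morphometrics.csv")
    import pandas as pd

    pd.DataFrame(
        [(i, g.a, g.b, g.cx, g.cy, g.theta) for i, g in enumerate(truths)],
        columns=["id", "a", "b", "cx", "cy", "theta"],
    ).to_csv(out_dir / "truths.csv", index=False)


def read_image(path, pixel_size: float = 1.0, label=None, stain=None) -> NucleusImage:
    """Load a PNG/TIFF micrograph as a raw :class:`NucleusImage` in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path).astype(np.float64)
        if arr.ndim == 3 and arr.shape[0] <= 4:  # (C, H, W) -> (H, W, C)
            arr = np.moveaxis(arr, 0, -1)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path).astype(np.float64)
    peak = arr.max()
    if peak > 1.0:
        denom = 255.0 if peak <= 255 else 65535.0
        arr = arr / denom
    return NucleusImage(pixels=arr, pixel_size=pixel_size, label=label,
                        stain=stain, provenance="raw")
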