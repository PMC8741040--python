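"""Built-in calibration table of published population statistics.

The synthetic-nucleus generator is calibrated against the group statistics
(mean, standard error of the mean, standard deviation) reported for each of
the eight shape descriptors in normal vs ovarian-cancer nuclei, separately for
lamin A- and lamin B-stained tissue. The source study deposited no images, so
these printed moments are the only quantitative anchor available; they are
reproduced here verbatim.

Sample sizes are not printed but follow from ``SEM = SD / sqrt(n)``:
``n = round((SD / SEM)^2)``. The area rows give ~338 normal and ~393 cancer
nuclei for lamin A, which the generator uses as default population sizes.

Note on data fidelity: the lamin-B normal circularity row carries an SD of
0.8024 as printed, which is not physically consistent with a mean of 0.9309
for a quantity bounded by 1 (plausibly a misprint of 0.08024). The value is
stored verbatim; it is never used for sampling (only area and eccentricity
rows parameterise the generator) nor for population-size inference.
"""

from __future__ import annotations

from .exceptions import ConfigurationError
from .types import DESCRIPTORS, GroupStats

# parameter -> stain -> group -> (mean, sem, sd)
_PRINTED: dict[str, dict[str, dict[str, tuple[float, float, float]]]] = {
    "perimeter": {
        "laminA": {"normal": (17.82, 0.3032, 5.574), "cancer": (27.59, 0.333, 6.626)},
        "laminB": {"normal": (16.11, 0.1259, 3.352), "cancer": (26.21, 0.3628, 7.814)},
    },
    "area": {
        "laminA": {"normal": (23.47, 0.7129, 13.11), "cancer": (51.62, 1.153, 22.86)},
        "laminB": {"normal": (19.94, 0.316, 8.414), "cancer": (49.31, 1.234, 26.35)},
    },
    "circularity": {
        "laminA": {"normal": (0.8796, 0.005994, 0.1285), "cancer": (0.8452, 0.006767, 0.1347)},
        "laminB": {"normal": (0.9309, 0.003013, 0.8024), "cancer": (0.8974, 0.005269, 0.1135)},
    },
    "eccentricity": {
        "laminA": {"normal": (0.7067, 0.01169, 0.2144), "cancer": (0.7885, 0.008241, 0.164)},
        "laminB": {"normal": (0.6348, 0.008105, 0.2147), "cancer": (0.7076, 0.008841, 0.19)},
    },
    "foci_distance": {
        "laminA": {"normal": (5.204, 0.1648, 3.03), "cancer": (8.942, 0.1729, 3.441)},
        "laminB": {"normal": (3.934, 0.07391, 1.968), "cancer": (7.414, 0.1738, 3.744)},
    },
    "loop_length": {
        "laminA": {"normal": (12.17, 0.3004, 5.523), "cancer": (20.01, 0.3152, 6.282)},
        "laminB": {"normal": (9.869, 0.1275, 3.396), "cancer": (17.5, 0.3255, 7.011)},
    },
    "max_curvature": {
        "laminA": {"normal": (1.1015, 0.03876, 0.7105), "cancer": (0.7776, 0.02854, 0.5651)},
        "laminB": {"normal": (0.797, 0.01755, 0.4672), "cancer": (0.6361, 0.0222, 0.4782)},
    },
    "normalized_curvature": {
        "laminA": {"normal": (0.5354, 0.01359, 0.2496), "cancer": (0.4402, 0.01048, 0.2086)},
        "laminB": {"normal": (0.6323, 0.008435, 0.2246), "cancer": (0.5489, 0.01401, 0.2243)},
    },
}


def get_stats(parameter: str, group: str, stain: str) -> GroupStats:
    """Return the printed :class:`~nucdhl.types.GroupStats` for one cell.

    Raises :class:`~nucdhl.exceptions.ConfigurationError` for an unknown
    (parameter, group, stain) combination.
    """
    try:
        mean, sem, sd = _PRINTED[parameter][stain][group]
    except KeyError as exc:
        raise ConfigurationError(
            f"no calibration entry for parameter={parameter!r}, group={group!r}, "
            f"stain={stain!r}"
        ) from exc
    return GroupStats(parameter=parameter, group=group, stain=stain,
                      mean=mean, sem=sem, sd=sd)


def calibration_table() -> list[GroupStats]:
    """The full built-in table as a flat list (8 descriptors x 2 stains x 2 groups)."""
    return [
        get_stats(parameter, group, stain)
        for parameter in DESCRIPTORS
        for stain in ("laminA", "laminB")
        for group in ("normal", "cancer")
    ]


def inferred_population_size(group: str, stain: str) -> int:
    """Default study-size of a (group, stain) population.

    Inferred from the area row as ``round((SD/SEM)^2)``: 338 normal / 393
    cancer for lamin A.
    """
    return get_stats("area", group, stain).n


def percent_shift(parameter: str, stain: str) -> float:
    """Percent change of a printed descriptor mean from normal to cancer.

    ``100 * (mean_cancer - mean_normal) / mean_normal``; e.g. the lamin-A
    eccentricity means 0.7067 -> 0.7885 give a shift of about 11.6%, the
    "around 12%" eccentricity shift reported for cancer nuclei.
    """
    normal = get_stats(parameter, "normal", stain).mean
    cancer = get_stats(parameter, "cancer", stain).mean
    return 100.0 * (cancer - normal) / normal
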