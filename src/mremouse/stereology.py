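"""Stereological cell-count estimators and a synthetic count generator.

Three estimators cover the study's quantification arithmetic:

* ``series_total`` scales an exhaustive count on a 1-in-k section series to
  the whole brain (counts on a 1-in-12 series are multiplied by 12);
* ``double_label_absolute`` converts a double-label proportion measured on
  a fixed sample (50 BrdU-positive cells) into an absolute number via the
  marker's total estimate;
* ``fractionator_estimate`` is the optical-fractionator total:
  N = sum_Q / (ssf * asf * hsf), i.e. the disector count divided by the
  section, area and height sampling fractions.

Counts are simulated as negative-binomial (overdispersed) draws around
specified cell means, matching the animal-to-animal variability of real
histology better than Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MARKERS",
    "REGIONS",
    "CountRecord",
    "FractionatorSpec",
    "series_total",
    "double_label_absolute",
    "fractionator_estimate",
    "simulate_counts",
    "default_count_means",
]

MARKERS = ("Iba1", "BrdU", "BrdU+Nestin", "BrdU+NeuN", "DAPI")
REGIONS = ("GCL_SGZ", "ML", "hilus", "GCL")

TIME_POINTS = ("baseline", "3", "6", "10", "14", "18")
TREATMENTS = ("CTR", "MPTP")


@dataclass(frozen=True)
class CountRecord:
    """One per-animal raw count on a systematic section series."""

    animal_id: str
    marker: str
    region: str
    raw_count: int
    sections_counted: int = 4
    series_interval: int = 12

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.raw_count < 0:
            raise ValueError(f"raw_count must be >= 0, got {self.raw_count}")
        if self.series_interval < 1:
            raise ValueError(f"series_interval must be >= 1, got {self.series_interval}")


@dataclass(frozen=True)
class FractionatorSpec:
    """Optical-fractionator sampling geometry (lengths in micrometers).

    Defaults: 30x30 um counting frame on a 120x100 um grid, 20 um disector
    height in 40 um sections with a 5 um guard zone, 1-in-12 section series.
    The guard zone affects disector placement, not the height sampling
    fraction, which is disector_height / slice_thickness.
    """

    frame: tuple[float, float] = (30.0, 30.0)
    grid: tuple[float, float] = (120.0, 100.0)
    disector_height: float = 20.0
    slice_thickness: float = 40.0
    series_interval: int = 12
    guard_zone: float = 5.0

    def __post_init__(self) -> None:
        if self.frame[0] > self.grid[0] or self.frame[1] > self.grid[1]:
            raise ValueError(f"counting frame {self.frame} does not fit in grid {self.grid}")
        if self.disector_height + self.guard_zone > self.slice_thickness:
            raise ValueError(
                f"disector height {self.disector_height} + guard zone {self.guard_zone} "
                f"exceeds slice thickness {self.slice_thickness}"
            )
        if self.series_interval < 1:
            raise ValueError(f"series_interval must be >= 1, got {self.series_interval}")

    @property
    def section_sampling_fraction(self) -> float:
        return 1.0 / self.series_interval

    @property
    def area_sampling_fraction(self) -> float:
        return (self.frame[0] * self.frame[1]) / (self.grid[0] * self.grid[1])

    @property
    def height_sampling_fraction(self) -> float:
        return self.disector_height / self.slice_thickness


def series_total(raw_count: float, series_interval: int) -> float:
    """Scale an exhaustive series count to the whole structure."""
    if raw_count < 0 or series_interval < 0:
        raise ValueError("raw_count and series_interval must be >= 0")
    return raw_count * series_interval


def double_label_absolute(
    n_double_of_sample: float, sample_size: float, total_marker_estimate: float
) -> float:
    """Absolute double-labeled cell estimate from a sampled proportion."""
    if not sample_size > 0:
        raise ValueError(f"sample_size must be > 0, got {sample_size}")
    if not 0 <= n_double_of_sample <= sample_size:
        raise ValueError(
            f"n_double_of_sample must be in [0, {sample_size}], got {n_double_of_sample}"
        )
    return (n_double_of_sample / sample_size) * total_marker_estimate


def fractionator_estimate(
    sum_q: float, spec: FractionatorSpec = FractionatorSpec()
) -> tuple[float, dict[str, float]]:
    """Optical-fractionator total cell number.

    Returns ``(N, fractions)`` with N = sum_Q / (ssf * asf * hsf) and
    ``fractions`` reporting the three sampling fractions. With defaults a
    disector count of 100 scales to 100 * 12 * (12000/900) * (40/20) = 32000.
    """
    if sum_q < 0:
        raise ValueError(f"sum_q must be >= 0, got {sum_q}")
    fractions = {
        "section_sampling_fraction": spec.section_sampling_fraction,
        "area_sampling_fraction": spec.area_sampling_fraction,
        "height_sampling_fraction": spec.height_sampling_fraction,
    }
    n = sum_q / (
        fractions["section_sampling_fraction"]
        * fractions["area_sampling_fraction"]
        * fractions["height_sampling_fraction"]
    )
    return n, fractions


def default_count_means() -> dict[str, dict[tuple[str, str], float]]:
    """Per-series raw-count cell means shaped like the study's time courses.

    Values are plausible hippocampal counts on a 1-in-12 series: BrdU-labeled
    cohorts decline after the labeling pulse; microglia (Iba1) rise
    transiently at 3 dpi in the MPTP arm; total granule-cell-layer nuclei
    (DAPI disector counts) are stable in both arms.
    """
    means: dict[str, dict[tuple[str, str], float]] = {m: {} for m in MARKERS}
    brdu_course = {"baseline": 80, "3": 75, "6": 60, "10": 45, "14": 35, "18": 30}
    for tp in TIME_POINTS:
        for tr in TREATMENTS:
            means["BrdU"][(tr, tp)] = float(brdu_course[tp])
            means["BrdU+Nestin"][(tr, tp)] = 0.4 * brdu_course[tp]
            means["BrdU+NeuN"][(tr, tp)] = 0.3 * brdu_course[tp]
            means["Iba1"][(tr, tp)] = 40.0
            means["DAPI"][(tr, tp)] = 250.0
    # MPTP-specific departures: precursor surge at 3 dpi, neuron surge at
    # 6 dpi, microglial peak at 3 dpi.
    means["BrdU+Nestin"][("MPTP", "3")] *= 1.8
    means["BrdU+NeuN"][("MPTP", "6")] *= 1.6
    means["Iba1"][("MPTP", "3")] *= 1.7
    return means


_MARKER_REGION = {
    "Iba1": "GCL_SGZ",
    "BrdU": "GCL_SGZ",
    "BrdU+Nestin": "GCL_SGZ",
    "BrdU+NeuN": "GCL_SGZ",
    "DAPI": "GCL",
}


def simulate_counts(
    marker_means: dict[str, dict[tuple[str, str], float]] | None = None,
    n_per_group: int = 5,
    seed: int = 0,
    *,
    dispersion: float = 30.0,
    sds: dict[str, float] | None = None,
    sections_counted: int = 4,
    series_interval: int = 12,
) -> pd.DataFrame:
    """Draw a balanced 2 treatments x 6 times x n animals count table.

    Counts are negative-binomial around the specified means with shape
    parameter ``dispersion`` (variance mean + mean^2/dispersion). Passing
    per-marker ``sds`` overrides the dispersion: sd = 0 gives deterministic
    rounded means; sd^2 <= mean falls back to Poisson. Deterministic under
    a fixed seed.
    """
    if n_per_group < 2:
        raise ValueError(f"n_per_group must be >= 2, got {n_per_group}")
    marker_means = marker_means if marker_means is not None else default_count_means()
    for marker, cells in marker_means.items():
        for key, mean in cells.items():
            if mean < 0:
                raise ValueError(f"mean for {marker} {key} must be >= 0, got {mean}")
    rng = np.random.default_rng(seed)

    records = []
    for marker in marker_means:
        region = _MARKER_REGION.get(marker, "GCL_SGZ")
        for tr in TREATMENTS:
            for tp in TIME_POINTS:
                mean = marker_means[marker][(tr, tp)]
                for a in range(n_per_group):
                    animal_id = f"{tr}_{tp}_{a + 1:02d}"
                    sd = None if sds is None else sds.get(marker)
                    if sd is not None and sd == 0:
                        count = int(round(mean))
                    elif sd is not None and sd**2 <= mean:
                        count = int(rng.poisson(mean))
                    elif sd is not None:
                        shape = mean**2 / (sd**2 - mean)
                        count = int(rng.negative_binomial(shape, shape / (shape + mean)))
                    elif mean == 0:
                        count = 0
                    else:
                        count = int(
                            rng.negative_binomial(dispersion, dispersion / (dispersion + mean))
                        )
                    records.append(
                        (
                            animal_id,
                            tr,
                            tp,
                            marker,
                            region,
                            count,
                            sections_counted,
                            series_interval,
                        )
                    )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "animal_id",
            "treatment",
            "time_point",
            "marker",
            "region",
            "raw_count",
            "sections_counted",
            "series_interval",
        ],
    )
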