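"""Synthetic longitudinal study tables of ROI-averaged viscoelastic values.

Emulates the in-vivo study design: two treatment arms (NaCl control and
MPTP), five time points after treatment cessation plus a baseline, two
ROIs (whole brain, hippocampus), and the four tabulated parameters per
scan. Values are drawn from a random-intercept model

    value = control_mean * multiplier(treatment, time)
            + animal_intercept + residual

with the intercept drawn once per (animal, ROI, parameter in {G', G''})
from N(0, between_animal_sd) and the residual per record from
N(0, within_animal_sd). |G*| and phi are derived per record from the
sampled G' and G'' so the four parameters stay internally consistent.

Default effect sizes encode the study's finding: a transient stiffening at
6 days post injection in MPTP animals (+51% G', +27% G'' in the
hippocampus; +29%, +16% whole brain), no effect at any other time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TIME_POINTS",
    "TREATMENTS",
    "ROIS",
    "PARAMETERS",
    "CONTROL_MEANS",
    "CONTROL_SEMS",
    "EffectSpec",
    "simulate_longitudinal_study",
]

TIME_POINTS = ("baseline", "3", "6", "10", "14", "18")
TREATMENTS = ("CTR", "MPTP")
ROIS = ("whole_brain", "hippocampus")
PARAMETERS = ("Gp", "Gpp", "absG", "phi")

# Control-group ROI means (Pa) for the sampled parameters.
CONTROL_MEANS: dict[tuple[str, str], float] = {
    ("hippocampus", "Gp"): 4608.0,
    ("hippocampus", "Gpp"): 1388.0,
    ("whole_brain", "Gp"): 5234.0,
    ("whole_brain", "Gpp"): 1447.0,
}

# Standard errors of the control means (Pa), n = 5 animals.
CONTROL_SEMS: dict[tuple[str, str], float] = {
    ("hippocampus", "Gp"): 719.0,
    ("hippocampus", "Gpp"): 125.0,
    ("whole_brain", "Gp"): 564.0,
    ("whole_brain", "Gpp"): 87.0,
}


def _default_multipliers() -> dict[tuple[str, str, str], float]:
    """Transient 6-dpi stiffening in the MPTP arm; 1.0 everywhere else."""
    return {
        ("hippocampus", "6", "Gp"): 1.51,
        ("hippocampus", "6", "Gpp"): 1.27,
        ("whole_brain", "6", "Gp"): 1.29,
        ("whole_brain", "6", "Gpp"): 1.16,
    }


def _default_sds(scale: float) -> dict[tuple[str, str], float]:
    # per-animal SD implied by the printed SEM at n = 5
    return {key: scale * sem * np.sqrt(5.0) for key, sem in CONTROL_SEMS.items()}


@dataclass
class EffectSpec:
    """Effect sizes and noise levels for the study generator.

    ``multipliers`` maps (roi, time_point, parameter) to the multiplicative
    effect on the MPTP cell mean relative to the control mean; missing keys
    mean 1.0 (no effect). Controls always have multiplier 1.
    ``between_animal_sd`` / ``within_animal_sd`` map (roi, parameter) to
    SDs in Pa; the defaults split the per-animal SD implied by the printed
    control SEMs equally (in variance) between the two levels.
    """

    multipliers: dict[tuple[str, str, str], float] = field(default_factory=_default_multipliers)
    between_animal_sd: dict[tuple[str, str], float] = field(
        default_factory=lambda: _default_sds(1.0 / np.sqrt(2.0))
    )
    within_animal_sd: dict[tuple[str, str], float] = field(
        default_factory=lambda: _default_sds(1.0 / np.sqrt(2.0))
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for key, m in self.multipliers.items():
            if not m > 0:
                raise ValueError(f"multiplier for {key} must be > 0, got {m}")
        for name in ("between_animal_sd", "within_animal_sd"):
            for key, sd in getattr(self, name).items():
                if sd < 0:
                    raise ValueError(f"{name} for {key} must be >= 0, got {sd}")

    @classmethod
    def null(cls, seed: int = 0) -> "EffectSpec":
        """No treatment effect anywhere (for type-I-error calibration)."""
        return cls(multipliers={}, seed=seed)

    @classmethod
    def noise_free(cls, seed: int = 0) -> "EffectSpec":
        """Default effects with zero variability (deterministic means)."""
        zero = {key: 0.0 for key in CONTROL_SEMS}
        return cls(between_animal_sd=dict(zero), within_animal_sd=dict(zero), seed=seed)

    def multiplier(self, treatment: str, roi: str, time_point: str, parameter: str) -> float:
        if treatment != "MPTP":
            return 1.0
        return self.multipliers.get((roi, time_point, parameter), 1.0)


def simulate_longitudinal_study(
    control_means: dict[tuple[str, str], float] | None = None,
    effects: EffectSpec | None = None,
    n_per_group: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a balanced longitudinal study table.

    Returns a long-format table with one record per (animal, time point,
    ROI, parameter): columns ``animal_id, treatment, time_point, roi,
    parameter, value``. 2 treatments x ``n_per_group`` animals x 6 time
    points x 2 ROIs x 4 parameters. Bit-identical under a fixed seed.

    ``seed`` overrides ``effects.seed`` when given.
    """
    if n_per_group < 2:
        raise ValueError(f"n_per_group must be >= 2 for a balanced design, got {n_per_group}")
    control_means = control_means if control_means is not None else dict(CONTROL_MEANS)
    effects = effects if effects is not None else EffectSpec()
    rng = np.random.default_rng(effects.seed if seed is None else seed)

    sampled = ("Gp", "Gpp")
    records = []
    for treatment in TREATMENTS:
        for a in range(n_per_group):
            animal_id = f"{treatment}_{a + 1:02d}"
            intercept = {
                (roi, p): rng.normal(0.0, effects.between_animal_sd.get((roi, p), 0.0))
                for roi in ROIS
                for p in sampled
            }
            for time_point in TIME_POINTS:
                for roi in ROIS:
                    draws = {}
                    for p in sampled:
                        mean = control_means[(roi, p)] * effects.multiplier(
                            treatment, roi, time_point, p
                        )
                        value = (
                            mean
                            + intercept[(roi, p)]
                            + rng.normal(0.0, effects.within_animal_sd.get((roi, p), 0.0))
                        )
                        draws[p] = value
                    draws["absG"] = float(np.hypot(draws["Gp"], draws["Gpp"]))
                    draws["phi"] = float(np.arctan2(draws["Gpp"], draws["Gp"]))
                    for p in PARAMETERS:
                        records.append(
                            (animal_id, treatment, time_point, roi, p, draws[p])
                        )

    return pd.DataFrame.from_records(
        records,
        columns=["animal_id", "treatment", "time_point", "roi", "parameter", "value"],
    )
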