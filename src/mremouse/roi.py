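"""ROI-wise spatial summaries of elastograms and percent-change arithmetic."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import LABEL_HIPPOCAMPUS, LABEL_PARENCHYMA, ViscoelasticPhantom
from .recon import Elastogram

__all__ = ["ROIMask", "ROISummary", "roi_average", "percent_change"]


@dataclass
class ROIMask:
    """Integer label image plus a name -> label(s) mapping.

    A named ROI may pool several labels (e.g. ``whole_brain`` is the union
    of parenchyma and hippocampus labels).
    """

    labels: np.ndarray
    name_map: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "whole_brain": (LABEL_PARENCHYMA, LABEL_HIPPOCAMPUS),
            "hippocampus": (LABEL_HIPPOCAMPUS,),
        }
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        for name, labs in self.name_map.items():
            if isinstance(labs, int):
                self.name_map[name] = (labs,)

    @classmethod
    def from_phantom(cls, phantom: ViscoelasticPhantom) -> "ROIMask":
        return cls(labels=phantom.region_labels.copy())

    def mask_for(self, roi_name: str) -> np.ndarray:
        if roi_name not in self.name_map:
            raise KeyError(f"unknown ROI {roi_name!r}; known: {sorted(self.name_map)}")
        labs = self.name_map[roi_name]
        mask = np.isin(self.labels, labs)
        if not mask.any():
            raise ValueError(f"ROI {roi_name!r} has no pixels (labels {labs})")
        return mask


@dataclass
class ROISummary:
    """Spatial means of the four viscoelastic parameter maps over one ROI."""

    roi_name: str
    means: dict[str, float]  # keys: Gp, Gpp, absG, phi
    medians: dict[str, float]
    n_pixels: int
    n_valid: int

    @property
    def invalid_fraction(self) -> float:
        return 1.0 - self.n_valid / self.n_pixels


def roi_average(elastogram: Elastogram, mask: ROIMask, roi_name: str) -> ROISummary:
    """Average each derived parameter map over the valid pixels of one ROI.

    Each of the four per-pixel maps (G', G'', |G*|, phi) is averaged
    independently over valid ROI pixels; phi is the mean of per-pixel loss
    tangents, not the arctan of the averaged components.
    """
    roi = mask.mask_for(roi_name)
    if roi.shape != elastogram.shape:
        raise ValueError(
            f"ROI mask shape {roi.shape} does not match elastogram {elastogram.shape}"
        )
    valid = roi & elastogram.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError(f"ROI {roi_name!r} contains zero valid pixels")

    maps = {"Gp": elastogram.gp, "Gpp": elastogram.gpp, "absG": elastogram.absg, "phi": elastogram.phi}
    means = {k: float(np.mean(v[valid])) for k, v in maps.items()}
    medians = {k: float(np.median(v[valid])) for k, v in maps.items()}
    return ROISummary(
        roi_name=roi_name,
        means=means,
        medians=medians,
        n_pixels=int(roi.sum()),
        n_valid=n_valid,
    )


def percent_change(value: float, reference: float) -> float:
    """Relative change in percent, 100*(value/reference - 1).

    No rounding is applied here; integer rounding happens only at the
    report layer.
    """
    if not reference > 0:
        raise ValueError(f"reference must be strictly positive, got {reference!r}")
    return 100.0 * (value / reference - 1.0)
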