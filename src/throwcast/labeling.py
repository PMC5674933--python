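"""Right/Left side labels from board landing coordinates.

Classes are separated by a participant-centered vertical "gray band" on the
target board: its center is the mean landing x over all good trials of the
participant, its default width 22.5 cm (25% of the lateral target spacing).
Throws landing inside the band are excluded from classification but still
contribute to the band center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_BAND_WIDTH_M = 0.225


@dataclass(frozen=True)
class SideLabel:
    value: str          # "Right" | "Left" | "Band"
    landing_x: float
    band_center: float
    band_width: float

    def __post_init__(self):
        if self.value not in ("Right", "Left", "Band"):
            raise ValueError(f"invalid side label {self.value!r}")
        in_band = abs(self.landing_x - self.band_center) <= self.band_width / 2
        if in_band != (self.value == "Band"):
            raise ValueError("label inconsistent with band geometry")


def band_center(landing_x: np.ndarray) -> float:
    """Mean landing x across all (non-excluded) trials of a participant."""
    landing_x = np.asarray(landing_x, float)
    if landing_x.size == 0:
        raise ValueError("no trials to compute the band center from")
    return float(landing_x.mean())


def assign_side(landing_x: float, center: float,
                band_width: float = DEFAULT_BAND_WIDTH_M) -> SideLabel:
    """Right if right of the band (positive x = thrower's right), Left if
    left of it, Band inside it (excluded from classification)."""
    if not (np.isfinite(landing_x) and np.isfinite(center)):
        raise ValueError("landing_x and center must be finite")
    half = band_width / 2
    if landing_x > center + half:
        value = "Right"
    elif landing_x < center - half:
        value = "Left"
    else:
        value = "Band"
    return SideLabel(value, float(landing_x), float(center), float(band_width))


def label_trials(landing_x: np.ndarray,
                 band_width: float = DEFAULT_BAND_WIDTH_M) -> list[SideLabel]:
    """Label a participant's landings with a common, data-derived band."""
    center = band_center(landing_x)
    return [assign_side(x, center, band_width) for x in np.asarray(landing_x)]
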