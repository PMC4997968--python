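"""Western-blot lane densitometry.

Quantifies protein bands from 1-D lane intensity profiles: a linear
background is fitted through the flanking margins of the band window, the
background-subtracted intensity is integrated over the window, and target
band densities are normalized first to a loading control (GAPDH-style) and
then to the reference-group mean so the reference group averages 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["LaneProfile", "BandQuant", "RelExpression",
           "quantify_band", "normalize"]


@dataclass(frozen=True)
class LaneProfile:
    intensity: np.ndarray            # a.u. along the migration axis
    position_step: float = 1.0

    def __post_init__(self):
        arr = np.asarray(self.intensity, float)
        object.__setattr__(self, "intensity", arr)
        if arr.size < 10:
            raise ValueError("profile must have length >= 10")
        if not np.all(np.isfinite(arr)):
            raise ValueError("profile intensities must be finite")


@dataclass
class BandQuant:
    band_window: tuple[int, int]     # [start, end) positions
    integrated_density: float        # a.u., background-subtracted, >= 0
    background_model: tuple[float, float]   # (slope, intercept)


@dataclass
class RelExpression:
    target_over_control: float
    normalized_to_reference: float | None


def quantify_band(profile: LaneProfile | np.ndarray,
                  window: tuple[int, int],
                  flank_frac: float = 0.10) -> BandQuant:
    """Integrate a band over ``window`` after subtracting a linear background.

    The background line is least-squares fitted through two flanking margins
    of width ``flank_frac`` × window width immediately outside the window.
    The integrated density is clipped at zero (with a warning) so noise
    cannot produce negative abundance.
    """
    y = profile.intensity if isinstance(profile, LaneProfile) else np.asarray(profile, float)
    start, end = window
    if not (0 <= start < end <= y.size):
        raise ValueError("window must lie inside the profile")
    fw = max(1, int(round(flank_frac * (end - start))))
    if start - fw < 0 or end + fw > y.size:
        raise ValueError("no flank for background: window touches the profile edge")

    xs = np.concatenate([np.arange(start - fw, start), np.arange(end, end + fw)])
    slope, intercept = np.polyfit(xs, y[xs], 1)
    xin = np.arange(start, end)
    dens = float(np.sum(y[xin] - (slope * xin + intercept)))
    if dens < 0:
        warnings.warn("integrated density negative after background "
                      "subtraction; clipped to 0")
        dens = 0.0
    return BandQuant(band_window=(start, end), integrated_density=dens,
                     background_model=(float(slope), float(intercept)))


def normalize(target: BandQuant, control: BandQuant,
              reference_values: list[float] | None = None) -> RelExpression:
    """Target/loading-control ratio, optionally rescaled so the mean of the
    ``reference_values`` ratios (e.g. the sham group) equals 1."""
    if control.integrated_density <= 0:
        raise ValueError("loading-control density must be positive")
    ratio = target.integrated_density / control.integrated_density
    if reference_values:
        ref = float(np.mean(reference_values))
        if ref <= 0:
            raise ValueError("reference-group mean must be positive")
        norm = ratio / ref
    else:
        norm = None
    return RelExpression(target_over_control=float(ratio),
                         normalized_to_reference=norm)
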