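"""Platen/dish geometry: stress and strain conversion, region classification.

Force amplitude is converted to a nominal compressive stress over the full
platen face, the commanded displacement amplitude to a dimensionless strain
referenced to the compliant agarose overlay, and dish radius to the
center/peripheral region split used throughout the cell-death readouts.
Cells beyond the region boundary are hypothesized to see shear on top of the
cyclic compression; that radial effect is carried by a single linear
shear-amplification factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PlatenGeometry",
    "StressResult",
    "stress_from_force",
    "strain_amplitude",
    "classify_region",
    "shear_amplification",
    "frequency_derating",
]

CENTER = "center"
PERIPHERAL = "peripheral"


@dataclass(frozen=True)
class PlatenGeometry:
    """Loading geometry.

    Defaults are the experimental rig: 34.2 mm Teflon platen over a 35 mm
    dish (radius 17.1 mm), region boundary at r = 10 mm, and a 2 mm agarose
    overlay acting as the compliant stack that sets the strain datum.
    """

    platen_diameter: float = 34.2  # mm
    dish_radius: float = 17.1  # mm
    region_boundary: float = 10.0  # mm
    stack_height: float = 2.0  # mm

    def __post_init__(self) -> None:
        if not 0 < self.region_boundary < self.dish_radius:
            raise ValueError(
                "region_boundary must lie strictly inside (0, dish_radius)"
            )
        if self.platen_diameter / 2 < self.dish_radius - 1e-9:
            raise ValueError("platen must cover the dish")
        if self.stack_height <= 0:
            raise ValueError("stack_height must be > 0 mm")

    @property
    def platen_area_m2(self) -> float:
        r_m = self.platen_diameter / 2 * 1e-3
        return math.pi * r_m * r_m


@dataclass(frozen=True)
class StressResult:
    sigma: float  # kPa, nominal compressive stress amplitude
    epsilon0: float  # dimensionless strain amplitude


def stress_from_force(delta_f: float, geom: PlatenGeometry | None = None) -> float:
    """Nominal stress amplitude: force amplitude over the full platen face, kPa."""
    if geom is None:
        geom = PlatenGeometry()
    if delta_f < 0:
        raise ValueError(f"force amplitude must be >= 0 N, got {delta_f}")
    return delta_f / geom.platen_area_m2 * 1e-3


def strain_amplitude(alpha: float, geom: PlatenGeometry | None = None) -> float:
    """Strain amplitude eps0 = alpha / stack_height (alpha um, stack mm)."""
    if geom is None:
        geom = PlatenGeometry()
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0 um, got {alpha}")
    return alpha * 1e-3 / geom.stack_height


def classify_region(r: float, geom: PlatenGeometry | None = None) -> str:
    """Classify a dish radius as ``center`` (r < boundary) or ``peripheral``.

    The boundary radius itself is peripheral (closed interval on the outer
    region).
    """
    if geom is None:
        geom = PlatenGeometry()
    if not 0 <= r <= geom.dish_radius + 1e-9:
        raise ValueError(
            f"r = {r:g} mm lies outside the dish [0, {geom.dish_radius:g}] mm"
        )
    return CENTER if r < geom.region_boundary else PERIPHERAL


def shear_amplification(
    r, kappa: float, geom: PlatenGeometry | None = None
):
    """Multiplicative energy amplification from peripheral shear exposure.

    Equals 1 inside the center region and rises linearly with radius to
    ``1 + kappa`` at the dish edge::

        A(r) = 1 + kappa * max(0, r - boundary) / (dish_radius - boundary)

    Accepts scalars or numpy arrays of radii.
    """
    import numpy as np

    if geom is None:
        geom = PlatenGeometry()
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    r = np.asarray(r, dtype=float)
    span = geom.dish_radius - geom.region_boundary
    amp = 1.0 + kappa * np.maximum(0.0, r - geom.region_boundary) / span
    return float(amp) if amp.ndim == 0 else amp


#: (frequency Hz, applied stress kPa) endpoints of the observed high-frequency
#: actuator derating at the smallest displacement amplitude.
DERATING_ANCHORS = ((0.1, 0.8), (30.0, 0.5))


def frequency_derating(freq: float) -> float:
    """Optional multiplicative stress derating, linear in log10(f).

    The actuator lags at higher frequency, so the delivered stress drops
    slightly with f (from 0.8 kPa at 0.1 Hz to 0.5 kPa at 30 Hz at the
    smallest amplitude).  Returns a factor in (0, 1] normalized to 1 at the
    low-frequency anchor; clamped outside the anchor range.  Off by default
    everywhere in the pipeline.
    """
    (f_lo, s_lo), (f_hi, s_hi) = DERATING_ANCHORS
    if freq <= 0:
        raise ValueError("freq must be > 0 Hz")
    x = min(max(math.log10(freq), math.log10(f_lo)), math.log10(f_hi))
    frac = (x - math.log10(f_lo)) / (math.log10(f_hi) - math.log10(f_lo))
    return (s_lo + frac * (s_hi - s_lo)) / s_lo
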