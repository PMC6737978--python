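"""Generative dose-response model: dissipated energy -> cell-death outcomes.

Each cell ends a loading run in one of four mutually exclusive states,
matching the two-probe staining readout (caspase-3/7 for apoptosis, PI for
membrane-integrity loss):

* ``none``  — unlabeled survivor
* ``early`` — caspase-positive only (early apoptosis)
* ``late``  — caspase- and PI-positive (late apoptosis, double positive)
* ``nec``   — PI-positive only (necrosis)

The driver is the effective dissipated energy density ``w_eff`` a cell
experienced: the bulk total energy W amplified by peripheral shear exposure
(growing with dish radius) and capped by a per-cell-line detachment ceiling —
loosely attached lines detach before damage accumulates to a lethal level.

Necrosis saturates with energy through a Hill-type response; apoptosis is a
unimodal bump peaking at sub-lethal energies, drawn from the cells necrosis
spared.  Both ride on small background rates matching unloaded controls.

All default parameters are a one-time calibration against the qualitative
anchors of the study (control bands, >90% necrosis at the harsh conditions,
~10% peak apoptosis); they are calibration values, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanics import PlatenGeometry, shear_amplification

__all__ = [
    "DamageParams",
    "OutcomeProbs",
    "effective_energy",
    "outcome_probabilities",
    "OUTCOMES",
]

#: Outcome labels in the order used by every probability vector and count table.
OUTCOMES = ("none", "early", "late", "nec")


@dataclass(frozen=True)
class DamageParams:
    """Dose-response parameters of the generative damage model.

    Parameters
    ----------
    w_nec : float
        Necrosis energy scale, J/m^3: w_eff at which the Hill response reaches
        1 - 1/e above background.
    h_nec : float
        Necrosis Hill exponent (steepness of the dose response).
    w_apo : float
        Apoptosis energy scale, J/m^3: location of the unimodal apoptosis peak.
    a_max : float
        Peak apoptosis probability (before necrosis competition).
    late_w_half : float
        Energy at which half the apoptotic cells are double positive, J/m^3.
    late_slope : float
        Steepness of the late-apoptosis logistic in log w_eff.
    kappa : float
        Peripheral shear-amplification gain (see mechanics module).
    bg_apo, bg_nec : float
        Background apoptosis / necrosis probabilities in unloaded controls.
    detach_scale : dict
        Per-cell-line energy ceiling, J/m^3: energy beyond which cells detach
        rather than accumulate further damage.
    """

    w_nec: float = 45.0
    h_nec: float = 3.0
    w_apo: float = 40.0
    a_max: float = 0.25
    late_w_half: float = 50.0
    late_slope: float = 1.5
    kappa: float = 2.0
    bg_apo: float = 0.001
    bg_nec: float = 0.004
    detach_scale: dict = field(
        default_factory=lambda: {"BT-474": 3000.0, "MDA-MB-231": 120.0}
    )

    def __post_init__(self) -> None:
        for name in ("w_nec", "h_nec", "w_apo", "late_w_half", "late_slope"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.a_max <= 1:
            raise ValueError("a_max must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not 0 <= self.bg_apo <= 0.002:
            raise ValueError("bg_apo must lie in the control band [0, 0.002]")
        if not 0 <= self.bg_nec <= 0.009:
            raise ValueError("bg_nec must lie in the control band [0, 0.009]")
        if any(v <= 0 for v in self.detach_scale.values()):
            raise ValueError("detach_scale values must be > 0 J/m^3")

    def replace(self, **kwargs) -> "DamageParams":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass(frozen=True)
class OutcomeProbs:
    p_none: float
    p_early: float
    p_late: float
    p_nec: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_none, self.p_early, self.p_late, self.p_nec])


def effective_energy(
    w_total,
    r,
    cell_line: str,
    params: DamageParams,
    geom: PlatenGeometry | None = None,
):
    """Effective energy a cell at radius ``r`` experienced, J/m^3.

    ``w_eff = min(w_total * A(r; kappa), detach_scale[cell_line])`` —
    non-decreasing in both ``w_total`` and ``r``.  Accepts scalar or array
    radii.
    """
    if geom is None:
        geom = PlatenGeometry()
    if cell_line not in params.detach_scale:
        raise ValueError(
            f"unknown cell line {cell_line!r}; expected one of "
            f"{sorted(params.detach_scale)}"
        )
    w_total = np.asarray(w_total, dtype=float)
    if (w_total < 0).any():
        raise ValueError("w_total must be >= 0")
    amp = shear_amplification(r, params.kappa, geom)
    w_eff = np.minimum(w_total * amp, params.detach_scale[cell_line])
    return float(w_eff) if np.ndim(w_eff) == 0 else w_eff


def _late_fraction(w_eff: np.ndarray, params: DamageParams) -> np.ndarray:
    """Fraction of apoptotic cells that are double positive; 0 at w_eff = 0."""
    w = np.asarray(w_eff, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(w > 0, (w / params.late_w_half) ** params.late_slope, 0.0)
    return ratio / (1.0 + ratio)


def outcome_probability_vectors(w_eff, params: DamageParams) -> np.ndarray:
    """Vectorized outcome probabilities; rows sum to 1 exactly.

    Necrosis is assigned first (Hill-saturating in energy, riding on the
    background rate); apoptosis is drawn from the surviving fraction with a
    unimodal x*exp(1-x) dose response peaking at ``w_apo``; apoptotic cells
    split into early/late by the logistic late fraction.
    """
    w = np.atleast_1d(np.asarray(w_eff, dtype=float))
    if (w < 0).any():
        raise ValueError("w_eff must be >= 0")
    p_nec = params.bg_nec + (1.0 - params.bg_nec) * (
        1.0 - np.exp(-((w / params.w_nec) ** params.h_nec))
    )
    x = w / params.w_apo
    bump = x * np.exp(1.0 - x)
    p_apo = params.bg_apo + params.a_max * (1.0 - p_nec) * bump
    p_apo = np.minimum(p_apo, 1.0 - p_nec)  # cap: death modes cannot exceed 1
    lf = _late_fraction(w, params)
    p_late = lf * p_apo
    p_early = p_apo - p_late
    p_none = 1.0 - p_nec - p_apo
    probs = np.column_stack([p_none, p_early, p_late, p_nec])
    return probs


def outcome_probabilities(w_eff: float, params: DamageParams) -> OutcomeProbs:
    """Outcome probabilities for one effective-energy value."""
    p = outcome_probability_vectors(float(w_eff), params)[0]
    return OutcomeProbs(p_none=p[0], p_early=p[1], p_late=p[2], p_nec=p[3])
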