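"""Linear viscoelasticity: complex modulus, per-cycle dissipation, total energy.

The cell layer is idealized as a generalized Maxwell (Prony-series) solid with
relaxation function

    G(t) = G_inf + sum_i w_i * exp(-t / tau_i),          G(0) = G_0,

whose dynamic modulus follows from the Laplace transform evaluated on the
imaginary axis, G*(omega) = (i*omega) * Gbar(i*omega):

    G1(omega) = G_inf + sum_i w_i * (omega*tau_i)^2 / (1 + (omega*tau_i)^2)
    G2(omega) =         sum_i w_i *  omega*tau_i    / (1 + (omega*tau_i)^2)

Under sinusoidal strain eps(t) = eps0 * sin(omega*t) the energy dissipated per
cycle and per unit volume is the hysteresis-loop area

    dw = pi * eps0^2 * |G*| * sin(delta) = pi * eps0^2 * G2(omega),

and the total dissipated energy density over a run of duration t at frequency
f is W = dw * f * t.  A second reading that attaches tan(delta) rather than
sin(delta) to the frequency term (W = pi * eps0^2 * |G*| * tan(delta) * f * t)
is kept behind an explicit variant flag for compatibility with the published
frequency analysis; the loss-modulus (sin delta) form is the physically exact
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "ViscoelasticModel",
    "ModulusAt",
    "EnergySummary",
    "FrequencyResponse",
    "relaxation_modulus",
    "complex_modulus",
    "energy_per_cycle",
    "dissipation_oracle",
    "total_energy",
    "frequency_response",
    "VARIANT_LOSS_MODULUS",
    "VARIANT_PAPER_TAN_DELTA",
]

VARIANT_LOSS_MODULUS = "loss-modulus"
VARIANT_PAPER_TAN_DELTA = "paper-tan-delta"
_VARIANTS = (VARIANT_LOSS_MODULUS, VARIANT_PAPER_TAN_DELTA)


@dataclass(frozen=True)
class ViscoelasticModel:
    """Generalized Maxwell model.

    Parameters
    ----------
    g_inst : float
        Instantaneous modulus G0, Pa.
    g_relaxed : float
        Relaxed (equilibrium) modulus G_inf, Pa.
    relax_times : tuple of float
        Relaxation time of each Maxwell branch, s.
    weights : tuple of float, optional
        Branch moduli w_i, Pa; must sum with g_relaxed to g_inst.  If omitted
        and there is a single branch, the weight is g_inst - g_relaxed.

    The defaults (2 kPa instantaneous, 1 kPa relaxed, 1 s relaxation time) are
    calibration placeholders in the soft-cell rheology range, not measured
    values.
    """

    g_inst: float = 2000.0
    g_relaxed: float = 1000.0
    relax_times: tuple[float, ...] = (1.0,)
    weights: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.g_relaxed < 0 or self.g_inst < self.g_relaxed:
            raise ValueError("need g_inst >= g_relaxed >= 0")
        taus = tuple(float(t) for t in self.relax_times)
        if any(t <= 0 for t in taus):
            raise ValueError("all relaxation times must be > 0 s")
        weights = tuple(float(w) for w in self.weights)
        if not weights:
            if len(taus) != 1:
                raise ValueError("weights required for multi-branch models")
            weights = (self.g_inst - self.g_relaxed,)
        if len(weights) != len(taus):
            raise ValueError("one weight per relaxation time required")
        if any(w < 0 for w in weights):
            raise ValueError("branch weights must be >= 0")
        if abs(sum(weights) + self.g_relaxed - self.g_inst) > 1e-6 * max(
            self.g_inst, 1.0
        ):
            raise ValueError("g_relaxed + sum(weights) must equal g_inst")
        object.__setattr__(self, "relax_times", taus)
        object.__setattr__(self, "weights", weights)


@dataclass(frozen=True)
class ModulusAt:
    """Complex modulus evaluated at one angular frequency."""

    omega: float  # rad/s
    g1: float  # storage modulus, Pa
    g2: float  # loss modulus, Pa
    g_abs: float  # |G*|, Pa
    delta: float  # loss angle, rad


@dataclass(frozen=True)
class EnergySummary:
    dw_cycle: float  # J/m^3 per cycle
    w_total: float  # J/m^3 over the whole run
    variant: str


@dataclass(frozen=True)
class FrequencyResponse:
    """The frequency-dependence term of total dissipated energy on a grid."""

    freqs: np.ndarray  # Hz
    response: np.ndarray  # Pa*Hz, f*G2 or f*|G*|*tan(delta)
    f_at_max: float
    is_interior: bool
    plateau_value: float | None  # analytic large-f limit where defined
    variant: str


def relaxation_modulus(model: ViscoelasticModel, t) -> float | np.ndarray:
    """Relaxation function G(t), Pa; non-increasing with G(0) = g_inst."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("time must be >= 0 s")
    g = model.g_relaxed + sum(
        w * np.exp(-t / tau) for w, tau in zip(model.weights, model.relax_times)
    )
    return float(g) if g.ndim == 0 else g


def complex_modulus(model: ViscoelasticModel, omega: float) -> ModulusAt:
    """Dynamic modulus G*(omega) = G1 + i*G2 from the Prony parameters."""
    if omega < 0:
        raise ValueError("omega must be >= 0 rad/s")
    g1 = model.g_relaxed
    g2 = 0.0
    for w, tau in zip(model.weights, model.relax_times):
        x = omega * tau
        g1 += w * x * x / (1.0 + x * x)
        g2 += w * x / (1.0 + x * x)
    g_abs = float(np.hypot(g1, g2))
    delta = float(np.arctan2(g2, g1))
    return ModulusAt(omega=omega, g1=g1, g2=g2, g_abs=g_abs, delta=delta)


def loss_modulus(model: ViscoelasticModel, omega) -> float | np.ndarray:
    """Vectorized loss modulus G2(omega), Pa."""
    omega = np.asarray(omega, dtype=float)
    g2 = sum(
        w * (omega * tau) / (1.0 + (omega * tau) ** 2)
        for w, tau in zip(model.weights, model.relax_times)
    )
    g2 = np.asarray(g2, dtype=float)
    return float(g2) if g2.ndim == 0 else g2


def energy_per_cycle(
    model: ViscoelasticModel, omega: float, epsilon0: float
) -> float:
    """Dissipated energy per cycle per unit volume, dw = pi*eps0^2*G2, J/m^3."""
    if epsilon0 < 0:
        raise ValueError("epsilon0 must be >= 0")
    return float(np.pi * epsilon0**2 * complex_modulus(model, omega).g2)


def dissipation_oracle(
    model: ViscoelasticModel,
    omega: float,
    epsilon0: float,
    cycles: int = 1,
) -> float:
    """Per-cycle dissipation by direct integration of stress x strain-rate.

    Steady-state stress under eps(t) = eps0*sin(omega*t) is
    sigma(t) = eps0*(G1*sin(omega*t) + G2*cos(omega*t)); the dissipated energy
    is the closed-loop integral of sigma * deps/dt over ``cycles`` cycles,
    divided by the cycle count.  This is the brute-force cross-check for
    :func:`energy_per_cycle` and deliberately does not call it.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if omega <= 0:
        return 0.0
    m = complex_modulus(model, omega)
    g1, g2 = m.g1, m.g2

    def power(t: float) -> float:
        strain_rate = epsilon0 * omega * np.cos(omega * t)
        stress = epsilon0 * (g1 * np.sin(omega * t) + g2 * np.cos(omega * t))
        return stress * strain_rate

    period = 2.0 * np.pi / omega
    total, _ = quad(power, 0.0, cycles * period, limit=200 * cycles)
    return total / cycles


def total_energy(
    model: ViscoelasticModel,
    f: float,
    t: float,
    epsilon0: float,
    variant: str = VARIANT_LOSS_MODULUS,
) -> EnergySummary:
    """Total dissipated energy density over a loading run, J/m^3.

    W is linear in duration ``t`` and quadratic in strain amplitude
    ``epsilon0`` in both variants.
    """
    if f <= 0:
        raise ValueError("f must be > 0 Hz")
    if t < 0:
        raise ValueError("t must be >= 0 s")
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {_VARIANTS}")
    omega = 2.0 * np.pi * f
    m = complex_modulus(model, omega)
    if variant == VARIANT_LOSS_MODULUS:
        dw = np.pi * epsilon0**2 * m.g2
    else:
        dw = np.pi * epsilon0**2 * m.g_abs * np.tan(m.delta)
    return EnergySummary(dw_cycle=float(dw), w_total=float(dw * f * t), variant=variant)


def frequency_response(
    model: ViscoelasticModel,
    f_grid,
    variant: str = VARIANT_LOSS_MODULUS,
) -> FrequencyResponse:
    """Evaluate the frequency term f*G2 (or f*|G*|*tan delta) on a grid.

    Reports the arg-max frequency (smallest frequency on ties), whether the
    maximum is interior to the grid, and for single-branch models the analytic
    large-f plateau weight/(2*pi*tau) of the loss-modulus variant.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {_VARIANTS}")
    f = np.asarray(list(f_grid), dtype=float)
    if len(f) < 3:
        raise ValueError("f_grid needs at least 3 points")
    if (f <= 0).any():
        raise ValueError("f_grid must be strictly positive")
    if (np.diff(f) <= 0).any():
        raise ValueError("f_grid must be strictly increasing")
    omega = 2.0 * np.pi * f
    g2 = np.atleast_1d(loss_modulus(model, omega))
    if variant == VARIANT_LOSS_MODULUS:
        resp = f * g2
    else:
        g1 = model.g_relaxed + sum(
            w * (omega * tau) ** 2 / (1.0 + (omega * tau) ** 2)
            for w, tau in zip(model.weights, model.relax_times)
        )
        gabs = np.hypot(g1, g2)
        with np.errstate(divide="ignore", invalid="ignore"):
            resp = np.where(g1 > 0, f * gabs * g2 / g1, 0.0)
    # smallest frequency attaining the max (within float tolerance) wins ties
    rmax = resp.max()
    idx = int(np.argmax(resp >= rmax * (1.0 - 1e-12)) if rmax > 0 else 0)
    plateau = None
    if variant == VARIANT_LOSS_MODULUS and len(model.weights) == 1:
        plateau = model.weights[0] / (2.0 * np.pi * model.relax_times[0])
    return FrequencyResponse(
        freqs=f,
        response=resp,
        f_at_max=float(f[idx]),
        is_interior=0 < idx < len(f) - 1,
        plateau_value=plateau,
        variant=variant,
    )
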