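"""Displacement-controlled oscillatory loading: waveform synthesis and force conversion.

The loading rig commands a platen displacement ``u(t)`` against a gel-overlaid
cell monolayer.  The commanded waveform ramps up an oscillation of peak-to-peak
amplitude ``alpha`` over a time constant ``tau1`` while adding an extra
compressive offset ``beta`` (time constant ``tau2``) that keeps the contact
force strictly compressive::

    u(t) = (1 - exp(-t/tau1)) * (alpha/2) * (1 - cos(2*pi*f*t))
         + beta * (1 - exp(-t/tau2))

This functional form is a reconstruction from the published parameter list and
contract (ramp-up without overshoot, steady peak-to-peak ``alpha``, ``u >= 0``,
``F > 0``); it is not a transcription of the original controller program.

Force is obtained from displacement through a linear contact model
``F = preload + k*u`` with the stiffness ``k`` calibrated by through-origin
least squares on measured (alpha, deltaF) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LoadingProtocol",
    "DisplacementTrace",
    "ContactModel",
    "ForceTrace",
    "build_waveform",
    "calibrate_stiffness",
    "force_trace",
    "count_cycles",
    "CALIBRATION_PAIRS",
]

#: Measured displacement-amplitude -> force-amplitude pairs (alpha um, deltaF N)
#: used for the default stiffness calibration.
CALIBRATION_PAIRS: tuple[tuple[float, float], ...] = (
    (40.0, 4.7),
    (70.0, 8.6),
    (100.0, 11.8),
    (130.0, 17.2),
)

#: Factor by which the steady-state window must clear the slowest ramp constant.
STEADY_STATE_FACTOR = 5.0

#: Default oversampling of the commanded frequency, capped at 10 kHz.
DEFAULT_SAMPLES_PER_CYCLE = 100
MAX_SAMPLE_RATE_HZ = 10_000.0


@dataclass(frozen=True)
class LoadingProtocol:
    """One displacement-controlled loading run.

    Parameters
    ----------
    alpha : float
        Displacement oscillation amplitude (peak-to-peak), um.
    freq : float
        Oscillation frequency, Hz.
    duration : float
        Total loading time, s.
    tau1 : float
        Ramp-up time constant of the oscillation envelope, s.
    tau2 : float
        Time constant of the additional compressive offset, s.
    beta : float
        Additional compressive displacement preventing tensile loading, um.
    preload : float
        Initial contact force before the program runs, N.
    """

    alpha: float
    freq: float
    duration: float
    tau1: float = 1.0
    tau2: float = 1.0
    beta: float = 5.0
    preload: float = 0.2

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0 um, got {self.alpha}")
        if self.freq <= 0:
            raise ValueError(f"freq must be > 0 Hz, got {self.freq}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0 s, got {self.duration}")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("tau1 and tau2 must be > 0 s")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0 um, got {self.beta}")

    @property
    def steady_state_start(self) -> float:
        """Time after which ramp transients are considered decayed, s."""
        return STEADY_STATE_FACTOR * max(self.tau1, self.tau2)

    def default_sample_rate(self) -> float:
        return min(DEFAULT_SAMPLES_PER_CYCLE * self.freq, MAX_SAMPLE_RATE_HZ)


@dataclass(frozen=True)
class DisplacementTrace:
    """Uniformly sampled displacement trace (times s, u um)."""

    times: np.ndarray
    u: np.ndarray
    protocol: LoadingProtocol

    def __post_init__(self) -> None:
        if len(self.times) != len(self.u):
            raise ValueError("times and u must have the same length")

    def steady_state_mask(self) -> np.ndarray:
        return self.times >= self.protocol.steady_state_start

    def steady_state_peak_to_peak(self) -> float:
        """Peak-to-peak displacement over the steady-state window, um."""
        mask = self.steady_state_mask()
        if not mask.any():
            raise ValueError(
                "trace too short: no samples past the steady-state onset "
                f"t = {self.protocol.steady_state_start:g} s"
            )
        window = self.u[mask]
        return float(window.max() - window.min())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.times, "displacement_um": self.u}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class ContactModel:
    """Linear displacement->force map, F = preload + stiffness * u."""

    stiffness: float  # N per um
    calibration_pairs: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError(f"stiffness must be > 0 N/um, got {self.stiffness}")


@dataclass(frozen=True)
class ForceTrace:
    """Force trace with steady-state amplitude summary.

    ``delta_f = f_max - f_min`` is taken over the steady-state window only, so
    the ramp-up transient does not contaminate the reported amplitude.
    """

    times: np.ndarray
    force: np.ndarray
    f_max: float
    f_min: float
    delta_f: float

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.times, "force_n": self.force}).to_csv(
            path, index=False
        )


def build_waveform(
    protocol: LoadingProtocol, sample_rate: float | None = None
) -> DisplacementTrace:
    """Synthesize the commanded displacement waveform for one loading run.

    Parameters
    ----------
    protocol : LoadingProtocol
    sample_rate : float, optional
        Samples per second.  Defaults to 100x the oscillation frequency capped
        at 10 kHz.  Must be at least 20x the frequency so extrema are resolved.

    Returns
    -------
    DisplacementTrace
        ``u(t) >= 0`` everywhere; steady-state peak-to-peak equals
        ``protocol.alpha`` up to sampling error; the envelope never overshoots
        ``alpha + beta``.
    """
    if sample_rate is None:
        sample_rate = protocol.default_sample_rate()
    if sample_rate < 20.0 * protocol.freq:
        raise ValueError(
            f"sample_rate {sample_rate:g} Hz is below the required "
            f"20 x freq = {20.0 * protocol.freq:g} Hz (Nyquist-style bound "
            "for resolving oscillation extrema)"
        )
    n = int(np.floor(protocol.duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    ramp = 1.0 - np.exp(-t / protocol.tau1)
    osc = 0.5 * protocol.alpha * (1.0 - np.cos(2.0 * np.pi * protocol.freq * t))
    offset = protocol.beta * (1.0 - np.exp(-t / protocol.tau2))
    return DisplacementTrace(times=t, u=ramp * osc + offset, protocol=protocol)


def calibrate_stiffness(pairs) -> ContactModel:
    """Fit the contact stiffness from (alpha um, deltaF N) calibration pairs.

    The stiffness is the through-origin least-squares slope of deltaF on
    alpha, ``k = sum(alpha * deltaF) / sum(alpha**2)``.
    """
    pairs = tuple((float(a), float(df)) for a, df in pairs)
    if not pairs:
        raise ValueError("at least one (alpha, deltaF) calibration pair is required")
    alphas = np.array([p[0] for p in pairs])
    forces = np.array([p[1] for p in pairs])
    if (alphas <= 0).any() or (forces <= 0).any():
        raise ValueError("calibration pairs must be strictly positive")
    stiffness = float(np.dot(alphas, forces) / np.dot(alphas, alphas))
    return ContactModel(stiffness=stiffness, calibration_pairs=pairs)


def default_contact_model() -> ContactModel:
    """Contact model calibrated on the four measured (alpha, deltaF) pairs."""
    return calibrate_stiffness(CALIBRATION_PAIRS)


def force_trace(disp: DisplacementTrace, contact: ContactModel) -> ForceTrace:
    """Convert a displacement trace to force via the linear contact model.

    Raises
    ------
    ValueError
        If any force sample is non-positive (violation of the anti-tensile
        design: the platen must stay in compression for the whole run).
    """
    preload = disp.protocol.preload
    force = preload + contact.stiffness * disp.u
    if (force <= 0).any():
        i = int(np.argmax(force <= 0))
        raise ValueError(
            "anti-tensile contract violated: non-positive force "
            f"{force[i]:g} N at t = {disp.times[i]:g} s"
        )
    mask = disp.steady_state_mask()
    window = force[mask] if mask.any() else force
    f_max = float(window.max())
    f_min = float(window.min())
    return ForceTrace(
        times=disp.times,
        force=force,
        f_max=f_max,
        f_min=f_min,
        delta_f=f_max - f_min,
    )


def count_cycles(trace: DisplacementTrace) -> int:
    """Count completed oscillation cycles from midline crossings.

    The slow envelope (ramp-up and compressive offset) is removed with a
    centered moving average over one oscillation period; a completed cycle is
    one upward plus one downward crossing of the detrended signal through zero.
    """
    period_samples = max(
        int(round(1.0 / (trace.protocol.freq * (trace.times[1] - trace.times[0])))), 2
    )
    kernel = np.ones(period_samples) / period_samples
    # pad by edge values so the rolling mean stays centered at the boundaries
    padded = np.pad(trace.u, period_samples // 2, mode="edge")
    trend = np.convolve(padded, kernel, mode="same")[
        period_samples // 2 : period_samples // 2 + len(trace.u)
    ]
    detrended = trace.u - trend
    signs = np.sign(detrended)
    signs = signs[signs != 0]
    crossings = int(np.count_nonzero(np.diff(signs)))
    return crossings // 2
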