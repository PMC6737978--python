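"""Synthetic-experiment simulator: dishes of cells under the two study designs.

Experiment 1 probes large displacement amplitudes at fixed frequency
(alpha = 40/70/100/130 um, f = 30 Hz, t = 210/300 s); Experiment 2 probes a
small amplitude across frequencies and short durations (alpha = 10 um,
f = 0.1/1/5/10/30 Hz, t = 30/60/90 s).  Both run two breast-cancer lines
(BT-474, MDA-MB-231) in three groups — medium-only "DMEM", gel overlay
without loading "w/o MS", and loaded "w/ MS" — with n = 3 replicate dishes.

Each simulated dish scatters cells uniformly in area over the dish, computes
the condition's dissipated energy density through the mechanics and
viscoelastic modules, maps it to per-cell outcome probabilities through the
damage model (radius-dependent via peripheral shear amplification), and draws
one categorical outcome per cell.  One RNG stream per dish is derived from
the master seed and a stable condition hash, so any subset of dishes reruns
identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .damage import DamageParams, effective_energy, outcome_probability_vectors
from .mechanics import PlatenGeometry, strain_amplitude
from .viscoelastic import ViscoelasticModel, total_energy

__all__ = [
    "Condition",
    "experiment_design",
    "condition_energy",
    "simulate_dish",
    "simulate_study",
    "CELL_LINES",
    "GROUPS",
    "TABLE_COLUMNS",
]

CELL_LINES = ("BT-474", "MDA-MB-231")
GROUPS = ("DMEM", "w/o MS", "w/ MS")
GROUP_LOADED = "w/ MS"

EXPERIMENT_1 = {"alphas": (40.0, 70.0, 100.0, 130.0), "freqs": (30.0,), "durations": (210.0, 300.0)}
EXPERIMENT_2 = {"alphas": (10.0,), "freqs": (0.1, 1.0, 5.0, 10.0, 30.0), "durations": (30.0, 60.0, 90.0)}

N_REPLICATES = 3

#: Default cells scattered per dish; roughly 2000 land in each region readout
#: under uniform-in-area placement (center holds ~34% of the dish area).
CELLS_PER_DISH = 4000

TABLE_COLUMNS = [
    "cell_line",
    "group",
    "alpha_um",
    "freq_hz",
    "duration_s",
    "region",
    "replicate",
    "n_total",
    "n_caspase",
    "n_pi",
    "n_double",
]


@dataclass(frozen=True)
class Condition:
    """One dish: cell line, treatment group, loading parameters, replicate.

    Control groups (DMEM, w/o MS) carry zero loading parameters.
    """

    cell_line: str
    group: str
    alpha: float  # um; 0 for controls
    freq: float  # Hz; 0 for controls
    duration: float  # s; 0 for controls
    replicate: int
    cells_per_dish: int = CELLS_PER_DISH

    def __post_init__(self) -> None:
        if self.cell_line not in CELL_LINES:
            raise ValueError(f"unknown cell line {self.cell_line!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.group != GROUP_LOADED and (self.alpha or self.freq or self.duration):
            raise ValueError("control conditions carry no loading parameters")
        if not 1 <= self.replicate <= N_REPLICATES:
            raise ValueError(f"replicate must be in 1..{N_REPLICATES}")
        if self.cells_per_dish < 1:
            raise ValueError("cells_per_dish must be >= 1")

    @property
    def loaded(self) -> bool:
        return self.group == GROUP_LOADED

    def key(self) -> str:
        return (
            f"{self.cell_line}|{self.group}|{self.alpha:g}|{self.freq:g}|"
            f"{self.duration:g}|{self.replicate}"
        )


def experiment_design(
    which: int, cells_per_dish: int = CELLS_PER_DISH
) -> list[Condition]:
    """Full dish list for one experiment: loaded conditions plus controls.

    Experiment 1 yields 2 lines x 4 alpha x 2 t x 3 replicates = 48 loaded
    dishes; Experiment 2 yields 2 x 5 f x 3 t x 3 = 90.  Each line adds 3
    DMEM and 3 w/o MS control dishes.
    """
    if which == 1:
        grid = EXPERIMENT_1
    elif which == 2:
        grid = EXPERIMENT_2
    else:
        raise ValueError(f"unknown experiment id {which!r}; expected 1 or 2")
    conditions: list[Condition] = []
    for line in CELL_LINES:
        for group in ("DMEM", "w/o MS"):
            for rep in range(1, N_REPLICATES + 1):
                conditions.append(
                    Condition(line, group, 0.0, 0.0, 0.0, rep, cells_per_dish)
                )
        for alpha in grid["alphas"]:
            for freq in grid["freqs"]:
                for dur in grid["durations"]:
                    for rep in range(1, N_REPLICATES + 1):
                        conditions.append(
                            Condition(
                                line, GROUP_LOADED, alpha, freq, dur, rep,
                                cells_per_dish,
                            )
                        )
    return conditions


def condition_energy(
    cond: Condition,
    model: ViscoelasticModel,
    geom: PlatenGeometry,
    variant: str = "loss-modulus",
) -> float:
    """Bulk dissipated energy density W for one condition, J/m^3 (0 for controls)."""
    if not cond.loaded:
        return 0.0
    eps0 = strain_amplitude(cond.alpha, geom)
    return total_energy(model, cond.freq, cond.duration, eps0, variant).w_total


def _dish_rng(cond: Condition, seed: int) -> np.random.Generator:
    # stable per-dish stream: master seed + CRC32 of the condition key
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(cond.key().encode())])
    )


def simulate_dish(
    cond: Condition,
    params: DamageParams,
    geom: PlatenGeometry,
    model: ViscoelasticModel,
    seed: int,
) -> pd.DataFrame:
    """Simulate one dish; returns per-cell records (r_mm, caspase_pos, pi_pos).

    Radial positions are uniform in area over the dish; each cell's stain
    outcome is a single categorical draw from the damage model evaluated at
    its effective energy.  Identical (condition, seed) give identical output.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    rng = _dish_rng(cond, seed)
    n = cond.cells_per_dish
    r = geom.dish_radius * np.sqrt(rng.random(n))  # uniform in area
    w_total = condition_energy(cond, model, geom)
    w_eff = effective_energy(w_total, r, cond.cell_line, params, geom)
    probs = outcome_probability_vectors(w_eff, params)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(n)
    outcome = (u[:, None] > cum).sum(axis=1)  # 0 none, 1 early, 2 late, 3 nec
    return pd.DataFrame(
        {
            "r_mm": r,
            "caspase_pos": np.isin(outcome, (1, 2)),
            "pi_pos": np.isin(outcome, (2, 3)),
        }
    )


def simulate_study(
    which: int,
    params: DamageParams | None = None,
    geom: PlatenGeometry | None = None,
    model: ViscoelasticModel | None = None,
    seed: int = 0,
    cells_per_dish: int = CELLS_PER_DISH,
    conditions: list[Condition] | None = None,
) -> pd.DataFrame:
    """Simulate a whole experiment into a region-stratified count table.

    Returns a tidy table with one row per (condition, replicate, region):
    columns ``cell_line, group, alpha_um, freq_hz, duration_s, region,
    replicate, n_total, n_caspase, n_pi, n_double``.  Write with
    ``df.to_csv(path, index=False)``.
    """
    params = params if params is not None else DamageParams()
    geom = geom if geom is not None else PlatenGeometry()
    model = model if model is not None else ViscoelasticModel()
    if conditions is None:
        conditions = experiment_design(which, cells_per_dish)
    rows = []
    for cond in conditions:
        cells = simulate_dish(cond, params, geom, model, seed)
        in_periph = cells["r_mm"].to_numpy() >= geom.region_boundary
        for region, mask in (("center", ~in_periph), ("peripheral", in_periph)):
            sub = cells[mask]
            casp = sub["caspase_pos"].to_numpy()
            pi = sub["pi_pos"].to_numpy()
            rows.append(
                {
                    "cell_line": cond.cell_line,
                    "group": cond.group,
                    "alpha_um": cond.alpha,
                    "freq_hz": cond.freq,
                    "duration_s": cond.duration,
                    "region": region,
                    "replicate": cond.replicate,
                    "n_total": int(len(sub)),
                    "n_caspase": int(casp.sum()),
                    "n_pi": int(pi.sum()),
                    "n_double": int((casp & pi).sum()),
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
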