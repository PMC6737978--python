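"""Readout analysis: death rates, summaries, radial profiles, trends, recovery.

Rates follow the staining arithmetic of the assay: apoptosis rate =
100 * n_caspase / n_total, necrosis rate = 100 * n_pi / n_total, late
(double-positive) rate = 100 * n_double / n_total.  Summaries are mean +/-
sample s.d. over replicate dishes.  The radial profile bins per-cell records
by dish radius and correlates bin rate with mid-radius.  Damage-model
parameters are recovered from count tables by maximizing the multinomial
likelihood of the four mutually exclusive stain categories
(none / caspase-only / double / PI-only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import xlogy

from .damage import DamageParams, outcome_probability_vectors
from .mechanics import PlatenGeometry
from .synthetic import Condition, condition_energy
from .viscoelastic import ViscoelasticModel

__all__ = [
    "compute_rates",
    "summarize",
    "RadialProfile",
    "radial_profile",
    "trend_checks",
    "RecoveryReport",
    "fit_damage_params",
    "two_way_anova",
    "FREE_PARAM_NAMES",
]

CONDITION_KEYS = ["cell_line", "group", "alpha_um", "freq_hz", "duration_s", "region"]
RATE_COLUMNS = ["apoptosis_rate", "necrosis_rate", "late_rate"]

#: Damage parameters the maximum-likelihood refit can free.
FREE_PARAM_NAMES = ("w_nec", "h_nec", "w_apo", "a_max", "kappa")


def compute_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row death rates (%) from a region-stratified count table."""
    bad = table["n_total"] < 1
    if bad.any():
        rows = table.index[bad].tolist()
        raise ValueError(f"rows with zero counted cells: {rows}")
    out = table.copy()
    out["apoptosis_rate"] = 100.0 * table["n_caspase"] / table["n_total"]
    out["necrosis_rate"] = 100.0 * table["n_pi"] / table["n_total"]
    out["late_rate"] = 100.0 * table["n_double"] / table["n_total"]
    return out


def summarize(rates: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample s.d. (n-1 denominator) over replicates per condition.

    Single-replicate conditions report the value as the mean and NaN s.d.
    """
    grouped = rates.groupby(CONDITION_KEYS, sort=False)
    agg = grouped[RATE_COLUMNS].agg(["mean", "std", "count"])
    agg.columns = [f"{rate}_{statname}" for rate, statname in agg.columns]
    agg = agg.rename(
        columns={f"{r}_count": "n_replicates" for r in RATE_COLUMNS[:1]}
    )
    agg = agg.drop(
        columns=[f"{r}_count" for r in RATE_COLUMNS[1:]], errors="ignore"
    )
    return agg.reset_index()


@dataclass(frozen=True)
class RadialProfile:
    """PI-positivity rate per radial bin, with the radius-rate correlation."""

    bin_mid: np.ndarray  # mm
    rate: np.ndarray  # %
    n_cells: np.ndarray
    correlation: float | None
    p_value: float | None
    method: str

    @property
    def computable(self) -> bool:
        return self.correlation is not None


def radial_profile(
    cells: pd.DataFrame,
    bin_width: float = 1.0,
    geom: PlatenGeometry | None = None,
    method: str = "pearson",
) -> RadialProfile:
    """Bin per-cell records by radius and correlate bin rate with mid-radius.

    Empty bins are dropped.  The correlation is reported as not computable
    (None) when fewer than 2 non-empty bins remain or the rates have zero
    variance (e.g. every cell PI-positive).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0 mm")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    geom = geom if geom is not None else PlatenGeometry()
    edges = np.arange(0.0, geom.dish_radius + bin_width, bin_width)
    edges[-1] = max(edges[-1], geom.dish_radius)
    r = cells["r_mm"].to_numpy()
    pi = cells["pi_pos"].to_numpy().astype(float)
    idx = np.clip(np.digitize(r, edges) - 1, 0, len(edges) - 2)
    n = np.bincount(idx, minlength=len(edges) - 1)
    hits = np.bincount(idx, weights=pi, minlength=len(edges) - 1)
    keep = n > 0
    mids = (0.5 * (edges[:-1] + edges[1:]))[keep]
    rate = 100.0 * hits[keep] / n[keep]
    corr = pval = None
    if keep.sum() >= 2 and np.ptp(rate) > 0 and np.ptp(mids) > 0:
        if method == "pearson":
            res = stats.pearsonr(mids, rate)
        else:
            res = stats.spearmanr(mids, rate)
        corr, pval = float(res.statistic), float(res.pvalue)
    return RadialProfile(
        bin_mid=mids,
        rate=rate,
        n_cells=n[keep],
        correlation=corr,
        p_value=pval,
        method=method,
    )


def _pooled_sd(sds: np.ndarray) -> float:
    sds = sds[np.isfinite(sds)]
    if len(sds) == 0:
        return 0.0
    return float(np.sqrt(np.mean(sds**2)))


def trend_checks(summary: pd.DataFrame) -> dict:
    """Headline trend verdicts on a per-condition summary of loaded dishes.

    Each factor is judged at the whole-design level: necrosis means are first
    averaged over every other design dimension (cell line, region, the other
    loading factors) within each factor level, and the slack is the pooled
    replicate s.d. over all loaded conditions.  Pooling keeps the verdicts
    stable — per-slice triplicate s.d. estimates are far too noisy to gate a
    boolean on.

    * ``force_monotone`` / ``time_monotone``: level means non-decreasing
      across alpha / duration, allowing one pooled s.d. of slack per step.
    * ``frequency_flat``: level means span at most two pooled s.d. across
      frequency.

    Factors with fewer than two levels are skipped with a notice; their
    verdict is None.
    """
    loaded = summary[summary["group"] == "w/ MS"]
    notes: list[str] = []
    slack = _pooled_sd(loaded["necrosis_rate_std"].to_numpy())

    def check(factor: str, mode: str) -> bool | None:
        levels = loaded.groupby(factor, sort=True)["necrosis_rate_mean"].mean()
        means = levels.to_numpy()
        if len(means) < 2:
            notes.append(f"{factor}: fewer than 2 levels, check skipped")
            return None
        if mode == "monotone":
            return bool(np.all(np.diff(means) >= -slack))
        return bool(means.max() - means.min() <= 2.0 * slack)

    return {
        "force_monotone": check("alpha_um", "monotone"),
        "time_monotone": check("duration_s", "monotone"),
        "frequency_flat": check("freq_hz", "flat"),
        "notes": notes,
    }


@dataclass(frozen=True)
class RecoveryReport:
    """Result of a maximum-likelihood damage-parameter refit."""

    params: DamageParams
    free: tuple[str, ...]
    rel_errors: dict | None  # per free parameter, only when truth supplied
    converged: bool
    n_iter: int
    nll: float
    message: str


def _region_nodes(geom: PlatenGeometry, region: str, n_nodes: int = 16):
    """Gauss-Legendre nodes/weights for area-uniform radial averaging."""
    if region == "center":
        lo, hi = 0.0, geom.region_boundary
    elif region == "peripheral":
        lo, hi = geom.region_boundary, geom.dish_radius
    else:
        raise ValueError(f"unknown region {region!r}")
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    # uniform-in-area <=> uniform in r^2
    u = 0.5 * (x + 1.0) * (hi**2 - lo**2) + lo**2
    return np.sqrt(u), w / 2.0


def fit_damage_params(
    table: pd.DataFrame,
    init: DamageParams,
    fixed: tuple[str, ...] = (),
    model: ViscoelasticModel | None = None,
    geom: PlatenGeometry | None = None,
    truth: DamageParams | None = None,
    n_nodes: int = 16,
) -> RecoveryReport:
    """Refit damage parameters by multinomial maximum likelihood.

    The four stain categories per row are reconstructed from the stored
    counts (none / caspase-only / double / PI-only); the expected category
    probabilities of a region row average the damage model over an
    area-uniform radial quadrature, so the likelihood is exactly consistent
    with the simulator.  Free parameters are ``FREE_PARAM_NAMES`` minus
    ``fixed``; positive parameters are optimized in log space, ``a_max`` in
    logit space.

    Requires at least two distinct loaded conditions (identifiability guard).
    Non-convergence is reported in the returned diagnostics, never silently.
    """
    model = model if model is not None else ViscoelasticModel()
    geom = geom if geom is not None else PlatenGeometry()
    free = tuple(p for p in FREE_PARAM_NAMES if p not in fixed)
    unknown = set(fixed) - set(FREE_PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")

    loaded_keys = table.loc[
        table["group"] == "w/ MS", ["alpha_um", "freq_hz", "duration_s"]
    ].drop_duplicates()
    if len(loaded_keys) < 2:
        raise ValueError(
            "need >= 2 distinct loaded conditions to identify dose-response "
            f"parameters, got {len(loaded_keys)}"
        )

    # aggregate replicates (iid within a condition/region cell)
    agg = (
        table.groupby(CONDITION_KEYS, sort=False)[
            ["n_total", "n_caspase", "n_pi", "n_double"]
        ]
        .sum()
        .reset_index()
    )
    n_double = agg["n_double"].to_numpy()
    n_early = agg["n_caspase"].to_numpy() - n_double
    n_pi_only = agg["n_pi"].to_numpy() - n_double
    n_none = agg["n_total"].to_numpy() - n_early - n_pi_only - n_double
    counts = np.column_stack([n_none, n_early, n_double, n_pi_only]).astype(float)
    if (counts < 0).any():
        raise ValueError("inconsistent counts: n_double > min(n_caspase, n_pi)")

    # precompute per-row radial nodes and bulk energies
    w_totals = np.empty(len(agg))
    radii = np.empty((len(agg), n_nodes))
    qweights = np.empty((len(agg), n_nodes))
    lines = agg["cell_line"].tolist()
    span = geom.dish_radius - geom.region_boundary
    for i, row in agg.iterrows():
        cond = Condition(
            cell_line=row["cell_line"],
            group=row["group"],
            alpha=row["alpha_um"],
            freq=row["freq_hz"],
            duration=row["duration_s"],
            replicate=1,
        )
        w_totals[i] = condition_energy(cond, model, geom)
        radii[i], qweights[i] = _region_nodes(geom, row["region"], n_nodes)
    shear_frac = np.maximum(0.0, radii - geom.region_boundary) / span
    detach = np.array([init.detach_scale[line] for line in lines])

    def unpack(z: np.ndarray) -> DamageParams:
        values = {}
        for name, zi in zip(free, z):
            if name == "a_max":
                values[name] = 1.0 / (1.0 + np.exp(-zi))
            else:
                values[name] = float(np.exp(zi))
        return replace(init, **values)

    def pack(p: DamageParams) -> np.ndarray:
        z = []
        for name in free:
            v = getattr(p, name)
            if name == "a_max":
                v = min(max(v, 1e-9), 1 - 1e-9)
                z.append(np.log(v / (1.0 - v)))
            else:
                if v <= 0:
                    raise ValueError(
                        f"cannot free {name}: initial value must be > 0"
                    )
                z.append(np.log(v))
        return np.asarray(z)

    def nll(z: np.ndarray) -> float:
        p = unpack(z)
        amp = 1.0 + p.kappa * shear_frac
        w_eff = np.minimum(w_totals[:, None] * amp, detach[:, None])
        probs = outcome_probability_vectors(w_eff.ravel(), p).reshape(
            len(agg), n_nodes, 4
        )
        pbar = np.einsum("ijk,ij->ik", probs, qweights)
        pbar = np.clip(pbar, 1e-300, 1.0)
        return float(-xlogy(counts, pbar).sum())

    z0 = pack(init)
    result = optimize.minimize(nll, z0, method="L-BFGS-B")
    fitted = unpack(result.x)
    rel_errors = None
    if truth is not None:
        rel_errors = {
            name: abs(getattr(fitted, name) - getattr(truth, name))
            / abs(getattr(truth, name))
            for name in free
        }
    return RecoveryReport(
        params=fitted,
        free=free,
        rel_errors=rel_errors,
        converged=bool(result.success),
        n_iter=int(result.nit),
        nll=float(result.fun),
        message=str(result.message),
    )


def two_way_anova(
    rates: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    response: str = "necrosis_rate",
) -> pd.DataFrame:
    """Convenience two-factor ANOVA table (statsmodels OLS, type-II SS).

    Offered for quick inspection of factor effects on the simulated rates;
    this is a standard-library fit, not a replication of any published
    ANOVA, and nothing downstream depends on it.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = rates.rename(columns={factor_a: "A", factor_b: "B"})
    fit = ols(f"{response} ~ C(A) * C(B)", data=df).fit()
    return sm.stats.anova_lm(fit, typ=2)
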