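"""Flat YAML configuration: loading protocol, geometry, viscoelastic model, damage params.

A config file is a single flat mapping; every key is optional and falls back
to the package defaults.  Example::

    alpha_um: 40
    freq_hz: 30
    duration_s: 300
    tau1_s: 1.0
    tau2_s: 1.0
    beta_um: 5.0
    preload_n: 0.2
    platen_diameter_mm: 34.2
    dish_radius_mm: 17.1
    region_boundary_mm: 10.0
    stack_height_mm: 2.0
    g_inst_pa: 2000.0
    g_relaxed_pa: 1000.0
    branches: [[1000.0, 1.0]]      # [weight_pa, tau_s] per Maxwell branch
    w_nec: 45.0
    h_nec: 3.0
    w_apo: 40.0
    a_max: 0.25
    late_w_half: 50.0
    late_slope: 1.5
    kappa: 2.0
    bg_apo: 0.001
    bg_nec: 0.004
    detach_scale: {BT-474: 3000.0, MDA-MB-231: 120.0}
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .damage import DamageParams
from .loading import LoadingProtocol
from .mechanics import PlatenGeometry
from .viscoelastic import ViscoelasticModel

__all__ = ["Config", "load_config", "default_config", "describe_params"]

_PROTOCOL_KEYS = {
    "alpha_um": "alpha",
    "freq_hz": "freq",
    "duration_s": "duration",
    "tau1_s": "tau1",
    "tau2_s": "tau2",
    "beta_um": "beta",
    "preload_n": "preload",
}
_GEOMETRY_KEYS = {
    "platen_diameter_mm": "platen_diameter",
    "dish_radius_mm": "dish_radius",
    "region_boundary_mm": "region_boundary",
    "stack_height_mm": "stack_height",
}
_DAMAGE_KEYS = (
    "w_nec",
    "h_nec",
    "w_apo",
    "a_max",
    "late_w_half",
    "late_slope",
    "kappa",
    "bg_apo",
    "bg_nec",
    "detach_scale",
)


@dataclass(frozen=True)
class Config:
    protocol: LoadingProtocol | None
    geometry: PlatenGeometry
    model: ViscoelasticModel
    damage: DamageParams


def default_config() -> Config:
    return Config(
        protocol=None,
        geometry=PlatenGeometry(),
        model=ViscoelasticModel(),
        damage=DamageParams(),
    )


def _build_model(raw: dict) -> ViscoelasticModel:
    kwargs = {}
    if "g_inst_pa" in raw:
        kwargs["g_inst"] = float(raw["g_inst_pa"])
    if "g_relaxed_pa" in raw:
        kwargs["g_relaxed"] = float(raw["g_relaxed_pa"])
    if "branches" in raw:
        branches = raw["branches"]
        kwargs["weights"] = tuple(float(b[0]) for b in branches)
        kwargs["relax_times"] = tuple(float(b[1]) for b in branches)
    return ViscoelasticModel(**kwargs)


def load_config(path) -> Config:
    """Load a flat YAML config, falling back to defaults for missing keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a flat mapping, got {type(raw).__name__}")

    protocol = None
    if any(k in raw for k in _PROTOCOL_KEYS):
        missing = [k for k in ("alpha_um", "freq_hz", "duration_s") if k not in raw]
        if missing:
            raise ValueError(f"protocol block incomplete: missing {missing}")
        protocol = LoadingProtocol(
            **{
                field: float(raw[key])
                for key, field in _PROTOCOL_KEYS.items()
                if key in raw
            }
        )
    geometry = PlatenGeometry(
        **{
            field: float(raw[key])
            for key, field in _GEOMETRY_KEYS.items()
            if key in raw
        }
    )
    model = _build_model(raw)
    damage_kwargs = {}
    for key in _DAMAGE_KEYS:
        if key in raw:
            if key == "detach_scale":
                damage_kwargs[key] = {
                    str(line): float(v) for line, v in raw[key].items()
                }
            else:
                damage_kwargs[key] = float(raw[key])
    damage = DamageParams(**damage_kwargs)
    return Config(protocol=protocol, geometry=geometry, model=model, damage=damage)


def describe_params(cfg: Config) -> str:
    """Human-readable dump of the active parameter set with provenance labels."""
    g = cfg.geometry
    m = cfg.model
    d = cfg.damage
    lines = [
        "# Geometry (measured rig dimensions)",
        f"platen_diameter_mm: {g.platen_diameter}",
        f"dish_radius_mm: {g.dish_radius}",
        f"region_boundary_mm: {g.region_boundary}",
        f"stack_height_mm: {g.stack_height}",
        "# Viscoelastic model (calibration placeholder, cell-rheology range)",
        f"g_inst_pa: {m.g_inst}",
        f"g_relaxed_pa: {m.g_relaxed}",
        f"branches: {[[w, tau] for w, tau in zip(m.weights, m.relax_times)]}",
        "# Damage dose-response (calibrated to qualitative anchors, not measured)",
        f"w_nec: {d.w_nec}",
        f"h_nec: {d.h_nec}",
        f"w_apo: {d.w_apo}",
        f"a_max: {d.a_max}",
        f"late_w_half: {d.late_w_half}",
        f"late_slope: {d.late_slope}",
        f"kappa: {d.kappa}",
        f"bg_apo: {d.bg_apo}",
        f"bg_nec: {d.bg_nec}",
        f"detach_scale: {d.detach_scale}",
    ]
    if cfg.protocol is not None:
        p = cfg.protocol
        lines = [
            "# Loading protocol",
            f"alpha_um: {p.alpha}",
            f"freq_hz: {p.freq}",
            f"duration_s: {p.duration}",
            f"tau1_s: {p.tau1}",
            f"tau2_s: {p.tau2}",
            f"beta_um: {p.beta}",
            f"preload_n: {p.preload}",
        ] + lines
    return "\n".join(lines)
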