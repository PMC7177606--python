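"""Structured-text (YAML) configuration for the UQ pipeline.

Every key has a shipped default: the three-layer child head at 900 MHz, the
64-electrode cap, the 30³ voxel grid, and the full-scale network
hyperparameters.  An empty file (or ``{}``) therefore yields the complete
default pipeline.  Unknown keys are rejected with the offending key path.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import yaml

from .doe import DEFAULT_DELTA, default_layout, fibonacci_cap_layout
from .forward import ForwardModelParams, TissueLayer, TissueModel, VoxelGrid
from .nets import AUTOENCODER_SPEC, REGRESSOR_SPEC, NetworkSpec
from .uq import PipelineConfig

__all__ = ["load_config", "save_config", "default_pipeline_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised with the key path of the offending configuration entry."""


_LAYOUT_KEYS = {"L", "radius_mm", "delta_rad", "delta_deg", "theta_max_rad", "cap_diameter_mm"}
_GRID_KEYS = {"n_per_axis", "extent_mm"}
_FORWARD_KEYS = {
    "attenuation_depth_mm",
    "bump_amplitude",
    "bump_width_mm",
    "base_field_amplitude_v_per_m",
    "electrode_depth_fraction",
    "rank_limited",
    "rank",
}
_SPEC_KEYS = {f.name for f in dataclasses.fields(NetworkSpec)}
_PIPE_KEYS = {
    "n_ae_train",
    "n_ae_test",
    "n_reg_train",
    "n_reg_test",
    "val_fraction",
    "n_ensemble",
    "seed",
}
_TOP_KEYS = {"layout", "tissue", "grid", "forward", "autoencoder", "regressor", "pipeline"}


def default_pipeline_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(
        layout=default_layout(),
        tissue=TissueModel.three_layer_child_900mhz(),
        grid=VoxelGrid(),
        forward_params=ForwardModelParams(),
        ae_spec=AUTOENCODER_SPEC,
        reg_spec=REGRESSOR_SPEC,
        seed=seed,
    )


def _check_keys(section: dict, allowed: set, path: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigError(f"unknown configuration key '{path}.{key}'")


def _build_layout(section: dict):
    _check_keys(section, _LAYOUT_KEYS, "layout")
    delta = section.get("delta_rad")
    if "delta_deg" in section:
        if delta is not None:
            raise ConfigError("layout: give delta_rad or delta_deg, not both")
        delta = math.radians(section["delta_deg"])
    if delta is None:
        delta = DEFAULT_DELTA
    if delta <= 0:
        raise ConfigError(f"layout.delta must be positive, got {delta}")
    try:
        return fibonacci_cap_layout(
            L=section.get("L", 64),
            radius_mm=section.get("radius_mm", 74.7),
            delta=delta,
            theta_max=section.get("theta_max_rad", math.pi / 2),
            cap_diameter_mm=section.get("cap_diameter_mm", 13.0),
        )
    except ValueError as exc:
        raise ConfigError(f"layout: {exc}") from exc


def _build_tissue(section) -> TissueModel:
    if not section:
        return TissueModel.three_layer_child_900mhz()
    if isinstance(section, dict):
        freq = section.get("frequency_mhz", 900.0)
        rows = section.get("layers")
        if rows is None:
            raise ConfigError("tissue: expected a 'layers' list")
    else:
        raise ConfigError("tissue: expected a mapping with 'layers'")
    try:
        layers = tuple(
            TissueLayer(
                name=r["name"],
                relative_permittivity=float(r["relative_permittivity"]),
                conductivity_s_per_m=float(r["conductivity_s_per_m"]),
                mass_density_kg_per_m3=float(r["mass_density_kg_per_m3"]),
                outer_radius_mm=float(r["outer_radius_mm"]),
            )
            for r in rows
        )
        return TissueModel(layers=layers, frequency_mhz=freq)
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"tissue.layers: {exc}") from exc


def _build_spec(section: dict, base: NetworkSpec, path: str) -> NetworkSpec:
    _check_keys(section, _SPEC_KEYS, path)
    kwargs = dict(section)
    if "hidden_widths" in kwargs:
        kwargs["hidden_widths"] = tuple(kwargs["hidden_widths"])
    try:
        return dataclasses.replace(base, **kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline configuration, applying shipped defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the configuration must be a mapping")
    _check_keys(raw, _TOP_KEYS, "<root>")

    layout = _build_layout(raw.get("layout", {}))
    tissue = _build_tissue(raw.get("tissue"))

    grid_sec = raw.get("grid", {})
    _check_keys(grid_sec, _GRID_KEYS, "grid")
    try:
        grid = VoxelGrid(**grid_sec)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"grid: {exc}") from exc

    f_sec = raw.get("forward", {})
    _check_keys(f_sec, _FORWARD_KEYS, "forward")
    try:
        forward = ForwardModelParams(**f_sec)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"forward: {exc}") from exc

    ae_spec = _build_spec(raw.get("autoencoder", {}), AUTOENCODER_SPEC, "autoencoder")
    reg_spec = _build_spec(raw.get("regressor", {}), REGRESSOR_SPEC, "regressor")

    p_sec = raw.get("pipeline", {})
    _check_keys(p_sec, _PIPE_KEYS, "pipeline")
    try:
        return PipelineConfig(
            layout=layout,
            tissue=tissue,
            grid=grid,
            forward_params=forward,
            ae_spec=ae_spec,
            reg_spec=reg_spec,
            **p_sec,
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"pipeline: {exc}") from exc


def _infer_theta_max(layout) -> float:
    # invert the Fibonacci-lattice cos-spacing from the last electrode
    L = layout.L
    c_min = math.cos(2 * layout.delta)
    c_last = math.cos(float(layout.theta[-1]))
    return math.acos(c_min + (c_last - c_min) * L / (L - 0.5)) if L > 1 else math.pi / 2


def _py(obj):
    """Recursively convert numpy scalars so yaml.safe_dump accepts the doc."""
    if isinstance(obj, dict):
        return {k: _py(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_py(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def save_config(cfg: PipelineConfig, path) -> None:
    """Serialize a PipelineConfig back to YAML (lossless roundtrip)."""
    doc = {
        "layout": {
            "L": cfg.layout.L,
            "radius_mm": cfg.layout.radius_mm,
            "delta_rad": cfg.layout.delta,
            "theta_max_rad": _infer_theta_max(cfg.layout),
            "cap_diameter_mm": cfg.layout.cap_diameter_mm,
        },
        "tissue": {
            "frequency_mhz": cfg.tissue.frequency_mhz,
            "layers": [dataclasses.asdict(l) for l in cfg.tissue.layers],
        },
        "grid": dataclasses.asdict(cfg.grid),
        "forward": dataclasses.asdict(cfg.forward_params),
        "autoencoder": {
            **dataclasses.asdict(cfg.ae_spec),
            "hidden_widths": list(cfg.ae_spec.hidden_widths),
        },
        "regressor": {
            **dataclasses.asdict(cfg.reg_spec),
            "hidden_widths": list(cfg.reg_spec.hidden_widths),
        },
        "pipeline": {
            "n_ae_train": cfg.n_ae_train,
            "n_ae_test": cfg.n_ae_test,
            "n_reg_train": cfg.n_reg_train,
            "n_reg_test": cfg.n_reg_test,
            "val_fraction": cfg.val_fraction,
            "n_ensemble": cfg.n_ensemble,
            "seed": cfg.seed,
        },
    }
    Path(path).write_text(yaml.safe_dump(_py(doc), sort_keys=False))
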