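"""Pipeline configuration: schema, defaults, loading and validation.

The whole pipeline is driven by one structured YAML (or JSON) document
with blocks ``device``, ``protocol``, ``generator``, ``solver`` and
``stats``.  Field names carry their units (``height_um``, ``dt_s``, ...).
Validation is eager: every run validates the full document before any
computation, and errors name the offending key path.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .device import ChannelGeometry, DeviceNetwork, HydraulicResistor
from .oxygen import DiffusionLayer, LayerStack
from .synthetic import BloodModelParams, CohortSpec, default_pressure_steps
from .viscometry import InversionSettings

__all__ = [
    "ConfigError",
    "default_config",
    "load_config",
    "validate_config",
    "config_hash",
    "network_from_config",
    "layer_stack_from_config",
    "inversion_settings_from_config",
    "blood_params_from_config",
    "cohort_spec_from_config",
    "write_default_config",
]


class ConfigError(ValueError):
    """Configuration document failed validation; message names the key path."""


def default_config() -> Dict[str, Any]:
    """The packaged default configuration as a plain dict.

    Channel geometries for the resistor region are illustrative (the real
    mask geometry is unpublished); they are chosen to be physically coherent
    with the published channel size and pressure range.
    """
    return {
        "device": {
            "profile_factor": 0.477,
            "velocity_rule": "continuity",
            "channels": {
                "inlet_resistor": {
                    "shape": "rectangular",
                    "height_um": 15.0,
                    "width_um": 45.0,
                    "length_mm": 50.0,
                },
                "bypass": {
                    "shape": "square",
                    "height_um": 15.0,
                    "width_um": 15.0,
                    "length_mm": 8.0,
                },
                "experimental": {
                    "shape": "square",
                    "height_um": 15.0,
                    "width_um": 15.0,
                    "length_mm": 8.0,
                },
            },
        },
        "protocol": {
            "pressure_steps_pa": [round(float(p), 3) for p in default_pressure_steps()],
            "oxygen_tensions_mmhg": [92.0, 46.0, 0.0],
            "step_duration_s": 20.0,
        },
        "generator": {
            # no default seed: stochastic commands must set one explicitly
            "noise_cv": 0.05,
            "replicates_per_step": 18,
            "blood": {
                "hct": 0.25,
                "mchc_g_dl": 33.0,
                "hbs": 1.0,
                "n_anchors": {"92": 0.76, "46": 0.74, "0": 0.87},
                "k_multipliers": {"92": 1.0, "46": 1.35, "0": 1.9},
                "k_oxygenated_pa_sn": 0.0151,
                "healthy_n": 0.76,
                "healthy_k_pa_sn": 0.012,
            },
            "cohort": {
                "n_patients": 9,
                "between_subject_sd": {"92": 0.075, "46": 0.049, "0": 0.056},
            },
        },
        "solver": {
            "fixed_point": {"tol": 1e-8, "max_iter": 100, "damping": 0.5,
                            "steady_state_fraction": 0.5},
            "diffusion": {
                "dz_um": 1.0,
                "dt_s": 0.05,
                "scheme": "implicit",
                "anoxia_threshold_mmhg": 2.0,
                "layers": [
                    {"name": "blood", "thickness_um": 15.0, "material": "water"},
                    {"name": "membrane_lower", "thickness_um": 100.0, "material": "pdms"},
                    {"name": "hydration", "thickness_um": 100.0, "material": "water"},
                    {"name": "membrane_upper", "thickness_um": 100.0, "material": "pdms"},
                ],
                "diffusion_coefficients_cm2_s": {"pdms": 3.3e-5, "water": 4.0e-5},
            },
        },
        "stats": {"alpha": 0.05, "posthoc": "sign_permutation"},
    }


def _req(cfg: Dict, path: str) -> Any:
    node: Any = cfg
    for key in path.split("."):
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(f"missing required config key {path!r}")
        node = node[key]
    return node


def _positive(cfg: Dict, path: str) -> float:
    v = _req(cfg, path)
    if not isinstance(v, (int, float)) or not math.isfinite(v) or v <= 0:
        raise ConfigError(f"config key {path!r} must be a positive number, got {v!r}")
    return float(v)


def validate_config(cfg: Dict[str, Any], require_seed: bool = False) -> Dict[str, Any]:
    """Validate the document, filling omitted blocks from the defaults.

    ``require_seed=True`` (any stochastic command) demands an explicit
    integer ``generator.seed``.
    """
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping at top level")
    merged = copy.deepcopy(default_config())

    def deep_update(base: Dict, upd: Dict, path: str = "") -> None:
        for k, v in upd.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                deep_update(base[k], v, f"{path}{k}.")
            else:
                base[k] = copy.deepcopy(v)

    deep_update(merged, cfg)

    # device block
    rule = _req(merged, "device.velocity_rule")
    if rule not in ("continuity", "area_proportional"):
        raise ConfigError(f"device.velocity_rule must be continuity|area_proportional, got {rule!r}")
    pf = _positive(merged, "device.profile_factor")
    if pf > 1:
        raise ConfigError("device.profile_factor must lie in (0, 1]")
    channels = merged["device"].get("channels")
    network = merged["device"].get("network")
    if channels is None and network is None:
        raise ConfigError("device block needs either 'channels' geometries or explicit 'network' constants")
    if channels is not None:
        for slot in ("inlet_resistor", "bypass", "experimental"):
            for field in ("height_um", "width_um", "length_mm"):
                _positive(merged, f"device.channels.{slot}.{field}")
            shape = _req(merged, f"device.channels.{slot}.shape")
            if shape not in ("square", "rectangular"):
                raise ConfigError(f"device.channels.{slot}.shape must be square|rectangular")
    if network is not None:
        for field in ("c1_per_m3", "c2_per_m3", "c3_per_m3"):
            _positive(merged, f"device.network.{field}")

    # protocol block
    steps = _req(merged, "protocol.pressure_steps_pa")
    if not isinstance(steps, (list, tuple)) or len(steps) == 0:
        raise ConfigError("protocol.pressure_steps_pa must be a non-empty list")
    if any((not isinstance(p, (int, float))) or p <= 0 for p in steps):
        raise ConfigError("protocol.pressure_steps_pa entries must be positive numbers")
    tensions = _req(merged, "protocol.oxygen_tensions_mmhg")
    if not isinstance(tensions, (list, tuple)) or len(tensions) == 0:
        raise ConfigError("protocol.oxygen_tensions_mmhg must be a non-empty list")
    _positive(merged, "protocol.step_duration_s")

    # generator block
    seed = merged["generator"].get("seed")
    if require_seed and not isinstance(seed, int):
        raise ConfigError("generator.seed must be an explicit integer for stochastic runs")
    cv = merged["generator"].get("noise_cv")
    if not isinstance(cv, (int, float)) or cv < 0:
        raise ConfigError("generator.noise_cv must be >= 0")
    reps = merged["generator"].get("replicates_per_step")
    if not isinstance(reps, int) or reps < 1:
        raise ConfigError("generator.replicates_per_step must be an integer >= 1")

    # solver block
    _positive(merged, "solver.fixed_point.tol")
    _positive(merged, "solver.diffusion.dz_um")
    _positive(merged, "solver.diffusion.dt_s")
    scheme = _req(merged, "solver.diffusion.scheme")
    if scheme not in ("implicit", "explicit"):
        raise ConfigError("solver.diffusion.scheme must be implicit|explicit")

    alpha = _req(merged, "stats.alpha")
    if not (isinstance(alpha, (int, float)) and 0 < alpha < 1):
        raise ConfigError("stats.alpha must lie in (0, 1)")

    return merged


def load_config(path: Optional[str] = None, require_seed: bool = False) -> Dict[str, Any]:
    """Load and validate a YAML/JSON config file; None loads the defaults."""
    if path is None:
        return validate_config({}, require_seed=require_seed)
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} failed to parse: {exc}") from exc
    if raw is None:
        raw = {}
    return validate_config(raw, require_seed=require_seed)


def config_hash(cfg: Dict[str, Any]) -> str:
    """Stable sha256 of the canonical JSON form, recorded in every run manifest."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"), default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _geometry_from(block: Dict[str, Any]) -> ChannelGeometry:
    return ChannelGeometry(
        height_m=block["height_um"] * 1e-6,
        width_m=block["width_um"] * 1e-6,
        length_m=block["length_mm"] * 1e-3,
        shape=block["shape"],
    )


def network_from_config(cfg: Dict[str, Any]) -> DeviceNetwork:
    """Build the resistor network from geometries or explicit constants."""
    dev = cfg["device"]
    channels = dev.get("channels")
    if channels is not None:
        return DeviceNetwork(
            inlet_resistor=HydraulicResistor.from_geometry(
                "inlet_resistor", _geometry_from(channels["inlet_resistor"])
            ),
            bypass=HydraulicResistor.from_geometry("bypass", _geometry_from(channels["bypass"])),
            experimental=HydraulicResistor.from_geometry(
                "experimental", _geometry_from(channels["experimental"])
            ),
        )
    net = dev["network"]
    geo = None
    exp_geo = net.get("experimental_channel")
    if exp_geo is not None:
        geo = _geometry_from(exp_geo)
    return DeviceNetwork(
        inlet_resistor=HydraulicResistor.from_constant("inlet_resistor", net["c1_per_m3"]),
        bypass=HydraulicResistor.from_constant("bypass", net["c2_per_m3"]),
        experimental=HydraulicResistor.from_constant("experimental", net["c3_per_m3"], geometry=geo),
    )


def layer_stack_from_config(cfg: Dict[str, Any]) -> LayerStack:
    diff = cfg["solver"]["diffusion"]
    d_map = diff["diffusion_coefficients_cm2_s"]
    layers = []
    for lyr in diff["layers"]:
        mat = lyr["material"]
        if mat not in d_map:
            raise ConfigError(f"no diffusion coefficient configured for material {mat!r}")
        layers.append(
            DiffusionLayer(
                name=lyr["name"],
                thickness_m=lyr["thickness_um"] * 1e-6,
                d_cm2_s=float(d_map[mat]),
                material=mat,
            )
        )
    return LayerStack(layers=tuple(layers))


def inversion_settings_from_config(cfg: Dict[str, Any]) -> InversionSettings:
    fp = cfg["solver"]["fixed_point"]
    return InversionSettings(
        profile_factor=cfg["device"]["profile_factor"],
        velocity_rule=cfg["device"]["velocity_rule"],
        tol=fp["tol"],
        max_iter=int(fp["max_iter"]),
        damping=fp["damping"],
        steady_state_fraction=fp["steady_state_fraction"],
    )


def _float_keys(d: Dict) -> Dict[float, float]:
    return {float(k): float(v) for k, v in d.items()}


def blood_params_from_config(cfg: Dict[str, Any]) -> BloodModelParams:
    b = cfg["generator"]["blood"]
    return BloodModelParams(
        n_anchors=_float_keys(b["n_anchors"]),
        k_multipliers=_float_keys(b["k_multipliers"]),
        k_oxygenated_pa_sn=float(b["k_oxygenated_pa_sn"]),
        healthy_n=float(b["healthy_n"]),
        healthy_k_pa_sn=float(b["healthy_k_pa_sn"]),
        noise_cv=float(cfg["generator"]["noise_cv"]),
    )


def cohort_spec_from_config(cfg: Dict[str, Any], seed: Optional[int] = None) -> CohortSpec:
    gen = cfg["generator"]
    if seed is None:
        seed = gen.get("seed")
    if seed is None:
        raise ConfigError("generator.seed must be an explicit integer for stochastic runs")
    return CohortSpec(
        n_patients=int(gen["cohort"]["n_patients"]),
        seed=int(seed),
        between_subject_sd=_float_keys(gen["cohort"]["between_subject_sd"]),
        pressure_steps_pa=tuple(float(p) for p in cfg["protocol"]["pressure_steps_pa"]),
        oxygen_tensions_mmhg=tuple(float(t) for t in cfg["protocol"]["oxygen_tensions_mmhg"]),
        replicates_per_step=int(gen["replicates_per_step"]),
    )


def write_default_config(path: str) -> None:
    """Write the packaged defaults as a commented-free YAML document."""
    Path(path).write_text(yaml.safe_dump(default_config(), sort_keys=False))
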