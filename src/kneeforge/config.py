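"""Workflow configuration: per-module defaults, YAML loading, hashing."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "synthbone": {
        # population model: number of latent modes and per-mode coefficient
        # spread (mm RMS surface displacement per unit coefficient)
        "k_latent": 6,
        "sd": 2.0,
        "scale_jitter": [0.92, 1.08],
        # pseudo-CT rasterization
        "spacing_mm": 1.0,
        "noise_sd_hu": 30.0,
        "pad_mm": 10.0,
        "cortical_hu": 700.0,
        "interior_hu": 300.0,
        "background_hu": 40.0,
        "shell_mm": 2.0,
    },
    "segment": {
        "threshold_hu": 200.0,
        "prob_threshold": 0.5,
        "min_area_mm2": 30.0,
        "marker_min_separation_mm": 10.0,
        "keep_components": 2,
        "smoothing_iters": 10,
    },
    "ssm": {
        "landmark_weight": 1.0,
        "var_threshold": 0.99,
        "nricp_outer_iters": 10,
        "stiffness_start": 10.0,
        "stiffness_end": 0.1,
        "correspondence_fail_mm": 5.0,
    },
    "fitting": {
        "ridge": 1.0,
        "trim_frac": 0.10,
        "iters": 25,
        "max_match_dist_mm": 5.0,
        "min_matches": 100,
        "end_frac": 0.28,  # model z-fraction matched to each extremity in ICP
        "rigid_max_iters": 50,
        "rigid_tol": 1e-6,
        "registration_fail_mm": 20.0,
    },
    "morpho": {
        "max_shift_mm": 5.0,
        "default_risk_weight": 0.8,
        "osteophyte_prone_weight": 0.2,
        "osteophyte_prone_names": [
            "Medial Epicondyle",
            "Lateral Epicondyle",
            "Medial Wear Point",
            "Lateral Wear Point",
        ],
    },
    "implant": {
        "pivot_ratio": 0.33,
        "distal_cut_mm": 9.0,
        "posterior_cut_mm": 8.0,
        "tibial_cut_mm": 8.0,
        "tibial_slope_deg": 3.0,
        "rim_offset_mm": 0.5,
        "posterior_retreat_mm": 3.0,
        "posterior_extent_frac": 0.20,
        "fillet_radius_mm": 2.0,
        "stem_scale": 0.35,
        "femoral_rim_offset_mm": 0.25,
        "clearance_mm": 0.5,
        "congruence_factor": 2.0,
        "anterior_frac": 0.85,
        "rollback_angle_deg": 25.0,
        "zones": {
            "tibial": [["tibial_posterior", 0.35, 0.65]],
            "femoral": [
                ["femoral_anterior_proximal_a", 0.0, 0.05],
                ["femoral_notch", 0.42, 0.58],
                ["femoral_anterior_proximal_b", 0.95, 1.0],
            ],
        },
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional per-run YAML override file."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    """Stable digest: changes iff some configuration value changes."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()[:16]
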