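"""Pipeline configuration: defaults, YAML loading, hashing.

The defaults are the published operating point of the method: the highCV
threshold at the upper 50% of the 2nd-98th percentile robust range, the 5%
low-intensity strip at the bolus peak, the 600e-6 mm^2/s ADC core threshold,
the 4.5 s / 9.5 s TTP-delay compartments and the 0.963 collateral cutoff.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Dict

import yaml

from .errors import ConfigurationError

DEFAULTS: Dict[str, Any] = {
    # CV / highCV extraction
    "robust_lower_pct": 2.0,
    "robust_upper_pct": 98.0,
    "highcv_range_fraction": 0.5,   # keep the upper 50% of the robust range
    "strip_fraction": 0.05,         # lowest 5% of signal at the bolus peak
    "strip_scope": "highcv",        # quantile over highCV voxels ("highcv"|"brain")
    # lesion thresholds
    "adc_core_threshold": 600e-6,   # mm^2/s
    "adc_units": "auto",            # "auto" | "1e-6 mm2/s" | "mm2/s"
    "delay_at_risk_s": 4.5,
    "delay_severe_s": 9.5,
    "min_component_mm3": 300.0,
    "restrict_perfusion_to_affected": True,
    # collateral dichotomization
    "cvi_cutoff": 0.963,
    # geometry / registration
    "left_right_axis": 0,
    "affected_side": None,          # "left" | "right", mandatory per case
    "tr": None,                     # seconds; fallback when pixdim[4] is zero
    "assume_registered": False,
    "motion_correction": True,
    "registration_metric": "correlation",  # or "mutual_information"
}


def load_config(path=None, **overrides) -> Dict[str, Any]:
    """Merge defaults, an optional YAML file and keyword overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(Path(path)) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"config {path} is not a mapping")
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    for key, value in overrides.items():
        if value is None:
            continue
        if key not in DEFAULTS:
            raise ConfigurationError(f"unknown config key: {key}")
        cfg[key] = value
    return cfg


def config_hash(cfg: Dict[str, Any]) -> str:
    """Stable short hash of the effective configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
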