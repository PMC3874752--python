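"""YAML configuration loading for the CLI."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from laphase.errors import ConfigError
from laphase.pipeline import PipelineConfig
from laphase.synthetic import CohortConfig, GroupParams


def _group_params(d: dict, defaults: GroupParams) -> GroupParams:
    kwargs = {}
    for var in ("lav_min", "lav_max", "lav_ac", "lvedp"):
        if var in d:
            pair = d[var]
            if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
                raise ConfigError(f"group param {var} must be [mean, sd]")
            kwargs[var] = (float(pair[0]), float(pair[1]))
        else:
            kwargs[var] = getattr(defaults, var)
    return GroupParams(**kwargs)


_COHORT_SCALARS = {
    "n_patients": int,
    "prevalence_elevated": float,
    "noise_sd_rel": float,
    "lvedp_link": bool,
    "seed": int,
}
_COHORT_PAIRS = ("hr_mean_sd", "n_frames_range", "bsa_mean_sd")
_PIPELINE_SCALARS = {
    "method": str,
    "smooth_window": int,
    "flat_tol": float,
    "lvedp_threshold": float,
    "welch": bool,
    "n_replicates": int,
    "replicate_cases": int,
    "seed": int,
}


def cohort_config_from_dict(d: dict) -> CohortConfig:
    base = CohortConfig()
    kwargs: dict = {}
    for key, cast in _COHORT_SCALARS.items():
        if key in d:
            kwargs[key] = cast(d[key])
    for key in _COHORT_PAIRS:
        if key in d:
            pair = d[key]
            if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
                raise ConfigError(f"{key} must be a pair")
            kwargs[key] = tuple(type(getattr(base, key)[0])(v) for v in pair)
    if "elevated" in d:
        kwargs["elevated"] = _group_params(d["elevated"], base.elevated)
    if "normal" in d:
        kwargs["normal"] = _group_params(d["normal"], base.normal)
    if "correlation" in d:
        kwargs["correlation"] = np.asarray(d["correlation"], dtype=float)
    unknown = set(d) - set(_COHORT_SCALARS) - set(_COHORT_PAIRS) - {
        "elevated", "normal", "correlation"
    }
    if unknown:
        raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
    cfg = dataclasses.replace(base, **kwargs)
    cfg.validate()
    return cfg


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d or {})
    cohort = cohort_config_from_dict(d.pop("cohort", {}))
    kwargs: dict = {"cohort": cohort}
    for key, cast in _PIPELINE_SCALARS.items():
        if key in d:
            kwargs[key] = cast(d.pop(key))
    if d:
        raise ConfigError(f"unknown pipeline config keys: {sorted(d)}")
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def load_pipeline_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top-level YAML must be a mapping")
    return pipeline_config_from_dict(raw)
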