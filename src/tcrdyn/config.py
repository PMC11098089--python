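"""Structured run configuration: a small YAML/JSON file whose leaf keys are
mirrored by CLI flags (flags override the file).  Unknown keys are rejected
so typos fail loudly."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .params import TcrParams

_PARAM_KEYS = {"pd", "pr", "pv", "m"}
_TOP_KEYS = {
    "seed", "params", "n_genes", "n_tumors", "n_reps", "n_sets", "coarse",
    "pv_fixed", "out", "out_dir", "n_chroms", "chrom_length",
    "lesion_rate", "miscoding_prob", "expected_rule", "verbosity",
}


class ConfigError(ValueError):
    pass


def parse_config(path: str | None = None, **overrides) -> dict:
    """Load and validate a run configuration.

    ``overrides`` are flag values; entries that are ``None`` are ignored so
    file values survive unless a flag was actually given.
    """
    cfg: dict = {}
    if path is not None:
        p = Path(path)
        try:
            text = p.read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if p.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        elif p.suffix == ".json":
            data = json.loads(text)
        else:
            raise ConfigError(f"unsupported config extension {p.suffix!r} "
                              "(use .yaml, .yml or .json)")
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        cfg.update(data)
    for key, val in overrides.items():
        if val is None:
            continue
        if key in _PARAM_KEYS:
            cfg.setdefault("params", {})
            if not isinstance(cfg["params"], dict):
                raise ConfigError("'params' must be a mapping")
            cfg["params"][key] = val
        else:
            cfg[key] = val

    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "params" in cfg:
        if not isinstance(cfg["params"], dict):
            raise ConfigError("'params' must be a mapping")
        bad = set(cfg["params"]) - _PARAM_KEYS
        if bad:
            raise ConfigError(f"unknown parameter keys: {sorted(bad)}")
        try:
            cfg["params"] = TcrParams(**cfg["params"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid params: {exc}") from exc
    for key in ("seed", "n_genes", "n_tumors", "n_reps", "n_sets",
                "n_chroms", "chrom_length"):
        if key in cfg:
            try:
                cfg[key] = int(cfg[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{key} must be an integer") from exc
            if key != "seed" and cfg[key] <= 0:
                raise ConfigError(f"{key} must be positive")
    return cfg


def require_params(cfg: dict) -> TcrParams:
    if "params" not in cfg:
        raise ConfigError(
            "model parameters are required: give --pd/--pr/--pv/--m or a "
            "config file with a 'params' section"
        )
    return cfg["params"]
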