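"""Run configuration: a single YAML file drives a full experiment.

The 2x2(x2) scenario design needs structured configuration, so runs are
specified in one file rather than many flags.  Unknown keys are rejected;
defaults (ps_min = 0.10, d_min = 5, n_reps = 1000, hotspot quantiles 0.975
and 0.99) are applied and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

_LANDSCAPE_KEYS = {
    "kind", "n_rows", "n_cols", "agg_factor", "peak_height", "ridge_axis_col",
    "ridge_halfwidth", "band_halfspan", "lapse_rate", "noise_sd", "seed",
}
_SPECIES_KEYS = {"n_species", "size_mu", "size_sigma", "band_width_min",
                 "band_width_max", "patchy_fraction", "montane_fraction", "seed"}
_SCENARIO_FLAGS = {
    "dispersal": ("free", "bounded"),
    "ranges": ("coherent", "patchy"),
    "sizes": ("empirical", "standardized"),
}


class ConfigError(ValueError):
    """Itemized configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class RunConfig:
    landscape: dict = field(default_factory=dict)
    species: dict = field(default_factory=dict)
    scenarios: list[dict] = field(default_factory=list)
    n_reps: int = 1000
    seed: int = 0
    ps_min: float = 0.10
    d_min: float = 5.0
    quantiles: tuple[float, ...] = (0.975, 0.99)
    standardization_reps: int = 1000
    out_dir: str = "rangeshape_out"

    def __post_init__(self) -> None:
        if not self.scenarios:
            self.scenarios = _all_scenarios()


def _all_scenarios() -> list[dict]:
    return [
        {"dispersal": d, "ranges": r, "sizes": s}
        for d in ("free", "bounded")
        for r in ("coherent", "patchy")
        for s in ("empirical", "standardized")
    ]


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default, and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config_dict(raw)


def validate_config_dict(raw: dict) -> RunConfig:
    errors: list[str] = []
    known = {f.name for f in fields(RunConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown key: {key!r}")

    cfg = RunConfig()
    for f in fields(RunConfig):
        if f.name in raw:
            setattr(cfg, f.name, raw[f.name])
        else:
            logger.info("config default applied: %s = %r", f.name, getattr(cfg, f.name))

    for key in cfg.landscape:
        if key not in _LANDSCAPE_KEYS:
            errors.append(f"unknown landscape key: {key!r}")
    for key in cfg.species:
        if key not in _SPECIES_KEYS:
            errors.append(f"unknown species key: {key!r}")

    n_rows = cfg.landscape.get("n_rows", 64)
    n_cols = cfg.landscape.get("n_cols", 64)
    f_agg = cfg.landscape.get("agg_factor", 4)
    if f_agg < 1:
        errors.append("landscape.agg_factor must be >= 1")
    elif n_rows % f_agg or n_cols % f_agg:
        errors.append(
            f"landscape dims ({n_rows}x{n_cols}) not divisible by "
            f"agg_factor={f_agg}"
        )

    if cfg.n_reps < 1:
        errors.append("n_reps must be >= 1")
    if not 0 < cfg.ps_min:
        errors.append("ps_min must be > 0")
    if not 0 < cfg.d_min:
        errors.append("d_min must be > 0")
    cfg.quantiles = tuple(cfg.quantiles)
    for q in cfg.quantiles:
        if not 0 < q < 1:
            errors.append(f"quantile {q} not in (0, 1)")
    if cfg.species.get("n_species", 30) < 1:
        errors.append("species.n_species must be >= 1")

    if not cfg.scenarios:
        cfg.scenarios = _all_scenarios()
    for sc in cfg.scenarios:
        for flag, allowed in _SCENARIO_FLAGS.items():
            val = sc.get(flag)
            if val not in allowed:
                errors.append(f"scenario {sc}: {flag!r} must be one of {allowed}")
        for key in sc:
            if key not in _SCENARIO_FLAGS:
                errors.append(f"scenario {sc}: unknown key {key!r}")

    if errors:
        raise ConfigError(errors)
    return cfg
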