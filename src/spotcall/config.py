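"""Analysis configuration: every tunable threshold in one place.

Configurations load from a YAML file with three optional sections::

    columns:                # column mapping (or use preset: chipskipper)
      spot_id: Spot
      clone_id: Clone
      gene_name: Name
      category_source: Type
      signal_ch1: "Signal Ch1"
      signal_ch2: "Signal Ch2"
    patterns:               # control-recognition globs, case-insensitive
      spike_in: ["SPIKE*"]
      background: ["BG*"]
      negative_control: ["NEG*"]
    thresholds:
      ratio_k_sigma: 2.0
      background_offset: 0.0
      est_p_call_threshold: 0.60
      est_center: mean          # or median
      ratio_scale: linear       # or log2
      tendency_fraction: 0.5
      rel_error_threshold: 15.0
      sort_members: false
      pooled_background: false
      bg_ch1: null              # manual cut-off overrides
      bg_ch2: null
      ratio_lower: null
      ratio_upper: null
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Any

import yaml

from .io import PRESETS, Category, ColumnMap, ConfigurationError

__all__ = ["AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunables of the evaluation pipeline with their defaults."""

    column_map: ColumnMap = field(default_factory=lambda: PRESETS["chipskipper"])
    ratio_k_sigma: float = 2.0
    background_offset: float = 0.0
    pooled_background: bool = False
    est_p_call_threshold: float = 0.60
    est_center: str = "mean"
    ratio_scale: str = "linear"
    tendency_fraction: float = 0.5
    rel_error_threshold: float = 15.0
    sort_members: bool = False
    manual_bg_ch1: float | None = None
    manual_bg_ch2: float | None = None
    manual_ratio_lower: float | None = None
    manual_ratio_upper: float | None = None

    @property
    def manual_bg(self) -> tuple[float, float] | None:
        if self.manual_bg_ch1 is not None and self.manual_bg_ch2 is not None:
            return (self.manual_bg_ch1, self.manual_bg_ch2)
        return None

    @property
    def manual_ratio(self) -> tuple[float, float] | None:
        if self.manual_ratio_lower is not None and self.manual_ratio_upper is not None:
            return (self.manual_ratio_lower, self.manual_ratio_upper)
        return None


_THRESHOLD_KEYS = {
    "ratio_k_sigma": float,
    "background_offset": float,
    "pooled_background": bool,
    "est_p_call_threshold": float,
    "est_center": str,
    "ratio_scale": str,
    "tendency_fraction": float,
    "rel_error_threshold": float,
    "sort_members": bool,
    "bg_ch1": ("manual_bg_ch1", float),
    "bg_ch2": ("manual_bg_ch2", float),
    "ratio_lower": ("manual_ratio_lower", float),
    "ratio_upper": ("manual_ratio_upper", float),
}


def load_config(source: str | Path | IO[str]) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file or stream."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = yaml.safe_load(source) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("configuration must be a mapping")
    return config_from_dict(data)


def config_from_dict(data: dict[str, Any]) -> AnalysisConfig:
    cfg = AnalysisConfig()

    preset = data.get("preset")
    if preset is not None:
        try:
            cmap = PRESETS[str(preset).lower()]
        except KeyError:
            raise ConfigurationError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            ) from None
        cfg = replace(cfg, column_map=cmap)

    columns = data.get("columns")
    patterns = data.get("patterns")
    if columns is not None or patterns is not None:
        base = cfg.column_map
        kwargs: dict[str, Any] = {
            "spot_id": base.spot_id,
            "clone_id": base.clone_id,
            "gene_name": base.gene_name,
            "category_source": base.category_source,
            "signal_ch1": base.signal_ch1,
            "signal_ch2": base.signal_ch2,
            "block": base.block,
            "row": base.row,
            "col": base.col,
            "comment": base.comment,
            "category_patterns": dict(base.category_patterns),
        }
        if columns is not None:
            for key, value in dict(columns).items():
                if key not in kwargs or key == "category_patterns":
                    raise ConfigurationError(f"unknown column key {key!r}")
                kwargs[key] = str(value) if value is not None else None
        if patterns is not None:
            pat = {}
            for key, value in dict(patterns).items():
                try:
                    cat = Category(key)
                except ValueError:
                    raise ConfigurationError(f"unknown category {key!r}") from None
                pat[cat] = tuple(str(v) for v in value)
            kwargs["category_patterns"] = pat
        cfg = replace(cfg, column_map=ColumnMap(**kwargs))

    thresholds = data.get("thresholds") or {}
    updates: dict[str, Any] = {}
    for key, value in dict(thresholds).items():
        if key not in _THRESHOLD_KEYS:
            raise ConfigurationError(f"unknown threshold key {key!r}")
        spec = _THRESHOLD_KEYS[key]
        if isinstance(spec, tuple):
            attr, caster = spec
        else:
            attr, caster = key, spec
        updates[attr] = None if value is None else caster(value)
    if updates:
        cfg = replace(cfg, **updates)
    if cfg.est_center not in ("mean", "median"):
        raise ConfigurationError("est_center must be 'mean' or 'median'")
    if cfg.ratio_scale not in ("linear", "log2"):
        raise ConfigurationError("ratio_scale must be 'linear' or 'log2'")
    if not 0 < cfg.est_p_call_threshold <= 1:
        raise ConfigurationError("est_p_call_threshold must be in (0, 1]")
    return cfg
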