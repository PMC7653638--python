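"""Pipeline configuration: defaults, TOML loading, resolved-config serialization.

Keys mirror the stage modules::

    [rarity]       max_af = 0.01, use_popmax = false
    [vote]         min_informative = 4
    [vote.thresholds]  CADD = 20.0, SIFT = 0.05, ...
    [segregation]  allow_other_parent_carrier = false, chromosomes = "autosomes"
    [digenic]      require_all_affected = true, geneset_mode = "both_in_same_set"
    [pipeline]     max_missing_annotation_frac = 0.2
"""
from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .records import ConfigError

# Conventional published operating points of the seven predictors. Numeric
# entries are score cutoffs (SIFT: damaging at or BELOW the cutoff, all other
# numeric scores at or ABOVE it); list entries are the categorical calls that
# count as damaging.
DEFAULT_THRESHOLDS: dict[str, Any] = {
    "CADD": 20.0,
    "SIFT": 0.05,
    "PolyPhen2": 0.446,
    "LRT": ["D"],
    "MutationTaster": ["A", "D"],
    "GERP++": 2.0,
    "PhyloP": 1.5,
}

GENESET_MODES = ("both_in_same_set", "either", "off")


@dataclass
class PipelineConfig:
    rarity_max_af: float = 0.01
    rarity_use_popmax: bool = False
    vote_min_informative: int = 4
    vote_thresholds: dict[str, Any] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    seg_allow_other_parent_carrier: bool = False
    seg_chromosomes: str = "autosomes"  # "autosomes" or "all"
    digenic_require_all_affected: bool = True
    digenic_geneset_mode: str = "both_in_same_set"
    pipeline_max_missing_annotation_frac: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.rarity_max_af <= 1.0):
            raise ConfigError(f"rarity.max_af must be in (0, 1], got {self.rarity_max_af}")
        if self.vote_min_informative < 1 or self.vote_min_informative > 7:
            raise ConfigError(
                f"vote.min_informative must be in [1, 7], got {self.vote_min_informative}"
            )
        if self.digenic_geneset_mode not in GENESET_MODES:
            raise ConfigError(
                f"digenic.geneset_mode must be one of {GENESET_MODES}, "
                f"got {self.digenic_geneset_mode!r}"
            )
        if self.seg_chromosomes not in ("autosomes", "all"):
            raise ConfigError(
                f"segregation.chromosomes must be 'autosomes' or 'all', "
                f"got {self.seg_chromosomes!r}"
            )
        unknown = set(self.vote_thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ConfigError(f"unknown predictor(s) in thresholds: {sorted(unknown)}")


_SECTION_MAP = {
    ("rarity", "max_af"): "rarity_max_af",
    ("rarity", "use_popmax"): "rarity_use_popmax",
    ("vote", "min_informative"): "vote_min_informative",
    ("segregation", "allow_other_parent_carrier"): "seg_allow_other_parent_carrier",
    ("segregation", "chromosomes"): "seg_chromosomes",
    ("digenic", "require_all_affected"): "digenic_require_all_affected",
    ("digenic", "geneset_mode"): "digenic_geneset_mode",
    ("pipeline", "max_missing_annotation_frac"): "pipeline_max_missing_annotation_frac",
}


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Build a config from defaults, an optional TOML file, then overrides."""
    kwargs: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            try:
                raw = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        thresholds = dict(DEFAULT_THRESHOLDS)
        for section, content in raw.items():
            if not isinstance(content, dict):
                raise ConfigError(f"top-level key {section!r} is not a table")
            for key, value in content.items():
                if section == "vote" and key == "thresholds":
                    thresholds.update(value)
                    continue
                attr = _SECTION_MAP.get((section, key))
                if attr is None:
                    raise ConfigError(f"unknown config key {section}.{key}")
                kwargs[attr] = value
        kwargs["vote_thresholds"] = thresholds
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**kwargs)


def _toml_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise ConfigError(f"cannot serialize {value!r} to TOML")


def dump_config(cfg: PipelineConfig) -> str:
    """Serialize the resolved configuration as TOML (for run provenance)."""
    by_section: dict[str, list[tuple[str, Any]]] = {}
    for (section, key), attr in _SECTION_MAP.items():
        by_section.setdefault(section, []).append((key, getattr(cfg, attr)))
    lines: list[str] = []
    for section in ("rarity", "vote", "segregation", "digenic", "pipeline"):
        lines.append(f"[{section}]")
        for key, value in by_section.get(section, []):
            lines.append(f"{key} = {_toml_value(value)}")
        if section == "vote":
            lines.append("[vote.thresholds]")
            for name in sorted(cfg.vote_thresholds):
                lines.append(f'"{name}" = {_toml_value(cfg.vote_thresholds[name])}')
        lines.append("")
    return "\n".join(lines)
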