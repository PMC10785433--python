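"""Pipeline configuration: one YAML file drives a whole run.

The config names the input event files with their spike-in roles, selects a
gate variant, optionally overrides individual threshold values (cytometer
settings differ, so every cut is adjustable per channel), and carries
optimizer settings and seeds.  See ``examples/`` for a complete file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .fcs import DEFAULT_CHANNEL_ALIASES
from .gating import GateVariant, ThresholdSet, default_thresholds
from .model import OptimizerConfig, SampleRole

__all__ = ["SampleEntry", "PipelineConfig", "load_config", "build_thresholds"]


@dataclass(frozen=True)
class SampleEntry:
    path: Path
    role: SampleRole
    sample_id: str


@dataclass(frozen=True)
class PipelineConfig:
    experiment_id: str
    samples: tuple[SampleEntry, ...]
    gate_variant: GateVariant
    output_dir: Path
    seed: int = 0
    threshold_overrides: dict[str, Any] = field(default_factory=dict)
    channel_aliases: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ALIASES))
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    comparison_path: Path | None = None
    comparison_percent: bool = True


def _as_bounds(value: Any) -> tuple[float | None, float | None]:
    lo, hi = value
    return (None if lo is None else float(lo), None if hi is None else float(hi))


def build_thresholds(variant: GateVariant, overrides: dict[str, Any] | None = None) -> ThresholdSet:
    """Default thresholds for a variant with per-channel overrides applied."""
    base = default_thresholds(variant)
    if not overrides:
        return base
    fluor = dict(base.fluorescence)
    for ch, bounds in (overrides.get("fluorescence") or {}).items():
        fluor[ch] = _as_bounds(bounds)
    quality = dict(base.quality)
    for ch, bounds in (overrides.get("quality") or {}).items():
        quality[ch] = _as_bounds(bounds)
    return ThresholdSet(fluorescence=fluor, quality=quality)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline config file.

    Referenced sample files must exist at validation time; exactly one gate
    variant applies per run.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    base = path.parent

    samples = []
    for entry in raw.get("samples", []):
        p = Path(entry["path"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"{path}: sample file {p} does not exist")
        samples.append(SampleEntry(
            path=p,
            role=SampleRole(entry["role"]),
            sample_id=str(entry.get("id", p.stem)),
        ))
    if not samples:
        raise ValueError(f"{path}: no samples configured")

    aliases = dict(DEFAULT_CHANNEL_ALIASES)
    aliases.update(raw.get("channel_aliases") or {})
    opt = OptimizerConfig(**(raw.get("optimizer") or {}))
    out_dir = Path(raw.get("output_dir", "meioflow_out"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    comparison = raw.get("comparison") or {}
    comp_path = comparison.get("path")
    if comp_path is not None:
        comp_path = Path(comp_path)
        if not comp_path.is_absolute():
            comp_path = base / comp_path
        if not comp_path.exists():
            raise FileNotFoundError(f"{path}: comparison file {comp_path} does not exist")

    return PipelineConfig(
        experiment_id=str(raw.get("experiment_id", path.stem)),
        samples=tuple(samples),
        gate_variant=GateVariant(raw.get("gate_variant", "quality_rfp_gfp")),
        output_dir=out_dir,
        seed=int(raw.get("seed", 0)),
        threshold_overrides=raw.get("threshold_overrides") or {},
        channel_aliases=aliases,
        optimizer=opt,
        comparison_path=comp_path,
        comparison_percent=bool(comparison.get("percent", True)),
    )
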