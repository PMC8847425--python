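"""Structured pipeline configuration (YAML) with CLI-flag overrides."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pattern_calling import CallParameters
from .quantify import WindowSpec

__all__ = ["ConfigError", "PipelineConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


#: mark mode -> window mode; repressive methylation covers the gene body
#: plus flanks, promoter/enhancer acetylation is quantified upstream only.
MARK_MODES = {
    "methylation": "gene_body_flanked",
    "acetylation": "upstream_only",
}


@dataclass
class PipelineConfig:
    conditions: list[str] = field(
        default_factory=lambda: ["reference", "disease", "rescue"]
    )
    tracks: dict[str, dict[str, str]] = field(default_factory=dict)
    genes: str | None = None
    genes_format: str = "bed"
    peaks: str | None = None
    gmt: str | None = None
    enhancer_map: str | None = None
    chrom_sizes: str | None = None
    bin_size: int = 50
    mark_mode: str = "methylation"
    window: WindowSpec = field(default_factory=WindowSpec)
    params: CallParameters = field(default_factory=CallParameters)
    outdir: str = "dynamark_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) != 3:
            raise ConfigError("exactly three conditions required")
        if self.mark_mode not in MARK_MODES:
            raise ConfigError(f"unknown mark mode {self.mark_mode!r}")
        if self.window.mode != MARK_MODES[self.mark_mode]:
            self.window = WindowSpec(
                upstream_bp=self.window.upstream_bp,
                downstream_bp=self.window.downstream_bp,
                mode=MARK_MODES[self.mark_mode],
            )
        if self.bin_size <= 0:
            raise ConfigError("bin_size must be positive")

    def require(self, *names: str) -> None:
        """Fail fast if a subcommand's mandatory inputs are missing."""
        for name in names:
            if name == "tracks":
                for cond in self.conditions:
                    for channel in ("chip", "input"):
                        path = self.tracks.get(cond, {}).get(channel)
                        if not path:
                            raise ConfigError(
                                f"missing {channel} track for condition {cond!r}"
                            )
                        if not Path(path).exists():
                            raise ConfigError(f"track not found: {path}")
            else:
                path = getattr(self, name)
                if not path:
                    raise ConfigError(f"missing required input {name!r}")
                if not Path(path).exists():
                    raise ConfigError(f"{name} not found: {path}")

    def resolved(self) -> dict:
        """Plain-dict view written next to every run's outputs."""
        return {
            "conditions": list(self.conditions),
            "tracks": self.tracks,
            "genes": self.genes,
            "genes_format": self.genes_format,
            "peaks": self.peaks,
            "gmt": self.gmt,
            "enhancer_map": self.enhancer_map,
            "chrom_sizes": self.chrom_sizes,
            "bin_size": self.bin_size,
            "mark_mode": self.mark_mode,
            "window": {
                "upstream_bp": self.window.upstream_bp,
                "downstream_bp": self.window.downstream_bp,
                "mode": self.window.mode,
            },
            "params": {
                "alpha": self.params.alpha,
                "fc_min": self.params.fc_min,
                "consistency_alpha": self.params.consistency_alpha,
                "pseudocount": self.params.pseudocount,
            },
            "outdir": self.outdir,
            "seed": self.seed,
        }


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Load YAML config (optional) and apply non-None keyword overrides."""
    raw: dict = {}
    if path is not None:
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping: {path}")
    window_kw = raw.pop("window", {}) or {}
    params_kw = raw.pop("params", {}) or {}
    for key, value in overrides.items():
        if value is None:
            continue
        if key in ("alpha", "fc_min", "consistency_alpha", "pseudocount"):
            params_kw[key] = value
        elif key in ("upstream_bp", "downstream_bp"):
            window_kw[key] = value
        else:
            raw[key] = value
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(
            window=WindowSpec(**window_kw),
            params=CallParameters(**params_kw),
            **raw,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
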