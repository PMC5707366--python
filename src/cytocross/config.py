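"""Pipeline configuration: YAML key-value files over printed defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; threshold defaults are the study's."""

    # inputs (unset paths mean "simulate instead")
    counts: str | None = None
    conditions: str | None = None
    reads_dir: str | None = None
    peaks_dir: str | None = None
    annotation: str | None = None
    genome: str | None = None
    motifs: str | None = None
    # simulation
    simulate: bool = True
    preset: str = "reference"  # or "demo"
    seed: int = 0
    # thresholds
    induction_fc: float = 1.5
    induction_q: float = 0.05
    antagonism_dual_fc: float = 1.2
    synergy_ratio: float = 1.2
    additivity: str = "baseline_corrected"
    assisted_fc: float = 1.7
    assisted_p: float = 0.01
    enhancer_fc: float = 2.0
    enhancer_q: float = 0.1
    extension: int = 150
    scale_per: float = 1e7
    universe: str = "il6-or-dual"
    # output
    outdir: str = "cytocross_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in (
            "induction_fc",
            "induction_q",
            "antagonism_dual_fc",
            "synergy_ratio",
            "assisted_fc",
            "assisted_p",
            "enhancer_fc",
            "enhancer_q",
            "extension",
            "scale_per",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path) -> PipelineConfig:
    """Load YAML config; unspecified keys keep the printed defaults.

    Unknown keys raise an error listing every valid key.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"{path}: unknown config key(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    return PipelineConfig(**data)
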