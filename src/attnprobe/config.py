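"""Pipeline configuration with the conventional defaults.

Defaults: 9.5 A tertiary contact cutoff; exclusion windows of 4
positions for nucleotides and 6 for amino acids; agreement threshold
theta = 0.3 (set to None for the threshold-free variant); 15% of
molecules held out for testing; five nested training batches starting
at 20 molecules.  The effective configuration is serialized verbatim
into every output's provenance block.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    cutoff: float = 9.5
    window_rna: int = 4
    window_protein: int = 6
    theta: float | None = 0.3
    mask_policy: str = "band_excluded"
    classifier: str = "logistic"
    threshold: float = 0.5
    test_fraction: float = 0.15
    batch_start: int = 20
    n_batches: int = 5
    seed: int = 0
    classifier_hyperparameters: dict = field(default_factory=dict)

    def window_for(self, kind: str) -> int:
        if kind == "rna":
            return self.window_rna
        if kind == "protein":
            return self.window_protein
        raise ConfigError(f"unknown molecule kind {kind!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
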