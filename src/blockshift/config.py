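"""Refinement configuration with YAML round-tripping.

Defaults follow the tool's standard operating point: identity gate 0.5,
maximum shift 4, block non-gap fraction 0.5, contact cutoff 6.5 A,
combination weights w1 = w2 = 0.5.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .errors import InputError


@dataclass
class Config:
    mode: str = "O+G+M"
    max_shift: int = 4
    min_identity: float = 0.5
    min_block_fraction: float = 0.5
    w1: float = 0.5
    w2: float = 0.5
    contact_cutoff: float = 6.5
    min_separation: int = 2
    matrix_path: Optional[str] = None
    include_original_family: bool = False
    # score candidates against the starting alignment instead of the
    # working state updated by earlier accepted blocks
    freeze_state: bool = False
    seed: int = 0
    # profile construction knobs (applied as MSA filters)
    max_seq_identity: float = 0.94
    min_coverage: float = 0.0
    pseudocount_weight: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.w1 <= 1.0 or not 0.0 <= self.w2 <= 1.0:
            raise InputError("combination weights must lie in [0, 1]")
        if self.max_shift < 0:
            raise InputError("max_shift must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise InputError(f"unknown config keys: {', '.join(sorted(bad))}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def updated(self, **overrides) -> "Config":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return Config(**data)
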