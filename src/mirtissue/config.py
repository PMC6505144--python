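"""Single declarative configuration for the whole pipeline.

Defaults are the analysis thresholds of the study this package
re-implements: a 20-24 nt size window, up to 2 annotation mismatches, a
-30 kcal/mol hairpin stability cut-off with 2-nt duplex overhangs, 10-kb
cluster chaining and the 3.5 / 2.0 / 0.5 log10 RPM tissue-pattern rules.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import yaml


@dataclass
class AnalysisConfig:
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    trim_min_overlap: int = 3
    trim_error_rate: float = 0.1
    size_min: int = 20
    size_max: int = 24
    max_mismatch: int = 2
    mfe_threshold: float = -30.0
    min_overhang: int = 2
    cluster_max_gap: int = 10_000
    pattern_high: float = 3.5
    pattern_low: float = 2.0
    pattern_delta: float = 0.5
    pseudocount: float = 1.0
    bin_bp: int = 100_000
    min_reciprocal_overlap: float = 0.5
    cycle_len: int = 50
    seed: int = 0
    tissues: List[str] = field(
        default_factory=lambda: ["fat_body", "midgut", "ovary", "remainder"]
    )
    replicates: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.size_min <= self.size_max):
            raise ValueError("size window must satisfy 0 < min <= max")
        if self.max_mismatch < 0 or self.min_overhang < 0:
            raise ValueError("mismatch / overhang counts must be >= 0")
        if self.cluster_max_gap < 0 or self.pseudocount < 0:
            raise ValueError("cluster_max_gap and pseudocount must be >= 0")
        if not self.pattern_high > self.pattern_low:
            raise ValueError("pattern_high must exceed pattern_low")

    def libraries(self) -> List[Tuple[str, str, int]]:
        """(library name, tissue, replicate) in a fixed order."""
        return [
            (f"{t}_rep{r}", t, r)
            for t in self.tissues
            for r in range(1, self.replicates + 1)
        ]

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def fingerprint(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
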