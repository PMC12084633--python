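"""Shared analysis thresholds.

The defaults are the strict filter set used throughout the pipeline: a
junction-read floor of 5 per replicate, p < 0.05 and BH q < 0.05 together
with |dPSI| > 10% for differential splicing, p < 0.01 and |log2FC| > 2 for
differential expression, a pan-neuronal breadth of at least 123 of 126
neuron types, and a minimum of 5 significant events per (pair, type) cell
for global summaries (1 for per-pair heatmaps).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError


@dataclass(frozen=True)
class Thresholds:
    junction: int = 5
    p: float = 0.05
    q: float = 0.05
    dpsi: float = 0.10
    expr_p: float = 0.01
    expr_lfc: float = 2.0
    min_events: int = 5
    breadth: int = 123
    breadth_total: int = 126

    def __post_init__(self) -> None:
        for name in ("junction", "p", "q", "dpsi", "expr_p", "expr_lfc", "min_events", "breadth", "breadth_total"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be positive")
        if self.breadth > self.breadth_total:
            raise ConfigError("breadth threshold exceeds total cell count")


DEFAULT_THRESHOLDS = Thresholds()
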