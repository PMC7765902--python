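"""Permutation-null distributions with percentile queries."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class NullDistribution:
    """Replicate values of a summary statistic under a permutation null.

    The upper bound used throughout is the one-sided empirical 95th
    percentile: the smallest value v such that at least 95% of replicates
    are <= v (``numpy``'s ``inverted_cdf`` quantile). An observed statistic
    "exceeds" the null only when strictly greater than that bound.
    """

    values: np.ndarray
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.size == 0:
            raise ValueError("a null distribution needs at least one replicate")

    @property
    def reps(self) -> int:
        return int(self.values.size)

    def percentile(self, q: float) -> float:
        """Empirical q-th percentile (inverted CDF, no interpolation)."""
        return float(np.quantile(self.values, q / 100.0, method="inverted_cdf"))

    def upper_bound(self, level: float = 0.95) -> float:
        return self.percentile(level * 100.0)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def exceeds(self, observed: float, level: float = 0.95) -> bool:
        """Strict: observed equal to the bound does not exceed it."""
        return observed > self.upper_bound(level)

    def summary(self) -> dict:
        return {
            "reps": self.reps,
            "seed": self.seed,
            "mean": self.mean,
            "percentiles": {q: self.percentile(q) for q in (5, 25, 50, 75, 95, 97.5)},
            **self.meta,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")
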