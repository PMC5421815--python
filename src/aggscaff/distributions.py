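"""Cluster size distributions.

The central observable shared by the particle simulator, the rate
equations and the likelihood fit is the concentration ``c_n`` of clusters
of size ``n`` (in particles per unit area).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["SizeDistribution", "typical_size"]


@dataclass
class SizeDistribution:
    """Concentrations (and optionally raw counts) of clusters by size.

    ``sizes`` are cluster sizes in particles, ``concentrations`` the
    corresponding number concentrations (per a^2 in simulation units or per
    um^2 in physical units).  ``counts`` holds raw sampled counts when the
    distribution comes from simulation snapshots, in which case ``area``
    is the total sampled area (box area times number of snapshots).
    """

    sizes: np.ndarray
    concentrations: np.ndarray
    counts: np.ndarray | None = None
    area: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.sizes.shape != self.concentrations.shape:
            raise ValueError("sizes and concentrations must have equal length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != self.sizes.shape:
                raise ValueError("counts must align with sizes")

    @property
    def mass(self) -> float:
        """Total particle concentration sum(n * c_n)."""
        return float(np.sum(self.sizes * self.concentrations))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"size": self.sizes, "concentration": self.concentrations})
        if self.counts is not None:
            df["count"] = self.counts
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **metadata: Any) -> "SizeDistribution":
        counts = df["count"].to_numpy() if "count" in df.columns else None
        return cls(
            sizes=df["size"].to_numpy(),
            concentrations=df["concentration"].to_numpy(),
            counts=counts,
            metadata=metadata,
        )


def typical_size(d: SizeDistribution) -> float:
    """Particle-weighted mean cluster size <<n>> = sum(n^2 c_n)/sum(n c_n).

    This is the average size of the cluster a randomly chosen *particle*
    belongs to, which characterises where the mass of the distribution
    sits (large clusters dominate it even when they are rare).
    """
    n = d.sizes.astype(float)
    w = n * d.concentrations
    denom = w.sum()
    if not denom > 0:
        raise ValueError("empty size distribution: sum(n*c_n) must be positive")
    return float(np.sum(n * w) / denom)
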