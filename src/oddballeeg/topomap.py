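"""Topographic maps over the 6x7 analysis matrix and map-score statistics.

A participant's "map score" is the Pearson product-moment correlation between
their 42-electrode voltage map at the component latency and the healthy-group
grand-average map of the same modality. Scores below 0.6 (P3) or 0.7 (ERD)
are flagged as topographic deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["TopographyMap", "grand_average_map", "map_score", "flag_map",
           "group_map_correlation", "MAP_FLAG_THRESHOLDS"]

#: Flag a map when its score is strictly below the modality threshold.
MAP_FLAG_THRESHOLDS = {"P3": 0.6, "ERD": 0.7}


@dataclass
class TopographyMap:
    """Ordered voltages (uV) over the analysis matrix at a fixed latency."""

    values: np.ndarray
    labels: tuple[str, ...]
    modality: str                  # "P3" or "ERD"
    source: str = "unknown"        # participant id or "grand-average"
    latency_ms: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = tuple(self.labels)
        if self.values.shape != (42,) or len(self.labels) != 42:
            raise ValueError("topography map must hold exactly 42 electrodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")
        if self.modality not in MAP_FLAG_THRESHOLDS:
            raise ValueError(f"modality must be one of "
                             f"{sorted(MAP_FLAG_THRESHOLDS)}")

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"# modality={self.modality} source={self.source} "
                 f"latency_ms={self.latency_ms}"]
        lines += [f"{ch}\t{v:.10g}" for ch, v in zip(self.labels, self.values)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, modality: str,
                 source: str = "unknown") -> "TopographyMap":
        labels, values = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ch, v = line.split("\t")
            labels.append(ch)
            values.append(float(v))
        return cls(np.asarray(values), tuple(labels), modality, source)


def _check_compatible(a: TopographyMap, b: TopographyMap) -> None:
    if a.modality != b.modality:
        raise ValueError(f"mixed modalities: {a.modality} vs {b.modality}")
    if a.labels != b.labels:
        raise ValueError("maps are over different electrode sets/orders")


def grand_average_map(maps: Sequence[TopographyMap]) -> TopographyMap:
    """Element-wise mean of same-modality maps (grand average)."""
    if len(maps) < 2:
        raise ValueError("grand average needs at least 2 maps")
    for m in maps[1:]:
        _check_compatible(maps[0], m)
    values = np.mean([m.values for m in maps], axis=0)
    return TopographyMap(values, maps[0].labels, maps[0].modality,
                         source="grand-average", latency_ms=None)


def map_score(individual: TopographyMap, reference: TopographyMap) -> float:
    """Pearson correlation of the 42 paired electrode voltages."""
    _check_compatible(individual, reference)
    x = individual.values - individual.values.mean()
    y = reference.values - reference.values.mean()
    sx, sy = np.sqrt(x @ x), np.sqrt(y @ y)
    if sx < 1e-15 or sy < 1e-15:
        raise ValueError("map score undefined: a map has zero variance")
    return float(x @ y / (sx * sy))


def flag_map(score: float, modality: str) -> bool:
    """True when the map score is strictly below the modality threshold."""
    if not -1.0 - 1e-12 <= score <= 1.0 + 1e-12:
        raise ValueError("correlation score must lie in [-1, 1]")
    try:
        return score < MAP_FLAG_THRESHOLDS[modality]
    except KeyError:
        raise ValueError(f"unknown modality {modality!r}") from None


def group_map_correlation(group_a: Sequence[TopographyMap],
                          group_b: Sequence[TopographyMap]) -> float:
    """Correlation between the grand-average maps of two groups."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ga = grand_average_map(group_a) if len(group_a) > 1 else group_a[0]
    gb = grand_average_map(group_b) if len(group_b) > 1 else group_b[0]
    return map_score(ga, gb)
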