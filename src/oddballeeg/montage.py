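"""64-channel montage and the 6x7 analysis matrix.

The analysis matrix is the fronto-central-to-parieto-occipital 6x7 electrode
grid over which peak search and topographic map scoring operate. Its exact
membership is configurable (shipped as a plain-text file); the default covers
rows F, FC, C, CP, P and PO at 10-10/10-5 positions 5,3,1,z,2,4,6 (PO row:
PO7..PO8).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_MATRIX_ROWS = [
    ["F5", "F3", "F1", "Fz", "F2", "F4", "F6"],
    ["FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6"],
    ["C5", "C3", "C1", "Cz", "C2", "C4", "C6"],
    ["CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6"],
    ["P5", "P3", "P1", "Pz", "P2", "P4", "P6"],
    ["PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8"],
]

_EXTRA_CHANNELS = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F8", "FT7", "FT8", "T7", "T8", "TP7", "TP8",
    "P7", "P8", "O1", "Oz", "O2", "Iz",
]

#: The default 64 scalp labels: the 42 matrix electrodes plus 22 surrounding sites.
DEFAULT_SCALP_64: list[str] = [ch for row in _MATRIX_ROWS for ch in row] + _EXTRA_CHANNELS

VEOG = "VEOG"

# Approximate anterior->posterior row index per label prefix, used only to
# build smooth simulation weight maps (not a head model).
_ROW_OF_PREFIX = {"Fp": 0.0, "AF": 1.0, "F": 2.0, "FT": 3.0, "FC": 3.0,
                  "T": 4.0, "C": 4.0, "TP": 5.0, "CP": 5.0, "P": 6.0,
                  "PO": 7.0, "O": 8.0, "I": 9.0}


def grid_position(label: str) -> tuple[float, float]:
    """(anterior-posterior row, left-right column) for a 10-10/10-5 label."""
    prefix = "".join(c for c in label if c.isalpha() and c != "z")
    if label in ("Fz", "Cz", "Pz", "Oz", "Iz", "Fpz", "AFz", "FCz", "CPz", "POz"):
        prefix = label[:-1]
    row = _ROW_OF_PREFIX.get(prefix)
    if row is None:
        raise KeyError(f"unknown electrode label {label!r}")
    digits = "".join(c for c in label if c.isdigit())
    if not digits:
        col = 0.0
    else:
        k = int(digits)
        col = (k + 1) // 2 * (-1.0 if k % 2 else 1.0)
    return row, col


def gaussian_weight_map(labels: list[str], center: tuple[float, float],
                        sigma: float) -> np.ndarray:
    """Unit-peak Gaussian spatial weights on the schematic electrode grid."""
    pos = np.array([grid_position(c) for c in labels])
    d2 = ((pos - np.asarray(center)) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2.0 * sigma ** 2))
    return w / w.max()


@dataclass(frozen=True)
class AnalysisMatrix:
    """Ordered 42-electrode grid used for peak search and map export."""

    labels: tuple[str, ...]
    coords: tuple[tuple[int, int], ...]  # (row, col) grid coordinates

    def __post_init__(self) -> None:
        if len(self.labels) != 42:
            raise ValueError(f"analysis matrix needs exactly 42 labels, "
                             f"got {len(self.labels)}")
        if len(set(self.labels)) != 42:
            raise ValueError("analysis matrix labels must be unique")
        if len(self.coords) != 42:
            raise ValueError("need one (row, col) pair per label")

    @classmethod
    def default(cls) -> "AnalysisMatrix":
        labels, coords = [], []
        for r, row in enumerate(_MATRIX_ROWS):
            for c, ch in enumerate(row):
                labels.append(ch)
                coords.append((r, c))
        return cls(tuple(labels), tuple(coords))

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisMatrix":
        """Read a matrix definition: TSV lines ``label<TAB>row<TAB>col``."""
        labels, coords = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed matrix line: {line!r}")
            labels.append(parts[0])
            coords.append((int(parts[1]), int(parts[2])))
        return cls(tuple(labels), tuple(coords))

    def to_file(self, path: str | Path) -> None:
        lines = ["# analysis matrix: label\trow\tcol"]
        lines += [f"{ch}\t{r}\t{c}" for ch, (r, c) in zip(self.labels, self.coords)]
        Path(path).write_text("\n".join(lines) + "\n")

    def indices_in(self, ch_names: list[str]) -> np.ndarray:
        """Channel indices of the matrix electrodes, in matrix order."""
        missing = [ch for ch in self.labels if ch not in ch_names]
        if missing:
            raise KeyError(f"matrix electrodes missing from montage: {missing}")
        lookup = {ch: i for i, ch in enumerate(ch_names)}
        return np.array([lookup[ch] for ch in self.labels])


def default_matrix_file() -> Path:
    """Path of the packaged default matrix definition."""
    return Path(importlib.resources.files("oddballeeg") / "data" / "matrix_6x7.tsv")
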