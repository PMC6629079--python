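"""P3 identification on averaged ERPs.

The P3 is the global maximum positivity over the 6x7 analysis matrix within
a 300-450 ms search window; its topography is the matrix voltage vector
exported at that single peak latency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ERP, EvokedWaveform
from .montage import AnalysisMatrix
from .topomap import TopographyMap

__all__ = ["PeakMeasure", "PeakAtEdgeWarning", "find_p3",
           "amplitudes_at_latency"]


class PeakAtEdgeWarning(UserWarning):
    """The extremum sits on a search-window edge and may be truncated."""


@dataclass(frozen=True)
class PeakMeasure:
    """A located component extremum (latency ms, amplitude uV, electrode)."""

    latency_ms: float
    amplitude_uv: float
    electrode: str
    search_window: tuple[float, float]
    polarity: str  # "positive" or "negative"

    def __post_init__(self) -> None:
        lo, hi = self.search_window
        if not lo - 1e-9 <= self.latency_ms <= hi + 1e-9:
            raise ValueError("peak latency outside its search window")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


def _extremum(evoked: EvokedWaveform, matrix: AnalysisMatrix,
              window: tuple[float, float], polarity: str) -> PeakMeasure:
    idx = matrix.indices_in(evoked.ch_names)
    sl = evoked.window_slice(window)
    block = evoked.data[idx, sl]
    signed = block if polarity == "positive" else -block
    # argmax scans electrodes in matrix order, samples left to right; for
    # ties we want earliest latency first, then matrix order -> scan
    # transposed (sample-major) and take the first maximum.
    flat = np.argmax(signed.T)  # ties -> lowest flat index = earliest sample
    s, e = np.unravel_index(flat, signed.T.shape)
    latency = float(evoked.times[sl][s])
    measure = PeakMeasure(latency, float(block[e, s]),
                          matrix.labels[e], tuple(window), polarity)
    if s == 0 or s == block.shape[1] - 1:
        warnings.warn(
            f"{polarity} extremum at search-window edge ({latency:g} ms); "
            "the component may be truncated", PeakAtEdgeWarning, stacklevel=3)
    return measure


def find_p3(evoked: EvokedWaveform, matrix: AnalysisMatrix | None = None,
            window: tuple[float, float] = (300.0, 450.0)) -> PeakMeasure:
    """Locate the P3: maximum positivity over matrix x window.

    Window edges are inclusive. Ties resolve to the earliest latency, then
    the first electrode in matrix order. A peak on a window edge raises
    :class:`PeakAtEdgeWarning`.
    """
    if evoked.kind != ERP:
        raise ValueError("find_p3 expects an ERP waveform")
    if matrix is None:
        matrix = AnalysisMatrix.default()
    return _extremum(evoked, matrix, window, "positive")


def amplitudes_at_latency(evoked: EvokedWaveform, latency_ms: float,
                          matrix: AnalysisMatrix | None = None,
                          modality: str = "P3",
                          source: str = "unknown") -> TopographyMap:
    """Export the 42 matrix voltages at one latency (nearest sample)."""
    if matrix is None:
        matrix = AnalysisMatrix.default()
    idx = matrix.indices_in(evoked.ch_names)
    s = evoked.time_index(latency_ms)
    return TopographyMap(evoked.data[idx, s], matrix.labels, modality,
                         source=source, latency_ms=float(evoked.times[s]))
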