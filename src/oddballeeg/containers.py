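"""In-memory containers for epoched EEG and averaged waveforms.

Voltages are microvolts throughout; time axes are milliseconds relative to
stimulus onset (0 ms). The sample grid is left-closed: an epoch spanning
-100..800 ms at 500 Hz holds 450 samples at -100, -98, ..., 798 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SCALP = "scalp"
EOG = "eog"

ERP = "erp"
ALPHA_ENVELOPE = "alpha-envelope"


def make_times(window_ms: tuple[float, float], sfreq: float) -> np.ndarray:
    """Sample grid for ``window_ms`` = (start, stop): left-closed, right-open."""
    step = 1000.0 / sfreq
    n = int(round((window_ms[1] - window_ms[0]) / step))
    return window_ms[0] + step * np.arange(n)


@dataclass
class EpochSet:
    """Trials x channels x samples voltage array with montage metadata.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Voltages in microvolts.
    times : ndarray, shape (n_samples,)
        Milliseconds relative to stimulus onset; strictly increasing,
        uniform step ``1000 / sfreq``.
    sfreq : float
        Sampling rate in Hz.
    ch_names, ch_roles : sequences of str
        Channel labels (unique) and roles (``"scalp"`` or ``"eog"``).
    trial_labels : sequence of str
        ``"target"`` or ``"standard"`` per trial.
    correct : ndarray of bool
        Behavioral correctness flag per trial.
    rejected : ndarray of bool
        Artifact-rejection mask; True = excluded from averaging.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    ch_names: list[str]
    ch_roles: list[str]
    trial_labels: list[str] = field(default_factory=list)
    correct: np.ndarray | None = None
    rejected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n_trials, n_ch, n_samp = self.data.shape
        if len(self.ch_names) != n_ch or len(self.ch_roles) != n_ch:
            raise ValueError("channel metadata length mismatch")
        if len(set(self.ch_names)) != n_ch:
            raise ValueError("channel labels must be unique")
        if self.times.shape != (n_samp,):
            raise ValueError("times length mismatch")
        if n_samp >= 2:
            steps = np.diff(self.times)
            step = 1000.0 / self.sfreq
            if not np.allclose(steps, step, rtol=0, atol=1e-6):
                raise ValueError("times must be uniform with step 1000/sfreq")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if not self.trial_labels:
            self.trial_labels = ["target"] * n_trials
        if len(self.trial_labels) != n_trials:
            raise ValueError("trial_labels length mismatch")
        if self.correct is None:
            self.correct = np.ones(n_trials, dtype=bool)
        else:
            self.correct = np.asarray(self.correct, dtype=bool)
        if self.rejected is None:
            self.rejected = np.zeros(n_trials, dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
        for arr, name in ((self.correct, "correct"), (self.rejected, "rejected")):
            if arr.shape != (n_trials,):
                raise ValueError(f"{name} mask length mismatch")

    # -- basic queries -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def scalp_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.ch_roles) == np.array(SCALP))

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def time_index(self, ms: float) -> int:
        """Nearest-sample index for a latency in ms (must be on the axis)."""
        if ms < self.times[0] - 1e-9 or ms > self.times[-1] + 1e-9:
            raise ValueError(f"latency {ms} ms outside epoch "
                             f"[{self.times[0]}, {self.times[-1]}] ms")
        return int(np.argmin(np.abs(self.times - ms)))

    def window_slice(self, window_ms: tuple[float, float]) -> slice:
        """Closed interval on the ms axis mapped to nearest samples."""
        lo, hi = window_ms
        if hi < lo:
            raise ValueError("empty window")
        i0 = self.time_index(lo)
        i1 = self.time_index(hi)
        return slice(i0, i1 + 1)

    def copy(self, **changes) -> "EpochSet":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out

    def kept_target_mask(self, require_correct: bool = True) -> np.ndarray:
        """Trials eligible for averaging: target, unrejected, (correct)."""
        mask = np.asarray(self.trial_labels) == "target"
        mask &= ~self.rejected
        if require_correct:
            mask &= self.correct
        return mask


@dataclass
class EvokedWaveform:
    """Channels x samples average: an ERP or a rectified-alpha envelope."""

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    ch_names: list[str]
    n_trials_averaged: int
    kind: str = ERP  # ERP or ALPHA_ENVELOPE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape != (len(self.ch_names), len(self.times)):
            raise ValueError("evoked shape mismatch")
        if self.kind not in (ERP, ALPHA_ENVELOPE):
            raise ValueError(f"unknown waveform kind {self.kind!r}")

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def time_index(self, ms: float) -> int:
        if ms < self.times[0] - 1e-9 or ms > self.times[-1] + 1e-9:
            raise ValueError(f"latency {ms} ms outside epoch "
                             f"[{self.times[0]}, {self.times[-1]}] ms")
        return int(np.argmin(np.abs(self.times - ms)))

    def window_slice(self, window_ms: tuple[float, float]) -> slice:
        lo, hi = window_ms
        if hi < lo:
            raise ValueError("empty window")
        return slice(self.time_index(lo), self.time_index(hi) + 1)

    def shifted(self, n_samples: int) -> "EvokedWaveform":
        """Circularly shift the waveform in time (testing helper)."""
        return EvokedWaveform(np.roll(self.data, n_samples, axis=1),
                              self.times, self.sfreq, list(self.ch_names),
                              self.n_trials_averaged, self.kind)
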