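"""Synthetic oddball EEG: epochs, behavior and whole cohorts with ground truth.

Target epochs are built from three additive parts on each scalp channel:

* an alpha-band carrier ``A * w_alpha[ch] * sin(2*pi*f*t + phi_trial)`` whose
  envelope is multiplied by ``1 - depth * g(t)`` with ``g`` a unit-peak
  Gaussian centered at the desynchronization latency — the event-related
  desynchronization (ERD). Per-trial phases are uniform on [0, 2*pi) and
  stratified (a shuffled equispaced set with a random global offset), so the
  non-phase-locked carrier cancels exactly in the ordinary trial average but
  survives the filter-rectify-average route;
* a parietally weighted positive Gaussian transient — the P3;
* additive zero-mean Gaussian noise.

The pre-stimulus interval (t < 0) contains carrier + noise only. Optional
blinks are 200 ms half-sine deflections mirrored into a simulated VEOG
channel and propagated to scalp sites with frontal weighting.

All randomness flows from ``SimulationParams.seed``; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .containers import EOG, SCALP, EpochSet, make_times
from .montage import DEFAULT_SCALP_64, VEOG, gaussian_weight_map, grid_position

__all__ = [
    "SimulationParams", "GroundTruth", "GroupSpec", "CohortMember",
    "simulate_trial_sequence", "simulate_epochs", "simulate_cohort",
    "default_group_specs", "PRESETS",
]


def default_p3_topography(ch_names: Sequence[str]) -> np.ndarray:
    """Parietal-maximum weight map (unit peak at Pz) for the P3 transient."""
    return gaussian_weight_map(list(ch_names), grid_position("Pz"), 2.0)

def default_alpha_topography(ch_names: Sequence[str]) -> np.ndarray:
    """Parieto-occipital weight map for the alpha carrier (peak near POz)."""
    return gaussian_weight_map(list(ch_names), grid_position("POz"), 2.5)


@dataclass
class SimulationParams:
    """Knobs of the oddball epoch generator.

    Trial structure (200 trials, 50 targets, SOA 1.5 s) follows the task;
    waveform parameters are in ms / microvolts. ``p3_width`` and ``erd_width``
    are Gaussian sigmas; ``erd_depth`` is the fractional envelope dip in
    [0, 1]; ``blink_rate`` is the expected number of blink events per epoch.
    """

    n_channels: int = 64
    sampling_rate: float = 500.0
    epoch_window: tuple[float, float] = (-100.0, 800.0)
    n_target: int = 50
    n_standard: int = 150
    soa: float = 1500.0
    p3_latency: float = 370.0
    p3_amplitude: float = 10.0
    p3_width: float = 40.0
    p3_topography: np.ndarray | None = None
    alpha_freq: float = 10.0
    alpha_amplitude: float = 4.0
    alpha_topography: np.ndarray | None = None
    erd_latency: float = 450.0
    erd_depth: float = 0.5
    erd_width: float = 100.0
    noise_sd: float = 2.0
    blink_rate: float = 0.0
    rt_mean: float = 418.0
    rt_sd: float = 72.0
    rt_bounds: tuple[float, float] = (150.0, 1500.0)
    accuracy: float = 0.993
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.epoch_window
        if not lo < hi:
            raise ValueError("epoch_window must be increasing")
        if not lo <= self.p3_latency <= hi:
            raise ValueError("p3_latency outside epoch_window")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        for name in ("p3_amplitude", "alpha_amplitude", "noise_sd",
                     "p3_width", "erd_width", "blink_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 8.0 <= self.alpha_freq <= 13.0:
            raise ValueError("alpha_freq must lie in the 8-13 Hz band")
        if self.n_channels != len(self.channel_names()):
            raise ValueError("n_channels must match the montage size (64)")

    def channel_names(self) -> list[str]:
        return list(DEFAULT_SCALP_64)

    def resolved_p3_topography(self) -> np.ndarray:
        w = (default_p3_topography(self.channel_names())
             if self.p3_topography is None else np.asarray(self.p3_topography, float))
        if w.shape != (self.n_channels,):
            raise ValueError("p3_topography must have one weight per scalp channel")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("p3_topography weights must lie in [0, 1]")
        return w

    def resolved_alpha_topography(self) -> np.ndarray:
        w = (default_alpha_topography(self.channel_names())
             if self.alpha_topography is None else np.asarray(self.alpha_topography, float))
        if w.shape != (self.n_channels,):
            raise ValueError("alpha_topography must have one weight per scalp channel")
        return w


@dataclass
class GroundTruth:
    """Injected parameters carried unchanged alongside a simulated EpochSet."""

    p3_latency: float
    p3_amplitude: float
    erd_latency: float
    erd_depth: float
    rts: np.ndarray            # per-target reaction times, ms
    trial_labels: list[str]
    blink_samples: list[list[int]]  # per-trial blink-onset sample indices
    seed: int

    def to_dict(self) -> dict:
        return {
            "p3_latency": self.p3_latency,
            "p3_amplitude": self.p3_amplitude,
            "erd_latency": self.erd_latency,
            "erd_depth": self.erd_depth,
            "rts": np.asarray(self.rts).tolist(),
            "trial_labels": list(self.trial_labels),
            "blink_samples": [list(map(int, b)) for b in self.blink_samples],
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(d["p3_latency"], d["p3_amplitude"], d["erd_latency"],
                   d["erd_depth"], np.asarray(d["rts"], float),
                   list(d["trial_labels"]), [list(b) for b in d["blink_samples"]],
                   int(d["seed"]))


def simulate_trial_sequence(n_target: int, n_standard: int, seed: int) -> list[str]:
    """Pseudorandom oddball order with no two consecutive targets.

    Targets are assigned to ``n_target`` distinct gaps among the standards
    (before, between or after), which makes adjacency impossible while every
    admissible order stays reachable.
    """
    if n_target < 0 or n_standard < 0:
        raise ValueError("trial counts must be non-negative")
    if n_target > n_standard + 1:
        raise ValueError(
            f"cannot place {n_target} non-adjacent targets among "
            f"{n_standard} standards (need n_target <= n_standard + 1)")
    rng = np.random.default_rng(seed)
    gaps = rng.choice(n_standard + 1, size=n_target, replace=False)
    in_gap = np.zeros(n_standard + 1, dtype=bool)
    in_gap[gaps] = True
    seq: list[str] = []
    for g in range(n_standard + 1):
        if in_gap[g]:
            seq.append("target")
        if g < n_standard:
            seq.append("standard")
    return seq


def _blinks(rng: np.random.Generator, n_samples: int, sfreq: float,
            rate: float) -> tuple[np.ndarray, list[int]]:
    """One epoch's blink trace (unit amplitude) and onset sample indices."""
    trace = np.zeros(n_samples)
    onsets: list[int] = []
    width = int(round(0.200 * sfreq))  # 200 ms half-sine
    for _ in range(rng.poisson(rate)):
        start = int(rng.integers(0, max(1, n_samples - width)))
        trace[start:start + width] += np.sin(np.pi * np.arange(width) / width)
        onsets.append(start)
    return trace, onsets


def simulate_epochs(params: SimulationParams,
                    include_standards: bool = False) -> tuple[EpochSet, GroundTruth]:
    """Generate one participant's oddball epochs plus behavioral ground truth.

    Returns target epochs only by default (standards carry no P3/ERD and are
    not analyzed); ``include_standards=True`` appends standard epochs that
    contain carrier + noise only.
    """
    rng = np.random.default_rng(params.seed)
    times = make_times(params.epoch_window, params.sampling_rate)
    t_s = times / 1000.0
    n_samp = times.size

    labels_seq = simulate_trial_sequence(params.n_target, params.n_standard,
                                         int(rng.integers(2 ** 31)))
    w_p3 = params.resolved_p3_topography()
    w_alpha = params.resolved_alpha_topography()

    # ERD envelope gain: 1 - depth * g(t), active only post-stimulus
    g = np.exp(-0.5 * ((times - params.erd_latency) / max(params.erd_width, 1e-9)) ** 2)
    gain = 1.0 - params.erd_depth * np.where(times >= 0.0, g, 0.0)
    p3 = params.p3_amplitude * np.exp(
        -0.5 * ((times - params.p3_latency) / max(params.p3_width, 1e-9)) ** 2)
    p3 = np.where(times >= 0.0, p3, 0.0)

    def build(n_trials: int, with_effects: bool) -> tuple[np.ndarray, list[list[int]]]:
        data = np.empty((n_trials, params.n_channels + 1, n_samp))
        blink_onsets: list[list[int]] = []
        blink_scalp = gaussian_weight_map(params.channel_names(),
                                          grid_position("Fpz"), 2.0) * 0.4
        # stratified per-trial phases: marginally uniform on [0, 2*pi) while
        # the phasor sum is exactly zero, so the non-phase-locked carrier
        # cancels in the trial average as it should
        phases = (rng.uniform(0.0, 2.0 * np.pi)
                  + 2.0 * np.pi * rng.permutation(n_trials) / max(n_trials, 1)
                  ) % (2.0 * np.pi)
        for i in range(n_trials):
            phi = phases[i]
            carrier = params.alpha_amplitude * np.sin(
                2.0 * np.pi * params.alpha_freq * t_s + phi)
            if with_effects:
                carrier = carrier * gain
            scalp = w_alpha[:, None] * carrier[None, :]
            if with_effects:
                scalp = scalp + w_p3[:, None] * p3[None, :]
            if params.noise_sd > 0:
                scalp = scalp + rng.normal(0.0, params.noise_sd,
                                           (params.n_channels, n_samp))
            veog = np.zeros(n_samp)
            if params.blink_rate > 0:
                trace, onsets = _blinks(rng, n_samp, params.sampling_rate,
                                        params.blink_rate)
                veog = 150.0 * trace
                scalp = scalp + 150.0 * blink_scalp[:, None] * trace[None, :]
                blink_onsets.append(onsets)
            else:
                blink_onsets.append([])
            if params.noise_sd > 0:
                veog = veog + rng.normal(0.0, params.noise_sd, n_samp)
            data[i, :-1] = scalp
            data[i, -1] = veog
        return data, blink_onsets

    tgt_data, tgt_blinks = build(params.n_target, with_effects=True)
    rts = np.clip(rng.normal(params.rt_mean, params.rt_sd, params.n_target),
                  *params.rt_bounds)
    correct_t = rng.random(params.n_target) < params.accuracy

    if include_standards:
        std_data, std_blinks = build(params.n_standard, with_effects=False)
        data = np.concatenate([tgt_data, std_data])
        labels = ["target"] * params.n_target + ["standard"] * params.n_standard
        blinks = tgt_blinks + std_blinks
        correct = np.concatenate([correct_t,
                                  np.ones(params.n_standard, dtype=bool)])
    else:
        data, labels, blinks, correct = tgt_data, ["target"] * params.n_target, \
            tgt_blinks, correct_t

    epochs = EpochSet(
        data=data, times=times, sfreq=params.sampling_rate,
        ch_names=params.channel_names() + [VEOG],
        ch_roles=[SCALP] * params.n_channels + [EOG],
        trial_labels=labels, correct=correct)
    truth = GroundTruth(params.p3_latency, params.p3_amplitude,
                        params.erd_latency, params.erd_depth, rts,
                        labels_seq, blinks, params.seed)
    return epochs, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class GroupSpec:
    """Between-subject normal distributions for one experimental group.

    Defaults (see ``PRESETS``) emulate the published group statistics of the
    oddball study: RT 418/457/494 ms, P3 latency 371/363/478 ms, ERD latency
    444/499/568 ms for healthy, low-EDSS and moderate-EDSS respectively.
    Latency draws are truncated to ``lat_bounds`` so every injected component
    stays inside the filter-reliable part of the epoch.
    """

    name: str
    rt_mean: float
    rt_sd: float
    p3_lat_mean: float
    p3_lat_sd: float
    p3_amp_mean: float
    p3_amp_sd: float
    erd_lat_mean: float
    erd_lat_sd: float
    erd_depth_mean: float = 0.5
    erd_depth_sd: float = 0.15
    lat_bounds: tuple[float, float] = (260.0, 690.0)

    def draw(self, rng: np.random.Generator) -> dict:
        def trunc_normal(mean, sd, lo, hi):
            for _ in range(1000):
                v = rng.normal(mean, sd)
                if lo <= v <= hi:
                    return float(v)
            return float(np.clip(mean, lo, hi))

        return {
            "rt_mean": trunc_normal(self.rt_mean, self.rt_sd, 150.0, 1500.0),
            "p3_latency": trunc_normal(self.p3_lat_mean, self.p3_lat_sd,
                                       *self.lat_bounds),
            "p3_amplitude": trunc_normal(self.p3_amp_mean, self.p3_amp_sd,
                                         2.0, 40.0),
            "erd_latency": trunc_normal(self.erd_lat_mean, self.erd_lat_sd,
                                        *self.lat_bounds),
            "erd_depth": trunc_normal(self.erd_depth_mean, self.erd_depth_sd,
                                      0.05, 0.95),
        }


PRESETS: dict[str, GroupSpec] = {
    "healthy": GroupSpec("healthy", 418.0, 72.32, 371.0, 58.70, 11.22, 5.39,
                         444.0, 89.53),
    "low-EDSS": GroupSpec("low-EDSS", 457.0, 69.19, 363.0, 48.99, 12.74, 9.09,
                          499.0, 82.91),
    "moderate-EDSS": GroupSpec("moderate-EDSS", 494.0, 66.40, 478.0, 123.03,
                               6.78, 2.33, 568.0, 47.75),
}


def default_group_specs() -> list[GroupSpec]:
    return [PRESETS["healthy"], PRESETS["low-EDSS"], PRESETS["moderate-EDSS"]]


@dataclass
class CohortMember:
    participant_id: str
    group: str
    epochs: EpochSet
    truth: GroundTruth
    behavioral: dict  # rt_mean (ms, over correct targets), accuracy_pct


def simulate_cohort(group_specs: Sequence[GroupSpec] | None = None,
                    n_per_group: int = 10,
                    seed: int = 0,
                    base_params: SimulationParams | None = None,
                    between_subject_scale: float = 1.0,
                    ) -> list[CohortMember]:
    """Draw per-participant parameters from group distributions and simulate.

    ``between_subject_scale`` multiplies every between-subject SD (0 makes
    each participant equal to the group mean). Ground truth is retained per
    participant.
    """
    if group_specs is None:
        group_specs = default_group_specs()
    if not group_specs:
        raise ValueError("need at least one group")
    base = base_params if base_params is not None else SimulationParams()
    rng = np.random.default_rng(seed)
    members: list[CohortMember] = []
    for spec in group_specs:
        scaled = replace(spec,
                         rt_sd=spec.rt_sd * between_subject_scale,
                         p3_lat_sd=spec.p3_lat_sd * between_subject_scale,
                         p3_amp_sd=spec.p3_amp_sd * between_subject_scale,
                         erd_lat_sd=spec.erd_lat_sd * between_subject_scale,
                         erd_depth_sd=spec.erd_depth_sd * between_subject_scale)
        for k in range(n_per_group):
            draw = scaled.draw(rng)
            params = replace(base, seed=int(rng.integers(2 ** 31)),
                             rt_mean=draw["rt_mean"],
                             p3_latency=draw["p3_latency"],
                             p3_amplitude=draw["p3_amplitude"],
                             erd_latency=draw["erd_latency"],
                             erd_depth=draw["erd_depth"])
            epochs, truth = simulate_epochs(params)
            correct_rts = truth.rts[epochs.correct[:params.n_target]]
            behavioral = {
                "rt_mean": float(np.mean(correct_rts)) if correct_rts.size else np.nan,
                "accuracy_pct": 100.0 * float(np.mean(epochs.correct[:params.n_target])),
            }
            members.append(CohortMember(f"{spec.name}-{k + 1:02d}", spec.name,
                                        epochs, truth, behavioral))
    return members
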