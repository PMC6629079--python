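"""Epoch preprocessing: average reference, EOG regression, baseline,
artifact rejection and minimum-trial averaging.

The canonical order, enforced by :func:`preprocess_pipeline`, is
re-reference -> EOG regression -> baseline correction -> +/-75 uV rejection
-> averaging over at least 15 artifact-free, behaviorally correct target
trials.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import ERP, EpochSet, EvokedWaveform

__all__ = [
    "rereference_average", "baseline_correct", "regress_eog",
    "reject_artifacts", "average_epochs", "preprocess_pipeline",
    "InsufficientTrialsError",
]


class InsufficientTrialsError(ValueError):
    """Raised when fewer artifact-free trials survive than the minimum."""


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean over scalp channels from each scalp
    channel; EOG channels are untouched."""
    scalp = epochs.scalp_indices()
    if scalp.size < 2:
        raise ValueError("average reference needs at least 2 scalp channels")
    out = epochs.copy()
    mean = out.data[:, scalp, :].mean(axis=1, keepdims=True)
    out.data[:, scalp, :] -= mean
    return out


def baseline_correct(epochs: EpochSet,
                     interval: tuple[float, float] = (-100.0, 0.0)) -> EpochSet:
    """Subtract each trial x channel mean over ``interval`` (ms, closed)."""
    sl = epochs.window_slice(interval)
    if sl.stop - sl.start < 1:
        raise ValueError("baseline interval contains no samples")
    out = epochs.copy()
    out.data -= out.data[:, :, sl].mean(axis=2, keepdims=True)
    return out


def regress_eog(epochs: EpochSet, eog_channel: str = "VEOG") -> EpochSet:
    """Remove ocular activity by per-channel least-squares regression.

    One pooled coefficient ``b_c = cov(c, EOG) / var(EOG)`` per scalp channel,
    estimated over all trials and samples jointly, is subtracted
    (``c - b_c * EOG``). After correction the pooled scalp/EOG covariance is
    numerically zero. A zero-variance EOG channel leaves the data unchanged
    (with a warning).
    """
    k = epochs.channel_index(eog_channel)
    out = epochs.copy()
    eog = out.data[:, k, :].ravel()
    eog_c = eog - eog.mean()
    var = float(eog_c @ eog_c)
    if var < 1e-24:
        warnings.warn("EOG channel has zero variance; no ocular correction "
                      "applied", RuntimeWarning, stacklevel=2)
        return out
    scalp = epochs.scalp_indices()
    flat = out.data[:, scalp, :].transpose(1, 0, 2).reshape(scalp.size, -1)
    b = (flat - flat.mean(axis=1, keepdims=True)) @ eog_c / var
    corrected = flat - b[:, None] * eog[None, :]
    out.data[:, scalp, :] = corrected.reshape(
        scalp.size, epochs.n_trials, epochs.n_samples).transpose(1, 0, 2)
    return out


def reject_artifacts(epochs: EpochSet,
                     threshold: float = 75.0) -> tuple[EpochSet, int]:
    """Mark trials whose absolute scalp voltage strictly exceeds ``threshold``.

    The boundary is strict: a trial whose extreme sample is exactly
    ``threshold`` uV is kept. Returns the updated EpochSet and the number of
    newly rejected trials.
    """
    if threshold <= 0:
        raise ValueError("rejection threshold must be positive")
    scalp = epochs.scalp_indices()
    exceeds = np.abs(epochs.data[:, scalp, :]).max(axis=(1, 2)) > threshold
    out = epochs.copy(rejected=epochs.rejected | exceeds)
    return out, int((exceeds & ~epochs.rejected).sum())


def average_epochs(epochs: EpochSet, min_trials: int = 15,
                   require_correct: bool = True) -> EvokedWaveform:
    """Average the surviving correct target trials into an ERP.

    Raises :class:`InsufficientTrialsError` (naming the surviving count) when
    fewer than ``min_trials`` trials remain, following the convention that a
    usable individual average needs at least 15 artifact-free trials.
    """
    mask = epochs.kept_target_mask(require_correct=require_correct)
    n = int(mask.sum())
    if n < min_trials:
        raise InsufficientTrialsError(
            f"only {n} artifact-free trials survive (need >= {min_trials})")
    return EvokedWaveform(epochs.data[mask].mean(axis=0), epochs.times,
                          epochs.sfreq, list(epochs.ch_names), n, ERP)


def preprocess_pipeline(epochs: EpochSet, *,
                        eog_channel: str | None = "VEOG",
                        baseline: tuple[float, float] = (-100.0, 0.0),
                        threshold: float = 75.0,
                        min_trials: int = 15,
                        ) -> tuple[EpochSet, EvokedWaveform, dict]:
    """Full preprocessing chain in canonical order.

    Returns the cleaned EpochSet (for the ERD route, which re-uses the same
    artifact-free trials), the averaged ERP, and a statistics dict with the
    rejection/behavior bookkeeping.
    """
    out = rereference_average(epochs)
    if eog_channel is not None and eog_channel in out.ch_names:
        out = regress_eog(out, eog_channel)
    out = baseline_correct(out, baseline)
    out, n_rejected = reject_artifacts(out, threshold)
    target = np.asarray(out.trial_labels) == "target"
    stats = {
        "n_trials": out.n_trials,
        "n_targets": int(target.sum()),
        "n_rejected_artifact": n_rejected,
        "n_incorrect_targets": int((target & ~out.correct).sum()),
        "n_averaged": int(out.kept_target_mask().sum()),
    }
    evoked = average_epochs(out, min_trials=min_trials)
    return out, evoked, stats
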