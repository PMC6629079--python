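"""File formats: the epoch exchange container, cohort CSV, the packaged
cohort fixture, ground-truth JSON and BrainVision reading.

Epoch exchange format
---------------------
A single ``.npz`` archive holding a JSON metadata document (key ``meta``:
sampling rate, time-axis start/step in ms, ordered channel labels and roles,
per-trial labels and correctness flags) plus one stacked voltage array
(key ``data``, trials x channels x samples, microvolts) and the rejection
mask. Write -> read round-trips are bit-identical on metadata and
value-identical on voltages.

Cohort CSV
----------
Header (exactly): ``id, group, rt_ms, accuracy_pct, p3_lat_ms, p3_amp_uv,
erd_lat_ms, erd_amp_uv, map_p3, map_erd, edss, sdmt, pasat, bdi``. Decimal
points only — decimal commas are rejected loudly rather than silently
misparsed. Empty cells encode the healthy-only missing clinical scores.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EOG, SCALP, EpochSet
from .simulate import GroundTruth
from .zprofile import ParticipantRecord

__all__ = ["COHORT_COLUMNS", "load_reference_cohort", "read_cohort_csv",
           "write_cohort_csv", "records_from_frame", "read_epochs",
           "write_epochs", "write_ground_truth", "read_ground_truth",
           "read_brainvision"]

COHORT_COLUMNS = ["id", "group", "rt_ms", "accuracy_pct", "p3_lat_ms",
                  "p3_amp_uv", "erd_lat_ms", "erd_amp_uv", "map_p3",
                  "map_erd", "edss", "sdmt", "pasat", "bdi"]

_FIXTURE_SHA256 = "30e2be1460c4be20ff213ed6b96ea970f9c31b96cf966777b0dfe5a6578a3fe3"


# ---------------------------------------------------------------------------
# cohort tables


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort table, enforcing the exact column set and decimal points."""
    raw = Path(path).read_text(encoding="utf-8")
    header = raw.splitlines()[0].split(",")
    if header != COHORT_COLUMNS:
        raise ValueError(f"cohort CSV header mismatch: expected "
                         f"{COHORT_COLUMNS}, got {header}")
    df = pd.read_csv(path, dtype={"id": str, "group": str})
    numeric = [c for c in COHORT_COLUMNS if c not in ("id", "group")]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"non-numeric value in column {col!r} — decimal commas are "
                f"not accepted, use decimal points ({exc})") from None
    return df


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    table[COHORT_COLUMNS].to_csv(path, index=False)


def records_from_frame(table: pd.DataFrame) -> list[ParticipantRecord]:
    def val(x):
        return None if pd.isna(x) else float(x)

    return [ParticipantRecord(
        id=row["id"], group=row["group"], rt_ms=float(row["rt_ms"]),
        p3_lat_ms=float(row["p3_lat_ms"]), erd_lat_ms=float(row["erd_lat_ms"]),
        map_p3=float(row["map_p3"]), map_erd=float(row["map_erd"]),
        accuracy_pct=val(row["accuracy_pct"]), p3_amp_uv=val(row["p3_amp_uv"]),
        erd_amp_uv=val(row["erd_amp_uv"]), edss=val(row["edss"]),
        sdmt=val(row["sdmt"]), pasat=val(row["pasat"]), bdi=val(row["bdi"]))
        for _, row in table.iterrows()]


def load_reference_cohort(as_records: bool = False
                        ) -> pd.DataFrame | list[ParticipantRecord]:
    """The packaged 30-participant cohort table (raw columns only).

    Three groups of ten (healthy, low-EDSS, moderate-EDSS) with reaction
    times, P3/ERD latencies, map scores and clinical scores. Z-columns and
    flags are never stored — they are recomputed by the profiling stage.
    """
    res = importlib.resources.files("oddballeeg") / "data" / "reference_cohort.csv"
    content = res.read_bytes()
    digest = hashlib.sha256(content).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(f"cohort fixture checksum mismatch ({digest})")
    with importlib.resources.as_file(res) as p:
        df = read_cohort_csv(p)
    return records_from_frame(df) if as_records else df


# ---------------------------------------------------------------------------
# epoch exchange format


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    meta = {
        "sampling_rate": epochs.sfreq,
        "time_start_ms": float(epochs.times[0]) if epochs.n_samples else 0.0,
        "time_step_ms": 1000.0 / epochs.sfreq,
        "n_samples": epochs.n_samples,
        "ch_names": list(epochs.ch_names),
        "ch_roles": list(epochs.ch_roles),
        "trial_labels": list(epochs.trial_labels),
        "correct": epochs.correct.astype(int).tolist(),
    }
    np.savez_compressed(path, meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8),
        data=epochs.data, rejected=epochs.rejected)


def read_epochs(path: str | Path) -> EpochSet:
    with np.load(path) as npz:
        if "meta" not in npz or "data" not in npz:
            raise ValueError("malformed epoch file: missing meta/data entries")
        try:
            meta = json.loads(bytes(npz["meta"]).decode())
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise ValueError(f"malformed epoch metadata: {exc}") from None
        data = npz["data"]
        rejected = npz["rejected"] if "rejected" in npz else None
    n_ch = len(meta["ch_names"])
    if data.ndim != 3 or data.shape[1] != n_ch or \
            data.shape[2] != meta["n_samples"]:
        raise ValueError(f"epoch matrix shape {data.shape} does not match "
                         f"metadata ({n_ch} channels, "
                         f"{meta['n_samples']} samples)")
    times = meta["time_start_ms"] + meta["time_step_ms"] * \
        np.arange(meta["n_samples"])
    return EpochSet(data=data, times=times, sfreq=meta["sampling_rate"],
                    ch_names=list(meta["ch_names"]),
                    ch_roles=list(meta["ch_roles"]),
                    trial_labels=list(meta["trial_labels"]),
                    correct=np.asarray(meta["correct"], dtype=bool),
                    rejected=rejected)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# BrainVision


def read_brainvision(vhdr_path: str | Path,
                     window_ms: tuple[float, float] = (-100.0, 800.0),
                     target_markers: tuple[str, ...] = ("Stimulus/S  2",),
                     standard_markers: tuple[str, ...] = ("Stimulus/S  1",),
                     eog_channels: tuple[str, ...] = ("VEOG", "HEOG"),
                     ) -> EpochSet:
    """Segment a BrainVision recording (.vhdr/.vmrk/.eeg triplet) into epochs.

    Stimulus markers matching ``target_markers`` / ``standard_markers`` become
    trial events; each is cut to ``window_ms`` around its onset. Voltages are
    converted to microvolts. A marker-free file yields zero trials with a
    warning.
    """
    import mne

    vhdr = Path(vhdr_path)
    if not vhdr.exists():
        raise FileNotFoundError(f"missing BrainVision header: {vhdr}")
    for suffix in (".vmrk", ".eeg"):
        if not vhdr.with_suffix(suffix).exists():
            raise FileNotFoundError(
                f"incomplete BrainVision triplet: missing {suffix} for {vhdr}")
    raw = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    data_uv = raw.get_data() * 1e6  # volts -> microvolts
    step = 1000.0 / sfreq
    n_pre = int(round(-window_ms[0] / step))
    n_post = int(round(window_ms[1] / step))
    times = window_ms[0] + step * np.arange(n_pre + n_post)

    events, labels = [], []
    for onset_s, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc in target_markers or desc in standard_markers:
            events.append(int(round(onset_s * sfreq)))
            labels.append("target" if desc in target_markers else "standard")
    if not events:
        warnings.warn("no stimulus markers found; returning zero trials",
                      RuntimeWarning, stacklevel=2)
    trials = []
    kept_labels = []
    for samp, lab in zip(events, labels):
        lo, hi = samp - n_pre, samp + n_post
        if lo < 0 or hi > data_uv.shape[1]:
            warnings.warn(f"event at sample {samp} too close to the recording "
                          "edge; skipped", RuntimeWarning, stacklevel=2)
            continue
        trials.append(data_uv[:, lo:hi])
        kept_labels.append(lab)
    data = np.stack(trials) if trials else \
        np.empty((0, data_uv.shape[0], times.size))
    roles = [EOG if name in eog_channels else SCALP for name in raw.ch_names]
    return EpochSet(data=data, times=times, sfreq=sfreq,
                    ch_names=list(raw.ch_names), ch_roles=roles,
                    trial_labels=kept_labels)
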