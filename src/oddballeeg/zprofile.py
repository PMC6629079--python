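"""Normative z-score profiling and the Z3 composite.

Every measure is standardized against the healthy group:
``Z = (value - healthy mean) / healthy SD`` with the sample SD (n-1
denominator). A z strictly greater than 1 flags an individual deviation.
Z3 is the mean of the reaction-time, P3-latency and ERD-latency z-scores and
serves as a single index of slowed processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .topomap import flag_map

__all__ = ["ParticipantRecord", "NormativeStats", "ZProfile", "GROUPS",
           "Z_VARIABLES", "normative_stats", "z_transform", "flag_z", "z3",
           "build_profile", "build_profiles", "add_z3_column"]

GROUPS = ("healthy", "low-EDSS", "moderate-EDSS")

#: Variables that are z-transformed against healthy norms.
Z_VARIABLES = ("rt_ms", "p3_lat_ms", "erd_lat_ms")


@dataclass
class ParticipantRecord:
    """One cohort-table row: behavior, EEG parameters and clinical scores.

    ``edss``, ``sdmt``, ``pasat`` and ``bdi`` are patient-only and may be
    None for healthy controls; ``accuracy`` and the amplitude fields may be
    absent (None) when only latencies were tabulated.
    """

    id: str
    group: str
    rt_ms: float
    p3_lat_ms: float
    erd_lat_ms: float
    map_p3: float
    map_erd: float
    accuracy_pct: float | None = None
    p3_amp_uv: float | None = None
    erd_amp_uv: float | None = None
    edss: float | None = None
    sdmt: float | None = None
    pasat: float | None = None
    bdi: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, "
                             f"got {self.group!r}")
        if self.edss is not None and not 0.0 <= self.edss <= 10.0:
            raise ValueError("EDSS must lie in [0, 10]")
        if self.accuracy_pct is not None and not 0.0 <= self.accuracy_pct <= 100.0:
            raise ValueError("accuracy must lie in [0, 100]")

    @property
    def is_patient(self) -> bool:
        return self.group != "healthy"


@dataclass(frozen=True)
class NormativeStats:
    """Healthy-group mean and sample SD (n-1) for one variable."""

    variable: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"normative SD must be positive "
                             f"({self.variable}: sd={self.sd})")


@dataclass
class ZProfile:
    """Derived individual profile: z-scores, deviation flags and Z3."""

    id: str
    group: str
    z: dict[str, float]
    z_flags: dict[str, bool]
    map_flags: dict[str, bool]
    z3: float


def _values(records: Iterable[ParticipantRecord] | pd.DataFrame,
            variable: str, group: str | None = "healthy") -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        sub = records if group is None else records[records["group"] == group]
        vals = sub[variable].to_numpy(dtype=float)
    else:
        vals = np.array([getattr(r, variable) for r in records
                         if group is None or r.group == group], dtype=float)
    return vals[~np.isnan(vals)]


def normative_stats(healthy: Iterable[ParticipantRecord] | pd.DataFrame,
                    variable: str) -> NormativeStats:
    """Sample mean and SD of one variable over the healthy group."""
    vals = _values(healthy, variable, group="healthy")
    if vals.size < 2:
        raise ValueError(f"need >= 2 healthy values for {variable!r}, "
                         f"got {vals.size}")
    sd = float(np.std(vals, ddof=1))
    if sd < 1e-15:
        raise ValueError(f"healthy {variable!r} has zero variance")
    return NormativeStats(variable, float(np.mean(vals)), sd, int(vals.size))


def compute_norms(records: Iterable[ParticipantRecord] | pd.DataFrame,
                  variables: Sequence[str] = Z_VARIABLES
                  ) -> dict[str, NormativeStats]:
    records = list(records) if not isinstance(records, pd.DataFrame) else records
    return {v: normative_stats(records, v) for v in variables}


def z_transform(value: float, norm: NormativeStats) -> float:
    return (value - norm.mean) / norm.sd


def flag_z(z: float) -> bool:
    """Individual deviation flag: z strictly greater than 1."""
    return z > 1.0


def z3(rt_z: float, p3_lat_z: float, erd_lat_z: float) -> float:
    """Composite index: arithmetic mean of the three slowing z-scores."""
    return (rt_z + p3_lat_z + erd_lat_z) / 3.0


def build_profile(record: ParticipantRecord,
                  norms: Mapping[str, NormativeStats]) -> ZProfile:
    """Assemble one participant's z-scores, flags and Z3."""
    zs = {v: z_transform(getattr(record, v), norms[v]) for v in Z_VARIABLES}
    z_flags = {v: flag_z(z) for v, z in zs.items()}
    map_flags = {"map_p3": flag_map(record.map_p3, "P3"),
                 "map_erd": flag_map(record.map_erd, "ERD")}
    return ZProfile(record.id, record.group, zs, z_flags, map_flags,
                    z3(zs["rt_ms"], zs["p3_lat_ms"], zs["erd_lat_ms"]))


def build_profiles(records: Sequence[ParticipantRecord],
                   norms: Mapping[str, NormativeStats] | None = None
                   ) -> list[ZProfile]:
    if norms is None:
        norms = compute_norms(records)
    return [build_profile(r, norms) for r in records]


def add_z3_column(table: pd.DataFrame,
                  norms: Mapping[str, NormativeStats] | None = None
                  ) -> pd.DataFrame:
    """Return a copy of the cohort table with z-score and ``z3`` columns.

    Norms default to the healthy rows of ``table`` itself.
    """
    if norms is None:
        norms = {v: normative_stats(table, v) for v in Z_VARIABLES}
    out = table.copy()
    for v in Z_VARIABLES:
        out[v + "_z"] = (out[v] - norms[v].mean) / norms[v].sd
    out["z3"] = out[[v + "_z" for v in Z_VARIABLES]].mean(axis=1)
    return out


def profiles_frame(profiles: Sequence[ZProfile]) -> pd.DataFrame:
    """Tabular view of a list of profiles (one row per participant)."""
    rows = []
    for p in profiles:
        row = {"id": p.id, "group": p.group}
        for v in Z_VARIABLES:
            row[v + "_z"] = p.z[v]
            row[v + "_flag"] = p.z_flags[v]
        row.update({k + "_flag": v for k, v in p.map_flags.items()})
        row["z3"] = p.z3
        rows.append(row)
    return pd.DataFrame(rows)
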