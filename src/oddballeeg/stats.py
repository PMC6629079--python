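"""Group-level inference: Kruskal-Wallis with Dunn-type Bonferroni post hoc
and the Pearson correlation screen.

With three groups of ten, group differences are tested non-parametrically
(tie-corrected Kruskal-Wallis H against chi-square, df = k-1) followed by
pairwise Dunn comparisons on the pooled mean ranks with Bonferroni-adjusted
p-values. Associations between clinical scores and the behavioral/EEG
measures are screened with Pearson's product-moment r over the pooled
patients; the significance level is alpha divided by the family size
(0.05 / 25 = 0.002 by default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["KWResult", "PairwiseComparison", "CorrelationResult",
           "kruskal_wallis", "pairwise_posthoc", "pearson",
           "correlation_screen", "default_screen_pairs",
           "CLINICAL_VARIABLES", "MEASURE_VARIABLES"]

#: Clinical / neuropsychological variables, defined for patients only.
CLINICAL_VARIABLES = ("edss", "sdmt", "pasat")
#: Behavioral and EEG measures entering the screen.
MEASURE_VARIABLES = ("rt_ms", "p3_lat_ms", "erd_lat_ms", "map_p3",
                     "map_erd", "z3")


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float


@dataclass
class KWResult:
    """Tie-corrected Kruskal-Wallis outcome with Dunn post hoc."""

    h: float
    df: int
    p: float
    mean_ranks: dict[str, float]
    pairwise: list[PairwiseComparison] = field(default_factory=list)

    def min_adjusted_pair(self) -> PairwiseComparison:
        return min(self.pairwise, key=lambda c: c.p_adjusted)


@dataclass
class CorrelationResult:
    var_x: str
    var_y: str
    n: int
    r: float
    p: float
    significant: bool | None = None


def _as_groups(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]
               ) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, Mapping):
        names = list(groups.keys())
        arrays = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        names = [f"group{i + 1}" for i in range(len(groups))]
        arrays = [np.asarray(g, dtype=float) for g in groups]
    return names, arrays


def pairwise_posthoc(groups: Mapping[str, Sequence[float]] |
                     Sequence[Sequence[float]]) -> list[PairwiseComparison]:
    """Dunn-type pairwise z-tests on pooled mean ranks, Bonferroni-adjusted.

    For groups i, j: ``z = (Rbar_i - Rbar_j) / SE`` with
    ``SE = sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))`` and the tie term
    ``T = sum(t^3 - t) / (12 (N - 1))``. Adjusted p = min(1, m * p_raw)
    with m the number of pairs.
    """
    names, arrays = _as_groups(groups)
    pooled = np.concatenate(arrays)
    n_tot = pooled.size
    ranks = sstats.rankdata(pooled)
    bounds = np.cumsum([0] + [a.size for a in arrays])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(arrays))]
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts ** 3 - counts).sum() / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    variance = n_tot * (n_tot + 1) / 12.0 - tie
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(variance * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        if se < 1e-15:  # all pooled values identical
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * sstats.norm.sf(abs(z))
        out.append(PairwiseComparison(names[i], names[j], float(z),
                                      float(p_raw),
                                      float(min(1.0, n_pairs * p_raw))))
    return out


def kruskal_wallis(groups: Mapping[str, Sequence[float]] |
                   Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected H against chi-square (df = k-1), plus Dunn post hoc."""
    names, arrays = _as_groups(groups)
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(arrays)
    df = len(arrays) - 1
    if np.ptp(pooled) < 1e-15:  # all values identical
        h, p = 0.0, 1.0
    else:
        h, p = sstats.kruskal(*arrays)
    ranks = sstats.rankdata(pooled)
    bounds = np.cumsum([0] + [a.size for a in arrays])
    mean_ranks = {names[i]: float(ranks[bounds[i]:bounds[i + 1]].mean())
                  for i in range(len(arrays))}
    return KWResult(float(h), df, float(p), mean_ranks,
                    pairwise_posthoc(groups))


def pearson(x: Sequence[float], y: Sequence[float],
            names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Product-moment r with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs equal-length samples with n >= 3")
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        raise ValueError("pearson undefined for zero-variance input")
    r, p = sstats.pearsonr(x, y)
    return CorrelationResult(names[0], names[1], int(x.size),
                             float(r), float(p))


def default_screen_pairs() -> list[tuple[str, str]]:
    """Clinical variables against the behavioral/EEG measures and Z3, plus
    the pairs among the clinical variables themselves (21 pairs).

    Component-versus-own-composite pairs (e.g. P3 latency against Z3) are
    deliberately excluded: they are correlated by construction and answer no
    clinical question.
    """
    pairs = [(c, m) for c in CLINICAL_VARIABLES for m in MEASURE_VARIABLES]
    pairs += list(itertools.combinations(CLINICAL_VARIABLES, 2))
    return pairs


def correlation_screen(table: pd.DataFrame,
                       pairs: Sequence[tuple[str, str]] | None = None,
                       family_size: int = 25,
                       alpha: float = 0.05,
                       patients_only: bool = True
                       ) -> list[CorrelationResult]:
    """Pearson screen with a Bonferroni-style adjusted significance level.

    Clinical scores exist for patients only, so the screen pools the patient
    rows (the default drops healthy rows entirely). ``family_size`` sets the
    adjusted level ``alpha / family_size`` independently of the number of
    pairs actually computed. Pairs with fewer than 3 complete observations
    are skipped with a warning.
    """
    if pairs is None:
        pairs = default_screen_pairs()
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    sub = table[table["group"] != "healthy"] if patients_only else table
    threshold = alpha / family_size
    results: list[CorrelationResult] = []
    for a, b in pairs:
        pair_df = sub[[a, b]].dropna()
        if len(pair_df) < 3:
            warnings.warn(f"skipping {a}-{b}: only {len(pair_df)} complete "
                          "observations", RuntimeWarning, stacklevel=2)
            continue
        res = pearson(pair_df[a].to_numpy(), pair_df[b].to_numpy(), (a, b))
        res.significant = res.p < threshold
        results.append(res)
    return results
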