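"""Positional composition statistics for splice-site sets.

Covers the logo-input frequency matrices, G-tests of base composition
between two site sets (summed over the -2..+5 donor positions by default),
U5 x U6 class contingency tables ordered by class mean log-likelihood, the
+4-base / direction-of-change table for alternative donor pairs, and
Spearman correlations of U5 vs U6 scores or log-odds ratios.

The G statistic is G = 2 sum O ln(O/E) with expectations from the pooled
margins; zero observed cells contribute 0 and base columns that are absent
from both sets are dropped from the degrees of freedom.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import order_classes_by_loglik, plus4_base, u5_class, u6_class
from .pssm import BASES, Pssm, score

log = logging.getLogger(__name__)

__all__ = [
    "FreqMatrix",
    "GTestResult",
    "freq_matrix",
    "g_test_composition",
    "class_contingency",
    "plus4_direction_table",
    "score_correlation",
    "DONOR_GTEST_POSITIONS",
]

#: Donor positions tested for composition differences (-2..+5, no 0).
DONOR_GTEST_POSITIONS: tuple[int, ...] = (-2, -1, 1, 2, 3, 4, 5)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class FreqMatrix:
    """Empirical per-position base probabilities (logo input, no pseudocount)."""

    positions: tuple[int, ...]
    probs: np.ndarray  # (n_positions, 4), rows sum to 1
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(self.positions), columns=list(BASES))

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("position").to_csv(path, sep="\t")

    def prob(self, position: int, base: str) -> float:
        return float(self.probs[self.positions.index(position), _BASE_INDEX[base]])


def _counts(sites: Sequence, positions: Sequence[int]) -> np.ndarray:
    counts = np.zeros((len(positions), 4))
    for w in sites:
        for i, pos in enumerate(positions):
            b = w.base(pos) if hasattr(w, "base") else w[i]
            if b in _BASE_INDEX:
                counts[i, _BASE_INDEX[b]] += 1
    return counts


def freq_matrix(sites: Sequence, positions: Sequence[int]) -> FreqMatrix:
    """Empirical base probabilities per position; N bases excluded per position."""
    sites = list(sites)
    if not sites:
        raise ValueError("cannot build a frequency matrix from an empty site set")
    positions = tuple(positions)
    counts = _counts(sites, positions)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("a position has no unambiguous bases")
    return FreqMatrix(positions, counts / totals, len(sites))


@dataclass(frozen=True)
class GTestResult:
    g: float
    df: int
    p: float
    per_position: dict[int, tuple[float, int]]


def _g_one_position(obs: np.ndarray, williams: bool = False) -> tuple[float, int]:
    """G and df for one groups x bases table; zero-total columns dropped."""
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    n = obs.sum()
    if obs.shape[1] < 2 or n == 0:
        return 0.0, 0
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * float(terms.sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if williams and df > 0:
        q = 1.0 + (
            (n * (1.0 / row).sum() - 1.0) * (n * (1.0 / col).sum() - 1.0)
        ) / (6.0 * n * df)
        g /= q
    return g, df


def g_test_composition(
    sites_a: Sequence,
    sites_b: Sequence,
    positions: Sequence[int] = DONOR_GTEST_POSITIONS,
    williams: bool = False,
) -> GTestResult:
    """Per-position group x base G-tests summed over ``positions``.

    Positions where either set has no unambiguous base are skipped with a log
    entry.  The p-value is the chi-square upper tail at the summed df.
    """
    sites_a, sites_b = list(sites_a), list(sites_b)
    if not sites_a or not sites_b:
        raise ValueError("both site sets must be non-empty")
    positions = tuple(positions)
    counts_a = _counts(sites_a, positions)
    counts_b = _counts(sites_b, positions)
    total_g = 0.0
    total_df = 0
    per_position = {}
    for i, pos in enumerate(positions):
        if counts_a[i].sum() == 0 or counts_b[i].sum() == 0:
            log.warning("position %+d skipped: one set has no unambiguous bases", pos)
            continue
        g, df = _g_one_position(np.vstack([counts_a[i], counts_b[i]]), williams)
        per_position[pos] = (g, df)
        total_g += g
        total_df += df
    p = float(stats.chi2.sf(total_g, total_df)) if total_df > 0 else 1.0
    return GTestResult(total_g, total_df, p, per_position)


@dataclass(frozen=True)
class ClassContingency:
    """U5 class x U6 class site counts, axes ordered by class mean
    log-likelihood (strongest class first)."""

    table: pd.DataFrame

    @property
    def n_sites(self) -> int:
        return int(self.table.to_numpy().sum())


def class_contingency(sites: Sequence, pssm_u5: Pssm, pssm_u6: Pssm) -> ClassContingency:
    sites = list(sites)
    if not sites:
        raise ValueError("empty site set")
    u5 = [u5_class(w) for w in sites]
    u6 = [u6_class(w) for w in sites]
    row_order = order_classes_by_loglik(sites, pssm_u5, u5_class)
    col_order = order_classes_by_loglik(sites, pssm_u6, u6_class)
    table = pd.crosstab(pd.Series(u5, name="u5_class"), pd.Series(u6, name="u6_class"))
    table = table.reindex(index=row_order, columns=col_order, fill_value=0)
    return ClassContingency(table)


def plus4_direction_table(
    pairs: Iterable[tuple],
) -> tuple[pd.DataFrame, float]:
    """2x2 table of (+4 is A vs not) x (reduced vs increased usage) over the
    sites of lost/gained donor pairs, plus the separation rate: the fraction
    of sites consistent with the A+4-lost / B+4-gained rule."""
    counts = pd.DataFrame(
        0, index=["A+4", "B+4"], columns=["reduced_usage", "increased_usage"]
    )
    consistent = 0
    total = 0
    for lost, gained in pairs:
        for window, col in ((lost, "reduced_usage"), (gained, "increased_usage")):
            is_a = plus4_base(window) == "A"
            counts.loc["A+4" if is_a else "B+4", col] += 1
            if (col == "reduced_usage") == is_a:
                consistent += 1
            total += 1
    if total == 0:
        raise ValueError("no pairs supplied")
    return counts, consistent / total


def score_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation over complete pairs (>= 3 required)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        raise ValueError("need at least 3 complete pairs for a rank correlation")
    rho, p = stats.spearmanr(x[mask], y[mask])
    return float(rho), float(p)
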