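"""Sequence-slotting dissimilarity (psi) between multivariate ordered series.

Two ordered multivariate series A (m positions) and B (n positions) are
compared by sliding along a least-cost monotone path through their pairwise
Euclidean distance matrix (moves: advance A, advance B, or both when
diagonals are allowed).  The summed distance along that path (AB_between) is
normalized by the summed distance between consecutive positions within each
series (AB_within):

    psi = ((AB_between - AB_within) / AB_within) + 1

With diagonal moves the path over two identical series has zero cost, so
psi(a, a) = 0; larger psi means more dissimilar sequences.

The module also provides the 500-year binning used to run the comparison in
"transposed" mode (pollen types as ordered positions, time bins as
variables) and the leave-one-bin-out attribution of dissimilarity to time
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .records import PercentageRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MultivariateSeries",
    "PsiResult",
    "DropResult",
    "distance_matrix",
    "least_cost_path",
    "psi",
    "align_variables",
    "bin_time_intervals",
    "drop_analysis",
]


@dataclass
class MultivariateSeries:
    """An ordered multivariate series: ordering axis x named variables.

    In the standard orientation the ordering axis is depth/age samples and
    the variables are pollen types; in transposed mode the ordering axis is
    pollen types and the variables are time bins.
    """

    name: str
    values: pd.DataFrame  # index: ordering axis labels, columns: variables

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2:
            raise ValueError(
                f"series {self.name!r} needs at least 2 positions on the ordering axis"
            )
        if self.values.isna().to_numpy().any():
            raise ValueError(f"series {self.name!r} contains missing values")

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def drop_variable(self, variable) -> "MultivariateSeries":
        return MultivariateSeries(self.name, self.values.drop(columns=[variable]))


@dataclass
class PsiResult:
    """psi with its components and one optimal least-cost path."""

    psi: float
    ab_between: float
    ab_within: float
    path: list[tuple[int, int]]  # 0-based (position in a, position in b)
    diagonals: bool = True


@dataclass
class DropResult:
    """Leave-one-bin-out attribution of psi to time intervals.

    ``drop_percent[b] = 100 * (psi_full - psi_without_b) / psi_full``:
    large positive values mark intervals whose removal makes the sequences
    more similar, i.e. intervals responsible for the dissimilarity.
    """

    bins: list
    drop_percent: pd.Series
    psi_full: float


def distance_matrix(a: MultivariateSeries, b: MultivariateSeries) -> np.ndarray:
    """Pairwise Euclidean distances between positions of a and b.

    Variables are aligned by label; asymmetric variable sets are an error
    (see :func:`align_variables` for the zero-fill union alignment used when
    comparing harmonization levels with different indicator sets).
    """
    va, vb = set(a.variables), set(b.variables)
    if va != vb:
        only_a, only_b = sorted(va - vb), sorted(vb - va)
        raise ValueError(
            f"variable sets differ: only in {a.name!r}: {only_a}; "
            f"only in {b.name!r}: {only_b}"
        )
    bv = b.values.loc[:, a.variables]
    return cdist(a.values.to_numpy(float), bv.to_numpy(float), metric="euclidean")


def least_cost_path(
    d: np.ndarray, diagonals: bool = True
) -> tuple[float, list[tuple[int, int]]]:
    """Minimal-cost monotone path from (0, 0) to (m-1, n-1) through ``d``.

    The cost is the sum of ``d`` over every visited cell, both endpoints
    included.  Allowed steps advance the first index, the second, or (when
    ``diagonals``) both.  Ties are broken preferring the diagonal step, then
    the step advancing the first sequence.  Returns ``(cost, path)``.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.size == 0:
        raise ValueError("distance matrix must be a non-empty 2-D array")
    if not np.all(np.isfinite(d)) or np.any(d < 0):
        raise ValueError("distance matrix must be finite and non-negative")
    m, n = d.shape
    acc = np.full((m, n), np.inf)
    acc[0, 0] = d[0, 0]
    for i in range(m):
        row = acc[i]
        prev = acc[i - 1] if i else None
        for j in range(n):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i and prev[j] < best:
                best = prev[j]
            if j and row[j - 1] < best:
                best = row[j - 1]
            if diagonals and i and j and prev[j - 1] < best:
                best = prev[j - 1]
            acc[i, j] = best + d[i, j]
    # Backtrack; tie-break: diagonal first, then advance the first sequence.
    path = [(m - 1, n - 1)]
    i, j = m - 1, n - 1
    while (i, j) != (0, 0):
        candidates = []
        if diagonals and i and j:
            candidates.append((acc[i - 1, j - 1], 0, (i - 1, j - 1)))
        if i:
            candidates.append((acc[i - 1, j], 1, (i - 1, j)))
        if j:
            candidates.append((acc[i, j - 1], 2, (i, j - 1)))
        _, _, (i, j) = min(candidates)
        path.append((i, j))
    path.reverse()
    return float(acc[m - 1, n - 1]), path


def _within(values: np.ndarray) -> float:
    """Sum of Euclidean distances between consecutive positions."""
    diffs = np.diff(values, axis=0)
    return float(np.sqrt((diffs**2).sum(axis=1)).sum())


def psi(
    a: MultivariateSeries, b: MultivariateSeries, diagonals: bool = True
) -> PsiResult:
    """Sequence-slotting dissimilarity between two series sharing variables.

    ``ab_between`` is the least-cost-path cost through the Euclidean distance
    matrix; ``ab_within`` the summed consecutive-position distance within
    each series.  Both series constant (``ab_within == 0``) is degenerate.
    """
    d = distance_matrix(a, b)
    ab_between, path = least_cost_path(d, diagonals=diagonals)
    ab_within = _within(a.values.to_numpy(float)) + _within(
        b.values.loc[:, a.variables].to_numpy(float)
    )
    if ab_within == 0:
        raise ValueError(
            "degenerate sequences: both series are constant (AB_within = 0)"
        )
    value = (ab_between - ab_within) / ab_within + 1.0
    return PsiResult(
        psi=float(value),
        ab_between=ab_between,
        ab_within=ab_within,
        path=path,
        diagonals=diagonals,
    )


def align_variables(
    a: MultivariateSeries, b: MultivariateSeries, fill: float = 0.0
) -> tuple[MultivariateSeries, MultivariateSeries]:
    """Align two series on the union of their variable labels, filling ``fill``.

    Used to compare harmonization levels whose indicator-type sets differ: a
    type merged away at the coarser level genuinely contributes nothing at
    the level where it does not exist.
    """
    union = sorted(set(a.variables) | set(b.variables))
    return (
        MultivariateSeries(a.name, a.values.reindex(columns=union, fill_value=fill)),
        MultivariateSeries(b.name, b.values.reindex(columns=union, fill_value=fill)),
    )


def bin_time_intervals(
    pct: PercentageRecord,
    width: float = 500.0,
    order_key: Optional[dict] = None,
    name: Optional[str] = None,
) -> MultivariateSeries:
    """Transposed series: pollen types (ordered positions) x time bins (variables).

    Bin edges sit on multiples of ``width`` cal yr BP; a bin ``[k*w, (k+1)*w)``
    is labelled by its older edge ``(k+1)*w`` (post-1950 samples fall in the
    ``[-w, 0)`` bin labelled 0).  The value for (type, bin) is the mean of the
    type's *non-zero* percentages among samples in the bin; a type absent from
    a bin scores 0.  Rows are ordered by ``order_key`` (e.g. the coarser-level
    harmonized label) then type name; default is alphabetical.
    """
    ages = pct.ages
    if len(ages) == 0:
        raise ValueError("no samples in the analysis window")
    k = np.floor(ages / width).astype(int)
    labels = (k + 1) * int(width)  # older bin edge
    present = sorted(set(labels))
    vals = pct.values
    out = pd.DataFrame(0.0, index=list(vals.columns), columns=present)
    for lab in present:
        sub = vals.loc[labels == lab]
        nonzero_sum = sub.where(sub > 0).sum(axis=0)
        nonzero_n = (sub > 0).sum(axis=0)
        means = nonzero_sum.div(nonzero_n.replace(0, np.nan)).fillna(0.0)
        out[lab] = means
    key = order_key or {}
    order = sorted(out.index, key=lambda t: (str(key.get(t, t)), t))
    out = out.loc[order]
    return MultivariateSeries(name or pct.site_name, out)


def drop_analysis(
    a: MultivariateSeries, b: MultivariateSeries, diagonals: bool = True
) -> DropResult:
    """Leave-one-bin-out psi drops for transposed series sharing bin labels.

    The two series must carry identical variable (bin) labels; their ordering
    axes (pollen types) need not match, since psi is defined over the ordering
    axis.  Bins whose removal would leave fewer than 2 variables are skipped
    with a warning.
    """
    if list(a.variables) != list(b.variables):
        raise ValueError(
            f"bin labels differ between {a.name!r} and {b.name!r}: "
            f"{a.variables} vs {b.variables}"
        )
    psi_full = psi(a, b, diagonals=diagonals).psi
    if psi_full == 0:
        raise ValueError("psi_full = 0: no dissimilarity to attribute to bins")
    drops: dict = {}
    for variable in a.variables:
        if len(a.variables) - 1 < 2:
            logger.warning("skipping bin %r: fewer than 2 variables would remain", variable)
            continue
        p = psi(a.drop_variable(variable), b.drop_variable(variable), diagonals=diagonals)
        drops[variable] = 100.0 * (psi_full - p.psi) / psi_full
    series = pd.Series(drops, name="drop_percent")
    return DropResult(bins=list(series.index), drop_percent=series, psi_full=psi_full)
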