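"""Change-point detection in summed anthropogenic pollen curves.

Binary segmentation with a Gaussian mean-and-variance cost: a segment's cost
is twice its negative log-likelihood under a normal distribution with the
segment's own MLE mean and variance.  A split at position tau is accepted
when

    cost(whole) > cost(left) + cost(right) + beta

and segments are split greedily in order of decreasing cost reduction, up to
``max_cp`` change points.  Samples are treated as an ordered sequence (index
domain); calibrated ages are carried along for reporting only, the standard
practice for unevenly spaced stratigraphic series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "segment_cost",
    "BinarySegmentation",
    "binary_segmentation",
    "ChangePointResult",
]

_LOG2PI = float(np.log(2.0 * np.pi))
#: Variance floor guarding the log-likelihood against constant segments.
VAR_EPS = 1e-8


def segment_cost(y: Sequence[float], model: str = "meanvar") -> float:
    """Twice the negative Gaussian log-likelihood of a slice.

    ``meanvar``: the slice's own MLE mean and variance (variance floored at
    a small epsilon), so cost = n * (log(2*pi) + log(var) + 1).  ``mean``:
    residual sum of squares about the slice mean (unit variance), the
    mean-shift-only cost.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    if model == "meanvar":
        var = max(float(np.var(y)), VAR_EPS)
        return y.size * (_LOG2PI + np.log(var) + 1.0)
    if model == "mean":
        return float(np.sum((y - y.mean()) ** 2))
    raise ValueError(f"unknown cost model {model!r}")


@dataclass
class ChangePointResult:
    """Detected change points with per-segment statistics.

    ``tau`` holds 0-based indices of the last sample of each segment but the
    final one (the convention in which a change point at tau splits
    ``y[:tau+1]`` from ``y[tau+1:]``), strictly increasing.
    """

    tau: list[int]
    ages: list[float]
    segments: pd.DataFrame  # start, end (inclusive), mean, variance per segment
    penalty_beta: float
    max_cp: int
    model: str = "meanvar"
    n: int = 0

    @property
    def n_changepoints(self) -> int:
        return len(self.tau)

    def summary(self) -> str:
        lines = [
            "Binary segmentation change-point analysis",
            f"  cost model: {self.model}, penalty beta = {self.penalty_beta:.4g}, "
            f"max change points = {self.max_cp}",
            f"  n = {self.n} samples, {self.n_changepoints} change point(s)",
        ]
        for t, a in zip(self.tau, self.ages):
            lines.append(f"  change point after sample {t} (age {a:g} cal yr BP)")
        lines.append("  segments:")
        for _, row in self.segments.iterrows():
            lines.append(
                f"    [{int(row.start)}, {int(row.end)}]  "
                f"mean = {row['mean']:.4g}  var = {row['variance']:.4g}"
            )
        return "\n".join(lines)


class BinarySegmentation:
    """Greedy binary-segmentation model for a univariate ordered series.

    Parameters
    ----------
    y : array-like
        The series (e.g. the total anthropogenic indicator curve), already
        restricted to the analysis window.
    ages : array-like, optional
        Per-sample ages (cal yr BP) used only to report change-point ages.
    model : {"meanvar", "mean"}
        Detect shifts in mean and variance jointly (default) or mean only.
    max_cp : int
        Maximum number of change points to search for (default 4).
    penalty : float, optional
        Acceptance penalty beta; default is an MBIC-style
        ``3 * log(n) * k`` with ``k`` parameters per change point
        (2 for meanvar, 1 for mean).
    min_size : int
        Minimum samples per segment (default 2).
    """

    def __init__(
        self,
        y: Sequence[float],
        ages: Optional[Sequence[float]] = None,
        model: str = "meanvar",
        max_cp: int = 4,
        penalty: Optional[float] = None,
        min_size: int = 2,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        if n < 4:
            raise ValueError("series too short for change-point detection (need >= 4)")
        if model not in ("meanvar", "mean"):
            raise ValueError(f"unknown cost model {model!r}")
        if ages is not None and len(ages) != n:
            raise ValueError("ages must align with the series")
        self.ages = None if ages is None else np.asarray(ages, dtype=float)
        self.model = model
        self.max_cp = int(max_cp)
        self.min_size = int(min_size)
        k = 2 if model == "meanvar" else 1
        self.penalty = float(penalty) if penalty is not None else 3.0 * np.log(n) * k
        # Prefix sums give O(1) segment costs.
        self._c1 = np.concatenate([[0.0], np.cumsum(self.y)])
        self._c2 = np.concatenate([[0.0], np.cumsum(self.y**2)])

    def _cost(self, start: int, end: int) -> float:
        """Cost of the inclusive slice y[start:end+1]."""
        n = end - start + 1
        s1 = self._c1[end + 1] - self._c1[start]
        s2 = self._c2[end + 1] - self._c2[start]
        var = max(s2 / n - (s1 / n) ** 2, 0.0)
        if self.model == "mean":
            return var * n
        return n * (_LOG2PI + np.log(max(var, VAR_EPS)) + 1.0)

    def _best_split(self, start: int, end: int):
        """Best tau in [start, end): minimal cost(left) + cost(right)."""
        best_tau, best_cost = None, np.inf
        for tau in range(start + self.min_size - 1, end - self.min_size + 1):
            c = self._cost(start, tau) + self._cost(tau + 1, end)
            if c < best_cost:
                best_tau, best_cost = tau, c
        return best_tau, best_cost

    def fit(self) -> ChangePointResult:
        """Run the greedy search and return the detected change points."""
        segments = [(0, self.y.size - 1)]
        taus: list[int] = []
        while len(taus) < self.max_cp:
            best = None  # (gain, tau, segment index)
            for idx, (s, e) in enumerate(segments):
                if e - s + 1 < 2 * self.min_size:
                    continue
                tau, split_cost = self._best_split(s, e)
                if tau is None:
                    continue
                gain = self._cost(s, e) - split_cost
                if best is None or gain > best[0]:
                    best = (gain, tau, idx)
            if best is None or best[0] <= self.penalty:
                break
            gain, tau, idx = best
            s, e = segments.pop(idx)
            segments[idx:idx] = [(s, tau), (tau + 1, e)]
            taus.append(tau)
        taus.sort()
        segments.sort()
        seg_rows = [
            {
                "start": s,
                "end": e,
                "mean": float(self.y[s : e + 1].mean()),
                "variance": float(np.var(self.y[s : e + 1])),
            }
            for s, e in segments
        ]
        ages = (
            [float(self.ages[t]) for t in taus] if self.ages is not None else
            [float(t) for t in taus]
        )
        return ChangePointResult(
            tau=taus,
            ages=ages,
            segments=pd.DataFrame(seg_rows, columns=["start", "end", "mean", "variance"]),
            penalty_beta=self.penalty,
            max_cp=self.max_cp,
            model=self.model,
            n=self.y.size,
        )


def binary_segmentation(
    y: Sequence[float],
    max_cp: int = 4,
    beta: Optional[float] = None,
    ages: Optional[Sequence[float]] = None,
    model: str = "meanvar",
    min_size: int = 2,
) -> ChangePointResult:
    """Functional wrapper around :class:`BinarySegmentation`."""
    return BinarySegmentation(
        y, ages=ages, model=model, max_cp=max_cp, penalty=beta, min_size=min_size
    ).fit()
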