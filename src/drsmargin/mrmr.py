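"""Minimum-redundancy-maximum-relevance feature ranking.

Features are discretized by equal-frequency binning (default 10 bins) and
ranked by greedy forward selection: the first feature maximizes the
mutual information MI(f; y) with the binary label; each subsequent feature
maximizes the MID score

    score(f) = MI(f; y) - (1/|S|) * sum_{s in S} MI(f; s)

over the already-selected set S.  Scores are recorded at selection time
and reported in bits (log base 2).  Features whose selection-time score is
>= the threshold (default 0.015) form the selected subset.

Ranking and selection happen inside each training fold; per-fold selections
may differ, and the reported "optimum feature" list is the modal selection
across folds.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureRanking",
    "discretize",
    "mutual_information",
    "mrmr_rank",
    "apply_threshold",
    "modal_selection",
]

DEFAULT_THRESHOLD = 0.015
DEFAULT_BINS = 10


@dataclass(frozen=True)
class FeatureRanking:
    """Greedy MRMR ranking: names and scores in selection order."""

    names: tuple[str, ...]
    scores: tuple[float, ...]
    threshold: float
    n_bins: int
    scheme: str

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(n for n, s in zip(self.names, self.scores) if s >= self.threshold)


def discretize(x: np.ndarray, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-frequency binning into integer codes 0..n_bins-1.

    Bin edges are empirical quantiles; ties that straddle an edge are
    broadened to the right (all equal values land in one bin, courtesy of
    ``searchsorted(..., side="right")`` on deduplicated edges).
    """
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise ValueError("discretize expects a 1-D feature")
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right").astype(np.int64)


def _codes(y: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(np.asarray(y), return_inverse=True)
    return codes.astype(np.int64), int(codes.max()) + 1


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two discrete vectors.

    Continuous inputs should be passed through :func:`discretize` first.
    A constant input carries no information and returns 0 by convention.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    cx, nx = _codes(x)
    cy, ny = _codes(y)
    if nx == 1 or ny == 1:
        return 0.0
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny).astype(float)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def _mi_from_codes(cx: np.ndarray, nx: int, cy: np.ndarray, ny: int) -> float:
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny).astype(float)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px[:, None] * py[None, :])[nz])))


def _mi_batch(codes: np.ndarray, rows: np.ndarray, nx_max: int, cy: np.ndarray, ny: int) -> np.ndarray:
    """MI (bits) of each codes[rows[i]] against cy, in one bincount pass."""
    m = rows.size
    if m == 0:
        return np.empty(0)
    w = nx_max * ny
    comb = codes[rows] * ny + cy[None, :] + (np.arange(m)[:, None] * w)
    joint = np.bincount(comb.ravel(), minlength=m * w).reshape(m, nx_max, ny).astype(float)
    n = codes.shape[1]
    joint /= n
    px = joint.sum(axis=2)
    py = joint.sum(axis=1)
    outer = px[:, :, None] * py[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / outer)
    return np.nansum(terms, axis=(1, 2))


def mrmr_rank(
    features: np.ndarray,
    labels: np.ndarray,
    names: list[str] | tuple[str, ...] | None = None,
    n_bins: int = DEFAULT_BINS,
    threshold: float = DEFAULT_THRESHOLD,
    scheme: str = "MID",
) -> FeatureRanking:
    """Rank all columns of ``features`` by greedy MRMR against ``labels``.

    ``scheme`` is ``"MID"`` (relevance minus mean redundancy, default) or
    ``"MIQ"`` (relevance divided by mean redundancy).  The full ranking
    covers every feature; the redundancy term uses lazily computed pairwise
    MI so the cost is one MI evaluation per (selected, remaining) pair.
    """
    X = np.asarray(features, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D feature table with >= 2 features")
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    if scheme not in ("MID", "MIQ"):
        raise ValueError(f"unknown MRMR scheme {scheme!r}")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("names must match feature count")

    codes = np.empty((p, n), dtype=np.int64)
    n_codes = np.empty(p, dtype=np.int64)
    for j in range(p):
        c = discretize(X[:, j], n_bins)
        codes[j] = c
        n_codes[j] = c.max() + 1
    cy, ny = _codes(y)

    nx_max = int(n_codes.max())
    all_rows = np.arange(p)
    relevance = _mi_batch(codes, all_rows, nx_max, cy, ny)
    redundancy_sum = np.zeros(p)
    remaining = np.ones(p, dtype=bool)
    order: list[int] = []
    scores: list[float] = []

    for step in range(p):
        if step == 0:
            crit = np.where(remaining, relevance, -np.inf)
        else:
            mean_red = redundancy_sum / step
            if scheme == "MID":
                crit = np.where(remaining, relevance - mean_red, -np.inf)
            else:
                crit = np.where(remaining, relevance / np.maximum(mean_red, 1e-12), -np.inf)
        j = int(np.argmax(crit))
        order.append(j)
        scores.append(float(crit[j]))
        remaining[j] = False
        idx = np.flatnonzero(remaining)
        redundancy_sum[idx] += _mi_batch(codes, idx, nx_max, codes[j], int(n_codes[j]))

    return FeatureRanking(
        names=tuple(names[j] for j in order),
        scores=tuple(scores),
        threshold=threshold,
        n_bins=n_bins,
        scheme=scheme,
    )


def apply_threshold(ranking: FeatureRanking, threshold: float | None = None) -> tuple[str, ...]:
    """Features with selection-time score >= threshold, in ranking order."""
    if threshold is None:
        threshold = ranking.threshold
    selected = tuple(n for n, s in zip(ranking.names, ranking.scores) if s >= threshold)
    if not selected:
        warnings.warn(
            "no feature reaches the MRMR importance threshold; "
            "downstream training will refuse an empty feature set",
            stacklevel=2,
        )
    return selected


def modal_selection(per_fold_selected: list[tuple[str, ...]]) -> tuple[str, ...]:
    """Features selected in a majority of folds (the reported optimum list).

    Ordered by selection frequency, ties broken by earliest mean rank.
    """
    if not per_fold_selected:
        return ()
    counts = Counter(name for sel in per_fold_selected for name in sel)
    majority = len(per_fold_selected) / 2.0
    rank_sums: dict[str, float] = {}
    for sel in per_fold_selected:
        for r, name in enumerate(sel):
            rank_sums[name] = rank_sums.get(name, 0.0) + r
    keep = [n for n, c in counts.items() if c >= majority]
    keep.sort(key=lambda n: (-counts[n], rank_sums[n] / counts[n], n))
    return tuple(keep)
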