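"""Window similarity metrics and sliding-window placement search.

A frame of ``w`` bins slides across each region of ``m`` bins; by
convention there are ``S = m - w`` admissible start offsets, half-open
``[0, S)``.  This convention (rather than ``m - w + 1``) is what the
candidate-pair arithmetic of :func:`count_candidate_pairs` is built on.

In pairwise search only one region's frame slides while the other is held
fixed at the centered offset ``S // 2`` ("anchor and slide"), giving ``S``
candidates per ordered pair, or ``2S`` when reversal is enabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata

from .signal import RegionProfile

__all__ = [
    "Metric",
    "get_metric",
    "METRIC_NAMES",
    "WindowPlacement",
    "SeedPair",
    "score",
    "extract_window",
    "best_window_pair",
    "best_window_vs_profile",
    "count_candidate_pairs",
    "iter_pair_candidates",
    "WindowBank",
]

METRIC_NAMES = ("pearson", "spearman", "euclidean")


@dataclass(frozen=True)
class Metric:
    """A similarity/distance metric with a well-defined "better" ordering."""

    name: str
    higher_is_better: bool

    def better(self, a: float, b: float) -> bool:
        """True when score ``a`` is strictly better than ``b``."""
        return a > b if self.higher_is_better else a < b

    @property
    def worst(self) -> float:
        return -np.inf if self.higher_is_better else np.inf

    def best_of(self, scores: np.ndarray) -> int:
        """Index of the best score; first occurrence wins on ties."""
        return int(np.argmax(scores) if self.higher_is_better else np.argmin(scores))


_METRICS = {
    "pearson": Metric("pearson", True),
    "spearman": Metric("spearman", True),
    "euclidean": Metric("euclidean", False),
}


def get_metric(name: str | Metric) -> Metric:
    if isinstance(name, Metric):
        return name
    try:
        return _METRICS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown metric {name!r}; choose from {METRIC_NAMES}"
        ) from None


@dataclass(frozen=True)
class WindowPlacement:
    """Placement of the alignment frame within one region."""

    region_index: int
    start_bin: int
    reversed: bool = False


@dataclass(frozen=True)
class SeedPair:
    """The best-scoring pair of window placements seeding an alignment."""

    placement_a: WindowPlacement
    placement_b: WindowPlacement
    score: float

    def __post_init__(self) -> None:
        if self.placement_a.region_index == self.placement_b.region_index:
            raise ValueError("seed pair must involve two distinct regions")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        warnings.warn(
            "constant window under a correlation metric; score set to 0.0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return float((xd @ yd) / denom)


def score(metric: str | Metric, x: np.ndarray, y: np.ndarray) -> float:
    """Score two equal-length windows under the given metric.

    Pearson is the sample correlation, Spearman is Pearson on mid-ranks
    (average-rank ties), Euclidean is the root of the summed squared
    differences.  A constant window under a correlation metric scores 0.0
    (with a warning) rather than NaN.
    """
    metric = get_metric(metric)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("windows must be 1-D with length >= 2")
    if metric.name == "pearson":
        return _pearson(x, y)
    if metric.name == "spearman":
        return _pearson(rankdata(x), rankdata(y))
    return float(np.sqrt(((x - y) ** 2).sum()))


def extract_window(
    profile: RegionProfile | np.ndarray,
    placement: WindowPlacement,
    frame_bins: int,
) -> np.ndarray:
    """Slice the frame out of a profile, reversing bin order if requested."""
    values = profile.values if isinstance(profile, RegionProfile) else np.asarray(profile, dtype=float)
    m = len(values)
    s = placement.start_bin
    if not (0 <= s and s + frame_bins <= m):
        raise ValueError(
            f"placement start {s} with frame {frame_bins} out of range for "
            f"{m}-bin profile"
        )
    window = values[s : s + frame_bins]
    return window[::-1].copy() if placement.reversed else window.copy()


# ---------------------------------------------------------------------------
# candidate bookkeeping
# ---------------------------------------------------------------------------

def n_starts(region_bins: int, frame_bins: int) -> int:
    """Number of admissible frame offsets S = m - w."""
    s = region_bins - frame_bins
    if s <= 0:
        raise ValueError(
            f"frame of {frame_bins} bins leaves no slack in a "
            f"{region_bins}-bin region"
        )
    return s


def count_candidate_pairs(
    n: int, region_bins: int, frame_bins: int, allow_reversal: bool
) -> int:
    """Number of candidate placements examined by the best-pair seed search.

    ``C(n, 2) * S`` placements without reversal and twice that with it,
    where ``S = region_bins - frame_bins``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 regions, got {n}")
    s = n_starts(region_bins, frame_bins)
    return comb(n, 2) * s * (2 if allow_reversal else 1)


def iter_pair_candidates(
    n: int, region_bins: int, frame_bins: int, allow_reversal: bool
) -> Iterator[tuple[int, int, int, bool]]:
    """Enumerate every (anchor, slider, start_bin, reversed) candidate.

    The enumeration order is the tie-breaking order of the search:
    ascending anchor index, ascending slider index, un-reversed before
    reversed, ascending start offset.
    """
    if n < 2:
        raise ValueError(f"need at least 2 regions, got {n}")
    s = n_starts(region_bins, frame_bins)
    for i in range(n - 1):
        for j in range(i + 1, n):
            for rev in (False, True) if allow_reversal else (False,):
                for start in range(s):
                    yield (i, j, start, rev)


# ---------------------------------------------------------------------------
# vectorized sliding-window scoring
# ---------------------------------------------------------------------------

class WindowBank:
    """Precomputed window views of a region matrix for fast frame search.

    Rows are laid out region-major; within a region the ``S`` un-reversed
    windows come first (ascending start), followed — when reversal is
    enabled — by the ``S`` reversed windows.  ``np.argmax`` over the
    flattened score array therefore breaks ties exactly in the documented
    enumeration order (lowest region, un-reversed first, lowest start).
    """

    def __init__(
        self,
        values: np.ndarray,
        frame_bins: int,
        metric: str | Metric,
        allow_reversal: bool,
    ) -> None:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if frame_bins < 2:
            raise ValueError("frame must span at least 2 bins")
        self.metric = get_metric(metric)
        self.n, self.m = values.shape
        self.w = int(frame_bins)
        self.S = n_starts(self.m, self.w)
        self.allow_reversal = bool(allow_reversal)
        self.R = 2 * self.S if allow_reversal else self.S

        win = sliding_window_view(values, self.w, axis=1)[:, : self.S]
        if allow_reversal:
            win = np.concatenate([win, win[:, :, ::-1]], axis=1)
        if self.metric.name == "spearman":
            win = rankdata(win, axis=-1)
        self.V = np.ascontiguousarray(win.reshape(self.n * self.R, self.w))
        self.sums = self.V.sum(axis=1)
        self.ssqs = (self.V * self.V).sum(axis=1)
        # per-window centered sum of squares (Pearson denominators)
        self.css = self.ssqs - self.sums * self.sums / self.w

    @property
    def center(self) -> int:
        """Fixed anchor offset S // 2."""
        return self.S // 2

    def _transform(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if len(p) != self.w:
            raise ValueError(f"profile length {len(p)} != frame {self.w}")
        return rankdata(p) if self.metric.name == "spearman" else p

    def scores_vs(self, p: np.ndarray) -> np.ndarray:
        """Score every stored window against vector ``p``; shape (n, R)."""
        t = self._transform(p)
        dots = self.V @ t
        if self.metric.name == "euclidean":
            ssq_t = t @ t
            d2 = np.maximum(self.ssqs - 2.0 * dots + ssq_t, 0.0)
            return np.sqrt(d2).reshape(self.n, self.R)
        sum_t = t.sum()
        css_t = t @ t - sum_t * sum_t / self.w
        cov = dots - self.sums * sum_t / self.w
        denom2 = self.css * css_t
        out = np.zeros_like(cov)
        ok = denom2 > 0
        out[ok] = cov[ok] / np.sqrt(denom2[ok])
        # guard rounding just beyond [-1, 1]
        np.clip(out, -1.0, 1.0, out=out)
        return out.reshape(self.n, self.R)

    def placement(self, region_index: int, flat_r: int) -> WindowPlacement:
        """Decode a column index of :meth:`scores_vs` into a placement."""
        rev = flat_r >= self.S
        return WindowPlacement(region_index, flat_r - self.S if rev else flat_r, rev)

    def window(self, region_index: int, flat_r: int) -> np.ndarray:
        """Oriented, untransformed window is not stored for spearman banks."""
        return self.V[region_index * self.R + flat_r]

    def centered_window(self, region_index: int) -> np.ndarray:
        """The (possibly rank-transformed) un-reversed centered window."""
        return self.V[region_index * self.R + self.center]


def _best_in_region_scores(metric: Metric, scores_r: np.ndarray) -> int:
    return int(np.argmax(scores_r) if metric.higher_is_better else np.argmin(scores_r))


def best_window_vs_profile(
    p: np.ndarray,
    z: RegionProfile | np.ndarray,
    frame_bins: int,
    metric: str | Metric = "pearson",
    allow_reversal: bool = False,
) -> tuple[WindowPlacement, float]:
    """Best placement of region ``z``'s frame against consensus vector ``p``.

    All ``S`` start offsets (and their reversed copies when enabled) are
    evaluated; returns the arg-best placement and its score, ties to the
    first candidate in enumeration order.
    """
    values = z.values if isinstance(z, RegionProfile) else np.asarray(z, dtype=float)
    bank = WindowBank(values[None, :], frame_bins, metric, allow_reversal)
    scores = bank.scores_vs(p)[0]
    r = _best_in_region_scores(bank.metric, scores)
    return bank.placement(0, r), float(scores[r])


def best_window_pair(
    a: RegionProfile | np.ndarray,
    b: RegionProfile | np.ndarray,
    frame_bins: int,
    metric: str | Metric = "pearson",
    allow_reversal: bool = False,
    region_index_a: int = 0,
    region_index_b: int = 1,
) -> SeedPair:
    """Anchor-and-slide search between two regions.

    ``a``'s frame is fixed at the centered offset ``S // 2``; ``b``'s frame
    is evaluated at every admissible offset, un-reversed and (optionally)
    reversed.  Exactly ``S`` candidates are scored without reversal and
    ``2S`` with it.
    """
    av = a.values if isinstance(a, RegionProfile) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, RegionProfile) else np.asarray(b, dtype=float)
    if len(av) != len(bv):
        raise ValueError("regions must have the same number of bins")
    metric = get_metric(metric)
    bank = WindowBank(bv[None, :], frame_bins, metric, allow_reversal)
    anchor_raw = av[bank.center : bank.center + frame_bins]
    scores = bank.scores_vs(anchor_raw)[0]
    r = _best_in_region_scores(metric, scores)
    return SeedPair(
        WindowPlacement(region_index_a, bank.center, False),
        bank.placement(region_index_b, r),
        float(scores[r]),
    )
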