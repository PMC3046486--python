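"""Progressive alignment of region profiles within a sliding frame.

Two strategies are provided.  ``single_best_pair`` seeds one progressive
alignment from the globally most similar pair of region windows;
``seed_sampling`` runs one forced-seed alignment per region and keeps the
one with the best post-alignment quality.  Both share the same greedy
core: the consensus starts as the mean of the two seed windows and each
remaining region is committed, best-scoring placement first, with the
consensus updated as a running mean ``P <- (P*(i-1) + Z) / i``.

All ties break to the earliest candidate in enumeration order (lowest
region index, un-reversed before reversed, lowest start offset), so runs
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .signal import RegionMatrix
from .similarity import (
    Metric,
    SeedPair,
    WindowBank,
    WindowPlacement,
    count_candidate_pairs,
    extract_window,
    get_metric,
)

__all__ = [
    "Alignment",
    "chosen_seed_alignment",
    "single_best_pair_alignment",
    "seed_sampling_alignment",
    "quality_assessment",
    "aligned_windows",
]


@dataclass
class Alignment:
    """A complete placement of every region within the alignment frame."""

    placements: list[WindowPlacement]
    consensus: np.ndarray
    addition_order: list[int]
    frame_bins: int
    metric: str
    allow_reversal: bool
    scores: list[float] = field(default_factory=list)
    quality: float | None = None
    seed: SeedPair | None = None

    @property
    def n(self) -> int:
        return len(self.placements)

    def start_bins(self) -> np.ndarray:
        return np.array([p.start_bin for p in self.placements], dtype=int)

    def reversed_flags(self) -> np.ndarray:
        return np.array([p.reversed for p in self.placements], dtype=bool)


def aligned_windows(alignment: Alignment, regions: RegionMatrix) -> np.ndarray:
    """The orientation-resolved frame of every region, shape (n, frame_bins)."""
    w = alignment.frame_bins
    return np.vstack(
        [
            extract_window(regions.values[p.region_index], p, w)
            for p in alignment.placements
        ]
    )


def _check_inputs(regions: RegionMatrix, frame_bins: int) -> None:
    if regions.n < 2:
        raise ValueError(f"alignment needs at least 2 regions, got {regions.n}")
    if frame_bins < 2 or frame_bins >= regions.m:
        raise ValueError(
            f"frame of {frame_bins} bins is degenerate for {regions.m}-bin regions"
        )


def chosen_seed_alignment(
    seed: SeedPair,
    regions: RegionMatrix,
    frame_bins: int,
    metric: str | Metric = "pearson",
    allow_reversal: bool = False,
    _bank: WindowBank | None = None,
) -> Alignment:
    """Greedy progressive alignment from a fixed seed pair.

    The consensus is initialized to the mean of the two orientation-resolved
    seed windows; then, repeatedly, the single (region, placement) with the
    best score against the consensus over all uncommitted regions and all
    their placements is committed, and the consensus updated by running mean.
    """
    metric = get_metric(metric)
    _check_inputs(regions, frame_bins)
    bank = _bank if _bank is not None else WindowBank(
        regions.values, frame_bins, metric, allow_reversal
    )
    n, w = regions.n, frame_bins
    ia = seed.placement_a.region_index
    ib = seed.placement_b.region_index
    for idx in (ia, ib):
        if not 0 <= idx < n:
            raise ValueError(f"seed region index {idx} outside matrix of {n} regions")

    placements: dict[int, WindowPlacement] = {
        ia: seed.placement_a,
        ib: seed.placement_b,
    }
    win_a = extract_window(regions.values[ia], seed.placement_a, w)
    win_b = extract_window(regions.values[ib], seed.placement_b, w)
    consensus = (win_a + win_b) / 2.0
    addition_order = [ia, ib]
    scores: dict[int, float] = {ia: seed.score, ib: seed.score}

    committed = np.zeros(n, dtype=bool)
    committed[[ia, ib]] = True
    i = 2
    while i < n:
        all_scores = bank.scores_vs(consensus)
        all_scores[committed, :] = metric.worst
        flat = int(
            np.argmax(all_scores) if metric.higher_is_better else np.argmin(all_scores)
        )
        region = flat // bank.R
        placement = bank.placement(region, flat % bank.R)
        window = extract_window(regions.values[region], placement, w)
        i += 1
        consensus = (consensus * (i - 1) + window) / i
        placements[region] = placement
        scores[region] = float(all_scores[region, flat % bank.R])
        addition_order.append(region)
        committed[region] = True

    return Alignment(
        placements=[placements[r] for r in range(n)],
        consensus=consensus,
        addition_order=addition_order,
        frame_bins=w,
        metric=metric.name,
        allow_reversal=allow_reversal,
        scores=[scores[r] for r in range(n)],
        seed=seed,
    )


def _best_seed_pair(
    regions: RegionMatrix, bank: WindowBank
) -> tuple[SeedPair, int]:
    """Globally best anchor-and-slide pair over all unordered region pairs.

    For each anchor ``i`` (un-reversed, centered frame) every placement of
    every slider ``j > i`` is scored; returns the arg-best seed and the
    number of candidates examined.
    """
    metric = bank.metric
    n, c, w = bank.n, bank.center, bank.w
    best: SeedPair | None = None
    candidates = 0
    for i in range(n - 1):
        anchor = regions.values[i, c : c + w]
        scores = bank.scores_vs(anchor)[i + 1 :]
        candidates += scores.size
        flat = int(np.argmax(scores) if metric.higher_is_better else np.argmin(scores))
        j = i + 1 + flat // bank.R
        sc = float(scores.flat[flat])
        if best is None or metric.better(sc, best.score):
            best = SeedPair(
                WindowPlacement(i, c, False),
                bank.placement(j, flat % bank.R),
                sc,
            )
    assert best is not None
    return best, candidates


def single_best_pair_alignment(
    regions: RegionMatrix,
    frame_bins: int,
    metric: str | Metric = "pearson",
    allow_reversal: bool = False,
) -> Alignment:
    """Seed from the globally most similar region pair, then align greedily."""
    metric = get_metric(metric)
    _check_inputs(regions, frame_bins)
    bank = WindowBank(regions.values, frame_bins, metric, allow_reversal)
    seed, candidates = _best_seed_pair(regions, bank)
    expected = count_candidate_pairs(regions.n, regions.m, frame_bins, allow_reversal)
    assert candidates == expected, "candidate enumeration out of sync with formula"
    return chosen_seed_alignment(
        seed, regions, frame_bins, metric, allow_reversal, _bank=bank
    )


def _forced_seed(regions: RegionMatrix, bank: WindowBank, i: int) -> SeedPair:
    """Best partner placement for anchor region ``i`` over all j != i."""
    metric = bank.metric
    anchor = regions.values[i, bank.center : bank.center + bank.w]
    scores = bank.scores_vs(anchor)
    scores[i, :] = metric.worst
    flat = int(np.argmax(scores) if metric.higher_is_better else np.argmin(scores))
    j = flat // bank.R
    return SeedPair(
        WindowPlacement(i, bank.center, False),
        bank.placement(j, flat % bank.R),
        float(scores[j, flat % bank.R]),
    )


def seed_sampling_alignment(
    regions: RegionMatrix,
    frame_bins: int,
    metric: str | Metric = "pearson",
    allow_reversal: bool = False,
    progress: bool = False,
) -> tuple[Alignment, np.ndarray]:
    """One forced-seed alignment per region; keep the best-quality one.

    Every region serves once as the seed anchor; its best partner over all
    placements forms the forced seed of an independent progressive
    alignment.  The alignment maximizing the post-alignment quality
    assessment is returned together with all ``n`` quality values.  Ties
    break to the lowest seed index.
    """
    metric = get_metric(metric)
    _check_inputs(regions, frame_bins)
    bank = WindowBank(regions.values, frame_bins, metric, allow_reversal)
    qualities = np.empty(regions.n)
    best_alignment: Alignment | None = None
    for i in range(regions.n):
        seed = _forced_seed(regions, bank, i)
        aln = chosen_seed_alignment(
            seed, regions, frame_bins, metric, allow_reversal, _bank=bank
        )
        aln.quality = quality_assessment(aln, regions, metric)
        qualities[i] = aln.quality
        if best_alignment is None or metric.better(aln.quality, best_alignment.quality):
            best_alignment = aln
        if progress:
            print(f"seed {i + 1}/{regions.n}: quality {aln.quality:.6f}", flush=True)
    assert best_alignment is not None
    return best_alignment, qualities


def quality_assessment(
    a: Alignment,
    regions: RegionMatrix,
    metric: str | Metric = "pearson",
) -> float:
    """Mean pairwise metric over all n(n-1)/2 pairs of aligned windows.

    For the correlation metrics a constant window contributes 0.0 to every
    pair it appears in; for euclidean the value is a mean distance (lower
    is better when selecting among alignments).
    """
    metric = get_metric(metric)
    if a.n < 2:
        raise ValueError("quality assessment needs at least 2 regions")
    windows = aligned_windows(a, regions)
    if metric.name == "euclidean":
        return float(pdist(windows, metric="euclidean").mean())
    if metric.name == "spearman":
        windows = rankdata(windows, axis=1)
    centered = windows - windows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    unit = np.zeros_like(centered)
    unit[ok] = centered[ok] / norms[ok, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)  # constant rows contribute 0
    iu = np.triu_indices(a.n, k=1)
    return float(corr[iu].mean())
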