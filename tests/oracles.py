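"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain Python loops, deliberately sharing no
code with the package: these are the straight-line definitions the fast
implementations are checked against.
"""

from __future__ import annotations

import math


# --- per-base signal pipeline ---------------------------------------------

def brute_coverage(tags, extension, genome_sizes):
    """tags: (chrom, start, end, strand); per-base loop accumulation."""
    cov = {c: [0.0] * size for c, size in genome_sizes.items()}
    for chrom, start, end, strand in tags:
        size = genome_sizes[chrom]
        if strand == "+":
            five = start
            rng = range(five, min(five + extension, size))
        else:
            five = end - 1
            rng = range(max(five - extension + 1, 0), five + 1)
        for b in rng:
            cov[chrom][b] += 1.0
    return cov


def brute_log2(cov, pseudocount):
    values = [v for arr in cov.values() for v in arr]
    mean = sum(values) / len(values)
    return {
        c: [math.log2((v + pseudocount) / (mean + pseudocount)) for v in arr]
        for c, arr in cov.items()
    }


def brute_extract(track_values, start, end, bin_size):
    """Mean of per-base values for each bin of [start, end)."""
    out = []
    for lo in range(start, end, bin_size):
        chunk = track_values[lo : lo + bin_size]
        out.append(sum(chunk) / len(chunk))
    return out


# --- similarity -----------------------------------------------------------

def brute_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def brute_ranks(x):
    """Mid-ranks (average over ties), 1-based."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(x, y):
    return brute_pearson(brute_ranks(x), brute_ranks(y))


def brute_euclidean(x, y):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))


def brute_score(metric, x, y):
    return {
        "pearson": brute_pearson,
        "spearman": brute_spearman,
        "euclidean": brute_euclidean,
    }[metric](list(x), list(y))


def better(metric, a, b):
    return a < b if metric == "euclidean" else a > b


def brute_window(values, start, w, rev):
    win = list(values[start : start + w])
    return win[::-1] if rev else win


def brute_best_vs_profile(p, z, w, metric, allow_reversal):
    """Exhaustive scan of all (2)S placements of z's frame against p."""
    s_max = len(z) - w
    best = None
    for rev in (False, True) if allow_reversal else (False,):
        for start in range(s_max):
            sc = brute_score(metric, p, brute_window(z, start, w, rev))
            if best is None or better(metric, sc, best[2]):
                best = (start, rev, sc)
    return best


def brute_best_pair(a, b, w, metric, allow_reversal):
    """Anchor-and-slide: a's frame fixed centered, b's frame scanned."""
    s_max = len(a) - w
    anchor = brute_window(a, s_max // 2, w, False)
    return brute_best_vs_profile(anchor, b, w, metric, allow_reversal)


# --- alignment ------------------------------------------------------------

def brute_chosen_seed(rows, seed_a, seed_b, w, metric, allow_reversal):
    """Straight-line greedy progressive alignment from a forced seed.

    seed_a: (region, start, rev); seed_b likewise.  Returns per-region
    placements {region: (start, rev)}, the consensus list, and the commit
    order.
    """
    n = len(rows)
    placements = {seed_a[0]: seed_a[1:], seed_b[0]: seed_b[1:]}
    wa = brute_window(rows[seed_a[0]], seed_a[1], w, seed_a[2])
    wb = brute_window(rows[seed_b[0]], seed_b[1], w, seed_b[2])
    consensus = [(x + y) / 2 for x, y in zip(wa, wb)]
    order = [seed_a[0], seed_b[0]]
    remaining = [r for r in range(n) if r not in placements]
    i = 2
    while remaining:
        best = None
        for r in remaining:
            for rev in (False, True) if allow_reversal else (False,):
                for start in range(len(rows[r]) - w):
                    sc = brute_score(
                        metric, consensus, brute_window(rows[r], start, w, rev)
                    )
                    if best is None or better(metric, sc, best[3]):
                        best = (r, start, rev, sc)
        r, start, rev, _ = best
        win = brute_window(rows[r], start, w, rev)
        i += 1
        consensus = [(c * (i - 1) + v) / i for c, v in zip(consensus, win)]
        placements[r] = (start, rev)
        order.append(r)
        remaining.remove(r)
    return placements, consensus, order


def brute_quality(windows, metric):
    """Mean pairwise score over all unordered window pairs."""
    n = len(windows)
    total = 0.0
    pairs = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            total += brute_score(metric, windows[i], windows[j])
            pairs += 1
    return total / pairs


def brute_seed_sampling(rows, w, metric, allow_reversal):
    """Full straight-line reference of the seed-sampling strategy."""
    n = len(rows)
    s_max = len(rows[0]) - w
    center = s_max // 2
    results = []
    for i in range(n):
        anchor = brute_window(rows[i], center, w, False)
        best = None
        for j in range(n):
            if j == i:
                continue
            for rev in (False, True) if allow_reversal else (False,):
                for start in range(s_max):
                    sc = brute_score(
                        metric, anchor, brute_window(rows[j], start, w, rev)
                    )
                    if best is None or better(metric, sc, best[3]):
                        best = (j, start, rev, sc)
        j, start, rev, sc = best
        placements, consensus, order = brute_chosen_seed(
            rows, (i, center, False), (j, start, rev), w, metric, allow_reversal
        )
        windows = [
            brute_window(rows[r], placements[r][0], w, placements[r][1])
            for r in range(n)
        ]
        results.append((i, placements, order, brute_quality(windows, metric)))
    best = results[0]
    for res in results[1:]:
        if better(metric, res[3], best[3]):
            best = res
    return best, [r[3] for r in results]


def brute_variability(windows):
    n = len(windows)
    w = len(windows[0])
    consensus = [sum(win[b] for win in windows) / n for b in range(w)]
    total = 0.0
    for win in windows:
        total += math.sqrt(sum((win[b] - consensus[b]) ** 2 for b in range(w)))
    return total / n
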