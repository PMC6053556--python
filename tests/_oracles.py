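"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a statistic or assignment from first principles,
deliberately avoiding the package's own code paths (and scipy shortcuts),
so that agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import math


def circ_diff(a, b):
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def circ_mean(bearings):
    s = sum(math.sin(math.radians(b)) for b in bearings)
    c = sum(math.cos(math.radians(b)) for b in bearings)
    if s == 0.0 and c == 0.0:
        return bearings[0] % 360.0
    return math.degrees(math.atan2(s, c)) % 360.0


def observer_assignment_bruteforce(calls, threshold=10.0, adjacent_start=True):
    """Re-apply the observer acceptance rule with plain lists of tuples.

    ``calls``: sequence of (bearing, volume, booms) in temporal order.
    Returns the list of clusters, each a list of call indices.
    """
    order = ["low", "med", "high"]
    clusters: list[list[int]] = []
    for i, (bearing, volume, booms) in enumerate(calls):
        candidates = []
        for ci, members in enumerate(clusters):
            ref = circ_mean([calls[j][0] for j in members])
            d = circ_diff(bearing, ref)
            if d > threshold:
                continue
            vols = {calls[j][1] for j in members}
            if volume not in vols:
                ok = (
                    adjacent_start
                    and len(members) == 1
                    and abs(order.index(volume) - order.index(next(iter(vols)))) == 1
                    and d <= threshold / 2.0
                )
                if not ok:
                    continue
            boom_set = {calls[j][2] for j in members}
            if len(members) >= 2 and booms not in boom_set:
                continue
            candidates.append((d, ci))
        if candidates:
            candidates.sort()
            clusters[candidates[0][1]].append(i)
        else:
            clusters.append([i])
    return clusters


def stereo_audible_bruteforce(calls):
    """Exhaustive distinct (volume, channel) set; ``calls`` = (volume, channel)."""
    seen = []
    for v, ch in calls:
        if (v, ch) not in seen:
            seen.append((v, ch))
    return len(seen)


def average_ranks(values):
    """Tie-averaged ranks, 1-based, computed by sorting index lists."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_bruteforce(x, y):
    """Rho as Pearson correlation of tie-averaged ranks."""
    return pearson(average_ranks(list(x)), average_ranks(list(y)))


def through_origin_slope_golden(x, y, lo=-100.0, hi=100.0, tol=1e-12):
    """Golden-section minimisation of the residual sum of squares over slopes."""

    def rss(b):
        return sum((yi - b * xi) ** 2 for xi, yi in zip(x, y))

    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    while abs(b - a) > tol:
        if rss(c) < rss(d):
            b = d
        else:
            a = c
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
    return (a + b) / 2.0
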