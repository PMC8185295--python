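"""Independently coded brute-force reference implementations.

Deliberately naive (explicit loops, textbook formulas) so they share no code
path with the package; used to cross-check the vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def naive_time_domain(x):
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    sdnn = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    diffs = [x[i + 1] - x[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    pnn50 = 100.0 * sum(1 for d in diffs if abs(d) > 50.0) / len(diffs)
    pnn20 = 100.0 * sum(1 for d in diffs if abs(d) > 20.0) / len(diffs)
    return {"mean": mean, "sdnn": sdnn, "rmssd": rmssd,
            "pnn50": pnn50, "pnn20": pnn20}


def naive_geometric(x, bin_width):
    x = np.asarray(x, dtype=float)
    lo = math.floor(x.min() / bin_width) * bin_width
    n_bins = max(int(math.ceil((x.max() - lo) / bin_width)), 1)
    if lo + n_bins * bin_width <= x.max():
        n_bins += 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak = int(np.argmax(counts))
    height = float(counts[peak])
    tri = x.size / height
    if np.count_nonzero(counts) == 1:
        return {"tinn": float(bin_width), "tri": tri}
    apex = centers[peak]
    best_sse, best_tinn = float("inf"), float(bin_width)
    for n_pos in edges[: peak + 1]:
        for m_pos in edges[peak + 1:]:
            sse = 0.0
            for c, d in zip(centers, counts):
                if n_pos <= c <= apex:
                    q = height * (c - n_pos) / (apex - n_pos)
                elif apex < c <= m_pos:
                    q = height * (m_pos - c) / (m_pos - apex)
                else:
                    q = 0.0
                sse += (d - q) ** 2
            if sse < best_sse - 1e-12:
                best_sse, best_tinn = sse, float(m_pos - n_pos)
    return {"tinn": best_tinn, "tri": tri}


def naive_entropies(x, m=2, r_fraction=0.2):
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return {"apen": 0.0, "sampen": 0.0}
    r = r_fraction * sd

    def phi(mm):
        k = n - mm + 1
        logs = []
        for i in range(k):
            c = 0
            for j in range(k):
                if max(abs(x[i + t] - x[j + t]) for t in range(mm)) <= r:
                    c += 1
            logs.append(math.log(c / k))
        return sum(logs) / k

    apen = phi(m) - phi(m + 1)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + t] - x[j + t]) for t in range(m)) <= r:
                b += 1
            if max(abs(x[i + t] - x[j + t]) for t in range(m + 1)) <= r:
                a += 1
    sampen = float("nan") if (a == 0 or b == 0) else -math.log(a / b)
    return {"apen": apen, "sampen": sampen}


def naive_poincare(x):
    x = np.asarray(x, dtype=float)
    diffs = np.diff(x)
    sd1 = math.sqrt(np.var(diffs, ddof=1) / 2.0)
    sdnn2 = np.var(x, ddof=1)
    sd2 = math.sqrt(max(2.0 * sdnn2 - sd1**2, 0.0))
    ratio = float("nan") if sd2 == 0 else sd1 / sd2
    return {"sd1": sd1, "sd2": sd2, "sd1sd2_ratio": ratio}


def naive_dfa(x, short_range=(4, 16), long_range=(16, 64)):
    x = np.asarray(x, dtype=float)
    profile = np.cumsum(x - x.mean())

    def fluctuation(n):
        k = profile.size // n
        if k < 2:
            return float("nan")
        total, count = 0.0, 0
        for seg in range(k):
            y = profile[seg * n:(seg + 1) * n]
            t = np.arange(n, dtype=float)
            slope, intercept = np.polyfit(t, y, 1)
            resid = y - (slope * t + intercept)
            total += float(np.sum(resid**2))
            count += n
        return math.sqrt(total / count)

    def alpha(lo, hi):
        pts = [(math.log(n), math.log(fluctuation(n)))
               for n in range(lo, hi + 1)
               if not math.isnan(fluctuation(n)) and fluctuation(n) > 0]
        if len(pts) < 2:
            return float("nan")
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        return float(np.polyfit(xs, ys, 1)[0])

    return {"dfa_alpha1": alpha(*short_range), "dfa_alpha2": alpha(*long_range)}


def naive_feature_set(x, bin_width, m, r_fraction, short_range, long_range):
    out = {}
    out.update(naive_time_domain(x))
    out.update(naive_geometric(x, bin_width))
    out.update(naive_entropies(x, m, r_fraction))
    out.update(naive_poincare(x))
    out.update(naive_dfa(x, short_range, long_range))
    return out


def naive_auc(scores, labels):
    """Pairwise concordance statistic (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def naive_vote_rule(weights, votes):
    """The printed ensemble rule, one observation at a time."""
    s = sum(w * v for w, v in zip(weights, votes))
    return (1 if s > 0.5 else 0), s


def naive_best_grid_accuracy(votes, labels, grid):
    """Exhaustive accuracy maximization over a weight grid."""
    best_acc, best_w = -1.0, None
    for w in grid:
        correct = 0
        for row, lab in zip(votes, labels):
            pred, _ = naive_vote_rule(w, row)
            correct += int(pred == lab)
        acc = correct / len(labels)
        if acc > best_acc:
            best_acc, best_w = acc, w
    return best_w, best_acc
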