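"""Independent brute-force oracles used only by the tests.

Each function re-derives a quantity with the most transparent method
available (per-base occupancy scans, exhaustive enumeration, direct formula
evaluation) and is kept deliberately separate from the package's
implementations.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


# ---- interval algebra ------------------------------------------------------


def per_base_merge(intervals, gap=0):
    """Occupancy-scan union of (chrom, start, end) triples with gap-joining."""
    by_chrom = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, set()).update(range(start, end))
    out = []
    for chrom in sorted(by_chrom):
        covered = sorted(by_chrom[chrom])
        run_start, prev = covered[0], covered[0]
        for pos in covered[1:]:
            if pos - prev <= gap + 1 and pos - prev > 0:
                # positions within `gap` of the current run extend it
                prev = pos
            elif pos == prev:
                continue
            else:
                out.append((chrom, run_start, prev + 1))
                run_start = prev = pos
        out.append((chrom, run_start, prev + 1))
    return out


def per_base_intersect(a, b):
    """Occupancy-scan intersection of two (chrom, start, end) collections."""
    cov_a, cov_b = {}, {}
    for cov, coll in ((cov_a, a), (cov_b, b)):
        for chrom, start, end in coll:
            cov.setdefault(chrom, set()).update(range(start, end))
    out = []
    for chrom in sorted(set(cov_a) & set(cov_b)):
        both = sorted(cov_a[chrom] & cov_b[chrom])
        if not both:
            continue
        run_start, prev = both[0], both[0]
        for pos in both[1:]:
            if pos == prev + 1:
                prev = pos
            else:
                out.append((chrom, run_start, prev + 1))
                run_start = prev = pos
        out.append((chrom, run_start, prev + 1))
    return out


# ---- statistics ------------------------------------------------------------


def enum_ranksum_p(a, b, side="greater"):
    """Exact one-sided rank-sum p by enumerating every assignment of the
    pooled ranks to group a (tie-free data only)."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    na = len(a)
    obs = sum(ranks[v] for v in a)
    total = 0
    count = 0
    for combo in combinations(range(1, len(pooled) + 1), na):
        total += 1
        s = sum(combo)
        if side == "greater" and s >= obs:
            count += 1
        elif side == "less" and s <= obs:
            count += 1
    return count / total


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values, written independently: sort,
    multiply by m/rank, enforce monotonicity from the largest down, cap."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = p[idx] * m / rank_from_top
        running_min = min(running_min, val)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def km_product_limit(times, events):
    """Product-limit estimate evaluated at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    event_times = sorted(set(times[events == 1]))
    surv = 1.0
    out = []
    for t in event_times:
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        surv *= 1.0 - d / n_at_risk
        out.append((t, surv))
    return out


def logrank_oe_v(times, events, group):
    """Two-group log-rank chi2 via direct O-E / hypergeometric-variance
    accumulation over distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group).astype(bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def welch_t(x, y):
    """Welch t statistic from the closed form."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    return (x.mean() - y.mean()) / np.sqrt(vx / len(x) + vy / len(y))


# ---- motif scanning --------------------------------------------------------


def pwm_int_scores(pwm, granularity):
    """Integer lattice per-position scores, identical rounding to the scanner."""
    scores = np.log2(
        (pwm.probabilities + pwm.pseudocount * pwm.background) / pwm.background
    )
    return np.rint(scores / granularity).astype(np.int64)


def enum_pvalues(pwm, granularity=1e-3):
    """Exhaustive enumeration of the score distribution over all 4^w words:
    maps each word to P(score >= word's score) under the background."""
    int_scores = pwm_int_scores(pwm, granularity)
    w = pwm.width
    words = list(product(range(4), repeat=w))
    scores = {}
    probs = {}
    for word in words:
        s = int(sum(int_scores[i, b] for i, b in enumerate(word)))
        pr = float(np.prod([pwm.background[b] for b in word]))
        scores[word] = s
        probs[word] = pr
    pvals = {}
    for word, s in scores.items():
        pvals[word] = sum(pr for w2, pr in probs.items() if scores[w2] >= s)
    return scores, pvals


def naive_scan(sequence, pwm, p_threshold, granularity=1e-3, both_strands=True):
    """Sliding-window scan with identical scoring, p-values from exhaustive
    enumeration (widths small enough to enumerate)."""
    comp = str.maketrans("ACGTN", "TGCAN")
    base_idx = {b: i for i, b in enumerate("ACGT")}
    _, pvals = enum_pvalues(pwm, granularity)
    hits = []

    def scan_strand(seq, strand, full_len):
        w = pwm.width
        for off in range(len(seq) - w + 1):
            word = seq[off : off + w]
            if any(c not in base_idx for c in word):
                continue
            key = tuple(base_idx[c] for c in word)
            if pvals[key] <= p_threshold:
                fwd = off if strand == "+" else full_len - w - off
                hits.append((fwd, strand))

    seq = sequence.upper()
    scan_strand(seq, "+", len(seq))
    if both_strands:
        scan_strand(seq.translate(comp)[::-1], "-", len(seq))
    return sorted(hits)
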