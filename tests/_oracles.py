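"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths: the Fisher tail is an
explicit term-by-term summation, BH is a hand step-up loop, and the event
caller is a pure-Python run-length scan.
"""

import math


def hypergeom_tail_enumeration(a, b, c, d):
    """One-sided Fisher p by explicit summation of upper-tail pmf terms."""
    M, K, n1 = a + b + c + d, a + c, a + b
    lg = math.lgamma

    def log_pmf(k):
        return (lg(K + 1) - lg(k + 1) - lg(K - k + 1)
                + lg(M - K + 1) - lg(n1 - k + 1) - lg(M - K - n1 + k + 1)
                - (lg(M + 1) - lg(n1 + 1) - lg(M - n1 + 1)))

    return sum(math.exp(log_pmf(k)) for k in range(a, min(K, n1) + 1))


def bh_stepup(p):
    """Hand step-up Benjamini-Hochberg: sort, scale by m/rank, cumulative
    minimum from the largest p downward, clip at 1."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = min(running, 1.0)
    return adj


def brute_force_caller(lengths, pvals, exon_keys, threshold,
                       min_nt=90, max_nt=200):
    """Reference run-length caller (join, 90-nt minimum, 200-nt split);
    returns event lengths in order."""
    events = []
    run = []
    prev_key = None
    for L, p, k in list(zip(lengths, pvals, exon_keys)) + [(None, None, None)]:
        boundary = k != prev_key
        if run and (p is None or p >= threshold or boundary):
            total = sum(run)
            if total >= min_nt:
                full, rem = divmod(total, max_nt)
                events.extend([max_nt] * full)
                if rem >= min_nt:
                    events.append(rem)
            run = []
        if p is not None and p < threshold:
            run.append(L)
        prev_key = k
    return events
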