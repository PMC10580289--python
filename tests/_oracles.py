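"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately literal, quadratic-time re-implementations of the
published rules; they share no code with the package internals.
"""

from __future__ import annotations

import itertools
from math import exp, lgamma, log

import numpy as np


def naive_call_roh(g, pos, params):
    """Literal window-scan re-implementation of the ROH caller on one
    sample / one chromosome.  Returns (start_bp, end_bp, n_snps) tuples."""
    g = list(g)
    pos = list(pos)
    s = len(g)
    w = params.window_snp
    qualifies = [False] * s
    for j in range(s):
        n_win = n_hit = 0
        for i in range(max(0, j - w + 1), min(s - w, j) + 1):
            if i < 0 or i + w > s:
                continue
            win = g[i : i + w]
            het = sum(1 for x in win if x == 1)
            mis = sum(1 for x in win if x < 0)
            n_win += 1
            if het <= params.window_het and mis <= params.window_missing:
                n_hit += 1
        if n_win and n_hit / n_win >= params.window_hit_threshold:
            qualifies[j] = True
    raw_runs = []
    j = 0
    while j < s:
        if qualifies[j]:
            k = j
            while k + 1 < s and qualifies[k + 1]:
                k += 1
            raw_runs.append((j, k))
            j = k + 1
        else:
            j += 1
    pieces = []
    for a, b in raw_runs:
        start = a
        for t in range(a, b):
            if pos[t + 1] - pos[t] > params.max_gap_kb * 1000:
                pieces.append((start, t))
                start = t + 1
        pieces.append((start, b))
    out = []
    for a, b in pieces:
        n = b - a + 1
        length_kb = (pos[b] - pos[a] + 1) / 1000
        if (
            n >= params.min_snp
            and length_kb >= params.min_kb
            and length_kb / n <= params.density_kb_per_snp
        ):
            out.append((pos[a], pos[b], n))
    return out


def brute_hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact HWE p by full enumeration of the conditional distribution."""
    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het

    def prob(h):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        if hom_r < 0 or hom_c < 0:
            return 0.0
        return exp(
            lgamma(n + 1) - lgamma(hom_r + 1) - lgamma(h + 1) - lgamma(hom_c + 1)
            + h * log(2)
            + lgamma(rare + 1) + lgamma(2 * n - rare + 1) - lgamma(2 * n + 1)
        )

    hs = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    ps = {h: prob(h) for h in hs}
    po = ps[n_het]
    return min(1.0, sum(p for p in ps.values() if p <= po * (1 + 1e-12)))


def brute_bh_flags(pvals, m, q):
    """Benjamini-Hochberg step-up by literal definition."""
    p = list(pvals)
    order = sorted(range(len(p)), key=lambda i: p[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= q * rank / m:
            k_star = rank
    flags = [False] * len(p)
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            flags[i] = True
    return flags


def enumerate_replication_power(powers, at_least: int) -> float:
    """P(at least `at_least` successes) by summing over all 2^k outcome
    patterns of independent Bernoulli(power_i) replications."""
    total = 0.0
    k = len(powers)
    for pattern in itertools.product([0, 1], repeat=k):
        if sum(pattern) >= at_least:
            pr = 1.0
            for b, p in zip(pattern, powers):
                pr *= p if b else (1.0 - p)
            total += pr
    return total


def rr_from_2x2(or_, pd):
    """Risk ratio via an explicit 2x2 construction achieving the given OR
    and unexposed risk pd."""
    odds_unexposed = pd / (1 - pd)
    odds_exposed = or_ * odds_unexposed
    pe = odds_exposed / (1 + odds_exposed)
    return pe / pd


def combined_par_arithmetic(p1, p2, or_at_0625, pd):
    """Spreadsheet-style evaluation of the printed two-class PAR formula."""
    beta = np.log(or_at_0625) / 0.0625
    out = 0.0
    for prev, f in ((p2, 0.015625), (p1, 0.0625)):
        or_f = np.exp(f * beta)
        rr = or_f / (1 - pd + pd * or_f)
        out += prev * (rr - 1) / (prev * (rr - 1) + 1)
    return 100.0 * out
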