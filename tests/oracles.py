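"""Independent brute-force oracles used by the tests.

These re-derive expected values directly from the definitions (explicit
running sums, exhaustive enumeration) and deliberately share no code with
the package implementation.
"""

from __future__ import annotations

import itertools
import math


def brute_running_sum(scores, is_hit, exponent):
    """Running sum of the weighted KS statistic, computed step by step."""
    n = len(scores)
    n_hit = sum(is_hit)
    n_miss = n - n_hit
    nr = sum(abs(s) ** exponent for s, h in zip(scores, is_hit) if h)
    running = []
    total = 0.0
    for s, h in zip(scores, is_hit):
        if h:
            total += (abs(s) ** exponent / nr) if nr > 0 else 1.0 / n_hit
        else:
            total -= 1.0 / n_miss
        running.append(total)
    return running


def brute_es(scores, is_hit, exponent):
    """(ES, 1-based peak index): first position of maximal |running sum|."""
    running = brute_running_sum(scores, is_hit, exponent)
    best = max(abs(v) for v in running)
    for i, v in enumerate(running):
        if abs(v) == best:
            return v, i + 1
    raise AssertionError("unreachable")


def brute_hypergeom_upper(n_universe, term, cluster):
    """P(overlap >= observed) by enumerating every same-size cluster draw."""
    universe = list(range(n_universe))
    k_obs = len(set(term) & set(cluster))
    n = len(cluster)
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(set(draw) & set(term)) >= k_obs:
            hits += 1
    return hits / total


def brute_bh(pvalues):
    """Benjamini-Hochberg step-up applied by hand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_worst, idx in enumerate(reversed(order)):
        rank = m - rank_from_worst
        val = min(prev, pvalues[idx] * m / rank)
        q[idx] = val
        prev = val
    return q


def brute_spearman_perm_p(rx, ry):
    """Two-tailed exhaustive permutation p for the rank correlation."""

    def rho(a, b):
        n = len(a)
        ma = sum(a) / n
        mb = sum(b) / n
        num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
        da = math.sqrt(sum((x - ma) ** 2 for x in a))
        db = math.sqrt(sum((y - mb) ** 2 for y in b))
        return num / (da * db)

    obs = abs(rho(rx, ry))
    hits = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho(rx, list(perm))) >= obs - 1e-12:
            hits += 1
    return hits / total


def brute_ssgsea(scores_by_gene, members, alpha):
    """Single-sample score by direct summation of the defining formula.

    Genes sorted descending by value (ties by symbol); rank weights run
    from N at the top to 1 at the bottom.
    """
    items = sorted(scores_by_gene.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(items)
    member_set = set(members)
    weights = []
    for i, (g, _) in enumerate(items):
        weights.append((n - i) ** alpha if g in member_set else 0.0)
    wsum = sum(weights)
    n_miss = n - len([1 for g, _ in items if g in member_set])
    total = 0.0
    p_hit = 0.0
    p_miss = 0.0
    for i, (g, _) in enumerate(items):
        if g in member_set:
            p_hit += weights[i] / wsum
        else:
            p_miss += 1.0 / n_miss
        total += p_hit - p_miss
    return total
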