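"""Independent oracles used by the test suite.

These deliberately take different computational routes from the package:
recursive / exhaustive formulations instead of iterative dynamic
programming, and exact rational arithmetic instead of floating point.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb


def nw_score_recursive(a: str, b: str, match: float, mismatch: float,
                       gap: float) -> float:
    """Optimal global alignment score by memoized recursion on prefixes."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == 0:
            return j * gap
        if j == 0:
            return i * gap
        s = match if a[i - 1] == b[j - 1] else mismatch
        return max(best(i - 1, j - 1) + s,
                   best(i - 1, j) + gap,
                   best(i, j - 1) + gap)

    return best(len(a), len(b))


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (gapped_a, gapped_b).

    Pure path enumeration; exponential, so only for very short inputs.
    """
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ga, gb in enumerate_alignments(a[:-1], b[:-1]):
            yield ga + a[-1], gb + b[-1]
    if a:
        for ga, gb in enumerate_alignments(a[:-1], b):
            yield ga + a[-1], gb + "-"
    if b:
        for ga, gb in enumerate_alignments(a, b[:-1]):
            yield ga + "-", gb + b[-1]


def score_gapped_pair(ga: str, gb: str, match: float, mismatch: float,
                      gap: float) -> float:
    total = 0.0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            total += gap
        else:
            total += match if x == y else mismatch
    return total


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p as an exact rational, by full enumeration of the
    margin-constrained table family."""
    n = a + b + c + d
    r = a + b
    k = a + c
    denom = comb(n, k)
    lo = max(0, r + k - n)
    hi = min(r, k)
    probs = {x: Fraction(comb(r, x) * comb(n - r, k - x), denom)
             for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum((p for p in probs.values() if p <= p_obs), Fraction(0))


def fisher_all_p_for_margins(n: int, r: int, k: int) -> dict[int, Fraction]:
    """Two-sided p for every table with margins (r, n-r) x (k, n-k),
    keyed by the a-cell. Exact rationals; O(s log s) per margin set."""
    denom = comb(n, k)
    lo = max(0, r + k - n)
    hi = min(r, k)
    probs = [Fraction(comb(r, x) * comb(n - r, k - x), denom)
             for x in range(lo, hi + 1)]
    order = sorted(range(len(probs)), key=lambda i: probs[i])
    prefix = [Fraction(0)]
    for i in order:
        prefix.append(prefix[-1] + probs[i])
    sorted_probs = [probs[i] for i in order]
    out = {}
    for idx, x in enumerate(range(lo, hi + 1)):
        p_obs = probs[idx]
        # rank: number of tables with probability <= p_obs
        import bisect
        rank = bisect.bisect_right(sorted_probs, p_obs)
        out[x] = prefix[rank]
    return out
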