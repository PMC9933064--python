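"""Independent brute-force oracles, deliberately naive and separate from the package.

These recompute alignment scores and edit-op decompositions by exhaustive
enumeration on tiny instances; the package's dynamic programming is checked
against them, never the other way around.
"""

from __future__ import annotations

from functools import lru_cache


def global_alignment_score(a: tuple, b: tuple, match: float, mismatch: float, gap: float) -> float:
    """Needleman-Wunsch global score by plain recursion (tiny inputs only)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -float("inf")
        if i < len(a) and j < len(b):
            best = max(best, (match if a[i] == b[j] else mismatch) + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def best_local_score(query: tuple, reference: tuple, match: float = 2.0, mismatch: float = -1.0, gap: float = -1.0) -> float:
    """Best Smith-Waterman local score: maximize the global score over all
    (query substring, reference substring) pairs, clamped at zero."""
    best = 0.0
    for q0 in range(len(query) + 1):
        for q1 in range(q0, len(query) + 1):
            for r0 in range(len(reference) + 1):
                for r1 in range(r0, len(reference) + 1):
                    s = global_alignment_score(query[q0:q1], reference[r0:r1], match, mismatch, gap)
                    best = max(best, s)
    return best


def best_local_matches(query: tuple, reference: tuple) -> int:
    """Maximum number of in-order exact token matches between any query
    substring and any reference substring (an alignment-free upper bound on
    MATCH ops used to sanity-check similarity)."""

    @lru_cache(maxsize=None)
    def lcs(i: int, j: int) -> int:
        if i == len(query) or j == len(reference):
            return 0
        if query[i] == reference[j]:
            return 1 + lcs(i + 1, j + 1)
        return max(lcs(i + 1, j), lcs(i, j + 1))

    return lcs(0, 0)


def minimal_edit_decompositions(ref: tuple, hyp: tuple) -> tuple[int, set[tuple[int, int, int, int]]]:
    """All (hits, S, I, D) decompositions achieving the minimal edit distance.

    Exhaustive recursion over alignment paths; feasible for sequences of at
    most ~6 tokens.
    """
    results: dict[int, set[tuple[int, int, int, int]]] = {}

    def rec(i: int, j: int, hits: int, subs: int, ins: int, dels: int) -> None:
        if i == len(ref) and j == len(hyp):
            cost = subs + ins + dels
            results.setdefault(cost, set()).add((hits, subs, ins, dels))
            return
        if i < len(ref) and j < len(hyp):
            if ref[i] == hyp[j]:
                rec(i + 1, j + 1, hits + 1, subs, ins, dels)
            else:
                rec(i + 1, j + 1, hits, subs + 1, ins, dels)
        if i < len(ref):
            rec(i + 1, j, hits, subs, ins, dels + 1)
        if j < len(hyp):
            rec(i, j + 1, hits, subs, ins + 1, dels)

    rec(0, 0, 0, 0, 0, 0)
    best = min(results)
    return best, results[best]
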