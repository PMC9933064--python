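"""Smith-Waterman local alignment of hypothesis tokens against a long reference.

A short ASR hypothesis (one audio segment, under 20 s of speech) is located
inside the full-length manual transcript of the whole interview by classic
Smith-Waterman dynamic programming over word tokens. The fraction of
hypothesis tokens that align as exact matches is the similarity score used to
gate segments: a segment whose hypothesis cannot be matched well anywhere in
the transcript is discarded, one that can is paired with the matched
transcript slice as its corrected label.

Token equality is exact string equality after normalization; there is no
fuzzy word matching. Full O(|query| x |reference|) dynamic programming is
used; hypotheses are short, so this is cheap even for hour-long transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .textnorm import NormalizedText

__all__ = [
    "ScoringScheme",
    "AlignOp",
    "LocalAlignment",
    "smith_waterman",
    "gate",
    "extract_correction",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Smith-Waterman scores: positive match, non-positive mismatch and gap."""

    match_score: float = 2.0
    mismatch_penalty: float = -1.0
    gap_penalty: float = -1.0

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.mismatch_penalty > 0 or self.gap_penalty > 0:
            raise ValueError("mismatch_penalty and gap_penalty must be <= 0")


DEFAULT_SCORING = ScoringScheme()


class AlignOp(str, Enum):
    """One column of a local alignment.

    MATCH / MISMATCH consume one token on each side. GAP_IN_QUERY consumes a
    query token aligned to a gap in the reference (the hypothesis has an
    extra word); GAP_IN_REF consumes a reference token aligned to a gap in
    the query (the hypothesis is missing a word).
    """

    MATCH = "match"
    MISMATCH = "mismatch"
    GAP_IN_QUERY = "gap_in_query"
    GAP_IN_REF = "gap_in_ref"


@dataclass(frozen=True)
class LocalAlignment:
    """Best local match of a hypothesis inside a reference transcript.

    ``query_span`` and ``ref_span`` are half-open token-index intervals.
    ``similarity`` is (number of MATCH ops) / (query token count), 0 for an
    empty query: it is 1.0 exactly when every hypothesis word appears, in
    order, in the reference.
    """

    query_span: tuple[int, int]
    ref_span: tuple[int, int]
    ops: tuple[AlignOp, ...]
    score: float
    similarity: float

    @property
    def n_matches(self) -> int:
        return sum(1 for op in self.ops if op is AlignOp.MATCH)


_EMPTY = LocalAlignment(query_span=(0, 0), ref_span=(0, 0), ops=(), score=0.0, similarity=0.0)


def smith_waterman(
    query: NormalizedText,
    reference: NormalizedText,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> LocalAlignment:
    """Maximal-scoring local alignment of ``query`` tokens in ``reference``.

    Deterministic tie-breaks: among equal-scoring end cells the smallest
    reference end index wins, then the smallest query end index; during
    traceback a diagonal step (match/mismatch) is preferred over consuming a
    reference token (GAP_IN_REF), which is preferred over consuming a query
    token (GAP_IN_QUERY). An empty query or reference yields score 0, empty
    spans and similarity 0.
    """
    q = query.tokens
    r = reference.tokens
    nq, nr = len(q), len(r)
    if nq == 0 or nr == 0:
        return _EMPTY

    match = scoring.match_score
    mismatch = scoring.mismatch_penalty
    gap = scoring.gap_penalty

    # H[i, j]: best local score of an alignment ending at q[i-1], r[j-1].
    H = np.zeros((nq + 1, nr + 1), dtype=np.float64)
    q_arr = np.array(q, dtype=object)
    r_arr = np.array(r, dtype=object)
    for i in range(1, nq + 1):
        eq = r_arr == q_arr[i - 1]
        sub = np.where(eq, match, mismatch)
        row = H[i]
        prev = H[i - 1]
        # vectorized over j is impossible for the left-neighbor dependency;
        # fall back to a tight scalar loop on the row.
        for j in range(1, nr + 1):
            row[j] = max(
                0.0,
                prev[j - 1] + sub[j - 1],
                prev[j] + gap,  # consume query token (gap in reference)
                row[j - 1] + gap,  # consume reference token (gap in query)
            )

    best = H.max()
    if best <= 0.0:
        return _EMPTY
    # smallest reference end index, then smallest query end index
    ends = np.argwhere(H == best)
    j_end = ends[:, 1].min()
    i_end = ends[ends[:, 1] == j_end][:, 0].min()

    ops: list[AlignOp] = []
    i, j = int(i_end), int(j_end)
    while i > 0 and j > 0 and H[i, j] > 0.0:
        here = H[i, j]
        diag = H[i - 1, j - 1] + (match if q[i - 1] == r[j - 1] else mismatch)
        if here == diag:
            ops.append(AlignOp.MATCH if q[i - 1] == r[j - 1] else AlignOp.MISMATCH)
            i -= 1
            j -= 1
        elif here == H[i, j - 1] + gap:
            ops.append(AlignOp.GAP_IN_REF)
            j -= 1
        else:
            assert here == H[i - 1, j] + gap
            ops.append(AlignOp.GAP_IN_QUERY)
            i -= 1
    ops.reverse()

    n_matches = sum(1 for op in ops if op is AlignOp.MATCH)
    return LocalAlignment(
        query_span=(i, int(i_end)),
        ref_span=(j, int(j_end)),
        ops=tuple(ops),
        score=float(best),
        similarity=n_matches / nq,
    )


def gate(alignment: LocalAlignment, threshold: float = 0.9) -> bool:
    """Accept iff similarity >= threshold.

    A segment strictly below the threshold is discarded; at exactly the
    threshold it is kept.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return alignment.similarity >= threshold


def extract_correction(alignment: LocalAlignment, reference: NormalizedText) -> NormalizedText:
    """Reference tokens inside ``ref_span``: the corrected label for the segment."""
    lo, hi = alignment.ref_span
    if not (0 <= lo <= hi <= len(reference.tokens)):
        raise ValueError(f"ref_span {alignment.ref_span} out of bounds for reference of length {len(reference.tokens)}")
    return NormalizedText(reference.tokens[lo:hi])
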