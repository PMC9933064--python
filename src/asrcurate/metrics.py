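"""Edit-operation counts, word error rate, and error-type distributions.

WER = (substitutions + insertions + deletions) / reference length, from a
minimal-cost Levenshtein alignment with unit costs. The same machinery runs
at word level (WER, validation curves) and at character level (error-type
ratios: which fraction of the total errors are insertions, deletions or
substitutions), on the normalized character rendering where tokens are joined
by single spaces.

Per-speaker-group summaries (residents / family / care professionals in the
interview setting) are plain boxplot statistics: median, quartiles by linear
interpolation, and outliers beyond the 1.5 x IQR whiskers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

from .textnorm import NormalizedText, to_characters

__all__ = [
    "EditCounts",
    "ErrorDistribution",
    "GroupStats",
    "edit_ops",
    "wer",
    "corpus_wer",
    "error_distribution",
    "group_boxplot_stats",
]


@dataclass(frozen=True)
class EditCounts:
    """Hits and edit-operation counts at word or character level.

    Invariants: hits + substitutions + deletions == reference_length and
    hits + substitutions + insertions == hypothesis length.
    """

    level: str
    hits: int
    substitutions: int
    insertions: int
    deletions: int
    reference_length: int

    @property
    def hypothesis_length(self) -> int:
        return self.hits + self.substitutions + self.insertions

    @property
    def total_errors(self) -> int:
        return self.substitutions + self.insertions + self.deletions

    @property
    def error_rate(self) -> float:
        """(S + I + D) / reference_length; undefined for an empty reference."""
        if self.reference_length == 0:
            raise ZeroDivisionError("error rate undefined for empty reference")
        return self.total_errors / self.reference_length

    def __add__(self, other: "EditCounts") -> "EditCounts":
        if self.level != other.level:
            raise ValueError("cannot pool counts across levels")
        return EditCounts(
            level=self.level,
            hits=self.hits + other.hits,
            substitutions=self.substitutions + other.substitutions,
            insertions=self.insertions + other.insertions,
            deletions=self.deletions + other.deletions,
            reference_length=self.reference_length + other.reference_length,
        )


@dataclass(frozen=True)
class ErrorDistribution:
    """Share of each error type in the total error count of a group, in percent."""

    insertion_pct: float
    substitution_pct: float
    deletion_pct: float
    group_label: Hashable | None = None
    no_errors: bool = False


@dataclass(frozen=True)
class GroupStats:
    """Boxplot statistics of per-segment WER values for one speaker group."""

    group_label: Hashable
    n: int
    median: float
    q1: float
    q3: float
    outliers: tuple[float, ...] = field(default_factory=tuple)


def _levenshtein_counts(ref: Sequence, hyp: Sequence, level: str) -> EditCounts:
    """Unit-cost minimal-edit counts with a deterministic traceback.

    Tie-break among equal-cost paths: prefer the diagonal step
    (hit/substitution), then deletion, then insertion.
    """
    nr, nh = len(ref), len(hyp)
    # D[i, j] = minimal edits between ref[:i] and hyp[:j]
    D = np.empty((nr + 1, nh + 1), dtype=np.int64)
    D[:, 0] = np.arange(nr + 1)
    D[0, :] = np.arange(nh + 1)
    for i in range(1, nr + 1):
        ri = ref[i - 1]
        prev = D[i - 1]
        row = D[i]
        for j in range(1, nh + 1):
            row[j] = min(
                prev[j - 1] + (ri != hyp[j - 1]),
                prev[j] + 1,  # deletion: ref token absent from hyp
                row[j - 1] + 1,  # insertion: extra hyp token
            )
    hits = subs = ins = dels = 0
    i, j = nr, nh
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1]):
            if ref[i - 1] == hyp[j - 1]:
                hits += 1
            else:
                subs += 1
            i -= 1
            j -= 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            dels += 1
            i -= 1
        else:
            ins += 1
            j -= 1
    return EditCounts(
        level=level,
        hits=hits,
        substitutions=subs,
        insertions=ins,
        deletions=dels,
        reference_length=nr,
    )


def edit_ops(reference: NormalizedText, hypothesis: NormalizedText, level: str = "word") -> EditCounts:
    """Minimal-edit counts between reference and hypothesis.

    ``level="word"`` compares token sequences; ``level="character"`` compares
    the space-joined character renderings (the unit the error-type analysis
    uses). Either side may be empty.
    """
    if level == "word":
        return _levenshtein_counts(reference.tokens, hypothesis.tokens, "word")
    if level == "character":
        return _levenshtein_counts(to_characters(reference), to_characters(hypothesis), "character")
    raise ValueError(f"unknown level {level!r}")


def wer(reference: NormalizedText, hypothesis: NormalizedText) -> float:
    """Word error rate in percent: (S + I + D) / reference words x 100.

    Can exceed 100 when insertions dominate. Raises on an empty reference,
    where WER is undefined.
    """
    if len(reference) == 0:
        raise ValueError("WER undefined for empty reference")
    return edit_ops(reference, hypothesis, level="word").error_rate * 100.0


def corpus_wer(pairs: Iterable[tuple[NormalizedText, NormalizedText]]) -> float:
    """Corpus-level WER in percent: total errors over total reference words."""
    total = EditCounts("word", 0, 0, 0, 0, 0)
    for ref, hyp in pairs:
        total = total + edit_ops(ref, hyp, level="word")
    return total.error_rate * 100.0


def error_distribution(
    pairs: Sequence[tuple[NormalizedText, NormalizedText]],
    level: str = "character",
    group_by: Sequence[Hashable] | None = None,
) -> list[ErrorDistribution]:
    """Per-group error-type percentages, pooling edit counts over each group's pairs.

    Percentages are 100 x (type count) / (total errors); a group with zero
    total errors reports all-zero percentages with ``no_errors`` set.
    """
    if not pairs:
        raise ValueError("at least one (reference, hypothesis) pair required")
    if group_by is None:
        group_by = [None] * len(pairs)
    if len(group_by) != len(pairs):
        raise ValueError("group_by must label every pair")

    pooled: dict[Hashable, EditCounts] = {}
    for (ref, hyp), label in zip(pairs, group_by):
        counts = edit_ops(ref, hyp, level=level)
        pooled[label] = pooled[label] + counts if label in pooled else counts

    out = []
    for label, counts in pooled.items():
        total = counts.total_errors
        if total == 0:
            out.append(ErrorDistribution(0.0, 0.0, 0.0, group_label=label, no_errors=True))
        else:
            out.append(
                ErrorDistribution(
                    insertion_pct=100.0 * counts.insertions / total,
                    substitution_pct=100.0 * counts.substitutions / total,
                    deletion_pct=100.0 * counts.deletions / total,
                    group_label=label,
                )
            )
    return out


def group_boxplot_stats(
    wer_values: Sequence[float],
    group_by: Sequence[Hashable],
) -> list[GroupStats]:
    """Median, quartiles (linear interpolation) and 1.5 x IQR outliers per group."""
    if len(wer_values) != len(group_by):
        raise ValueError("group_by must label every value")
    groups: dict[Hashable, list[float]] = {}
    for v, label in zip(wer_values, group_by):
        groups.setdefault(label, []).append(float(v))
    out = []
    for label, values in groups.items():
        if not values:
            raise ValueError(f"empty group {label!r}")
        arr = np.asarray(values)
        q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = tuple(float(v) for v in arr[(arr < lo) | (arr > hi)])
        out.append(GroupStats(group_label=label, n=len(values), median=float(med), q1=float(q1), q3=float(q3), outliers=outliers))
    return out
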