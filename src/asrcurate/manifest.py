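"""JSONL curation manifests and the Table-2-style iteration log.

One JSON object per line describes one audio segment: where it came from,
what the model heard, what correction (if any) it was paired with, its
similarity, and whether it was accepted. JSONL rather than CSV because the
texts contain commas and quotes. Unknown fields round-trip untouched. Times
are seconds throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .curation import IterationRecord, Segment

__all__ = [
    "ManifestRecord",
    "ManifestError",
    "segment_to_record",
    "read_manifest",
    "write_manifest",
    "write_iteration_log",
]

_STATUSES = {"accepted", "discarded", "error"}


class ManifestError(ValueError):
    """Malformed or invariant-violating manifest content."""


@dataclass(frozen=True)
class ManifestRecord:
    audio_path: str
    start_s: float
    end_s: float
    hypothesis_text: str
    similarity: float
    status: str
    correction_text: str | None = None
    speaker_group: str | None = None
    iteration_index: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ManifestError(f"unknown status {self.status!r}")
        if not self.start_s < self.end_s:
            raise ManifestError(f"start_s {self.start_s} must precede end_s {self.end_s}")
        if self.status == "accepted" and self.correction_text is None:
            raise ManifestError("accepted record lacks correction_text")


_OWN_FIELDS = (
    "audio_path",
    "start_s",
    "end_s",
    "hypothesis_text",
    "similarity",
    "status",
    "correction_text",
    "speaker_group",
    "iteration_index",
)


def segment_to_record(seg: Segment, audio_path: str, iteration_index: int | None = None) -> ManifestRecord:
    return ManifestRecord(
        audio_path=audio_path,
        start_s=seg.span.start_s,
        end_s=seg.span.end_s,
        hypothesis_text=seg.hypothesis.char_string,
        similarity=seg.similarity,
        status=seg.status.value,
        correction_text=None if seg.correction is None else seg.correction.char_string,
        speaker_group=seg.group_label,
        iteration_index=iteration_index,
    )


def write_manifest(path: str | Path, records: Iterable[ManifestRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = {k: getattr(rec, k) for k in _OWN_FIELDS if getattr(rec, k) is not None}
            obj.update(rec.extra)
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_manifest(path: str | Path, gate_threshold: float | None = None) -> list[ManifestRecord]:
    """Read a JSONL manifest, re-checking gate soundness when a threshold is given.

    With ``gate_threshold``, a record whose similarity clears the threshold
    but is marked discarded (or vice versa) raises: the accept/reject status
    must be reproducible from the stored similarity.
    """
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ManifestError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            known = {k: obj.pop(k) for k in _OWN_FIELDS if k in obj}
            try:
                rec = ManifestRecord(**known, extra=obj)
            except (TypeError, ManifestError) as exc:
                raise ManifestError(f"{path}:{lineno}: {exc}") from exc
            if gate_threshold is not None and rec.status != "error":
                should_accept = rec.similarity >= gate_threshold
                if should_accept != (rec.status == "accepted"):
                    raise ManifestError(
                        f"{path}:{lineno}: status {rec.status!r} inconsistent with "
                        f"similarity {rec.similarity} at threshold {gate_threshold}"
                    )
            records.append(rec)
    return records


def write_iteration_log(path: str | Path, records: Sequence[IterationRecord]) -> None:
    """CSV iteration log: iteration, cumulative accepted samples, validation WER %."""
    df = pd.DataFrame(
        {
            "iteration": [r.iteration_index for r in records],
            "cumulative_samples": [r.cumulative_accepted_samples for r in records],
            "validation_wer_pct": [round(r.validation_wer_pct, 4) for r in records],
            "stop_reason": [r.stop_reason or "" for r in records],
        }
    )
    df.to_csv(path, index=False)
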