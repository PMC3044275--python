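"""Merging of overlapping octapeptide windows into variable-length helices.

Consecutive windows of one chain (start offsets differing by 1) share seven
residues and are merged into a single helix that is one residue longer per
extra window.  Two modes exist: ``within`` additionally requires all windows
in a run to carry the same subclass label, producing subclass-pure stretches
for propensity analysis; ``across`` merges regardless of label, producing
the complete helix for classifier training.  Flanking context (up to four
residues before and after the helix) is attached with an explicit validity
mask so chain-terminal helices keep a fixed-width flank contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .geometry import OctapeptideWindow, WINDOW_SIZE

__all__ = [
    "HelixSegment",
    "merge_windows",
    "attach_flanks",
    "select_training_segments",
    "FLANK_WIDTH",
]

FLANK_WIDTH = 4
MIXED = "mixed"


@dataclass
class HelixSegment:
    """A merged helix with per-window subclass labels and flanking context.

    ``flank_before``/``flank_after`` are always 4 characters; positions
    outside the chain are ``-`` with the corresponding mask entry False.
    ``flank_before`` reads in chain order (its last character is adjacent to
    the helix start); ``flank_after``'s first character follows the helix.
    """

    source_id: str
    start: int
    end: int
    sequence: str
    subclass_labels: tuple = ()
    flank_before: str = "-" * FLANK_WIDTH
    flank_after: str = "-" * FLANK_WIDTH
    flank_before_mask: tuple = (False,) * FLANK_WIDTH
    flank_after_mask: tuple = (False,) * FLANK_WIDTH

    def __post_init__(self) -> None:
        if self.length < WINDOW_SIZE:
            raise ValueError("a helix segment spans at least 8 residues")
        if len(self.sequence) != self.length:
            raise ValueError("sequence length must equal end - start + 1")
        if len(self.flank_before) != FLANK_WIDTH or len(self.flank_after) != FLANK_WIDTH:
            raise ValueError("flanks are fixed-width (4)")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def purity_label(self):
        """The single subclass if every window agrees, else ``"mixed"``."""
        labels = set(self.subclass_labels)
        return next(iter(labels)) if len(labels) == 1 else MIXED

    @property
    def is_pure(self) -> bool:
        return self.purity_label != MIXED


def merge_windows(
    windows: Sequence[OctapeptideWindow],
    labels: Sequence,
    mode: str = "across",
) -> list[HelixSegment]:
    """Merge maximal runs of consecutive windows into helix segments.

    Windows must be sorted by start position and belong to one chain.  A run
    of r consecutive windows yields a segment of length 8 + (r − 1).  In
    ``within`` mode a run is additionally broken whenever the subclass label
    changes, so each segment is label-pure; in ``across`` mode runs ignore
    labels and segments record the full label sequence.
    """
    if mode not in ("within", "across"):
        raise ValueError("mode must be 'within' or 'across'")
    if len(windows) != len(labels):
        raise ValueError("one label per window required")
    if not windows:
        return []
    starts = [w.start for w in windows]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("windows must be sorted by strictly increasing start")

    segments: list[HelixSegment] = []
    run_start = 0
    for i in range(1, len(windows) + 1):
        boundary = (
            i == len(windows)
            or starts[i] != starts[i - 1] + 1
            or (mode == "within" and labels[i] != labels[i - 1])
        )
        if boundary:
            run = windows[run_start:i]
            seg_start = run[0].start
            seg_end = run[-1].start + WINDOW_SIZE - 1
            parent = run[0].parent
            segments.append(
                HelixSegment(
                    source_id=parent.source_id,
                    start=seg_start,
                    end=seg_end,
                    sequence=parent.sequence[seg_start - 1 : seg_end],
                    subclass_labels=tuple(labels[run_start:i]),
                )
            )
            run_start = i
    return segments


def attach_flanks(segment: HelixSegment, chain_sequence: str) -> HelixSegment:
    """Fill the 4-residue flanks from the parent chain sequence.

    Positions that fall outside the chain are masked invalid and encoded as
    ``-``; both flanks always have width 4.
    """
    if not (1 <= segment.start and segment.end <= len(chain_sequence)):
        raise ValueError("segment bounds outside the chain sequence")
    before_chars, before_mask = [], []
    for pos in range(segment.start - FLANK_WIDTH, segment.start):
        ok = pos >= 1
        before_chars.append(chain_sequence[pos - 1] if ok else "-")
        before_mask.append(ok)
    after_chars, after_mask = [], []
    for pos in range(segment.end + 1, segment.end + 1 + FLANK_WIDTH):
        ok = pos <= len(chain_sequence)
        after_chars.append(chain_sequence[pos - 1] if ok else "-")
        after_mask.append(ok)
    return HelixSegment(
        source_id=segment.source_id,
        start=segment.start,
        end=segment.end,
        sequence=segment.sequence,
        subclass_labels=segment.subclass_labels,
        flank_before="".join(before_chars),
        flank_after="".join(after_chars),
        flank_before_mask=tuple(before_mask),
        flank_after_mask=tuple(after_mask),
    )


def select_training_segments(
    segments: Sequence[HelixSegment],
    positive_label="regular",
    max_length: int = 15,
) -> tuple[list[HelixSegment], list[HelixSegment]]:
    """Split across-merged segments into classifier positives and negatives.

    Keeps only label-pure segments of length 8..``max_length``; segments
    whose windows span more than one subclass are discarded.  Positives are
    the ``positive_label`` (regular-helix) segments, negatives everything
    else.
    """
    positives, negatives = [], []
    for seg in segments:
        if not (WINDOW_SIZE <= seg.length <= max_length) or not seg.is_pure:
            continue
        (positives if seg.purity_label == positive_label else negatives).append(seg)
    return positives, negatives
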