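"""Candidate enumeration: every mature-start window of a hairpin by
1-nt sliding, labelling against the annotated start, and the position
deviation metric."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .io import Hairpin, MirstartError

#: mature windows are ~20-25 nt; 22 is the canonical duplex length
DEFAULT_WINDOW_LEN = 22


@dataclass(frozen=True)
class CandidateWindow:
    hairpin_id: str
    start: int  # 1-based
    window_len: int
    label: int | None = None  # +1 true start, -1 decoy, None unlabelled


def generate_windows(
    hairpin: Hairpin, window_len: int = DEFAULT_WINDOW_LEN
) -> list[CandidateWindow]:
    """All L - w + 1 windows of the hairpin, starts ascending."""
    L = len(hairpin)
    if window_len > L:
        raise MirstartError(
            f"window length {window_len} exceeds hairpin {hairpin.id!r} length {L}"
        )
    if window_len < 1:
        raise MirstartError("window length must be positive")
    return [
        CandidateWindow(hairpin_id=hairpin.id, start=s, window_len=window_len)
        for s in range(1, L - window_len + 2)
    ]


def label_windows(
    windows: list[CandidateWindow], mature_start: int
) -> list[CandidateWindow]:
    """Label the window starting exactly at the annotated mature start
    +1 and every other window -1.  If the true start is not among the
    enumerable starts the hairpin contributes negatives only.
    """
    if not windows:
        return []
    starts = {w.start for w in windows}
    if mature_start not in starts:
        warnings.warn(
            f"hairpin {windows[0].hairpin_id!r}: mature start {mature_start} "
            "not enumerable at this window length; all windows labelled negative",
            stacklevel=2,
        )
    return [
        replace(w, label=1 if w.start == mature_start else -1) for w in windows
    ]


def position_deviation(pred_start: int, true_start: int) -> int:
    """|predicted - true| start position in nt; symmetric."""
    if pred_start < 1 or true_start < 1:
        raise MirstartError("start positions are 1-based and must be >= 1")
    return abs(pred_start - true_start)
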