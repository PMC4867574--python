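"""Secondary-structure model: pair tables, terminal-loop location,
the gapped miRNA:miRNA* duplex alignment of a candidate window, and
nearest-neighbor stability of duplex sub-regions.

All coordinates are 1-based inclusive (miRBase convention).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, NamedTuple

from .io import Hairpin, MirstartError

#: fixed width of every duplex alignment; shorter alignments are
#: right-padded with (N, N) columns, longer ones truncated.
DUPLEX_COLS = 25


class StructureError(MirstartError):
    """Invalid or degenerate secondary structure."""


# ---------------------------------------------------------------------------
# Pair table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairTable:
    """1-based pairing map: partner[i] = j if (i, j) paired, 0 if not.

    Index 0 is an unused sentinel so positions match dot-bracket
    coordinates directly.
    """

    partner: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.partner) - 1

    def is_paired(self, i: int) -> bool:
        return self.partner[i] != 0


def pair_table(structure: str) -> PairTable:
    """Build the pairing map of a pseudoknot-free dot-bracket string."""
    partner = [0] * (len(structure) + 1)
    stack: list[int] = []
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            opener = stack.pop()
            partner[opener] = pos
            partner[pos] = opener
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unmatched '(' at position {stack[0]}")
    return PairTable(partner=tuple(partner))


def to_dot_bracket(pt: PairTable) -> str:
    """Render a pair table back to its dot-bracket string."""
    chars = []
    for i in range(1, pt.length + 1):
        j = pt.partner[i]
        chars.append("." if j == 0 else ("(" if j > i else ")"))
    return "".join(chars)


def terminal_loop_start(pt: PairTable) -> int:
    """First base of the terminal (hairpin) loop: one past the largest
    5'-arm position that pairs downstream.
    """
    last_open = 0
    for i in range(1, pt.length + 1):
        if pt.partner[i] > i:
            last_open = i
    if last_open == 0:
        raise StructureError("no stem: structure has no base pairs")
    return last_open + 1


# ---------------------------------------------------------------------------
# Duplex alignment
# ---------------------------------------------------------------------------

class DuplexColumn(NamedTuple):
    top: str
    bottom: str
    paired: bool


_PAD = DuplexColumn("N", "N", False)


@dataclass(frozen=True)
class DuplexAlignment:
    """Gapped alignment of a candidate window (top strand, 5'->3')
    against its pairing partner region (bottom strand, 3'->5'),
    fixed at DUPLEX_COLS columns.
    """

    columns: tuple[DuplexColumn, ...]

    def __post_init__(self) -> None:
        if len(self.columns) != DUPLEX_COLS:
            raise StructureError(
                f"duplex must have exactly {DUPLEX_COLS} columns, "
                f"got {len(self.columns)}"
            )

    @property
    def n_real(self) -> int:
        """Number of non-pad columns."""
        return sum(1 for c in self.columns if c != _PAD)


def build_duplex(
    hairpin: Hairpin,
    start: int,
    window_len: int,
    pt: PairTable | None = None,
) -> DuplexAlignment:
    """Align the window [start, start+window_len-1] against the star
    strand read along decreasing partner coordinates.

    Between consecutive paired anchors the unpaired runs of both
    strands are emitted left-justified, the shorter run padded with
    '-'; window positions outside the anchored region face '-'.
    """
    L = len(hairpin)
    if not 1 <= start or start + window_len - 1 > L:
        raise MirstartError(
            f"window [{start}, {start + window_len - 1}] outside hairpin "
            f"{hairpin.id!r} of length {L}"
        )
    if pt is None:
        pt = pair_table(hairpin.structure)
    seq = hairpin.sequence
    end = start + window_len - 1
    anchors = [(i, pt.partner[i]) for i in range(start, end + 1) if pt.partner[i] > i]

    cols: list[DuplexColumn] = []
    if not anchors:
        cols = [DuplexColumn(seq[i - 1], "-", False) for i in range(start, end + 1)]
    else:
        first_i, first_j = anchors[0]
        for i in range(start, first_i):
            cols.append(DuplexColumn(seq[i - 1], "-", False))
        cols.append(DuplexColumn(seq[first_i - 1], seq[first_j - 1], True))
        for (i1, j1), (i2, j2) in zip(anchors, anchors[1:]):
            top_gap = [seq[p - 1] for p in range(i1 + 1, i2)]
            bot_gap = [seq[p - 1] for p in range(j1 - 1, j2, -1)]
            for t in range(max(len(top_gap), len(bot_gap))):
                top = top_gap[t] if t < len(top_gap) else "-"
                bot = bot_gap[t] if t < len(bot_gap) else "-"
                cols.append(DuplexColumn(top, bot, False))
            cols.append(DuplexColumn(seq[i2 - 1], seq[j2 - 1], True))
        last_i = anchors[-1][0]
        for i in range(last_i + 1, end + 1):
            cols.append(DuplexColumn(seq[i - 1], "-", False))

    cols = cols[:DUPLEX_COLS]
    cols.extend([_PAD] * (DUPLEX_COLS - len(cols)))
    return DuplexAlignment(columns=tuple(cols))


# ---------------------------------------------------------------------------
# Stacking energies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackTable:
    """Nearest-neighbor stack free energies keyed by (pair, next pair),
    each pair written top-base + bottom-base.
    """

    energy: Mapping[tuple[str, str], float]


def load_stack_table(path=None) -> StackTable:
    """Load a stack table from a key/value TSV ('XY<tab>WZ<tab>dG')."""
    if path is None:
        text = (
            resources.files("mirstart.data")
            .joinpath("stack_energies.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    energy: dict[tuple[str, str], float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        p1, p2, dg = line.split("\t")
        energy[(p1, p2)] = float(dg)
    return StackTable(energy=energy)


@lru_cache(maxsize=1)
def default_stack_table() -> StackTable:
    return load_stack_table()


def region_energy(
    duplex: DuplexAlignment,
    cols: tuple[int, int],
    table: StackTable | None = None,
) -> float:
    """Stability of an inclusive 1-based column range: the sum of
    stack energies over adjacent paired columns.  Interrupted helices
    contribute nothing across the interruption; fewer than two paired
    columns give 0.0.
    """
    lo, hi = cols
    if not 1 <= lo <= hi <= DUPLEX_COLS:
        raise MirstartError(f"column range ({lo}, {hi}) outside 1..{DUPLEX_COLS}")
    if table is None:
        table = default_stack_table()
    total = 0.0
    for c in range(lo, hi):
        a = duplex.columns[c - 1]
        b = duplex.columns[c]
        if a.paired and b.paired:
            total += table.energy.get((a.top + a.bottom, b.top + b.bottom), 0.0)
    return total
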