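"""The 110-dimensional encoding of one candidate window.

Layout (in order):

==========  ====  ====================================================
pn1-25       25   paired-nucleotide type of each duplex column
ss1-50       50   nucleotide + pair-state code per column, top strand
                  (25) then bottom strand (25)
fl1-18       18   nucleotide + pair-state of the 9 hairpin positions
                  immediately 5' of the window and their partners
fr1-6         6   same for the 3 positions immediately 3'
MFE1-5        5   stability of (whole duplex, left 3, left 5, left 9,
                  right 3 columns), kcal/mol
length        1   distance from window start to the terminal loop
Num1-3        3   '-' counts over duplex columns 2-5, 3-8, 9-12
fn            1   first window nucleotide (A=0, C=1, G=2, U=3)
pair          1   0 if duplex column 1 is paired, else 1
==========  ====  ====================================================

Both categorical codebooks are fixed, versioned bijections; models
persist the codebook version and refuse to score with a different one.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candidates import CandidateWindow
from .io import Hairpin, MirstartError
from .structure import (
    PairTable,
    StackTable,
    build_duplex,
    pair_table,
    region_energy,
    terminal_loop_start,
)

CODEBOOK_VERSION = "1"

N_FEATURES = 110

#: paired-nucleotide types, codes 0..25 in this exact order
PAIR_TYPES: tuple[str, ...] = (
    "NN", "AA", "AC", "AG", "AU", "CA", "CC", "CG", "CU",
    "GA", "GC", "GG", "GU", "UA", "UC", "UG", "UU",
    "-A", "-C", "-G", "-U", "A-", "C-", "G-", "U-", "--",
)
_PAIR_TYPE_CODE = {p: i for i, p in enumerate(PAIR_TYPES)}

#: nucleotide + pair-state classes, codes 0..9 in this exact order
NT_PAIRSTATES: tuple[str, ...] = (
    "N.", "A(", "C(", "G(", "U(", "A.", "C.", "G.", "U.", "-.",
)
_NT_PAIRSTATE_CODE = {p: i for i, p in enumerate(NT_PAIRSTATES)}

_ALPHABET = frozenset("ACGU-N")
_FN_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"pn{i}" for i in range(1, 26))
    + tuple(f"ss{i}" for i in range(1, 51))
    + tuple(f"fl{i}" for i in range(1, 19))
    + tuple(f"fr{i}" for i in range(1, 7))
    + tuple(f"MFE{i}" for i in range(1, 6))
    + ("length",)
    + tuple(f"Num{i}" for i in range(1, 4))
    + ("fn", "pair")
)
assert len(FEATURE_NAMES) == N_FEATURES


def encode_pair_type(top: str, bottom: str) -> int:
    """Code 0..25 for a duplex column's (top, bottom) characters."""
    if top not in _ALPHABET or bottom not in _ALPHABET:
        raise MirstartError(f"invalid duplex characters ({top!r}, {bottom!r})")
    key = top + bottom
    if key in _PAIR_TYPE_CODE:
        return _PAIR_TYPE_CODE[key]
    # N never co-occurs with a real base: pads are (N, N)
    raise MirstartError(f"no pair-type code for ({top!r}, {bottom!r})")


def decode_pair_type(code: int) -> tuple[str, str]:
    pair = PAIR_TYPES[code]
    return pair[0], pair[1]


def encode_nt_pairstate(nt: str, paired: bool) -> int:
    """Code 0..9 for one strand character and its pairing state; any
    paired base uses its '(' class regardless of arm."""
    if nt not in _ALPHABET:
        raise MirstartError(f"invalid nucleotide {nt!r}")
    if paired:
        if nt in "-N":
            raise MirstartError(f"{nt!r} cannot be paired")
        return _NT_PAIRSTATE_CODE[nt + "("]
    if nt == "N":
        return _NT_PAIRSTATE_CODE["N."]
    return _NT_PAIRSTATE_CODE[nt + "."]


def decode_nt_pairstate(code: int) -> tuple[str, bool]:
    cls = NT_PAIRSTATES[code]
    return cls[0], cls[1] == "("


def _flank_codes(
    hairpin: Hairpin, pt: PairTable, positions: range
) -> tuple[list[int], list[int]]:
    """Top- and bottom-strand codes for hairpin positions flanking the
    duplex; positions off the sequence ends count as (N, unpaired)."""
    seq = hairpin.sequence
    top, bottom = [], []
    for p in positions:
        if 1 <= p <= len(hairpin):
            j = pt.partner[p]
            top.append(encode_nt_pairstate(seq[p - 1], j != 0))
            if j != 0:
                bottom.append(encode_nt_pairstate(seq[j - 1], True))
            else:
                bottom.append(encode_nt_pairstate("-", False))
        else:
            top.append(encode_nt_pairstate("N", False))
            bottom.append(encode_nt_pairstate("N", False))
    return top, bottom


def extract_features(
    hairpin: Hairpin,
    window: CandidateWindow,
    table: StackTable | None = None,
    pt: PairTable | None = None,
) -> np.ndarray:
    """Encode one candidate window as the 110-value feature vector."""
    if pt is None:
        pt = pair_table(hairpin.structure)
    start, wlen = window.start, window.window_len
    duplex = build_duplex(hairpin, start, wlen, pt=pt)
    cols = duplex.columns

    pn = [encode_pair_type(c.top, c.bottom) for c in cols]
    ss_top = [encode_nt_pairstate(c.top, c.paired) for c in cols]
    ss_bot = [encode_nt_pairstate(c.bottom, c.paired) for c in cols]
    fl_top, fl_bot = _flank_codes(hairpin, pt, range(start - 9, start))
    fr_top, fr_bot = _flank_codes(hairpin, pt, range(start + wlen, start + wlen + 3))

    n_real = duplex.n_real
    mfe = [
        region_energy(duplex, (1, 25), table),
        region_energy(duplex, (1, 3), table),
        region_energy(duplex, (1, 5), table),
        region_energy(duplex, (1, 9), table),
    ]
    if n_real >= 2:
        right_lo = max(1, n_real - 2)
        mfe.append(region_energy(duplex, (right_lo, n_real), table))
    else:
        mfe.append(0.0)

    try:
        length = terminal_loop_start(pt) - start
    except Exception:
        length = 0  # degenerate pair-free structure

    def gap_count(lo: int, hi: int) -> int:
        return sum(
            (c.top == "-") + (c.bottom == "-") for c in cols[lo - 1 : hi]
        )

    num = [gap_count(2, 5), gap_count(3, 8), gap_count(9, 12)]
    fn = _FN_CODE[hairpin.sequence[start - 1]]
    pair = 0 if cols[0].paired else 1

    vec = np.array(
        pn + ss_top + ss_bot + fl_top + fl_bot + fr_top + fr_bot
        + mfe + [length] + num + [fn, pair],
        dtype=float,
    )
    assert vec.shape == (N_FEATURES,)
    return vec


def feature_matrix(
    hairpin: Hairpin,
    windows: list[CandidateWindow],
    table: StackTable | None = None,
) -> np.ndarray:
    """Feature vectors for many windows of one hairpin; the pair table
    is computed once."""
    pt = pair_table(hairpin.structure)
    if not windows:
        return np.empty((0, N_FEATURES))
    return np.vstack(
        [extract_features(hairpin, w, table=table, pt=pt) for w in windows]
    )


# ---------------------------------------------------------------------------
# Min-max normalization to [-1, 1]
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature (min, max) taken from the training matrix."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        if self.mins.shape != (N_FEATURES,) or self.maxs.shape != (N_FEATURES,):
            raise MirstartError(
                f"normalization needs exactly {N_FEATURES} (min, max) pairs"
            )
        if np.any(self.mins > self.maxs):
            raise MirstartError("normalization min exceeds max")


def _check_width(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != N_FEATURES:
        raise MirstartError(
            f"feature matrix must have {N_FEATURES} columns, got shape "
            f"{matrix.shape}"
        )
    return matrix


def fit_normalization(matrix: np.ndarray) -> NormalizationParams:
    matrix = _check_width(matrix)
    return NormalizationParams(
        mins=matrix.min(axis=0), maxs=matrix.max(axis=0)
    )


def apply_normalization(
    matrix: np.ndarray, params: NormalizationParams
) -> np.ndarray:
    """Affine map of each feature to [-1, 1] by the training min/max;
    constant features map to 0, out-of-range values are clipped."""
    matrix = _check_width(matrix)
    span = params.maxs - params.mins
    safe = np.where(span == 0, 1.0, span)
    scaled = -1.0 + 2.0 * (matrix - params.mins) / safe
    scaled = np.where(span == 0, 0.0, scaled)
    return np.clip(scaled, -1.0, 1.0)
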