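"""Readers and writers for the pipeline's file formats.

Pre-miRNA hairpins arrive as FASTA, secondary structures as
Vienna-style dot-bracket blocks (the layout RNAfold prints), mature
5' start annotations as a three-column TSV, and trained ensembles
are persisted as a self-describing joblib archive tagged with the
feature-codebook version so stale models cannot silently mis-decode
feature vectors.
"""
from __future__ import annotations

import math
import re
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import joblib
from Bio import SeqIO


class MirstartError(Exception):
    """Base class for errors raised by this package."""


class ParseError(MirstartError):
    """Malformed input file."""


class ModelIOError(MirstartError):
    """Unreadable or incompatible model archive."""


#: Accepted hairpin length bounds (nt); pre-miRNAs fall well inside.
MIN_HAIRPIN_LEN = 40
MAX_HAIRPIN_LEN = 200

_RNA_ALPHABET = frozenset("ACGU")
_STRUCT_ALPHABET = frozenset("().")
#: trailing "( -12.30)" free-energy token on RNAfold structure lines
_ENERGY_RE = re.compile(r"\s*\(\s*-?\d+(\.\d+)?\s*\)\s*$")


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and map DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def _check_balanced(structure: str) -> None:
    stack = []
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {pos}")
            stack.pop()
    if stack:
        raise ParseError(f"unmatched '(' at position {stack[0]}")


@dataclass(frozen=True)
class Hairpin:
    """A pre-miRNA hairpin: sequence, dot-bracket structure and an
    optional annotated 5' mature start (1-based, miRBase convention).
    """

    id: str
    sequence: str
    structure: str
    mature_start: int | None = None
    mature_len: int = 22

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ParseError(
                f"hairpin {self.id!r}: invalid letters {sorted(bad)} in sequence"
            )
        n = len(self.sequence)
        if not MIN_HAIRPIN_LEN <= n <= MAX_HAIRPIN_LEN:
            raise ParseError(
                f"hairpin {self.id!r}: length {n} outside "
                f"[{MIN_HAIRPIN_LEN}, {MAX_HAIRPIN_LEN}]"
            )
        if len(self.structure) != n:
            raise ParseError(
                f"hairpin {self.id!r}: structure length {len(self.structure)} "
                f"!= sequence length {n}"
            )
        if set(self.structure) - _STRUCT_ALPHABET:
            raise ParseError(f"hairpin {self.id!r}: invalid dot-bracket characters")
        try:
            _check_balanced(self.structure)
        except ParseError as exc:
            raise ParseError(f"hairpin {self.id!r}: {exc}") from None
        if self.mature_len < 1:
            raise ParseError(f"hairpin {self.id!r}: mature_len must be positive")
        if self.mature_start is not None:
            if not 1 <= self.mature_start <= n - self.mature_len + 1:
                raise ParseError(
                    f"hairpin {self.id!r}: mature_start {self.mature_start} "
                    f"outside [1, {n - self.mature_len + 1}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs, order preserved.

    Sequences are uppercased with T mapped to U; letters outside
    {A,C,G,U,T} are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path.name} line {lineno}: expected FASTA header '>'"
                    )
                break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_rna(str(rec.seq))
        if not seq:
            raise ParseError(f"{path.name}: record {rec.id!r} has no sequence")
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ParseError(
                f"{path.name}: record {rec.id!r} has invalid letters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    if not records:
        raise ParseError(f"{path.name}: no records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Vienna dot-bracket blocks (RNAfold-style output)
# ---------------------------------------------------------------------------

def _parse_structure_blocks(lines: Sequence[str], source: str) -> dict[str, str]:
    structures: dict[str, str] = {}
    rows = [ln.rstrip("\n") for ln in lines if ln.strip()]
    i = 0
    while i < len(rows):
        header = rows[i]
        if not header.startswith(">"):
            raise ParseError(f"{source}: expected '>' header, got {header[:30]!r}")
        name = header[1:].split()[0]
        if i + 2 >= len(rows) or rows[i + 1].startswith(">") or rows[i + 2].startswith(">"):
            raise ParseError(f"{source}: block {name!r} missing sequence or structure line")
        seq = re.sub(r"\s+", "", rows[i + 1])
        struct = _ENERGY_RE.sub("", rows[i + 2])
        struct = re.sub(r"\s+", "", struct)
        if set(struct) - _STRUCT_ALPHABET:
            raise ParseError(f"{source}: block {name!r} has invalid structure characters")
        if len(struct) != len(seq):
            raise ParseError(
                f"{source}: block {name!r} structure length {len(struct)} "
                f"!= sequence length {len(seq)}"
            )
        try:
            _check_balanced(struct)
        except ParseError as exc:
            raise ParseError(f"{source}: block {name!r}: {exc}") from None
        structures[name] = struct
        i += 3
    if not structures:
        raise ParseError(f"{source}: no structure blocks")
    return structures


def read_structures(path: str | Path) -> dict[str, str]:
    """Read RNAfold-style blocks (">id", sequence, structure [energy])."""
    path = Path(path)
    with open(path) as fh:
        return _parse_structure_blocks(fh.readlines(), path.name)


def write_structures(
    items: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    """Write (id, sequence, dot-bracket) triples as Vienna blocks."""
    with open(path, "w") as fh:
        for name, seq, struct in items:
            fh.write(f">{name}\n{seq}\n{struct}\n")


def fold_structures(
    records: Iterable[tuple[str, str]], fold_cmd: str
) -> dict[str, str]:
    """Pipe FASTA through an external folding command (e.g. RNAfold
    --noPS) and parse the dot-bracket blocks it prints.
    """
    fasta = "".join(f">{name}\n{seq}\n" for name, seq in records)
    proc = subprocess.run(
        fold_cmd, shell=True, input=fasta, capture_output=True, text=True
    )
    if proc.returncode != 0:
        raise MirstartError(
            f"fold command {fold_cmd!r} failed (exit {proc.returncode}): "
            f"{proc.stderr.strip()[:200]}"
        )
    return _parse_structure_blocks(proc.stdout.splitlines(), f"fold-cmd {fold_cmd!r}")


# ---------------------------------------------------------------------------
# Mature-start annotations (3-column TSV: id, 1-based start, mature length)
# ---------------------------------------------------------------------------

def read_mature_tsv(path: str | Path) -> dict[str, tuple[int, int]]:
    path = Path(path)
    out: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path.name} line {lineno}: expected 3 columns")
            name, start_s, len_s = fields[0], fields[1], fields[2]
            try:
                start, mlen = int(start_s), int(len_s)
            except ValueError:
                if lineno == 1 and not out:
                    continue  # optional header row
                raise ParseError(
                    f"{path.name} line {lineno}: non-integer start/length"
                ) from None
            if start < 1:
                raise ParseError(f"{path.name} line {lineno}: start {start} < 1")
            if mlen < 1:
                raise ParseError(f"{path.name} line {lineno}: length {mlen} < 1")
            if name in out:
                raise ParseError(f"{path.name} line {lineno}: duplicate id {name!r}")
            out[name] = (start, mlen)
    if not out:
        raise ParseError(f"{path.name}: no annotations")
    return out


def write_mature_tsv(
    annotations: dict[str, tuple[int, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("hairpin_id\tmature_start\tmature_len\n")
        for name, (start, mlen) in annotations.items():
            fh.write(f"{name}\t{start}\t{mlen}\n")


def load_hairpins(
    fasta_path: str | Path,
    structures_path: str | Path | None = None,
    mature_path: str | Path | None = None,
    fold_cmd: str | None = None,
) -> list[Hairpin]:
    """Assemble Hairpin objects from a FASTA file plus a structure
    source (file, or external fold command when no file is given) and
    optional mature annotations.
    """
    records = read_fasta(fasta_path)
    if structures_path is not None:
        structures = read_structures(structures_path)
    elif fold_cmd is not None:
        structures = fold_structures(records, fold_cmd)
    else:
        raise MirstartError("either a structure file or a fold command is required")
    annotations = read_mature_tsv(mature_path) if mature_path is not None else {}
    hairpins = []
    for name, seq in records:
        if name not in structures:
            raise ParseError(f"no structure for hairpin {name!r}")
        start, mlen = annotations.get(name, (None, 22))
        hairpins.append(
            Hairpin(id=name, sequence=seq, structure=structures[name],
                    mature_start=start, mature_len=mlen)
        )
    return hairpins


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

_MODEL_FORMAT = "mirstart-ensemble"


@dataclass
class ModelBundle:
    """Persisted form of a trained ensemble.

    rounds holds (classifier, alpha, C, g) per boosting round;
    normalization is the per-feature (min, max) training scaling.
    """

    rounds: list[tuple[object, float, float, float]]
    normalization: object
    window_len: int
    codebook_version: str

    def validate(self) -> None:
        if not self.rounds:
            raise ModelIOError("model has no rounds")
        for _, alpha, _, _ in self.rounds:
            if not math.isfinite(alpha):
                raise ModelIOError("model has a non-finite round weight")
        mins = getattr(self.normalization, "mins", None)
        maxs = getattr(self.normalization, "maxs", None)
        if mins is None or maxs is None or len(mins) != 110 or len(maxs) != 110:
            raise ModelIOError("model normalization must have exactly 110 entries")
        if self.window_len < 1:
            raise ModelIOError("model window_len must be positive")


def save_model(bundle: ModelBundle, path: str | Path) -> None:
    bundle.validate()
    joblib.dump(
        {
            "format": _MODEL_FORMAT,
            "codebook_version": bundle.codebook_version,
            "bundle": bundle,
        },
        path,
    )


def load_model(path: str | Path) -> ModelBundle:
    from .features import CODEBOOK_VERSION  # deferred: avoids import cycle

    try:
        payload = joblib.load(path)
    except Exception as exc:  # noqa: BLE001 - any unpickling failure
        raise ModelIOError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ModelIOError(f"{path} is not a {_MODEL_FORMAT} archive")
    if payload.get("codebook_version") != CODEBOOK_VERSION:
        raise ModelIOError(
            f"model codebook version {payload.get('codebook_version')!r} does not "
            f"match library codebook {CODEBOOK_VERSION!r}; retrain the model"
        )
    bundle = payload["bundle"]
    bundle.validate()
    return bundle
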