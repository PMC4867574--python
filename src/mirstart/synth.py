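"""Synthetic stem-loop generator with a planted, learnable mature
start, so the whole pipeline can be trained and evaluated offline.

Each hairpin is flank5 + 5'arm + loop + 3'arm + flank3, the 3' arm
being the reverse complement of the 5' arm with seeded bulges and
mismatches; the dot-bracket structure is emitted by construction, so
fixtures are exact and independent of any folding energy model.  The
annotated mature window starts at the first 5'-arm base.  With
probability ``signal_strength`` the planted signature is enforced:
the first mature nucleotide is U and the first 9 stem positions are
defect-free (fully paired) — properties expressible in the feature
set (fn, pair, pn/fl codes), so learnability exercises the feature
extractor rather than a positional artifact.  Flank, stem and loop
lengths are jittered per hairpin so the distance-to-loop feature is
informative without being a positional give-away.

This is not a biological pre-miRNA simulator: base composition,
asymmetric internal loops and multi-branch structures of real
precursors are not modelled.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import Hairpin, MirstartError, write_fasta, write_mature_tsv, write_structures

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = ("A", "C", "G", "U")


@dataclass(frozen=True)
class SynthConfig:
    n_hairpins: int = 200
    flank5_len: int = 8
    flank3_len: int = 8
    stem_len: int = 30
    loop_len: int = 8
    mature_len: int = 22
    bulge_rate: float = 0.08
    signal_strength: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hairpins", "flank5_len", "flank3_len", "stem_len",
                     "loop_len", "mature_len"):
            if getattr(self, name) < 1:
                raise MirstartError(f"{name} must be positive")
        if self.stem_len < self.mature_len - 3:
            raise MirstartError("stem_len must be >= mature_len - 3")
        for name in ("bulge_rate", "signal_strength"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise MirstartError(f"{name} must lie in [0, 1]")


def _random_base(rng) -> str:
    return _BASES[int(rng.integers(4))]


def make_hairpin(cfg: SynthConfig, index: int) -> Hairpin:
    """Deterministically generate hairpin ``index`` of the dataset;
    the same (seed, index) always yields the same hairpin."""
    rng = np.random.default_rng([cfg.seed, index])
    f5 = max(4, cfg.flank5_len + int(rng.integers(-3, 4)))
    f3 = max(4, cfg.flank3_len + int(rng.integers(-3, 4)))
    stem = max(cfg.mature_len - 3, cfg.stem_len + int(rng.integers(-2, 3)))
    loop = max(3, cfg.loop_len + int(rng.integers(-2, 3)))
    signature = bool(rng.random() < cfg.signal_strength)

    arm5: list[str] = []
    db5: list[str] = []
    arm3_rev: list[str] = []  # 3'->5', reversed at the end
    db3_rev: list[str] = []
    for t in range(1, stem + 1):
        base = _random_base(rng)
        if t == 1 and signature:
            base = "U"
        protected = t == stem or (signature and t <= 9)
        event = "match"
        if not protected and rng.random() < cfg.bulge_rate:
            event = ("mismatch", "bulge5", "bulge3")[int(rng.integers(3))]
        if event == "match":
            arm5.append(base)
            db5.append("(")
            arm3_rev.append(_COMPLEMENT[base])
            db3_rev.append(")")
        elif event == "mismatch":
            arm5.append(base)
            db5.append(".")
            other = _COMPLEMENT[base]
            while other == _COMPLEMENT[base]:
                other = _random_base(rng)
            arm3_rev.append(other)
            db3_rev.append(".")
        elif event == "bulge5":
            arm5.append(base)
            db5.append(".")
        else:  # bulge3
            arm3_rev.append(_random_base(rng))
            db3_rev.append(".")

    flank5 = "".join(_random_base(rng) for _ in range(f5))
    flank3 = "".join(_random_base(rng) for _ in range(f3))
    loop_seq = "".join(_random_base(rng) for _ in range(loop))
    sequence = (
        flank5 + "".join(arm5) + loop_seq + "".join(reversed(arm3_rev)) + flank3
    )
    structure = (
        "." * f5 + "".join(db5) + "." * loop
        + "".join(reversed(db3_rev)) + "." * f3
    )
    return Hairpin(
        id=f"synth-{cfg.seed}-{index}",
        sequence=sequence,
        structure=structure,
        mature_start=f5 + 1,
        mature_len=cfg.mature_len,
    )


def make_dataset(
    cfg: SynthConfig, out_dir: str | Path | None = None
) -> tuple[list[Hairpin], list[Hairpin]]:
    """Generate the full cohort and split it ~90/10 into train and
    test with a seeded shuffle; optionally emit the FASTA, structure
    and annotation files (plus a manifest) consumable by the readers.
    """
    if cfg.n_hairpins < 10:
        raise MirstartError("need at least 10 hairpins for a train/test split")
    hairpins = [make_hairpin(cfg, i) for i in range(cfg.n_hairpins)]
    order = np.random.default_rng([cfg.seed, 999983]).permutation(cfg.n_hairpins)
    n_test = max(1, round(cfg.n_hairpins / 10))
    test = [hairpins[i] for i in order[:n_test]]
    train = [hairpins[i] for i in order[n_test:]]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta([(h.id, h.sequence) for h in hairpins],
                    out_dir / "hairpins.fasta")
        write_structures([(h.id, h.sequence, h.structure) for h in hairpins],
                         out_dir / "structures.txt")
        write_mature_tsv(
            {h.id: (h.mature_start, h.mature_len) for h in hairpins},
            out_dir / "mature.tsv",
        )
        manifest = {
            "config": asdict(cfg),
            "train_ids": [h.id for h in train],
            "test_ids": [h.id for h in test],
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return train, test
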