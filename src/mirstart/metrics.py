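"""Evaluation surfaces: accuracy at each position deviation, the
exact-deviation histogram, top-k accuracy and the average position
deviation (APD).  Acc is computed per hairpin — one first candidate
(or best of top k) per test hairpin."""
from __future__ import annotations

from dataclasses import dataclass

from .candidates import position_deviation
from .io import MirstartError


@dataclass(frozen=True)
class EvalReport:
    acc_by_pd: dict[int, float]        # cumulative Acc at PD 0..max_pd
    pd_distribution: tuple[float, ...]  # exact-PD mass at 0..max_pd + overflow
    top_k_acc: dict[int, float]        # k -> Acc at PD 0
    apd: float


def _check_parallel(pred_starts, true_starts) -> None:
    if len(pred_starts) == 0:
        raise MirstartError("no predictions to evaluate")
    if len(pred_starts) != len(true_starts):
        raise MirstartError("prediction and truth lists must be parallel")


def accuracy_at_pd(pred_starts, true_starts, pd: int) -> float:
    """Fraction of hairpins whose predicted start deviates <= pd nt."""
    _check_parallel(pred_starts, true_starts)
    hits = sum(
        position_deviation(p, t) <= pd for p, t in zip(pred_starts, true_starts)
    )
    return hits / len(pred_starts)


def pd_distribution(pred_starts, true_starts, max_pd: int = 5) -> tuple[float, ...]:
    """Exact-deviation histogram at 0..max_pd plus an overflow bin,
    normalized to total mass 1."""
    _check_parallel(pred_starts, true_starts)
    counts = [0] * (max_pd + 2)
    for p, t in zip(pred_starts, true_starts):
        d = position_deviation(p, t)
        counts[d if d <= max_pd else max_pd + 1] += 1
    n = len(pred_starts)
    return tuple(c / n for c in counts)


def apd(pred_starts, true_starts) -> float:
    """Average position deviation in nt."""
    _check_parallel(pred_starts, true_starts)
    total = sum(
        position_deviation(p, t) for p, t in zip(pred_starts, true_starts)
    )
    return total / len(pred_starts)


def top_k_accuracy(ranked_lists, true_starts, k: int, pd: int = 0) -> float:
    """Fraction of hairpins whose best candidate among the top k
    deviates <= pd nt."""
    _check_parallel(ranked_lists, true_starts)
    hits = 0
    for ranked, t in zip(ranked_lists, true_starts):
        if not ranked:
            raise MirstartError("empty ranked candidate list")
        if min(position_deviation(p, t) for p in ranked[:k]) <= pd:
            hits += 1
    return hits / len(ranked_lists)


def build_report(
    ranked_lists, true_starts, max_pd: int = 5, ks=(1, 5)
) -> EvalReport:
    """Full evaluation of per-hairpin ranked candidate starts."""
    _check_parallel(ranked_lists, true_starts)
    first = [ranked[0] for ranked in ranked_lists]
    return EvalReport(
        acc_by_pd={
            d: accuracy_at_pd(first, true_starts, d) for d in range(max_pd + 1)
        },
        pd_distribution=pd_distribution(first, true_starts, max_pd),
        top_k_acc={k: top_k_accuracy(ranked_lists, true_starts, k) for k in ks},
        apd=apd(first, true_starts),
    )
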