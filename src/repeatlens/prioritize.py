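"""Priority scoring of repeat copy-number changes and multi-dataset joining.

Single-dataset ranking: per repeat, optionally drop the single most extreme
expansion and contraction (when the dataset's mean prediction count is >= 3),
take the most extreme remaining change, convert it to bases, and score it as

    (length increase in bases) / (reference repeat length + 30)

times a genomic-context multiplier, doubled for coding polyglutamine /
polyalanine units.  Repeats are ranked by |score|.

Case/control joining combines per-individual scores with cubic means
(emphasizing large values) into max(d - max(h, 0), 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotations import GeneContext, RepeatAnnotation
from .copy_number import RepeatResult

__all__ = [
    "PriorityRecord",
    "JoinRecord",
    "select_top_change",
    "is_polyQ_or_polyA",
    "priority_score",
    "rank_records",
    "score_results",
    "mean_prediction_count",
    "cubic_mean",
    "joint_priority",
    "join_datasets",
]

_GLN_CODONS = {"CAA", "CAG"}
_ALA_CODONS = {"GCA", "GCC", "GCG", "GCT"}

_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PriorityRecord:
    repeat: RepeatAnnotation
    context: GeneContext
    topChangeCopies: int
    topChangeBases: int
    score: float
    rank: int = 0
    result: RepeatResult | None = None


@dataclass
class JoinRecord:
    repeat: RepeatAnnotation
    context: GeneContext
    d: float
    h: float
    jointScore: float
    rank: int = 0


def mean_prediction_count(results: Iterable[RepeatResult]) -> float:
    """Dataset-wide mean number of predictions over repeats with >= 1."""
    counts = [r.n_predictions for r in results if r.n_predictions > 0]
    if not counts:
        return 0.0
    return sum(counts) / len(counts)


def select_top_change(result: RepeatResult, dataset_mean_predictions: float) -> tuple[int, int]:
    """Pick the change to score: (bases, copies).

    When the dataset mean prediction count is >= 3 and this repeat has at
    least 3 predictions, one copy of the maximum and one of the minimum
    change are dropped first (guards against outlier reads).  The most
    extreme remaining change (largest |bases|, ties to the expansion) wins.
    """
    changes = list(result.changes)
    if not changes:
        raise ValueError("select_top_change needs at least one prediction")
    if dataset_mean_predictions >= 3 and len(changes) >= 3:
        changes.remove(max(changes))
        changes.remove(min(changes))
    top = max(changes, key=lambda c: (abs(c), c))
    return top * result.repeat.u, top


def is_polyQ_or_polyA(unit: str) -> bool:
    """True if endless repetition of the unit encodes pure polyglutamine or
    polyalanine in any of the 6 reading frames (3 frames x 2 strands)."""
    unit = unit.upper()
    u = len(unit)
    period = math.lcm(u, 3)
    for seq in (unit, unit.translate(_RC)[::-1]):
        tiled = seq * (period // u + 2)
        for frame in range(3):
            codons = [tiled[frame + k: frame + k + 3] for k in range(0, period, 3)]
            if all(c in _GLN_CODONS for c in codons) or all(c in _ALA_CODONS for c in codons):
                return True
    return False


def priority_score(top_change_bases: int, ref_len: int, context: GeneContext, unit: str) -> float:
    """Signed priority score; contractions come out negative."""
    score = top_change_bases / (ref_len + 30) * context.multiplier
    if context.category == "coding" and is_polyQ_or_polyA(unit):
        score *= 2
    return score


def rank_records(records: Sequence[PriorityRecord]) -> list[PriorityRecord]:
    """Stable sort by descending |score|; 1-based ranks.

    Ties break by descending |topChangeBases|, then (chrom, start) so output
    is deterministic.
    """
    ordered = sorted(
        records,
        key=lambda r: (-abs(r.score), -abs(r.topChangeBases), r.repeat.chrom, r.repeat.start),
    )
    for i, rec in enumerate(ordered, 1):
        rec.rank = i
    return ordered


def score_results(results: Sequence[RepeatResult],
                  contexts: Mapping[int, GeneContext] | None = None) -> list[PriorityRecord]:
    """Score and rank one dataset's repeat results.

    ``contexts`` maps result index -> GeneContext; results may also carry
    their context on ``result.context``.  Repeats without predictions emit no
    record.
    """
    mean_n = mean_prediction_count(results)
    records = []
    for idx, res in enumerate(results):
        if res.n_predictions == 0:
            continue
        ctx = (contexts or {}).get(idx) or res.context or GeneContext.intergenic()
        bases, copies = select_top_change(res, mean_n)
        score = priority_score(bases, res.repeat.ref_length, ctx, res.repeat.unit)
        records.append(PriorityRecord(res.repeat, ctx, copies, bases, score, result=res))
    return rank_records(records)


# --------------------------------------------------------------------------
# multi-dataset joining


def cubic_mean(xs: Sequence[float]) -> float:
    """Sign-preserving cube root of the mean of cubes."""
    if not xs:
        raise ValueError("cubic_mean of empty sequence")
    m = sum(x ** 3 for x in xs) / len(xs)
    return math.copysign(abs(m) ** (1.0 / 3.0), m)


def joint_priority(case_scores: Sequence[float], control_scores: Sequence[float]) -> tuple[float, float, float]:
    """Return (d, h, joint) where joint = max(d - max(h, 0), 0).

    d and h are cubic means of case and control scores; when d is negative
    (a contraction of interest) both are negated first.  Empty controls
    contribute h = 0.
    """
    d = cubic_mean(case_scores)
    h = cubic_mean(control_scores) if control_scores else 0.0
    if d < 0:
        d, h = -d, -h
    return d, h, max(d - max(h, 0.0), 0.0)


def _repeat_key(repeat: RepeatAnnotation) -> tuple[str, int, int, str]:
    return repeat.chrom, repeat.start, repeat.end, repeat.unit


def join_datasets(case_datasets: Sequence[Sequence[RepeatResult]],
                  control_datasets: Sequence[Sequence[RepeatResult]]) -> list[JoinRecord]:
    """Joint case/control ranking across datasets.

    Each dataset is scored independently (its own mean-prediction gate and
    contexts); a repeat missing from a dataset contributes score 0 for that
    dataset.  Records are ranked by descending joint score.
    """
    case_scored = [
        {_repeat_key(rec.repeat): rec for rec in score_results(ds)} for ds in case_datasets
    ]
    control_scored = [
        {_repeat_key(rec.repeat): rec for rec in score_results(ds)} for ds in control_datasets
    ]
    keys: dict[tuple, PriorityRecord] = {}
    for scored in case_scored:
        for key, rec in scored.items():
            keys.setdefault(key, rec)
    records = []
    for key, anchor in keys.items():
        case_scores = [scored[key].score if key in scored else 0.0 for scored in case_scored]
        control_scores = [scored[key].score if key in scored else 0.0 for scored in control_scored]
        d, h, joint = joint_priority(case_scores, control_scores)
        records.append(JoinRecord(anchor.repeat, anchor.context, d, h, joint))
    records.sort(key=lambda r: (-r.jointScore, -abs(r.d), r.repeat.chrom, r.repeat.start))
    for i, rec in enumerate(records, 1):
        rec.rank = i
    return records
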