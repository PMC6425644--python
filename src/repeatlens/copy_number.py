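"""Per-read tandem-repeat copy-number-change prediction from split alignments.

For each read and annotated repeat the pipeline is: discard ambiguous
(high-mismap) and mostly-soft-masked alignments, join colinear alignment
parts, find parts overlapping the repeat, then predict an integer copy-number
change either from the internal gaps of a single spanning alignment or from
the unaligned span between two flanking alignments.  Expansions are positive.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .annotations import RepeatAnnotation
from .maf_io import AlignmentPart, GapRun, ScoringParams, alignment_gaps, gentle_masked_max_segment

__all__ = [
    "PredictionConfig",
    "ReadPrediction",
    "RepeatResult",
    "PREDICTED",
    "GAVE_UP",
    "NO_COVERAGE",
    "far_near",
    "filter_alignments",
    "join_colinear",
    "round_to_unit",
    "net_deletion",
    "predict_single",
    "predict_multi",
    "predict_read",
    "predict_repeat",
    "predict_all",
]

PREDICTED = "predicted"
GAVE_UP = "gave_up"
NO_COVERAGE = "no_coverage"


@dataclass(frozen=True)
class PredictionConfig:
    mismap_max: float = 1e-6
    join_gap_max: int = 1_000_000
    far_floor: int = 100
    near_floor: int = 60
    min_unit: int = 2
    scoring: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        if self.near_floor > self.far_floor:
            raise ValueError("near_floor must be <= far_floor")


@dataclass(frozen=True)
class ReadPrediction:
    readName: str
    strand: str
    status: str
    copyChange: int = 0


@dataclass
class RepeatResult:
    repeat: RepeatAnnotation
    forwardChanges: list[int] = field(default_factory=list)
    reverseChanges: list[int] = field(default_factory=list)
    context: object = None  # GeneContext, attached downstream

    @property
    def changes(self) -> list[int]:
        return self.forwardChanges + self.reverseChanges

    @property
    def n_predictions(self) -> int:
        return len(self.forwardChanges) + len(self.reverseChanges)


# --------------------------------------------------------------------------
# small arithmetic primitives


def far_near(u: int, ref_edge_distances: tuple[int, int],
             far_floor: int = 100, near_floor: int = 60) -> tuple[int, int, int]:
    """Return (f_left, f_right, n) for a repeat with unit length ``u``.

    f = max(far_floor, u), truncated per side at the reference-sequence edge;
    n = max(near_floor, u).
    """
    f = max(far_floor, u)
    n = max(near_floor, u)
    left_edge, right_edge = ref_edge_distances
    return min(f, left_edge), min(f, right_edge), n


def round_to_unit(D: int, u: int) -> int:
    """Nearest multiple of ``u`` to ``D``; exact midpoints round toward zero."""
    sign = -1 if D < 0 else 1
    q, rem = divmod(abs(D), u)
    if rem > u - rem:
        q += 1
    return sign * q * u


def net_deletion(d: int, i: int, r: int) -> int:
    """Net deletion of a gap: deleted minus inserted bases, capped at the
    unaligned reference bases falling inside the repeat."""
    return min(d - i, r)


# --------------------------------------------------------------------------
# filtering and joining


def filter_alignments(parts: Sequence[AlignmentPart], config: PredictionConfig) -> list[AlignmentPart]:
    """Drop ambiguous and mostly-soft-masked parts, preserving read order."""
    out = []
    for p in parts:
        if p.mismap > config.mismap_max:
            continue
        if gentle_masked_max_segment(p, config.scoring) < config.scoring.threshold:
            continue
        out.append(p)
    return out


def _mergeable(p: AlignmentPart, q: AlignmentPart, gap_max: int) -> bool:
    if p.refName != q.refName or p.readStrand != q.readStrand:
        return False
    if q.readStart < p.readEnd:
        return False
    if p.readStrand == "+":
        return p.refEnd <= q.refStart <= p.refEnd + gap_max
    return q.refEnd <= p.refStart <= q.refEnd + gap_max


def _merge(p: AlignmentPart, q: AlignmentPart) -> AlignmentPart:
    """Merge two colinear parts; the bridge becomes an ordinary gap run."""
    i_gap = q.readStart - p.readEnd
    if p.readStrand == "+":
        d_gap = q.refStart - p.refEnd
        first, second = p, q
    else:
        d_gap = p.refStart - q.refEnd
        first, second = q, p  # reference-ascending order
    bridge_ref = "N" * d_gap + "-" * i_gap
    bridge_read = "-" * d_gap + "N" * i_gap
    return AlignmentPart(
        readName=p.readName,
        readStrand=p.readStrand,
        refName=p.refName,
        refStart=first.refStart,
        refEnd=second.refEnd,
        refSrcSize=p.refSrcSize,
        readStart=p.readStart,
        readEnd=q.readEnd,
        readSrcSize=p.readSrcSize,
        refText=first.refText + bridge_ref + second.refText,
        readText=first.readText + bridge_read + second.readText,
        mismap=max(p.mismap, q.mismap),
        score=(p.score + q.score) if p.score is not None and q.score is not None else None,
        order=p.order,
    )


def join_colinear(parts: Sequence[AlignmentPart], config: PredictionConfig) -> list[AlignmentPart]:
    """Left-to-right transitive merge of consecutive colinear parts."""
    out: list[AlignmentPart] = []
    for q in parts:
        if out and _mergeable(out[-1], q, config.join_gap_max):
            out[-1] = _merge(out[-1], q)
        else:
            out.append(q)
    for i, p in enumerate(out):
        p.order = i
    return out


# --------------------------------------------------------------------------
# gap geometry relative to the repeat

# Distance conventions (self-consistent; used identically by gap rules and
# their test oracle): an unaligned reference BASE at index p has distance
# rs-p-1 to a repeat starting at rs (adjacent base: 0) and p-re to a repeat
# ending at re.  A pure-insertion POINT at coordinate p has distance rs-p /
# p-re; a point is "inside" the repeat when rs <= p < re.


def _gap_overlaps(gap: GapRun, rs: int, re_: int) -> bool:
    if gap.d == 0:
        return rs <= gap.refLo < re_
    return gap.refLo < re_ and gap.refHi > rs


def _gap_farness(gap: GapRun, rs: int, re_: int, f_left: int, f_right: int) -> tuple[bool, bool]:
    """(any position >= f away, all positions >= f away), side-aware."""
    if gap.d == 0:
        p = gap.refLo
        if p < rs:
            far = rs - p >= f_left
        elif p > re_:
            far = p - re_ >= f_right
        else:
            far = False
        return far, far
    lo, hi = gap.refLo, gap.refHi
    any_far = False
    if lo < rs and rs - lo - 1 >= f_left:
        any_far = True
    if hi > re_ and hi - 1 - re_ >= f_right:
        any_far = True
    if hi <= rs:
        all_far = rs - hi >= f_left
    elif lo >= re_:
        all_far = lo - re_ >= f_right
    else:
        all_far = False
    return any_far, all_far


def _gap_wholly_beyond(gap: GapRun, rs: int, re_: int, n: int) -> bool:
    if gap.d == 0:
        p = gap.refLo
        return (p < rs and rs - p > n) or (p > re_ and p - re_ > n)
    if gap.refHi <= rs:
        return rs - gap.refHi > n
    if gap.refLo >= re_:
        return gap.refLo - re_ > n
    return False


def _gap_in_repeat(gap: GapRun, rs: int, re_: int) -> int:
    """r: unaligned reference bases of the gap inside the repeat."""
    return max(0, min(gap.refHi, re_) - max(gap.refLo, rs))


# --------------------------------------------------------------------------
# prediction


def predict_single(part: AlignmentPart, repeat: RepeatAnnotation,
                   f_left: int, f_right: int, n: int, u: int | None = None) -> ReadPrediction:
    """Predict from one alignment spanning the repeat.

    The alignment must extend at least f beyond both repeat edges; each gap
    run is then tested against the four ignore/give-up rules in order, and
    surviving gaps contribute a rounded per-gap copy change.
    """
    u = repeat.u if u is None else u
    rs, re_ = repeat.start, repeat.end
    strand = part.readStrand
    if not (part.refStart <= rs - f_left and part.refEnd >= re_ + f_right):
        return ReadPrediction(part.readName, strand, GAVE_UP)
    total = 0
    for gap in alignment_gaps(part):
        if not _gap_overlaps(gap, rs, re_) and 2 * gap.i <= u:
            continue
        any_far, all_far = _gap_farness(gap, rs, re_, f_left, f_right)
        if all_far:
            continue
        if any_far:
            return ReadPrediction(part.readName, strand, GAVE_UP)
        if _gap_wholly_beyond(gap, rs, re_, n):
            continue
        r = _gap_in_repeat(gap, rs, re_)
        D = net_deletion(gap.d, gap.i, r)
        total += -(round_to_unit(D, u) // u)
    return ReadPrediction(part.readName, strand, PREDICTED, total)


def predict_multi(parts: Sequence[AlignmentPart], overlapping: Sequence[int],
                  repeat: RepeatAnnotation, f_left: int, f_right: int,
                  u: int | None = None) -> ReadPrediction:
    """Predict from several alignments overlapping the repeat.

    The overlapping parts must be consecutive along the read and on one
    strand; the reference-leftmost of them must provide the left flank
    (extending >= f left of the repeat and of every other part) and likewise
    on the right.  The copy change is the rounded net unaligned span between
    the flanking alignments.
    """
    u = repeat.u if u is None else u
    name = parts[overlapping[0]].readName
    rs, re_ = repeat.start, repeat.end
    ov = [parts[i] for i in overlapping]
    strand = ov[0].readStrand
    if any(p.readStrand != strand for p in ov):
        return ReadPrediction(name, strand, GAVE_UP)
    if any(overlapping[k + 1] - overlapping[k] != 1 for k in range(len(overlapping) - 1)):
        return ReadPrediction(name, strand, GAVE_UP)
    # reference-left alignment is first in read order on '+', last on '-'
    left = ov[0] if strand == "+" else ov[-1]
    right = ov[-1] if strand == "+" else ov[0]
    others = [p for p in ov if p is not left]
    if not (left.refStart <= rs - f_left):
        return ReadPrediction(name, strand, GAVE_UP)
    if any(other.refStart - left.refStart < f_left for other in others):
        return ReadPrediction(name, strand, GAVE_UP)
    if any(other.refStart <= rs - f_left for other in others):
        return ReadPrediction(name, strand, GAVE_UP)
    others_r = [p for p in ov if p is not right]
    if not (right.refEnd >= re_ + f_right):
        return ReadPrediction(name, strand, GAVE_UP)
    if any(right.refEnd - other.refEnd < f_right for other in others_r):
        return ReadPrediction(name, strand, GAVE_UP)
    if any(other.refEnd >= re_ + f_right for other in others_r):
        return ReadPrediction(name, strand, GAVE_UP)
    ref_gap = right.refStart - left.refEnd
    if strand == "+":
        read_gap = right.readStart - left.readEnd
    else:
        read_gap = left.readStart - right.readEnd
    insertion = read_gap - ref_gap
    change = round_to_unit(insertion, u) // u
    return ReadPrediction(name, strand, PREDICTED, change)


def prepare_read(parts: Sequence[AlignmentPart], config: PredictionConfig) -> list[AlignmentPart]:
    """Filter then join one read's alignment parts (read order preserved)."""
    return join_colinear(filter_alignments(parts, config), config)


def predict_read(prepared: Sequence[AlignmentPart], repeat: RepeatAnnotation,
                 config: PredictionConfig) -> ReadPrediction:
    """Predict one read's copy change at one repeat (parts already prepared)."""
    overlapping = [i for i, p in enumerate(prepared)
                   if p.refName == repeat.chrom and p.overlaps_ref(repeat.start, repeat.end)]
    if not overlapping:
        name = prepared[0].readName if prepared else ""
        return ReadPrediction(name, "+", NO_COVERAGE)
    part = prepared[overlapping[0]]
    src = part.refSrcSize
    f_left, f_right, n = far_near(
        repeat.u, (repeat.start, src - repeat.end),
        config.far_floor, config.near_floor,
    )
    if len(overlapping) == 1:
        return predict_single(part, repeat, f_left, f_right, n)
    return predict_multi(prepared, overlapping, repeat, f_left, f_right)


def predict_repeat(read_groups: Mapping[str, Sequence[AlignmentPart]],
                   repeat: RepeatAnnotation, config: PredictionConfig) -> RepeatResult:
    """Aggregate per-read predictions for one repeat, split by strand."""
    result = RepeatResult(repeat)
    for parts in read_groups.values():
        prepared = prepare_read(parts, config)
        pred = predict_read(prepared, repeat, config)
        _tally(result, pred)
    return result


def _tally(result: RepeatResult, pred: ReadPrediction) -> None:
    if pred.status != PREDICTED:
        return
    if pred.strand == "+":
        result.forwardChanges.append(pred.copyChange)
    else:
        result.reverseChanges.append(pred.copyChange)


class _PartIndex:
    """Per-chromosome interval lookup over prepared alignment parts."""

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        self._starts: dict[str, list[int]] = {}
        self._max_end: dict[str, list[int]] = {}

    def add(self, part: AlignmentPart) -> None:
        self._by_chrom.setdefault(part.refName, []).append(
            (part.refStart, part.refEnd, part.readName))

    def finalize(self) -> None:
        for chrom, entries in self._by_chrom.items():
            entries.sort()
            self._starts[chrom] = [e[0] for e in entries]
            running = 0
            max_end = []
            for e in entries:
                running = max(running, e[1])
                max_end.append(running)
            self._max_end[chrom] = max_end

    def reads_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        entries = self._by_chrom.get(chrom)
        if not entries:
            return []
        starts = self._starts[chrom]
        max_end = self._max_end[chrom]
        hi = bisect.bisect_left(starts, end)
        names: list[str] = []
        for k in range(hi - 1, -1, -1):
            if max_end[k] <= start:
                break
            if entries[k][1] > start:
                names.append(entries[k][2])
        # de-duplicate, stable
        seen: set[str] = set()
        out = []
        for nm in names:
            if nm not in seen:
                seen.add(nm)
                out.append(nm)
        return out


def predict_all(read_groups: Mapping[str, Sequence[AlignmentPart]],
                repeats: Sequence[RepeatAnnotation],
                config: PredictionConfig) -> list[RepeatResult]:
    """Run prediction for many repeats, preparing each read only once."""
    prepared: dict[str, list[AlignmentPart]] = {
        name: prepare_read(parts, config) for name, parts in read_groups.items()
    }
    index = _PartIndex()
    for parts in prepared.values():
        for p in parts:
            index.add(p)
    index.finalize()
    results = []
    for repeat in repeats:
        if repeat.u < config.min_unit:
            continue
        result = RepeatResult(repeat)
        for name in index.reads_overlapping(repeat.chrom, repeat.start, repeat.end):
            pred = predict_read(prepared[name], repeat, config)
            _tally(result, pred)
        results.append(result)
    return results
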