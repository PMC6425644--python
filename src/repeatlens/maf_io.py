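"""MAF alignment I/O and gentle-masking alignment rescoring.

The input dialect is the one emitted by split-read aligners: two-row blocks
(reference row first, read row second), ``a`` lines carrying ``score=`` and a
per-alignment ``mismap=`` probability, and lowercase letters marking
soft-masked simple sequence.  Case is preserved: it matters for filtering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence, TextIO

__all__ = [
    "AlignmentPart",
    "GapRun",
    "ScoringParams",
    "read_maf",
    "write_maf",
    "alignment_gaps",
    "gentle_masked_max_segment",
    "scoring_params_from_header",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GapRun:
    """One maximal run of gap columns in an alignment.

    ``d`` unaligned reference bases and ``i`` unaligned read bases, occupying
    reference interval [refLo, refHi); refLo == refHi for a pure insertion.
    """

    d: int
    i: int
    refLo: int
    refHi: int

    def __post_init__(self) -> None:
        if self.d < 0 or self.i < 0 or self.d + self.i < 1:
            raise ValueError(f"degenerate gap run d={self.d} i={self.i}")
        if self.refHi - self.refLo != self.d:
            raise ValueError("gap run reference interval inconsistent with d")


@dataclass
class AlignmentPart:
    """One aligned segment of one read, column-accurate.

    Coordinates are 0-based half-open.  ``readStart``/``readEnd`` are in
    forward-read orientation regardless of strand; ``refText``/``readText``
    are the gapped rows in reference-ascending orientation, case preserved.
    """

    readName: str
    readStrand: str
    refName: str
    refStart: int
    refEnd: int
    refSrcSize: int
    readStart: int
    readEnd: int
    readSrcSize: int
    refText: str
    readText: str
    mismap: float = 0.0
    score: float | None = None
    order: int = 0

    def validate(self) -> None:
        if len(self.refText) != len(self.readText):
            raise ValueError("alignment rows have unequal length")
        nref = len(self.refText) - self.refText.count("-")
        nread = len(self.readText) - self.readText.count("-")
        if nref != self.refEnd - self.refStart:
            raise ValueError("reference row length mismatches coordinates")
        if nread != self.readEnd - self.readStart:
            raise ValueError("read row length mismatches coordinates")
        for a, b in zip(self.refText, self.readText):
            if a == "-" and b == "-":
                raise ValueError("column with gaps in both rows")

    def overlaps_ref(self, start: int, end: int) -> bool:
        return self.refStart < end and start < self.refEnd


@dataclass(frozen=True)
class ScoringParams:
    """Substitution/gap scores and the aligner's score threshold.

    Defaults are order-of-magnitude typical of trained long-read scoring;
    real runs can scrape the values from MAF header comments.
    """

    match: int = 6
    mismatch: int = -18
    gap_open: int = 21
    gap_extend: int = 9
    threshold: int = 180
    matrix: dict[tuple[str, str], int] | None = None

    def substitution(self, a: str, b: str) -> int:
        au, bu = a.upper(), b.upper()
        if self.matrix is not None:
            try:
                return self.matrix[(au, bu)]
            except KeyError:
                pass
        if au in "ACGT" and bu in "ACGT":
            return self.match if au == bu else self.mismatch
        logger.warning("unknown letter pair %r/%r scored as minimum", a, b)
        return min(self.mismatch, min(self.matrix.values()) if self.matrix else self.mismatch)


# --------------------------------------------------------------------------
# reading / writing


_A_FIELD_RE = re.compile(r"(\w+)=([^\s]+)")


def _parse_a_line(line: str) -> dict[str, str]:
    return dict(_A_FIELD_RE.findall(line))


def read_maf(stream: Iterable[str]) -> dict[str, list[AlignmentPart]]:
    """Parse MAF into alignments grouped by read, ordered 5'->3' along the read.

    Each block must hold exactly two ``s`` rows: reference first, read
    second.  Read-row start/size are strand-local per the MAF standard and
    are converted to forward-read coordinates.  ``mismap`` defaults to 0 when
    absent.  Header ``#`` lines are collected on the returned dict under the
    attribute-free key handled by :func:`scoring_params_from_header` callers.
    """
    groups: dict[str, list[AlignmentPart]] = {}
    block_idx = 0
    a_fields: dict[str, str] | None = None
    s_lines: list[list[str]] = []

    def flush() -> None:
        nonlocal a_fields, s_lines, block_idx
        if a_fields is None:
            return
        block_idx += 1
        if len(s_lines) != 2:
            raise ValueError(f"MAF block {block_idx}: expected 2 's' lines, got {len(s_lines)}")
        ref, read = s_lines
        ref_name, ref_start, ref_size, ref_strand, ref_src, ref_text = ref
        rd_name, rd_start, rd_size, rd_strand, rd_src, rd_text = read
        if len(ref_text) != len(rd_text):
            raise ValueError(f"MAF block {block_idx}: rows have unequal length")
        if ref_strand != "+":
            raise ValueError(f"MAF block {block_idx}: reference row must be on '+' strand")
        rs, rsz = int(ref_start), int(ref_size)
        qs, qsz, qsrc = int(rd_start), int(rd_size), int(rd_src)
        if rd_strand == "-":
            # strand-local -> forward-read coordinates
            q_lo, q_hi = qsrc - (qs + qsz), qsrc - qs
        else:
            q_lo, q_hi = qs, qs + qsz
        part = AlignmentPart(
            readName=rd_name,
            readStrand=rd_strand,
            refName=ref_name,
            refStart=rs,
            refEnd=rs + rsz,
            refSrcSize=int(ref_src),
            readStart=q_lo,
            readEnd=q_hi,
            readSrcSize=qsrc,
            refText=ref_text,
            readText=rd_text,
            mismap=float(a_fields.get("mismap", 0.0)),
            score=float(a_fields["score"]) if "score" in a_fields else None,
        )
        part.validate()
        groups.setdefault(rd_name, []).append(part)
        a_fields, s_lines = None, []

    for line in stream:
        if line.startswith("a"):
            flush()
            a_fields = _parse_a_line(line)
            s_lines = []
        elif line.startswith("s"):
            cols = line.split()
            if len(cols) != 7:
                raise ValueError(f"malformed 's' line: {line!r}")
            s_lines.append(cols[1:])
        # 'p'/'q'/comment/blank lines are ignored
    flush()

    for parts in groups.values():
        parts.sort(key=lambda p: p.readStart)
        for i, p in enumerate(parts):
            p.order = i
    return groups


def write_maf(groups: dict[str, list[AlignmentPart]] | Iterable[AlignmentPart],
              stream: TextIO, header: str | None = None) -> None:
    """Write AlignmentParts as two-row MAF blocks (inverse of :func:`read_maf`)."""
    if isinstance(groups, dict):
        parts: list[AlignmentPart] = [p for ps in groups.values() for p in ps]
    else:
        parts = list(groups)
    if header:
        for line in header.splitlines():
            stream.write(line if line.startswith("#") else "# " + line)
            stream.write("\n")
    for p in parts:
        fields = []
        if p.score is not None:
            fields.append(f"score={p.score:g}")
        fields.append(f"mismap={p.mismap:g}")
        stream.write("a " + " ".join(fields) + "\n")
        stream.write(
            f"s {p.refName} {p.refStart} {p.refEnd - p.refStart} + "
            f"{p.refSrcSize} {p.refText}\n"
        )
        if p.readStrand == "-":
            q_start = p.readSrcSize - p.readEnd
        else:
            q_start = p.readStart
        stream.write(
            f"s {p.readName} {q_start} {p.readEnd - p.readStart} {p.readStrand} "
            f"{p.readSrcSize} {p.readText}\n"
        )
        stream.write("\n")


def scoring_params_from_header(lines: Iterable[str]) -> ScoringParams | None:
    """Scrape scoring parameters from MAF ``#`` comment lines, if present.

    Recognizes aligner-style ``a=<gap open> b=<gap extend> e=<threshold>``
    tokens and a commented square substitution matrix with an ACGT header
    row.  Returns None when nothing usable is found.
    """
    gap_open = gap_extend = threshold = None
    matrix: dict[tuple[str, str], int] | None = None
    alphabet: list[str] | None = None
    for raw in lines:
        if not raw.startswith("#"):
            continue
        body = raw[1:].strip()
        for key, val in _A_FIELD_RE.findall(body):
            if key == "a":
                gap_open = int(val)
            elif key == "b":
                gap_extend = int(val)
            elif key == "e":
                threshold = int(val)
        toks = body.split()
        if toks and all(t in "ACGT" and len(t) == 1 for t in toks) and len(toks) >= 4:
            alphabet = toks
            matrix = {}
        elif alphabet and toks and toks[0] in alphabet and len(toks) == len(alphabet) + 1:
            row = toks[0]
            assert matrix is not None
            for col, val in zip(alphabet, toks[1:]):
                matrix[(row, col)] = int(val)
    if gap_open is None and matrix is None:
        return None
    defaults = ScoringParams()
    match = defaults.match
    mismatch = defaults.mismatch
    if matrix:
        match = max(matrix.values())
        mismatch = min(matrix.values())
    return ScoringParams(
        match=match,
        mismatch=mismatch,
        gap_open=gap_open if gap_open is not None else defaults.gap_open,
        gap_extend=gap_extend if gap_extend is not None else defaults.gap_extend,
        threshold=threshold if threshold is not None else defaults.threshold,
        matrix=matrix or None,
    )


# --------------------------------------------------------------------------
# column arithmetic


def alignment_gaps(part: AlignmentPart) -> list[GapRun]:
    """Extract maximal gap runs; adjacent deletion and insertion columns merge."""
    gaps: list[GapRun] = []
    ref_pos = part.refStart
    run_d = run_i = 0
    run_lo = part.refStart
    in_run = False
    for a, b in zip(part.refText, part.readText):
        if a == "-" or b == "-":
            if not in_run:
                in_run = True
                run_d = run_i = 0
                run_lo = ref_pos
            if b == "-":
                run_d += 1
                ref_pos += 1
            else:
                run_i += 1
        else:
            if in_run:
                gaps.append(GapRun(run_d, run_i, run_lo, run_lo + run_d))
                in_run = False
            ref_pos += 1
    if in_run:
        # MAF alignments start/end on aligned columns, but be safe
        gaps.append(GapRun(run_d, run_i, run_lo, run_lo + run_d))
    return gaps


def _column_scores(part: AlignmentPart, params: ScoringParams) -> list[int]:
    """Per-column gentle-masked scores: masked columns contribute <= 0."""
    scores: list[int] = []
    in_gap = False
    for a, b in zip(part.refText, part.readText):
        if a == "-" or b == "-":
            s = -(params.gap_extend if in_gap else params.gap_open + params.gap_extend)
            in_gap = True
        else:
            s = params.substitution(a, b)
            in_gap = False
        if a.islower() or b.islower():
            s = min(s, 0)
        scores.append(s)
    return scores


def gentle_masked_max_segment(part: AlignmentPart, params: ScoringParams) -> int:
    """Maximum contiguous-segment score under gentle masking (>= 0).

    Columns where either letter is lowercase are capped at zero, then the
    best-scoring contiguous column segment is found (max-subarray); an
    all-masked alignment scores 0.
    """
    best = cur = 0
    for s in _column_scores(part, params):
        cur = max(0, cur + s)
        best = max(best, cur)
    return best
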