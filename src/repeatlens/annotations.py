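"""Tandem-repeat and gene annotation parsing, plus genomic-context classification.

Supported repeat annotation inputs:

* UCSC RepeatMasker ``rmsk.txt`` tables — rows whose ``repName`` looks like
  ``(CAG)n`` are tandem repeats; everything else (named transposable
  elements and such) is skipped.
* BED-like custom files: ``chrom  start  end  unit  [name ...]``.

Gene models come from UCSC ``refFlat.txt``.  A repeat's genomic context
(coding / UTR / promoter / ncRNA exon / intron / intergenic) carries the
multiplier used by the prioritization score.

All coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

__all__ = [
    "RepeatAnnotation",
    "GeneModel",
    "GeneContext",
    "GeneIndex",
    "DEFAULT_MULTIPLIERS",
    "DEFAULT_PROMOTER_BP",
    "read_rmsk",
    "read_bed_repeats",
    "read_refflat",
    "classify_region",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Region-category multipliers used by the priority score.  Intergenic is a
#: neutral baseline (no value is prescribed for it).
DEFAULT_MULTIPLIERS: dict[str, float] = {
    "coding": 50.0,
    "UTR": 20.0,
    "promoter": 15.0,
    "ncRNA_exon": 15.0,
    "intron": 5.0,
    "intergenic": 1.0,
}

#: Strand-aware promoter window upstream of the transcription start.
DEFAULT_PROMOTER_BP = 1000

# Specificity order used to break multiplier ties (ncRNA exon beats promoter:
# exonic evidence is more specific than a window heuristic).
_CATEGORY_SPECIFICITY = {
    "coding": 5,
    "UTR": 4,
    "ncRNA_exon": 3,
    "promoter": 2,
    "intron": 1,
    "intergenic": 0,
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatAnnotation:
    """One annotated tandem repeat on the reference genome."""

    chrom: str
    start: int
    end: int
    unit: str
    name: str = ""
    source: str = "bed"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid repeat interval {self.chrom}:{self.start}-{self.end}"
            )
        if not self.unit or not set(self.unit) <= set("ACGTN"):
            raise ValueError(f"invalid repeat unit {self.unit!r}")

    @property
    def u(self) -> int:
        """Repeating-unit length in bases."""
        return len(self.unit)

    @property
    def ref_length(self) -> int:
        """Annotated repeat length in bases (not necessarily a multiple of u)."""
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """One transcript from a refFlat-style gene table."""

    geneName: str
    name: str
    chrom: str
    strand: str
    txStart: int
    txEnd: int
    cdsStart: int
    cdsEnd: int
    exonStarts: tuple[int, ...]
    exonEnds: tuple[int, ...]

    @property
    def coding(self) -> bool:
        return self.cdsStart < self.cdsEnd

    def promoter_window(self, promoter_bp: int) -> tuple[int, int]:
        """Strand-aware window of ``promoter_bp`` bases upstream of the TSS."""
        if self.strand == "-":
            return self.txEnd, self.txEnd + promoter_bp
        return max(0, self.txStart - promoter_bp), self.txStart


@dataclass(frozen=True)
class GeneContext:
    """Genomic-context verdict for one repeat, with its score multiplier."""

    category: str
    geneName: str
    multiplier: float

    @classmethod
    def intergenic(cls, multipliers: dict[str, float] | None = None) -> "GeneContext":
        mult = (multipliers or DEFAULT_MULTIPLIERS)["intergenic"]
        return cls("intergenic", "", mult)


# --------------------------------------------------------------------------
# parsing


_RMSK_UNIT_RE = re.compile(r"^\(([ACGTNacgtn]+)\)n$")


def _fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_rmsk(stream: Iterable[str], min_unit: int = 2) -> Iterator[RepeatAnnotation]:
    """Yield tandem repeats from a UCSC rmsk.txt table.

    Only rows whose ``repName`` matches ``(<unit>)n`` are tandem repeats with
    a known unit; other rows are skipped.  Units annotated on the "-" strand
    are reverse-complemented so every unit is reference-forward.  Units
    shorter than ``min_unit`` are skipped (``min_unit=1`` keeps homopolymers).
    """
    skipped = 0
    for lineno, line in enumerate(stream, 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = _fields(line)
        # UCSC rmsk layout: bin, swScore, milliDiv, milliDel, milliIns,
        # genoName, genoStart, genoEnd, genoLeft, strand, repName, ...
        if len(cols) < 11:
            raise ValueError(f"rmsk line {lineno}: expected >=11 columns, got {len(cols)}")
        try:
            chrom = cols[5]
            start = int(cols[6])
            end = int(cols[7])
            strand = cols[9]
            rep_name = cols[10]
        except ValueError as exc:
            raise ValueError(f"rmsk line {lineno}: bad coordinates: {exc}") from exc
        m = _RMSK_UNIT_RE.match(rep_name)
        if m is None:
            skipped += 1
            continue
        unit = m.group(1).upper()
        if strand == "-":
            unit = reverse_complement(unit)
        if len(unit) < min_unit:
            skipped += 1
            continue
        yield RepeatAnnotation(chrom, start, end, unit, name=rep_name, source="rmsk")


def read_bed_repeats(stream: Iterable[str]) -> Iterator[RepeatAnnotation]:
    """Yield repeats from a BED-like file: chrom, start, end, unit[, name...]."""
    for lineno, line in enumerate(stream, 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = _fields(line)
        if len(cols) < 4:
            raise ValueError(f"repeat file line {lineno}: expected >=4 columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise ValueError(f"repeat file line {lineno}: bad coordinates") from exc
        if end <= start:
            raise ValueError(f"repeat file line {lineno}: end <= start")
        unit = cols[3].upper()
        if not unit:
            raise ValueError(f"repeat file line {lineno}: empty unit")
        name = cols[4] if len(cols) > 4 else ""
        yield RepeatAnnotation(cols[0], start, end, unit, name=name, source="bed")


def _int_list(text: str) -> tuple[int, ...]:
    # UCSC exon lists are comma-terminated: "100,200,300,"
    return tuple(int(x) for x in text.strip().rstrip(",").split(",") if x)


def read_refflat(stream: Iterable[str]) -> Iterator[GeneModel]:
    """Yield GeneModels from a UCSC refFlat.txt table."""
    for lineno, line in enumerate(stream, 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = _fields(line)
        if len(cols) < 11:
            raise ValueError(f"refFlat line {lineno}: expected 11 columns, got {len(cols)}")
        exon_count = int(cols[8])
        exon_starts = _int_list(cols[9])
        exon_ends = _int_list(cols[10])
        if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
            raise ValueError(
                f"refFlat line {lineno}: exonCount={exon_count} but "
                f"{len(exon_starts)}/{len(exon_ends)} exon coordinates"
            )
        yield GeneModel(
            geneName=cols[0],
            name=cols[1],
            chrom=cols[2],
            strand=cols[3],
            txStart=int(cols[4]),
            txEnd=int(cols[5]),
            cdsStart=int(cols[6]),
            cdsEnd=int(cols[7]),
            exonStarts=exon_starts,
            exonEnds=exon_ends,
        )


# --------------------------------------------------------------------------
# classification


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


class GeneIndex:
    """Per-chromosome transcript index supporting interval queries.

    Queries are answered with a sorted-start / running-max-end sweep so that
    lookups on large tables stay cheap.
    """

    def __init__(self, genes: Iterable[GeneModel], promoter_bp: int = DEFAULT_PROMOTER_BP):
        self.promoter_bp = promoter_bp
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {}
        self._genes: dict[str, list[GeneModel]] = {}
        self._max_end: dict[str, list[int]] = {}
        for chrom, gl in by_chrom.items():
            # effective span includes the promoter window
            def span(g: GeneModel) -> tuple[int, int]:
                pw = g.promoter_window(promoter_bp)
                return min(g.txStart, pw[0]), max(g.txEnd, pw[1])

            gl.sort(key=lambda g: span(g)[0])
            starts = [span(g)[0] for g in gl]
            max_end: list[int] = []
            running = 0
            for g in gl:
                running = max(running, span(g)[1])
                max_end.append(running)
            self._starts[chrom] = starts
            self._genes[chrom] = gl
            self._max_end[chrom] = max_end

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Transcripts whose tx-or-promoter span intersects [start, end)."""
        if chrom not in self._genes:
            return []
        starts = self._starts[chrom]
        genes = self._genes[chrom]
        max_end = self._max_end[chrom]
        hi = bisect.bisect_left(starts, end)
        out = []
        for i in range(hi - 1, -1, -1):
            if max_end[i] <= start:
                break
            g = genes[i]
            pw = g.promoter_window(self.promoter_bp)
            lo = min(g.txStart, pw[0])
            hi_ = max(g.txEnd, pw[1])
            if _overlaps(lo, hi_, start, end):
                out.append(g)
        out.reverse()
        return out


def _transcript_categories(
    repeat: RepeatAnnotation, gene: GeneModel, promoter_bp: int
) -> list[str]:
    """All context categories this one transcript supports for the repeat."""
    cats: list[str] = []
    rs, re_ = repeat.start, repeat.end
    in_exon = any(
        _overlaps(es, ee, rs, re_) for es, ee in zip(gene.exonStarts, gene.exonEnds)
    )
    if in_exon:
        if gene.coding:
            cds_exon = any(
                _overlaps(max(es, gene.cdsStart), min(ee, gene.cdsEnd), rs, re_)
                for es, ee in zip(gene.exonStarts, gene.exonEnds)
                if max(es, gene.cdsStart) < min(ee, gene.cdsEnd)
            )
            if cds_exon:
                cats.append("coding")
            utr_exon = any(
                _overlaps(es, min(ee, gene.cdsStart), rs, re_)
                or _overlaps(max(es, gene.cdsEnd), ee, rs, re_)
                for es, ee in zip(gene.exonStarts, gene.exonEnds)
            )
            if utr_exon:
                cats.append("UTR")
        else:
            cats.append("ncRNA_exon")
    pw = gene.promoter_window(promoter_bp)
    if _overlaps(pw[0], pw[1], rs, re_):
        cats.append("promoter")
    if not cats and _overlaps(gene.txStart, gene.txEnd, rs, re_):
        cats.append("intron")
    return cats


def classify_region(
    repeat: RepeatAnnotation,
    genes: GeneIndex,
    promoter_bp: int | None = None,
    multipliers: dict[str, float] | None = None,
) -> GeneContext:
    """Classify a repeat's genomic context, keeping the largest multiplier.

    Every transcript overlapping the repeat (or whose promoter window does)
    is evaluated; ties on multiplier are broken toward the more specific
    category (e.g., ncRNA exon beats promoter).
    """
    mult = multipliers or DEFAULT_MULTIPLIERS
    pbp = genes.promoter_bp if promoter_bp is None else promoter_bp
    best: GeneContext | None = None
    best_key: tuple[float, int] = (-1.0, -1)
    for gene in genes.overlapping(repeat.chrom, repeat.start, repeat.end):
        for cat in _transcript_categories(repeat, gene, pbp):
            key = (mult[cat], _CATEGORY_SPECIFICITY[cat])
            if key > best_key:
                best_key = key
                best = GeneContext(cat, gene.geneName, mult[cat])
    if best is None:
        return GeneContext.intergenic(mult)
    return best
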