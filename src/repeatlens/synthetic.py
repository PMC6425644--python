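"""Synthetic loci, reads and ground-truth alignments for pipeline testing.

Everything the genotyping pipeline consumes can be generated here without an
aligner: repeat loci with flanks, reads carrying planted copy-number changes
(optionally with uniform or strand-systematic errors), and MAF alignments
derived from the ground-truth edit script rather than from sequence search.
Generation is a pure function of (spec, seed).
"""

from __future__ import annotations

import io
import math
import random
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

from .annotations import RepeatAnnotation, reverse_complement
from .maf_io import AlignmentPart, write_maf

__all__ = [
    "LocusSpec",
    "Locus",
    "ReadSpec",
    "SimulatedRead",
    "UniformError",
    "StrandSystematicError",
    "make_locus",
    "make_read",
    "random_flank",
    "script_to_parts",
    "edit_script_to_maf",
    "make_chimeric_read",
    "make_background_genome",
    "reads_to_maf",
    "loci_to_bed",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class UniformError:
    """I.i.d. per-base substitutions and scattered single-base indels.

    Indels keep a minimum spacing from each other and (with ``flanks_only``)
    a buffer away from the repeat tract, so planted copy changes stay exactly
    recoverable.
    """

    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    flanks_only: bool = False
    buffer: int = 5
    min_indel_spacing: int = 2


@dataclass(frozen=True)
class StrandSystematicError:
    """Motif conversion on one strand: every repeat unit is rewritten.

    The converted tract no longer matches the reference repeat, so its
    ground-truth alignment leaves the whole tract unaligned (one big gap) —
    the mechanism behind strand-separated bimodal predictions.
    """

    source: str
    target: str
    strand: str = "-"


@dataclass(frozen=True)
class ReadSpec:
    name: str = "read"
    deltaCopies: int = 0
    strand: str = "+"
    error: UniformError | StrandSystematicError | None = None
    #: emit the expansion as an unaligned read span between two alignment
    #: parts that each reach into the repeat (the parts overlap on the
    #: reference, so they cannot be re-joined; exercises the multi-alignment
    #: prediction path).  Requires deltaCopies >= 1.
    split: bool = False
    split_overlap_units: int = 2


@dataclass(frozen=True)
class LocusSpec:
    leftFlank: str
    rightFlank: str
    unit: str
    refCopies: int
    chrom: str = "synth"
    offset: int = 0


@dataclass(frozen=True)
class Locus:
    spec: LocusSpec
    construct: str
    annotation: RepeatAnnotation

    @property
    def chrom(self) -> str:
        return self.spec.chrom

    @property
    def offset(self) -> int:
        return self.spec.offset

    @property
    def src_size(self) -> int:
        return self.spec.offset + len(self.construct)


@dataclass
class SimulatedRead:
    name: str
    strand: str
    seq: str            # as sequenced (reverse-complemented for '-' reads)
    fwd_seq: str        # reference-forward orientation of the same read
    ops: tuple[tuple, ...]  # edit script vs the locus construct, ref-ascending
    deltaCopies: int
    locus: Locus


def _contains_triple(flank: str, unit: str) -> bool:
    return unit * 3 in flank


def random_flank(length: int, unit: str, rng: random.Random) -> str:
    """Random DNA flank guaranteed not to contain the unit repeated 3 times."""
    while True:
        flank = "".join(rng.choice(_BASES) for _ in range(length))
        if not _contains_triple(flank, unit):
            return flank


def make_locus(spec: LocusSpec) -> Locus:
    """Build reference construct leftFlank + unit*refCopies + rightFlank."""
    if spec.refCopies < 1:
        raise ValueError("refCopies must be >= 1")
    unit = spec.unit.upper()
    if _contains_triple(spec.leftFlank, unit) or _contains_triple(spec.rightFlank, unit):
        raise ValueError("flank contains the repeat unit tripled; boundaries ambiguous")
    construct = spec.leftFlank + unit * spec.refCopies + spec.rightFlank
    start = spec.offset + len(spec.leftFlank)
    annotation = RepeatAnnotation(
        spec.chrom, start, start + len(unit) * spec.refCopies, unit, name="synthetic"
    )
    return Locus(replace(spec, unit=unit), construct, annotation)


def _push(ops: list, op: str, n: int) -> None:
    if n <= 0:
        return
    if ops and ops[-1][0] == op:
        ops[-1] = (op, ops[-1][1] + n)
    else:
        ops.append((op, n))


class _ScriptBuilder:
    """Accumulates read characters and a compressed edit script."""

    def __init__(self, rng: random.Random, error: UniformError | None,
                 tract_start: int, tract_end: int):
        self.rng = rng
        self.error = error
        self.tract = (tract_start, tract_end)
        self.ops: list = []
        self.read: list[str] = []
        self.ref_pos = 0
        self._last_indel = -(10 ** 9)
        self._col = 0

    def _indel_allowed(self, ref_pos: int) -> bool:
        err = self.error
        assert err is not None
        if self._col - self._last_indel < err.min_indel_spacing + 1:
            return False
        if err.flanks_only:
            lo, hi = self.tract
            if lo - err.buffer <= ref_pos < hi + err.buffer:
                return False
        return True

    def aligned(self, segment: str) -> None:
        err = self.error
        if err is None or (err.substitution_rate == 0 and err.indel_rate == 0):
            self.read.append(segment)
            _push(self.ops, "M", len(segment))
            self.ref_pos += len(segment)
            self._col += len(segment)
            return
        rng = self.rng
        for ch in segment:
            if rng.random() < err.indel_rate and self._indel_allowed(self.ref_pos):
                self._last_indel = self._col
                if rng.random() < 0.5:  # deletion: ref base unmatched in read
                    _push(self.ops, "D", 1)
                    self.ref_pos += 1
                    self._col += 1
                    continue
                _push(self.ops, "I", 1)  # insertion before this base
                self.read.append(rng.choice(_BASES))
                self._col += 1
            if rng.random() < err.substitution_rate:
                choices = [b for b in _BASES if b != ch.upper()]
                self.read.append(rng.choice(choices))
            else:
                self.read.append(ch)
            _push(self.ops, "M", 1)
            self.ref_pos += 1
            self._col += 1

    def insert(self, segment: str) -> None:
        self.read.append(segment)
        _push(self.ops, "I", len(segment))
        self._col += len(segment)

    def delete(self, n: int) -> None:
        _push(self.ops, "D", n)
        self.ref_pos += n
        self._col += n

    def split(self) -> None:
        self.ops.append(("split",))

    def back(self, n: int) -> None:
        """Rewind the reference cursor (only meaningful right after a split):
        the next block re-aligns reference bases already covered upstream."""
        self.ops.append(("B", n))
        self.ref_pos -= n


def make_read(locus: Locus, spec: ReadSpec, seed: int = 0) -> SimulatedRead:
    """Generate one read with a planted copy change and its edit script.

    The read carries unit x (refCopies + deltaCopies) between the flanks.
    The edit script maps the read (reference-forward orientation) onto the
    locus construct; '-' strand reads are reverse-complemented at the end.
    """
    lspec = locus.spec
    u = len(lspec.unit)
    copies = lspec.refCopies + spec.deltaCopies
    if copies < 0:
        raise ValueError("refCopies + deltaCopies must be >= 0")
    rng = random.Random(seed)
    tract_start = len(lspec.leftFlank)
    tract_end = tract_start + u * lspec.refCopies
    uniform = spec.error if isinstance(spec.error, UniformError) else None
    b = _ScriptBuilder(rng, uniform, tract_start, tract_end)

    systematic = (
        isinstance(spec.error, StrandSystematicError)
        and spec.error.strand == spec.strand
        and spec.error.source.upper() == lspec.unit
    )
    b.aligned(lspec.leftFlank)
    if spec.split:
        if spec.deltaCopies < 1:
            raise ValueError("split geometry needs an expansion (deltaCopies >= 1)")
        k = max(1, min(spec.split_overlap_units, spec.deltaCopies, lspec.refCopies))
        # left part spans the whole reference tract; the expansion is an
        # unaligned read span; the right part re-aligns the last k units
        b.aligned(lspec.unit * lspec.refCopies)
        b.split()
        b.insert(lspec.unit * (spec.deltaCopies - k))
        b.split()
        b.back(u * k)
        b.aligned(lspec.unit * k)
    elif systematic:
        # converted tract does not match the reference repeat: wholly unaligned
        b.delete(u * lspec.refCopies)
        b.insert(spec.error.target.upper() * copies)  # type: ignore[union-attr]
    elif spec.deltaCopies >= 0:
        # extra copies inserted just before the final reference unit
        b.aligned(lspec.unit * (lspec.refCopies - 1))
        b.insert(lspec.unit * spec.deltaCopies)
        b.aligned(lspec.unit)
    else:
        b.aligned(lspec.unit * copies)
        b.delete(u * (-spec.deltaCopies))
    b.aligned(lspec.rightFlank)

    fwd = "".join(b.read)
    seq = reverse_complement(fwd) if spec.strand == "-" else fwd
    return SimulatedRead(spec.name, spec.strand, seq, fwd, tuple(b.ops),
                         spec.deltaCopies, locus)


# --------------------------------------------------------------------------
# edit script -> MAF


def _mask(text: str, positions: list[bool]) -> str:
    return "".join(c.lower() if m else c for c, m in zip(text, positions))


def script_to_parts(read: SimulatedRead, mismap: float = 0.0,
                    mask_ranges: Sequence[tuple[int, int]] = (),
                    score: float | None = None) -> list[AlignmentPart]:
    """Convert a read's edit script into AlignmentParts (one per split block).

    ``mask_ranges`` are construct-local reference intervals lowercased in
    both rows (soft masking).  Blocks are trimmed to start and end on
    aligned columns, as real MAF blocks do.
    """
    locus = read.locus
    construct = locus.construct
    blocks: list[tuple[int, int, list]] = []  # (ref_start, read_start, ops)
    cur_ops: list = []
    ref_pos = read_pos = 0
    cur_ref0, cur_read0 = 0, 0

    def flush() -> None:
        nonlocal cur_ops, cur_ref0, cur_read0
        ops = list(cur_ops)
        r0, q0 = cur_ref0, cur_read0
        while ops and ops[0][0] in "ID":
            op, n = ops.pop(0)
            if op == "I":
                q0 += n
            else:
                r0 += n
        while ops and ops[-1][0] in "ID":
            ops.pop()
        if ops:
            blocks.append((r0, q0, ops))
        cur_ops = []
        cur_ref0, cur_read0 = ref_pos, read_pos

    for op in read.ops:
        if op[0] == "split":
            flush()
            continue
        if op[0] == "B":
            if cur_ops:
                raise ValueError("reference rewind only allowed at a block start")
            ref_pos -= op[1]
            cur_ref0 = ref_pos
            continue
        cur_ops.append(op)
        if op[0] in ("M", "D"):
            ref_pos += op[1]
        if op[0] in ("M", "I"):
            read_pos += op[1]
    flush()

    parts: list[AlignmentPart] = []
    src_size = locus.src_size
    read_len = len(read.seq)
    for r0, q0, ops in blocks:
        ref_chars: list[str] = []
        read_chars: list[str] = []
        rp, qp = r0, q0
        for op, n in ops:
            if op == "M":
                ref_chars.append(construct[rp:rp + n])
                read_chars.append(read.fwd_seq[qp:qp + n])
                rp += n
                qp += n
            elif op == "D":
                ref_chars.append(construct[rp:rp + n])
                read_chars.append("-" * n)
                rp += n
            else:
                ref_chars.append("-" * n)
                read_chars.append(read.fwd_seq[qp:qp + n])
                qp += n
        ref_text = "".join(ref_chars)
        read_text = "".join(read_chars)
        if mask_ranges:
            masked: list[bool] = []
            pos = r0
            for c in ref_text:
                inside = any(lo <= pos < hi for lo, hi in mask_ranges)
                masked.append(inside)
                if c != "-":
                    pos += 1
            ref_text = _mask(ref_text, masked)
            read_text = _mask(read_text, masked)
        # q0/qp index fwd_seq (ref-ascending orientation); for '-' reads the
        # forward-read coordinates are mirrored
        if read.strand == "-":
            q_lo, q_hi = read_len - qp, read_len - q0
        else:
            q_lo, q_hi = q0, qp
        parts.append(AlignmentPart(
            readName=read.name,
            readStrand=read.strand,
            refName=locus.chrom,
            refStart=locus.offset + r0,
            refEnd=locus.offset + rp,
            refSrcSize=src_size,
            readStart=q_lo,
            readEnd=q_hi,
            readSrcSize=read_len,
            refText=ref_text,
            readText=read_text,
            mismap=mismap,
            score=score,
        ))
    for i, p in enumerate(parts):
        p.order = i
        p.validate()
    return parts


def edit_script_to_maf(read: SimulatedRead, mismap: float = 0.0,
                       mask_ranges: Sequence[tuple[int, int]] = (),
                       score: float | None = None) -> str:
    """MAF text for one read's ground-truth alignment."""
    buf = io.StringIO()
    write_maf(script_to_parts(read, mismap, mask_ranges, score), buf)
    return buf.getvalue()


def reads_to_maf(reads: Iterable[SimulatedRead], mismap: float = 0.0) -> str:
    """MAF text for a collection of reads (stands in for the aligner output)."""
    buf = io.StringIO()
    parts = [p for r in reads for p in script_to_parts(r, mismap)]
    write_maf(parts, buf)
    return buf.getvalue()


def make_chimeric_read(host_read: str, host_repeat_interval: tuple[int, int],
                       donor_repeat_sequence: str) -> str:
    """Replace the repeat interval of a host read with a donor tract."""
    lo, hi = host_repeat_interval
    if not (0 <= lo <= hi <= len(host_read)):
        raise ValueError("repeat interval outside host read")
    return host_read[:lo] + donor_repeat_sequence + host_read[hi:]


# --------------------------------------------------------------------------
# background genomes for ranking experiments


def make_background_genome(
    n_repeats: int,
    unit_sampler: Callable[[random.Random], str] | None = None,
    copy_noise: Callable[[random.Random], int] | None = None,
    seed: int = 0,
    reads_per_locus: int = 3,
    flank: int = 150,
    ref_copies_range: tuple[int, int] = (8, 15),
) -> tuple[list[Locus], list[SimulatedRead]]:
    """Many independent loci with small background copy noise, one per
    synthetic chromosome; byte-identical output for a fixed seed."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = random.Random(seed)
    if unit_sampler is None:
        def unit_sampler(r: random.Random) -> str:
            length = r.randint(2, 6)
            while True:
                unit = "".join(r.choice(_BASES) for _ in range(length))
                if len(set(unit)) > 1:  # avoid homopolymer units
                    return unit
    if copy_noise is None:
        def copy_noise(r: random.Random) -> int:
            return r.randint(-2, 2)
    loci: list[Locus] = []
    reads: list[SimulatedRead] = []
    for idx in range(n_repeats):
        unit = unit_sampler(rng)
        ref_copies = rng.randint(*ref_copies_range)
        spec = LocusSpec(
            leftFlank=random_flank(flank, unit, rng),
            rightFlank=random_flank(flank, unit, rng),
            unit=unit,
            refCopies=ref_copies,
            chrom=f"bg{idx}",
        )
        locus = make_locus(spec)
        loci.append(locus)
        for k in range(reads_per_locus):
            delta = copy_noise(rng)
            delta = max(delta, 1 - ref_copies)
            rspec = ReadSpec(
                name=f"bg{idx}_r{k}",
                deltaCopies=delta,
                strand="+" if k % 2 == 0 else "-",
            )
            reads.append(make_read(locus, rspec, seed=rng.randrange(2 ** 31)))
    return loci, reads


def loci_to_bed(loci: Iterable[Locus]) -> str:
    lines = []
    for loc in loci:
        a = loc.annotation
        lines.append(f"{a.chrom}\t{a.start}\t{a.end}\t{a.unit}\t{a.name}")
    return "\n".join(lines) + "\n"


def loci_to_fasta(loci: Iterable[Locus]) -> str:
    out = []
    for loc in loci:
        out.append(f">{loc.chrom}")
        seq = "N" * loc.offset + loc.construct
        for i in range(0, len(seq), 70):
            out.append(seq[i:i + 70])
    return "\n".join(out) + "\n"


def reads_to_fasta(reads: Iterable[SimulatedRead]) -> str:
    out = []
    for r in reads:
        out.append(f">{r.name}")
        for i in range(0, len(r.seq), 70):
            out.append(r.seq[i:i + 70])
    return "\n".join(out) + "\n"


def truth_table(reads: Iterable[SimulatedRead]) -> str:
    lines = ["#read\tstrand\tdeltaCopies"]
    for r in reads:
        lines.append(f"{r.name}\t{r.strand}\t{r.deltaCopies}")
    return "\n".join(lines) + "\n"
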