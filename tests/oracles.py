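"""Independent brute-force re-implementations used as test oracles.

These deliberately do everything the slow, literal way: per-column scans,
per-position distance checks, exhaustive segment enumeration.  They share no
code with the package paths they check.
"""

from __future__ import annotations

import random

from repeatlens.copy_number import GAVE_UP, PREDICTED
from repeatlens.maf_io import AlignmentPart


def column_gaps_bruteforce(ref_text: str, read_text: str, ref_start: int):
    """(d, i, refLo, refHi) per maximal gap run, via a naive column scan."""
    runs = []
    pos = ref_start
    cur = None
    for a, b in zip(ref_text, read_text):
        if a == "-" or b == "-":
            if cur is None:
                cur = {"d": 0, "i": 0, "lo": pos}
            if b == "-":
                cur["d"] += 1
                pos += 1
            else:
                cur["i"] += 1
        else:
            if cur is not None:
                runs.append((cur["d"], cur["i"], cur["lo"], cur["lo"] + cur["d"]))
                cur = None
            pos += 1
    if cur is not None:
        runs.append((cur["d"], cur["i"], cur["lo"], cur["lo"] + cur["d"]))
    return runs


def max_segment_bruteforce(scores: list[int]) -> int:
    """O(n^2) maximum over all contiguous segments (and the empty segment)."""
    best = 0
    for i in range(len(scores)):
        total = 0
        for j in range(i, len(scores)):
            total += scores[j]
            best = max(best, total)
    return best


def round_to_unit_bruteforce(D: int, u: int) -> int:
    """Nearest multiple of u by exhaustive candidate enumeration; ties pick
    the candidate closer to zero."""
    span = abs(D) // u + 2
    candidates = [k * u for k in range(-span, span + 1)]
    return min(candidates, key=lambda c: (abs(D - c), abs(c)))


def predict_single_bruteforce(part: AlignmentPart, rs: int, re_: int, u: int,
                              f_left: int, f_right: int, n: int):
    """Literal per-position application of the single-alignment gap rules.

    Returns (status, copyChange).
    """
    if not (part.refStart <= rs - f_left and part.refEnd >= re_ + f_right):
        return GAVE_UP, 0

    def base_dist(p: int) -> int:
        if p < rs:
            return rs - p - 1
        if p >= re_:
            return p - re_
        return 0

    def base_far(p: int) -> bool:
        if p < rs:
            return rs - p - 1 >= f_left
        if p >= re_:
            return p - re_ >= f_right
        return False

    total = 0
    for d, i, lo, hi in column_gaps_bruteforce(part.refText, part.readText, part.refStart):
        if d == 0:
            p = lo
            if p < rs:
                dists = [rs - p]
                fars = [rs - p >= f_left]
                overlap = False
            elif p > re_:
                dists = [p - re_]
                fars = [p - re_ >= f_right]
                overlap = False
            else:
                dists = [0]
                fars = [False]
                overlap = rs <= p < re_
        else:
            positions = list(range(lo, hi))
            dists = [base_dist(p) for p in positions]
            fars = [base_far(p) for p in positions]
            overlap = any(rs <= p < re_ for p in positions)
        # the four rules, in order
        if not overlap and 2 * i <= u:
            continue
        if all(fars):
            continue
        if any(fars):
            return GAVE_UP, 0
        if all(dist > n for dist in dists):
            continue
        r = sum(1 for p in range(lo, hi) if rs <= p < re_)
        D = min(d - i, r)
        total += -(round_to_unit_bruteforce(D, u) // u)
    return PREDICTED, total


def random_single_alignment_case(rng: random.Random):
    """One random (part, repeat geometry) case for oracle comparison.

    Random repeat interval and unit length, an alignment that may or may not
    span it, and random gap runs of random shapes and placements.
    """
    u = rng.randint(1, 8)
    ref_len = rng.randint(500, 900)
    rs = rng.randint(150, 350)
    re_ = rs + rng.randint(u, 60)
    a_start = rng.randint(0, 120)
    a_end = rng.randint(re_ + 20, ref_len)

    cols = []  # (ref_char?, read_char?) as booleans; build texts
    ref_chars, read_chars = [], []
    pos = a_start
    bases = "ACGT"
    while pos < a_end:
        if ref_chars and rng.random() < 0.06 and pos < a_end - 1:
            # a gap run: deletion part and/or insertion part
            d = rng.choice([0, 1, 2, 3, 5, 10, 25, 60, 120])
            i = rng.choice([0, 1, 2, 3, 5, 10, 25, 60, 150])
            d = min(d, a_end - 1 - pos)
            if d + i == 0:
                continue
            for _ in range(d):
                ref_chars.append(rng.choice(bases))
                read_chars.append("-")
                pos += 1
            for _ in range(i):
                ref_chars.append("-")
                read_chars.append(rng.choice(bases))
        else:
            c = rng.choice(bases)
            ref_chars.append(c)
            read_chars.append(c if rng.random() < 0.9 else rng.choice(bases))
            pos += 1
    # alignments must end on an aligned column
    if read_chars[-1] == "-" or ref_chars[-1] == "-":
        ref_chars.append("A")
        read_chars.append("A")
        pos += 1
        a_end = pos
    a_end = pos
    read_len = sum(1 for c in read_chars if c != "-")
    part = AlignmentPart(
        readName="case", readStrand="+", refName="chr",
        refStart=a_start, refEnd=a_end, refSrcSize=ref_len,
        readStart=0, readEnd=read_len, readSrcSize=read_len,
        refText="".join(ref_chars), readText="".join(read_chars),
    )
    part.validate()
    return part, rs, re_, u
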