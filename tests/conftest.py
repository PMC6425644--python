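from __future__ import annotations

import random

import pytest

from repeatlens.copy_number import PredictionConfig
from repeatlens.synthetic import Locus, LocusSpec, make_locus, random_flank


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture
def config() -> PredictionConfig:
    return PredictionConfig()


def build_locus(unit: str, ref_copies: int, *, chrom: str = "chrT",
                flank: int = 200, seed: int = 0, offset: int = 0) -> Locus:
    r = random.Random(seed)
    spec = LocusSpec(
        leftFlank=random_flank(flank, unit, r),
        rightFlank=random_flank(flank, unit, r),
        unit=unit,
        refCopies=ref_copies,
        chrom=chrom,
        offset=offset,
    )
    return make_locus(spec)


@pytest.fixture
def cag_locus() -> Locus:
    """CAG x 21 with 200 bp flanks (the classic coding-repeat geometry)."""
    return build_locus("CAG", 21, seed=11)
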