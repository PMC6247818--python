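"""Shared fixtures: caller config, a designed fixture genome and gene model,
and independent oracles (exact big-integer Fisher enumeration, whole-protein
translation diff) used to cross-check the implementation."""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np
import pytest

from fetcall.annotate import Gene, GeneModel
from fetcall.core import CallerConfig
from fetcall.pileup import ReadObservation


@pytest.fixture
def cfg() -> CallerConfig:
    return CallerConfig()


def fet_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact one-tailed FET p by brute-force enumeration of the support.

    Enumerates every achievable table with the observed margins via the
    full factorial form of the hypergeometric pmf and sums those with
    cell ``a`` at or beyond the observed value (the direction swept by
    the implementation).  Pure big-integer rationals: no floats.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    num = factorial(r1) * factorial(r2) * factorial(c1) * factorial(n - c1)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if x < a:
            continue
        den = (
            factorial(n)
            * factorial(x)
            * factorial(r1 - x)
            * factorial(c1 - x)
            * factorial(r2 - c1 + x)
        )
        total += Fraction(num, den)
    return total


def make_obs(
    n_ref: int,
    n_var: int,
    var_allele: str = "T",
    phred: int = 40,
    ref_fwd: int | None = None,
    var_fwd: int | None = None,
) -> list[ReadObservation]:
    """Synthetic site evidence with near-balanced strands by default."""
    from fetcall.pileup import REF

    obs = []
    rf = ref_fwd if ref_fwd is not None else n_ref // 2
    vf = var_fwd if var_fwd is not None else n_var // 2
    for i in range(n_ref):
        obs.append(ReadObservation(REF, i < rf, phred))
    for i in range(n_var):
        obs.append(ReadObservation(var_allele, i < vf, phred))
    return obs


# ---------------------------------------------------------------------------
# Fixture genome: one plus-strand two-exon gene, one minus-strand gene.

GENOME_LEN = 6000

# Plus-strand gene G1: tx 2001-2600, exons 2001-2200 / 2301-2600,
# CDS 2101-2200 + 2301-2500 (300 nt = 100 codons).
G1 = Gene(
    name="G1",
    chrom="chr1",
    strand="+",
    tx_start=2001,
    tx_end=2600,
    exons=((2001, 2200), (2301, 2600)),
    cds=((2101, 2200), (2301, 2500)),
)
# Codons: ATG, then GCT x 97, TAC, TAA.
G1_CDS = "ATG" + "GCT" * 97 + "TAC" + "TAA"

# Minus-strand gene G2: single exon 4001-4400, CDS 4101-4301 (201 nt).
G2 = Gene(
    name="G2",
    chrom="chr1",
    strand="-",
    tx_start=4001,
    tx_end=4400,
    exons=((4001, 4400),),
    cds=((4101, 4301),),
)
G2_CDS = "ATG" + "GCT" * 65 + "TAA"  # transcript sense


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture(scope="session")
def genome() -> dict[str, str]:
    rng = np.random.default_rng(42)
    seq = list(rng.choice(list("ACGT"), size=GENOME_LEN))
    # overwrite CDS intervals with the designed codons
    assert len(G1_CDS) == 300
    seq[2100:2200] = G1_CDS[:100]
    seq[2300:2500] = G1_CDS[100:]
    assert len(G2_CDS) == 201
    seq[4100:4301] = _revcomp(G2_CDS)
    return {"chr1": "".join(seq)}


@pytest.fixture(scope="session")
def gene_model() -> GeneModel:
    return GeneModel([G1, G2], promoter_window=2000, splice_window=2)
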