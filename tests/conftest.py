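"""Shared fixtures: templates, random sequence factories, and a small
hand-checkable two-gene genome."""

from __future__ import annotations

import numpy as np
import pytest

from gcsplice._codons import AA_TO_CODONS
from gcsplice.genomecomp import GeneModel
from gcsplice.seqdesign import CodingSequence

AA_POOL = [aa for aa in sorted(AA_TO_CODONS) if aa not in "MW"]
SENSE_CODONS = sorted(
    c for codons in AA_TO_CODONS.values() for c in codons
)


def make_random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame CDS without internal stops, ATG start, TAA stop."""
    body = "".join(
        rng.choice(AA_TO_CODONS[aa])
        for aa in rng.choice(AA_POOL, size=n_codons - 2)
    )
    return "ATG" + body + "TAA"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def template_240(rng) -> CodingSequence:
    """A 240-codon reporter-length template with 5' context for folding."""
    return CodingSequence(
        id="reporter",
        cds=make_random_cds(rng, 240),
        context5="GCCACCATTACG",  # >4 nt upstream of the start codon
    )


# ---------------------------------------------------------------------------
# Hand-checkable two-gene genome: the same transcript on both strands.
#
# CDS = ATG GGC GGA TTT TAA; exon1 = first 7 CDS nt, 4-nt intron, exon2 = rest.
# Fourfold codons: GGC (third pos C, transcript offset 5, exon rank 1) and
# GGA (third pos A, transcript offset 8, exon rank 2).  Gene GC4 = 0.5.
# ---------------------------------------------------------------------------

_PRE_MRNA = "ATGGGCG" + "GTAG" + "GATTTTAA"
_COMP = str.maketrans("ACGT", "TGCA")


@pytest.fixture
def hand_genome() -> tuple[list[GeneModel], dict[str, str]]:
    plus = GeneModel(
        gene_id="gplus",
        transcript_id="tplus",
        chrom="cplus",
        strand="+",
        exons=[(0, 7), (11, 19)],
        cds_intervals=[(0, 7), (11, 19)],
    )
    minus = GeneModel(
        gene_id="gminus",
        transcript_id="tminus",
        chrom="cminus",
        strand="-",
        exons=[(12, 19), (0, 8)],
        cds_intervals=[(12, 19), (0, 8)],
    )
    genome = {
        "cplus": _PRE_MRNA,
        "cminus": _PRE_MRNA.translate(_COMP)[::-1],
    }
    return [plus, minus], genome
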