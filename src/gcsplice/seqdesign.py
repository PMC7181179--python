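"""Design of synonymous coding-sequence variants at a target GC3.

A variant is designed by replacing every codon (independently, at random)
with a synonymous codon drawn from a per-amino-acid distribution built so
that the expected G/C content at the third codon position equals the design
target.  The target mass is split uniformly over the G/C-ending synonymous
codons of each amino acid, and the remaining mass uniformly over the
A/T-ending codons; e.g. glycine at target GC3 = 0.25 yields
GGA 37.5%, GGT 37.5%, GGC 12.5%, GGG 12.5%.

Methionine and tryptophan have a single codon and are kept fixed, so the
whole-sequence expected GC3 deviates slightly from the target; the target
is exact at every degenerate codon position.  Stop codons are never
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from ._codons import (
    AA_TO_CODONS,
    STOP_CODONS,
    VALID_BASES,
    codons_of,
    is_gc_ending,
    translate,
)

__all__ = [
    "CodingSequence",
    "CodonDistribution",
    "build_codon_distribution",
    "design_variant",
    "design_panel",
    "panel_subseed",
]


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding sequence with optional transcript context.

    ``context5``/``context3`` hold flanking mRNA sequence (e.g. the 5' UTR
    needed for folding windows that start upstream of the AUG).
    """

    id: str
    cds: str
    context5: str = ""
    context3: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", self.cds.upper())
        object.__setattr__(self, "context5", self.context5.upper())
        object.__setattr__(self, "context3", self.context3.upper())

    @property
    def protein(self) -> str:
        return translate(self.cds)

    def validate(self) -> None:
        """Raise ``ValueError`` on broken frame, internal stop or bad alphabet."""
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.id}: CDS length {len(self.cds)} not divisible by 3")
        if not set(self.cds) <= VALID_BASES:
            bad = sorted(set(self.cds) - VALID_BASES)
            raise ValueError(f"{self.id}: invalid bases {bad} in CDS")
        prot = self.protein
        if "*" in prot[:-1]:
            raise ValueError(f"{self.id}: internal stop codon at aa {prot.index('*') + 1}")


@dataclass(frozen=True)
class CodonDistribution:
    """Sampling probabilities over the synonymous codons of one amino acid."""

    amino_acid: str
    probabilities: dict[str, float]
    target_gc3: float

    @cached_property
    def _sampler(self) -> tuple[list[str], np.ndarray]:
        codons = sorted(self.probabilities)
        cum = np.cumsum([self.probabilities[c] for c in codons])
        cum[-1] = 1.0
        return codons, cum

    def sample(self, rng: np.random.Generator) -> str:
        """One codon by inverse-CDF sampling from the generator's stream."""
        codons, cum = self._sampler
        return codons[int(np.searchsorted(cum, rng.random(), side="right"))]

    @property
    def expected_gc3(self) -> float:
        return sum(p for c, p in self.probabilities.items() if is_gc_ending(c))


def build_codon_distribution(amino_acid: str, target_gc3: float) -> CodonDistribution:
    """Codon sampling distribution for one amino acid at a target GC3.

    The target GC3 mass is split uniformly among G/C-ending synonymous
    codons and ``1 - target_gc3`` uniformly among A/T-ending ones.
    Single-codon amino acids (M, W) put probability 1 on their sole codon.
    """
    aa = amino_acid.upper()
    if aa not in AA_TO_CODONS:
        raise ValueError(f"unknown amino acid code: {amino_acid!r}")
    if not 0.0 <= target_gc3 <= 1.0:
        raise ValueError(f"target_gc3 must be in [0, 1], got {target_gc3}")
    codons = AA_TO_CODONS[aa]
    gc = [c for c in codons if is_gc_ending(c)]
    at = [c for c in codons if not is_gc_ending(c)]
    probs: dict[str, float] = {}
    if not at:  # single-codon families are all G-ending (ATG, TGG)
        for c in gc:
            probs[c] = 1.0 / len(gc)
    elif not gc:
        for c in at:
            probs[c] = 1.0 / len(at)
    else:
        for c in gc:
            probs[c] = target_gc3 / len(gc)
        for c in at:
            probs[c] = (1.0 - target_gc3) / len(at)
    return CodonDistribution(amino_acid=aa, probabilities=probs, target_gc3=target_gc3)


def _distributions_for(protein: str, target_gc3: float) -> dict[str, CodonDistribution]:
    return {aa: build_codon_distribution(aa, target_gc3) for aa in set(protein) - {"*"}}


def design_variant(
    template: CodingSequence, target_gc3: float, seed: int
) -> CodingSequence:
    """Randomize every codon of ``template`` at the target GC3.

    Each non-stop codon is drawn independently from the distribution of its
    amino acid; a terminal stop codon is preserved verbatim.  The output
    translates to the identical protein and is deterministic given ``seed``.
    """
    template.validate()
    rng = np.random.default_rng(seed)
    dists = _distributions_for(template.protein, target_gc3)
    out: list[str] = []
    for codon in codons_of(template.cds):
        if codon in STOP_CODONS:
            out.append(codon)
        else:
            out.append(dists[translate(codon)].sample(rng))
    return CodingSequence(
        id=f"{template.id}_gc3-{int(round(target_gc3 * 100)):03d}_seed-{seed}",
        cds="".join(out),
        context5=template.context5,
        context3=template.context3,
    )


def panel_subseed(seed: int, index: int) -> int:
    """Deterministic per-target sub-seed for panel designs.

    Splitting rule: the first state word of ``SeedSequence(seed).spawn()``
    child ``index``, reduced below 2**31 so sub-seeds remain plain ints.
    """
    child = np.random.SeedSequence(seed).spawn(index + 1)[index]
    return int(child.generate_state(1)[0] % (2**31))


def design_panel(
    template: CodingSequence, targets: list[float], seed: int
) -> list[CodingSequence]:
    """One independently randomized variant per target GC3.

    Sub-seeds derive from ``seed`` via :func:`panel_subseed`, so panels are
    reproducible element-wise: element ``i`` equals
    ``design_variant(template, targets[i], panel_subseed(seed, i))``.
    """
    if not targets:
        raise ValueError("empty target list")
    for t in targets:
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"target GC3 {t} outside [0, 1]")
    return [
        design_variant(template, t, panel_subseed(seed, i))
        for i, t in enumerate(targets)
    ]
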