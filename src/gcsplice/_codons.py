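"""Standard genetic code tables and codon-class helpers.

Derived from Biopython's standard (NCBI table 1) codon table so the code
stays consistent with the translation used elsewhere in the package.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]

#: codon (DNA, upper case) -> 1-letter amino acid; stop codons excluded
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: 1-letter amino acid -> sorted tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

#: dinucleotide prefixes of the eight fourfold-degenerate codon families
FOURFOLD_PREFIXES: frozenset[str] = frozenset(
    {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
)

VALID_BASES = frozenset("ACGT")


def is_gc_ending(codon: str) -> bool:
    return codon[2] in "GC"


def codons_of(seq: str) -> list[str]:
    """Split an in-frame sequence into codons; raises on broken frame."""
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def translate(seq: str) -> str:
    """Translate an in-frame DNA sequence; '*' marks stop codons."""
    out = []
    for codon in codons_of(seq.upper()):
        if codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)
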