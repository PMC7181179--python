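"""Sequence covariates of coding sequences.

Implements the battery of features used to correlate reporter sequence
composition with expression: third-position GC content (GC3, whole-gene,
regional, and restricted to fourfold-degenerate codons as GC4), CpG
density, start-codon folding energy, codon-adaptation indices (CAI/tAI),
AU-rich element score, AT/GC tandem stretches, and PSSM-based counts of
cryptic polyadenylation signals and splice-donor-like motifs.

Conventions: codons containing ambiguous bases are excluded from
GC3/GC4/CAI/tAI; motif scans treat ambiguous bases as matching nothing;
all computations are pure functions of the sequence and configuration.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from ._codons import (
    AA_TO_CODONS,
    CODON_TO_AA,
    FOURFOLD_PREFIXES,
    STOP_CODONS,
    codons_of,
)
from ._tables import DEFAULT_CAI_WEIGHTS, DEFAULT_TAI_WEIGHTS_SYNTHETIC
from .folding import DEFAULT_BACKEND, mfe
from .pssm import ARE_PSSM, POLY_A_PSSM, PSSM, SD_PSSM, scan_pssm
from .seqdesign import CodingSequence

__all__ = [
    "gc3",
    "gc4",
    "regional_gc3",
    "cpg_count",
    "folding_energy_start",
    "cai",
    "tai",
    "count_iupac_motif",
    "are_top_score",
    "FeatureConfig",
    "feature_table",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

SD_CRYPTIC_PATTERN = "RSGTNNHT"
AT_STRETCH_PATTERN = "AT" * 9
GC_STRETCH_PATTERN = "GC" * 9


def _third_positions(cds: CodingSequence | str) -> list[str]:
    seq = cds.cds if isinstance(cds, CodingSequence) else cds.upper()
    return [c[2] for c in codons_of(seq)]


def gc3(cds: CodingSequence | str) -> float:
    """GC fraction at third codon positions (ambiguous codons excluded)."""
    thirds = [b for b in _third_positions(cds) if b in "ACGT"]
    if not thirds:
        raise ValueError("no unambiguous third positions")
    return sum(b in "GC" for b in thirds) / len(thirds)


def gc4(cds: CodingSequence | str) -> float:
    """GC3 restricted to codons of the eight fourfold-degenerate families.

    Returns ``nan`` when the sequence contains no fourfold codon.
    """
    seq = cds.cds if isinstance(cds, CodingSequence) else cds.upper()
    thirds = [
        c[2]
        for c in codons_of(seq)
        if c[:2] in FOURFOLD_PREFIXES and c[2] in "ACGT"
    ]
    if not thirds:
        return math.nan
    return sum(b in "GC" for b in thirds) / len(thirds)


def regional_gc3(cds: CodingSequence | str, start_nt: int, end_nt: int) -> float:
    """GC3 of the codon range delimited by a 1-based inclusive nt range.

    ``start_nt``/``end_nt`` must fall on codon boundaries (e.g. 1..360).
    """
    seq = cds.cds if isinstance(cds, CodingSequence) else cds.upper()
    if start_nt < 1 or end_nt > len(seq) or start_nt > end_nt:
        raise ValueError(f"range {start_nt}-{end_nt} outside sequence of length {len(seq)}")
    if (start_nt - 1) % 3 != 0 or end_nt % 3 != 0:
        raise ValueError(f"range {start_nt}-{end_nt} is not codon-aligned")
    return gc3(seq[start_nt - 1 : end_nt])


def cpg_count(seq: str) -> int:
    """Number of CpG dinucleotides (overlapping scan)."""
    if not seq:
        raise ValueError("empty sequence")
    return len(re.findall("(?=CG)", seq.upper()))


def folding_energy_start(
    cds_with_context: CodingSequence,
    window_start: int = -4,
    window_end: int = 38,
    backend: str | None = None,
) -> float:
    """MFE (kcal/mol) of the window around the start codon.

    The window is half-open ``[window_start, window_end)`` in coordinates
    where the A of the start codon is 0, so the default -4..38 covers
    42 nt: 4 nt of 5' context plus the first 38 nt of the CDS.
    """
    if window_start >= window_end:
        raise ValueError("window_start must be below window_end")
    need_up = -window_start
    if need_up > 0 and len(cds_with_context.context5) < need_up:
        raise ValueError(
            f"{cds_with_context.id}: needs {need_up} nt of 5' context, "
            f"has {len(cds_with_context.context5)}"
        )
    mrna = cds_with_context.context5 + cds_with_context.cds + cds_with_context.context3
    start = len(cds_with_context.context5)
    lo, hi = start + window_start, start + window_end
    if hi > len(mrna):
        raise ValueError(f"{cds_with_context.id}: window extends past the sequence")
    return mfe(mrna[lo:hi], backend=backend)


def _geometric_index(cds: CodingSequence | str, weights: dict[str, float]) -> float:
    seq = cds.cds if isinstance(cds, CodingSequence) else cds.upper()
    logs = []
    for codon in codons_of(seq):
        if codon in STOP_CODONS or not set(codon) <= set("ACGT"):
            continue
        if len(AA_TO_CODONS[CODON_TO_AA[codon]]) < 2:
            continue  # M and W carry no synonymous information
        try:
            w = weights[codon]
        except KeyError:
            raise ValueError(f"no adaptiveness weight for codon {codon}")
        if w <= 0:
            raise ValueError(f"non-positive weight for codon {codon}")
        logs.append(math.log(w))
    if not logs:
        raise ValueError("no degenerate codons to score")
    return math.exp(sum(logs) / len(logs))


def cai(cds: CodingSequence | str, weights: dict[str, float] | None = None) -> float:
    """Codon Adaptation Index: geometric-mean relative adaptiveness.

    Computed over codons of amino acids with more than one synonym;
    methionine, tryptophan and stops are excluded.
    """
    return _geometric_index(cds, weights or DEFAULT_CAI_WEIGHTS)


def tai(cds: CodingSequence | str, s_weights: dict[str, float] | None = None) -> float:
    """tRNA Adaptation Index under supplied tRNA-adaptiveness weights."""
    return _geometric_index(cds, s_weights or DEFAULT_TAI_WEIGHTS_SYNTHETIC)


def count_iupac_motif(seq: str, pattern: str) -> int:
    """Overlapping occurrences of an IUPAC-degenerate motif (forward strand)."""
    try:
        regex = "".join(f"[{IUPAC[c]}]" for c in pattern.upper())
    except KeyError as e:
        raise ValueError(f"invalid IUPAC symbol {e.args[0]!r} in pattern")
    return len(re.findall(f"(?=({regex}))", seq.upper()))


def are_top_score(seq: str) -> float:
    """Best log-odds score of the AU-rich element core motif ATTTA."""
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) < len(ARE_PSSM):
        return ARE_PSSM.min_score
    _, best = scan_pssm(seq, ARE_PSSM, p_threshold=1.0)
    return best


@dataclass
class FeatureConfig:
    """Tunable knobs of the feature battery."""

    cai_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CAI_WEIGHTS))
    tai_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAI_WEIGHTS_SYNTHETIC)
    )
    p_threshold: float = 1e-4
    folding_backend: str = DEFAULT_BACKEND
    fold_window: tuple[int, int] = (-4, 38)
    half_split_nt: int = 360  # boundary between "first half" and "second half"


def _halves(seq: str, split_nt: int) -> tuple[str, str]:
    """Split at the configured boundary, falling back to the codon-aligned
    midpoint for sequences shorter than twice the boundary."""
    if len(seq) >= 2 * split_nt:
        cut = split_nt
    else:
        cut = (len(seq) // 6) * 3
    return seq[:cut], seq[cut:]


def feature_table(
    panel: list[CodingSequence], config: FeatureConfig | None = None
) -> pd.DataFrame:
    """One row of features per variant; deterministic given the config.

    Folding energy is reported as ``nan`` for variants lacking the 5'
    context the window requires.
    """
    cfg = config or FeatureConfig()
    rows = []
    for var in panel:
        var.validate()
        seq = var.cds
        try:
            dg = folding_energy_start(
                var, *cfg.fold_window, backend=cfg.folding_backend
            )
        except ValueError:
            dg = math.nan
        first, second = _halves(seq, cfg.half_split_nt)
        n_poly_a, _ = scan_pssm(seq, POLY_A_PSSM, cfg.p_threshold)
        n_sd, _ = scan_pssm(seq, SD_PSSM, cfg.p_threshold)
        try:
            rows.append(
                {
                    "id": var.id,
                    "gc3": gc3(seq),
                    "gc4": gc4(seq),
                    "cpg": cpg_count(seq),
                    "dg": dg,
                    "cai": cai(seq, cfg.cai_weights),
                    "tai": tai(seq, cfg.tai_weights),
                    "are": are_top_score(seq),
                    "at_stretch": count_iupac_motif(seq, AT_STRETCH_PATTERN),
                    "gc_stretch": count_iupac_motif(seq, GC_STRETCH_PATTERN),
                    "poly_a": n_poly_a,
                    "sd_cryptic": count_iupac_motif(seq, SD_CRYPTIC_PATTERN),
                    "sd_pssm": n_sd,
                    "gc3_first_half": gc3(first) if first else math.nan,
                    "gc3_second_half": gc3(second) if second else math.nan,
                }
            )
        except ValueError as e:
            raise ValueError(f"feature computation failed for {var.id}: {e}") from e
    return pd.DataFrame(rows)
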