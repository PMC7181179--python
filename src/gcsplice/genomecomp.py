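"""Genome-composition analyses: GC4 versus splicing structure.

Works from gene models (transcript structures with rank-ordered exons and
CDS intervals) plus a genome FASTA and asks how GC content at
fourfold-degenerate third codon positions (GC4) relates to exon count,
exon rank, and distance from the transcription start site, and whether
intronless retrocopies are GC-enriched relative to their spliced parents.

Coordinate conventions: all intervals are 0-based half-open on the genome;
exon rank is counted 1..n in transcription order from the first exon even
when that exon is noncoding; each codon is assigned to the exon containing
its *third* nucleotide (where the GC4 signal lives), which makes
junction-spanning codons unambiguous; TSS distance is the position of that
third nucleotide in mature-transcript coordinates (0 = first transcribed
base), orientation-aware on both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._codons import FOURFOLD_PREFIXES, STOP_CODONS, translate

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "cds_codon_sites",
    "gene_gc4",
    "select_isoform",
    "dedupe_paralogs",
    "gc4_by_exon_count",
    "gc4_by_exon_rank",
    "gc4_tss_profile",
    "retrogene_test",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One transcript: strand, rank-ordered exons, and CDS intervals.

    ``exons`` and ``cds_intervals`` are lists of 0-based half-open genomic
    intervals given in transcription order (for minus-strand transcripts
    that is decreasing genomic coordinate).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        key = (lambda iv: iv[0]) if self.strand == "+" else (lambda iv: -iv[1])
        self.exons = sorted((tuple(iv) for iv in self.exons), key=key)
        self.cds_intervals = sorted((tuple(iv) for iv in self.cds_intervals), key=key)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the first transcribed base."""
        first = self.exons[0]
        return first[0] if self.strand == "+" else first[1] - 1

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_sequence(self, genome: dict[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        parts = []
        for s, e in self.cds_intervals:
            piece = chrom_seq[s:e].upper()
            parts.append(piece if self.strand == "+" else _revcomp(piece))
        return "".join(parts)

    def transcript_coordinate(self, genomic_pos: int) -> int:
        """Mature-transcript offset (0 = TSS base) of a genomic position."""
        offset = 0
        for s, e in self.exons:
            if s <= genomic_pos < e:
                if self.strand == "+":
                    return offset + (genomic_pos - s)
                return offset + (e - 1 - genomic_pos)
            offset += e - s
        raise ValueError(
            f"{self.transcript_id}: position {genomic_pos} not exonic"
        )

    def exon_rank_of(self, genomic_pos: int) -> int:
        """1-based rank (transcription order) of the exon containing a position."""
        for rank, (s, e) in enumerate(self.exons, start=1):
            if s <= genomic_pos < e:
                return rank
        raise ValueError(
            f"{self.transcript_id}: position {genomic_pos} not exonic"
        )

    def validate_cds(self, genome: dict[str, str]) -> None:
        """Frame/stop sanity; raises ``ValueError`` on failure."""
        for cs, ce in self.cds_intervals:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS interval outside exons")
        seq = self.cds_sequence(genome)
        if len(seq) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length {len(seq)} not in frame")
        prot = translate(seq)
        if "*" in prot[:-1]:
            raise ValueError(f"{self.transcript_id}: internal stop codon")


def cds_codon_sites(model: GeneModel, genome: dict[str, str]) -> pd.DataFrame:
    """Per-codon table: third-position genomic site, exon rank, TSS distance,
    fourfold-family membership, and G/C indicator at the third position.

    Stop codons are excluded (their third position is not a synonymous
    site).
    """
    seq = model.cds_sequence(genome)
    # genomic position of every CDS nucleotide, in transcription order
    positions: list[int] = []
    for s, e in model.cds_intervals:
        rng = range(s, e) if model.strand == "+" else range(e - 1, s - 1, -1)
        positions.extend(rng)
    rows = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            continue
        third_pos = positions[i + 2]
        rows.append(
            {
                "codon_index": i // 3,
                "third_genomic_pos": third_pos,
                "rank": model.exon_rank_of(third_pos),
                "tss_distance": model.transcript_coordinate(third_pos),
                "fourfold": codon[:2] in FOURFOLD_PREFIXES and codon[2] in "ACGT",
                "gc": codon[2] in "GC",
            }
        )
    return pd.DataFrame(rows)


def gene_gc4(model: GeneModel, genome: dict[str, str]) -> float:
    sites = cds_codon_sites(model, genome)
    four = sites[sites.fourfold]
    return float(four.gc.mean()) if len(four) else np.nan


def select_isoform(models: list[GeneModel]) -> list[GeneModel]:
    """Keep one transcript per gene: the longest CDS, ties broken by
    lexicographically smallest transcript id."""
    best: dict[str, GeneModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.cds_length > cur.cds_length
            or (m.cds_length == cur.cds_length and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    return [best[g] for g in sorted(best)]


def dedupe_paralogs(
    models: list[GeneModel], clusters: dict[str, str], seed: int
) -> list[GeneModel]:
    """Keep one random gene per paralog cluster (seeded, deterministic)."""
    missing = sorted({m.gene_id for m in models} - set(clusters))
    if missing:
        raise ValueError(f"genes missing from cluster table: {', '.join(missing)}")
    by_cluster: dict[str, list[GeneModel]] = {}
    for m in models:
        by_cluster.setdefault(clusters[m.gene_id], []).append(m)
    rng = np.random.default_rng(seed)
    kept = []
    for cluster in sorted(by_cluster):
        members = sorted(by_cluster[cluster], key=lambda m: m.gene_id)
        kept.append(members[rng.integers(len(members))])
    return sorted(kept, key=lambda m: m.gene_id)


def _usable(models: list[GeneModel], genome: dict[str, str]) -> list[GeneModel]:
    out = []
    for m in models:
        try:
            m.validate_cds(genome)
        except ValueError as e:
            logger.warning("skipping %s: %s", m.transcript_id, e)
            continue
        out.append(m)
    return out


def gc4_by_exon_count(
    models: list[GeneModel], genome: dict[str, str]
) -> tuple[pd.DataFrame, float, float]:
    """Per-gene GC4 with exon count, plus Spearman correlation of the two.

    Returns ``(table, rho, p)``; rho is ``nan`` (and flagged by the caller)
    when either variable is constant.
    """
    rows = []
    for m in _usable(models, genome):
        g = gene_gc4(m, genome)
        if np.isnan(g):
            logger.warning("skipping %s: no fourfold codons", m.transcript_id)
            continue
        rows.append({"gene_id": m.gene_id, "exon_count": m.exon_count, "gc4": g})
    table = pd.DataFrame(rows)
    if len(table) < 2 or table.exon_count.nunique() < 2 or table.gc4.nunique() < 2:
        return table, np.nan, np.nan
    rho, p = stats.spearmanr(table.exon_count, table.gc4)
    return table, float(rho), float(p)


def gc4_by_exon_rank(
    models: list[GeneModel], genome: dict[str, str]
) -> tuple[pd.DataFrame, float]:
    """Mean GC4 per (exon rank, exon count) cell across genes.

    Also runs a one-tailed paired Wilcoxon signed-rank test of per-gene
    rank-1 GC4 exceeding rank-2 GC4 (genes with fourfold codons in both
    ranks); returns ``(table, p_value)``, p ``nan`` with <5 usable pairs.
    """
    cells: list[pd.DataFrame] = []
    pairs: list[tuple[float, float]] = []
    for m in _usable(models, genome):
        sites = cds_codon_sites(model=m, genome=genome)
        four = sites[sites.fourfold]
        if not len(four):
            continue
        per_rank = four.groupby("rank").gc.agg(["mean", "size"])
        per_rank["exon_count"] = m.exon_count
        per_rank["gene_id"] = m.gene_id
        cells.append(per_rank.reset_index())
        if 1 in per_rank.index and 2 in per_rank.index:
            pairs.append((per_rank.loc[1, "mean"], per_rank.loc[2, "mean"]))
    if not cells:
        return pd.DataFrame(columns=["rank", "exon_count", "mean_gc4", "n_sites"]), np.nan
    per_gene = pd.concat(cells, ignore_index=True)
    table = (
        per_gene.groupby(["rank", "exon_count"])
        .apply(
            lambda g: pd.Series(
                {
                    "mean_gc4": np.average(g["mean"], weights=g["size"]),
                    "n_sites": g["size"].sum(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    p = np.nan
    diffs = [a - b for a, b in pairs if a != b]
    if len(pairs) >= 5 and diffs:
        _, p = stats.wilcoxon(diffs, alternative="greater")
    return table, float(p) if p == p else np.nan


def gc4_tss_profile(
    models: list[GeneModel],
    genome: dict[str, str],
    ranks: tuple[int, ...] = (1, 2),
) -> pd.DataFrame:
    """Mean GC4 indicator by (TSS distance of the third position, exon rank).

    Averages the per-codon G/C indicator across genes for all fourfold
    codons whose third position sits at the same mature-transcript distance
    from the TSS inside an exon of the same rank, enabling a rank-1 versus
    rank-2 comparison that controls for TSS distance.
    """
    frames = []
    for m in _usable(models, genome):
        sites = cds_codon_sites(m, genome)
        four = sites[sites.fourfold & sites["rank"].isin(ranks)]
        frames.append(four[["tss_distance", "rank", "gc"]])
    if not frames:
        return pd.DataFrame(columns=["tss_distance", "rank", "mean_gc4", "n"])
    allsites = pd.concat(frames, ignore_index=True)
    out = (
        allsites.groupby(["tss_distance", "rank"])
        .gc.agg(mean_gc4="mean", n="size")
        .reset_index()
    )
    return out


def retrogene_test(
    pairs: pd.DataFrame, alternative: str = "greater"
) -> tuple[float, float, int]:
    """Paired GC4 comparison of retrocopies against their parents.

    ``pairs`` needs columns ``gc4_parent`` and ``gc4_retro``.  Returns the
    median of (retro - parent), the one-tailed Wilcoxon signed-rank
    p-value in the stated direction, and n.  Zero differences are dropped
    for the test, per the signed-rank convention; the p-value is ``nan``
    when every difference is zero.
    """
    if len(pairs) < 5:
        raise ValueError(f"need at least 5 pairs, got {len(pairs)}")
    diffs = (pairs["gc4_retro"] - pairs["gc4_parent"]).to_numpy(dtype=float)
    median = float(np.median(diffs))
    nonzero = diffs[diffs != 0]
    if not len(nonzero):
        return median, np.nan, len(diffs)
    _, p = stats.wilcoxon(nonzero, alternative=alternative)
    return median, float(p), len(diffs)
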