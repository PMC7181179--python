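"""Synthetic inputs with planted ground truth for every pipeline stage.

Each simulator emulates the sampling process of one assay:

* Flow-seq: per-cell fluorescence is lognormal around a per-variant latent
  mean; cells fall into 8 bins at the configured (or pooled-octile)
  boundaries, and per-bin amplicon reads are multinomial over the
  variants' cell shares within the bin.
* Fractionation: cytoplasmic reads are binomial with the planted RCC.
* Polysome pools: reads are multinomial over a 4-pool profile; profiles
  are shifted-binomial, Binomial(3, p) over pool indices 1..4, so the
  planted ribosome density is exactly 1 + 3p.
* Gene models: genes with exon counts from a configurable distribution on
  both strands; codons are drawn from the target-GC3 sampling
  distributions at a gene-level GC4 target that declines linearly with
  exon count (the planted slope).
* Expression tables: log2 expression linear in GC4 with distinct planted
  coefficients for spliced (multi-exon) and unspliced transcripts.
* Decay: exponential timecourses with multiplicative noise.

All simulators derive child random streams from one global seed via a
fixed labeling scheme, are bit-reproducible, and return machine-readable
truth tables alongside the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codons import AA_TO_CODONS
from .seqdesign import build_codon_distribution
from .sortquant import BinCountMatrix, FLOWSEQ_BINS, FRACTIONS, POLYSOME_POOLS
from .genomecomp import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "FlowseqConfig",
    "FractionationConfig",
    "PolysomeConfig",
    "GeneModelConfig",
    "ExpressionConfig",
    "DecayConfig",
    "simulate_flowseq",
    "simulate_fractionation",
    "simulate_polysome",
    "simulate_gene_models",
    "simulate_expression",
    "simulate_decay",
]

# fixed labeling scheme for child streams
_STREAMS = {
    "flowseq": 1,
    "fractionation": 2,
    "polysome": 3,
    "gene_models": 4,
    "expression": 5,
    "decay": 6,
}


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class FlowseqConfig:
    n_variants: int = 217
    reads_per_bin: int = 100_000
    n_cells_per_variant: int = 10_000
    #: latent per-variant mean fluorescence, log10 units; None = evenly
    #: spaced over two decades (the assay's bin span is ~100-fold)
    log10_means: np.ndarray | None = None
    cell_noise_sd: float = 0.25  # log10-scale lognormal spread per cell
    bin_boundaries: np.ndarray | None = None  # None = pooled octiles


@dataclass
class FractionationConfig:
    n_variants: int = 217
    reads_per_variant: int = 10_000
    #: planted RCC per variant; None = evenly spaced over the observed
    #: assay range 0.09..0.64
    true_rcc: np.ndarray | None = None


@dataclass
class PolysomeConfig:
    n_variants: int = 217
    reads_per_variant: int = 100_000
    #: planted ribosome density (mean pool index) per variant; None =
    #: evenly spaced in 1.5..3.5
    true_density: np.ndarray | None = None
    #: explicit n_variants x 4 pool probabilities; overrides true_density
    profiles: np.ndarray | None = None


@dataclass
class GeneModelConfig:
    n_genes: int = 500
    #: exon counts are drawn from a geometric distribution (success p)
    #: truncated to 1..max_exons, roughly matching the human skew
    exon_geometric_p: float = 0.15
    max_exons: int = 20
    gc4_intercept: float = 0.65
    gc4_slope_vs_exons: float = -0.02
    gc4_noise_sd: float = 0.05
    cds_codons: int = 200
    utr5_length: int = 60
    utr3_length: int = 30
    intron_length: int = 120
    intergenic_gap: int = 100
    chrom: str = "chrSim"


@dataclass
class ExpressionConfig:
    n_transcripts: int = 2000
    b_spliced: float = 0.0
    b_unspliced: float = 4.0
    intercept_spliced: float = 2.0
    intercept_unspliced: float = 2.0
    noise_sd: float = 1.0
    gc4_low: float = 0.2
    gc4_high: float = 0.95
    unspliced_fraction: float = 0.5
    zero_fraction: float = 0.0  # optional zero-inflation


@dataclass
class DecayConfig:
    k: float = 0.1  # decay constant, 1/hour
    a: float = 1.0
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0)
    noise_sd: float = 0.05  # multiplicative, levels * (1 + eps)


@dataclass
class SimulationConfig:
    """One global seed plus per-assay sections."""

    seed: int = 0
    flowseq: FlowseqConfig = field(default_factory=FlowseqConfig)
    fractionation: FractionationConfig = field(default_factory=FractionationConfig)
    polysome: PolysomeConfig = field(default_factory=PolysomeConfig)
    genes: GeneModelConfig = field(default_factory=GeneModelConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    decay: DecayConfig = field(default_factory=DecayConfig)


def _variant_ids(n: int) -> list[str]:
    return [f"var{i:04d}" for i in range(1, n + 1)]


def simulate_flowseq(cfg: SimulationConfig) -> tuple[BinCountMatrix, pd.DataFrame]:
    """Simulate a FACS-sort/sequencing experiment; truth = latent means."""
    fc = cfg.flowseq
    rng = _child_rng(cfg.seed, "flowseq")
    ids = _variant_ids(fc.n_variants)
    means = (
        np.asarray(fc.log10_means, dtype=float)
        if fc.log10_means is not None
        else np.linspace(0.0, 2.0, fc.n_variants)
    )
    # per-cell log10 fluorescence
    cells = rng.normal(
        loc=means[:, None], scale=fc.cell_noise_sd, size=(fc.n_variants, fc.n_cells_per_variant)
    )
    if fc.bin_boundaries is None:
        bounds = np.quantile(cells, np.linspace(0, 1, 9)[1:-1])
    else:
        bounds = np.asarray(fc.bin_boundaries, dtype=float)
        if len(bounds) != 7 or (np.diff(bounds) <= 0).any():
            raise ValueError("bin_boundaries must be 7 strictly increasing cut points")
        lo, hi = cells.min(), cells.max()
        if lo < bounds[0] - 5 or hi > bounds[-1] + 5:
            logger.warning("fluorescence support far outside bin boundaries; edge bins open-ended")
    # cells per (variant, bin)
    bin_of = np.digitize(cells, bounds)  # 0..7
    cell_counts = np.stack(
        [(bin_of == b).sum(axis=1) for b in range(8)], axis=1
    ).astype(float)
    # per-bin sequencing: reads multinomial over variant cell shares
    reads = np.zeros((fc.n_variants, 8), dtype=int)
    for b in range(8):
        col = cell_counts[:, b]
        if col.sum() == 0:
            continue
        reads[:, b] = rng.multinomial(fc.reads_per_bin, col / col.sum())
    counts = pd.DataFrame(reads, index=pd.Index(ids, name="variant_id"), columns=FLOWSEQ_BINS)
    truth = pd.DataFrame({"variant_id": ids, "log10_fluorescence": means}).set_index(
        "variant_id"
    )
    return BinCountMatrix(counts=counts, replicate_id="sim"), truth


def simulate_fractionation(cfg: SimulationConfig) -> tuple[BinCountMatrix, pd.DataFrame]:
    """Binomial cytoplasmic/nuclear splits at planted RCC values."""
    fr = cfg.fractionation
    rng = _child_rng(cfg.seed, "fractionation")
    ids = _variant_ids(fr.n_variants)
    true_rcc = (
        np.asarray(fr.true_rcc, dtype=float)
        if fr.true_rcc is not None
        else np.linspace(0.09, 0.64, fr.n_variants)
    )
    if ((true_rcc < 0) | (true_rcc > 1)).any():
        raise ValueError("true_rcc values must lie in [0, 1]")
    cyto = rng.binomial(fr.reads_per_variant, true_rcc)
    nuc = fr.reads_per_variant - cyto
    counts = pd.DataFrame(
        {"cyto": cyto, "nuc": nuc}, index=pd.Index(ids, name="variant_id")
    )[list(FRACTIONS)]
    truth = pd.DataFrame({"variant_id": ids, "true_rcc": true_rcc}).set_index("variant_id")
    return BinCountMatrix(counts=counts, replicate_id="sim"), truth


def simulate_polysome(cfg: SimulationConfig) -> tuple[BinCountMatrix, pd.DataFrame]:
    """Multinomial reads over shifted-binomial 4-pool profiles.

    Pool index = 1 + Binomial(3, p), so planted density = 1 + 3p and
    planted association = (1 - (1-p)^3) / (1-p)^3.
    """
    pc = cfg.polysome
    rng = _child_rng(cfg.seed, "polysome")
    ids = _variant_ids(pc.n_variants)
    if pc.profiles is not None:
        profiles = np.asarray(pc.profiles, dtype=float)
        if profiles.shape != (pc.n_variants, 4):
            raise ValueError("profiles must be n_variants x 4")
        if not np.allclose(profiles.sum(axis=1), 1.0):
            raise ValueError("each profile must sum to 1")
        density = profiles @ np.arange(1, 5)
    else:
        density = (
            np.asarray(pc.true_density, dtype=float)
            if pc.true_density is not None
            else np.linspace(1.5, 3.5, pc.n_variants)
        )
        if ((density < 1) | (density > 4)).any():
            raise ValueError("true_density must lie in [1, 4]")
        p = (density - 1.0) / 3.0
        j = np.arange(4)
        from scipy.stats import binom

        profiles = binom.pmf(j[None, :], 3, p[:, None])
    reads = np.stack([rng.multinomial(pc.reads_per_variant, prof) for prof in profiles])
    counts = pd.DataFrame(reads, index=pd.Index(ids, name="variant_id"), columns=POLYSOME_POOLS)
    free = profiles[:, 0]
    with np.errstate(divide="ignore"):
        association = np.where(free > 0, (1 - free) / free, np.inf)
    truth = pd.DataFrame(
        {"variant_id": ids, "true_density": density, "true_association": association}
    ).set_index("variant_id")
    return BinCountMatrix(counts=counts, replicate_id="sim"), truth


_AA_POOL = [aa for aa in AA_TO_CODONS if aa not in "MW"]


def _random_cds(rng: np.random.Generator, n_codons: int, gc_target: float) -> str:
    """In-frame CDS: ATG + random codons at the GC3 target + TAA stop."""
    aas = rng.choice(_AA_POOL, size=n_codons - 2)
    codons = ["ATG"]
    for aa in aas:
        dist = build_codon_distribution(str(aa), gc_target)
        codons.append(dist.sample(rng))
    codons.append("TAA")
    return "".join(codons)


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def simulate_gene_models(
    cfg: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, str], pd.DataFrame]:
    """Gene models with a planted GC4-versus-exon-count slope.

    Returns ``(models, genome, truth)``; ``genome`` maps chromosome name
    to sequence.  Gene-level GC4 targets are
    ``intercept + slope * exon_count + Normal(0, noise)``, clipped to
    [0, 1] with a warning when infeasible.  Genes alternate strands; the
    first exon begins with a noncoding 5' UTR so exon rank 1 is counted
    from the transcript start, not the CDS start.
    """
    gc_ = cfg.genes
    rng = _child_rng(cfg.seed, "gene_models")
    chrom_parts: list[str] = []
    offset = 0
    models: list[GeneModel] = []
    truth_rows = []
    for i in range(1, gc_.n_genes + 1):
        n_exons = int(min(rng.geometric(gc_.exon_geometric_p), gc_.max_exons))
        target = gc_.gc4_intercept + gc_.gc4_slope_vs_exons * n_exons + rng.normal(
            0, gc_.gc4_noise_sd
        )
        if not 0.0 <= target <= 1.0:
            logger.warning("gene %d: GC4 target %.3f clipped into [0, 1]", i, target)
            target = float(np.clip(target, 0.0, 1.0))
        cds = _random_cds(rng, gc_.cds_codons, target)
        utr5 = _random_seq(rng, gc_.utr5_length)
        utr3 = _random_seq(rng, gc_.utr3_length)
        # split the CDS into n_exons pieces, each >= 3 nt
        if n_exons > 1:
            cuts = np.sort(
                rng.choice(np.arange(1, len(cds) // 3), size=n_exons - 1, replace=False)
            ) * 3
        else:
            cuts = np.array([], dtype=int)
        pieces = np.split(np.frombuffer(cds.encode(), dtype="S1"), cuts)
        cds_pieces = [p.tobytes().decode() for p in pieces]
        # assemble pre-mRNA in transcript orientation, tracking intervals
        strand = "+" if i % 2 else "-"
        seq_parts: list[str] = []
        exon_iv: list[tuple[int, int]] = []  # transcript-space, half-open
        cds_iv: list[tuple[int, int]] = []
        pos = 0

        def _append(s: str) -> tuple[int, int]:
            nonlocal pos
            seq_parts.append(s)
            iv = (pos, pos + len(s))
            pos += len(s)
            return iv

        for j, piece in enumerate(cds_pieces):
            exon_start = pos
            if j == 0:
                _append(utr5)
            civ = _append(piece)
            cds_iv.append(civ)
            if j == len(cds_pieces) - 1:
                _append(utr3)
            exon_iv.append((exon_start, pos))
            if j < len(cds_pieces) - 1:
                _append("GT" + _random_seq(rng, gc_.intron_length - 4) + "AG")
        pre_mrna = "".join(seq_parts)
        L = len(pre_mrna)
        if strand == "+":
            genomic = pre_mrna
            to_genomic = lambda iv: (offset + iv[0], offset + iv[1])
        else:
            genomic = _revcomp(pre_mrna)
            to_genomic = lambda iv: (offset + L - iv[1], offset + L - iv[0])
        models.append(
            GeneModel(
                gene_id=f"gene{i:04d}",
                transcript_id=f"tx{i:04d}",
                chrom=gc_.chrom,
                strand=strand,
                exons=[to_genomic(iv) for iv in exon_iv],
                cds_intervals=[to_genomic(iv) for iv in cds_iv],
            )
        )
        truth_rows.append(
            {"gene_id": f"gene{i:04d}", "exon_count": n_exons, "gc4_target": target}
        )
        chrom_parts.append(genomic)
        chrom_parts.append(_random_seq(rng, gc_.intergenic_gap))
        offset += L + gc_.intergenic_gap
    genome = {gc_.chrom: "".join(chrom_parts)}
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return models, genome, truth


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_expression(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression table with distinct planted GC4 coefficients per stratum.

    log2 expression = intercept_stratum + b_stratum * gc4 + Normal(0, sd),
    back-transformed to the measure scale; a configurable fraction of
    rows is zeroed to exercise the zero-removal rule.
    """
    ec = cfg.expression
    rng = _child_rng(cfg.seed, "expression")
    n = ec.n_transcripts
    ids = [f"txpt{i:05d}" for i in range(1, n + 1)]
    unspliced = rng.random(n) < ec.unspliced_fraction
    exon_count = np.where(unspliced, 1, rng.integers(2, 21, size=n))
    gc4 = rng.uniform(ec.gc4_low, ec.gc4_high, size=n)
    b = np.where(unspliced, ec.b_unspliced, ec.b_spliced)
    a = np.where(unspliced, ec.intercept_unspliced, ec.intercept_spliced)
    log2_expr = a + b * gc4 + rng.normal(0, ec.noise_sd, size=n)
    measure = np.exp2(log2_expr)
    zeroed = rng.random(n) < ec.zero_fraction
    measure = np.where(zeroed, 0.0, measure)
    table = pd.DataFrame(
        {
            "transcript_id": ids,
            "measure": measure,
            "exon_count": exon_count,
            "gc4": gc4,
        }
    )
    truth = pd.DataFrame(
        {
            "transcript_id": ids,
            "log2_expr_true": log2_expr,
            "spliced": ~unspliced,
            "zeroed": zeroed,
        }
    ).set_index("transcript_id")
    truth.attrs["b_spliced"] = ec.b_spliced
    truth.attrs["b_unspliced"] = ec.b_unspliced
    return table, truth


def simulate_decay(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exponential decay timecourse with multiplicative noise."""
    dc = cfg.decay
    rng = _child_rng(cfg.seed, "decay")
    t = np.asarray(dc.timepoints, dtype=float)
    eps = rng.normal(0, dc.noise_sd, size=len(t)) if dc.noise_sd > 0 else np.zeros(len(t))
    levels = dc.a * np.exp(-dc.k * t) * (1.0 + eps)
    levels = np.clip(levels, 1e-12, None)  # keep levels positive for log fits
    table = pd.DataFrame({"time": t, "level": levels})
    t_half = np.log(2) / dc.k if dc.k > 0 else np.inf
    truth = pd.DataFrame({"k": [dc.k], "t_half": [t_half]})
    return table, truth
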