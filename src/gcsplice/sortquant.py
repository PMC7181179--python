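"""Scores for pooled-reporter read-count matrices.

Three assays share one data layout (variants x ordered compartments):

* Flow-seq: cells FACS-sorted into 8 fluorescence bins; the fluorescence
  score of a variant is the read-weighted mean bin index
  ``sum_i i * n(i) / sum_i n(i)``.
* Nuclear/cytoplasmic fractionation: the relative cytoplasmic
  concentration RCC = n(cyto) / (n(cyto) + n(nuc)); 0 means fully
  nuclear, 1 fully cytoplasmic.
* Polysome pools (free RNP, monosome, light, heavy): ribosome density is
  the read-weighted mean pool index (1..4) and ribosome association the
  ratio of ribosome-bound to free reads.

Variants with fewer than ``min_reads`` raw reads summed across
compartments are flagged and left unscored (sampling-noise filter; the
filter always applies to raw, pre-normalization totals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinCountMatrix",
    "FLOWSEQ_BINS",
    "FRACTIONS",
    "POLYSOME_POOLS",
    "depth_normalize",
    "flowseq_score",
    "rcc",
    "ribosome_density",
    "ribosome_association",
    "average_replicates",
]

FLOWSEQ_BINS = tuple(f"bin{i}" for i in range(1, 9))
FRACTIONS = ("cyto", "nuc")
POLYSOME_POOLS = ("free", "mono", "light", "heavy")

DEFAULT_MIN_READS = 1000


@dataclass
class BinCountMatrix:
    """Read counts for variants (rows) across ordered compartments (columns).

    Compartments must be ordered by increasing fluorescence / ribosome
    load; the column order defines the bin indices 1..k.
    """

    counts: pd.DataFrame
    replicate_id: str = ""

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValueError("negative read counts")
        if not np.issubdtype(c.values.dtype, np.number):
            raise ValueError("counts must be numeric")
        self.counts = c.astype(float)

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @property
    def variant_ids(self) -> pd.Index:
        return self.counts.index


def depth_normalize(m: BinCountMatrix, mode: str = "per-compartment-total") -> BinCountMatrix:
    """Rescale compartment columns to equal totals (mean raw column sum).

    ``mode="none"`` returns the matrix unchanged.
    """
    if mode == "none":
        return m
    if mode != "per-compartment-total":
        raise ValueError(f"unknown normalization mode {mode!r}")
    sums = m.counts.sum(axis=0)
    empty = sums[sums == 0]
    if len(empty):
        raise ValueError(f"empty compartment column(s): {', '.join(empty.index)}")
    scaled = m.counts * (sums.mean() / sums)
    return BinCountMatrix(counts=scaled, replicate_id=m.replicate_id)


def _weighted_bin_mean(
    m: BinCountMatrix, n_bins: int, min_reads: int, normalize: bool
) -> pd.DataFrame:
    if len(m.compartments) != n_bins:
        raise ValueError(f"expected {n_bins} compartments, got {len(m.compartments)}")
    raw_totals = m.counts.sum(axis=1)
    work = depth_normalize(m) if normalize else m
    weights = np.arange(1, n_bins + 1)
    totals = work.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = (work.counts * weights).sum(axis=1) / totals
    passed = raw_totals >= min_reads
    score[~passed] = np.nan
    return pd.DataFrame(
        {
            "variant_id": m.variant_ids,
            "score": score.values,
            "total_reads": raw_totals.values,
            "passed_filter": passed.values,
        }
    ).set_index("variant_id")


def flowseq_score(
    m: BinCountMatrix,
    min_reads: int = DEFAULT_MIN_READS,
    normalize: bool = True,
) -> pd.DataFrame:
    """Read-weighted mean fluorescence-bin index per variant (8 bins).

    Columns are depth-normalized by default (bins were sorted to roughly
    equal cell numbers); the read filter applies to raw totals.
    """
    return _weighted_bin_mean(m, n_bins=8, min_reads=min_reads, normalize=normalize)


def rcc(m: BinCountMatrix, min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Relative cytoplasmic concentration n(cyto)/(n(cyto)+n(nuc))."""
    if len(m.compartments) != 2:
        raise ValueError("RCC needs exactly two compartments (cyto, nuc)")
    cyto = m.counts.iloc[:, 0]
    total = m.counts.sum(axis=1)
    passed = total >= min_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        score = cyto / total
    score[(total == 0) | ~passed] = np.nan
    return pd.DataFrame(
        {
            "variant_id": m.variant_ids,
            "score": score.values,
            "total_reads": total.values,
            "passed_filter": (passed & (total > 0)).values,
        }
    ).set_index("variant_id")


def ribosome_density(
    m: BinCountMatrix,
    min_reads: int = DEFAULT_MIN_READS,
    normalize: bool = False,
) -> pd.DataFrame:
    """Read-weighted mean polysome-pool index (free=1 .. heavy=4)."""
    return _weighted_bin_mean(m, n_bins=4, min_reads=min_reads, normalize=normalize)


def ribosome_association(
    m: BinCountMatrix, min_reads: int = DEFAULT_MIN_READS
) -> pd.DataFrame:
    """(monosome + light + heavy reads) / free-RNP reads per variant.

    Variants with zero free-RNP reads are flagged unbounded (no score).
    """
    if len(m.compartments) != 4:
        raise ValueError("ribosome association needs the 4 polysome pools")
    free = m.counts.iloc[:, 0]
    bound = m.counts.iloc[:, 1:].sum(axis=1)
    total = m.counts.sum(axis=1)
    passed = (total >= min_reads) & (free > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = bound / free
    score[~passed] = np.nan
    return pd.DataFrame(
        {
            "variant_id": m.variant_ids,
            "score": score.values,
            "total_reads": total.values,
            "passed_filter": passed.values,
        }
    ).set_index("variant_id")


def average_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean score across replicates, averaging passing replicates only.

    Returns score (mean over replicates that passed the read filter),
    ``n_replicates`` used per variant, and the combined pass flag
    (>=1 passing replicate).
    """
    if not tables:
        raise ValueError("no replicate tables")
    labels = [f"rep{i}" for i in range(len(tables))]
    scores = pd.concat(
        [t["score"].rename(lab) for t, lab in zip(tables, labels)], axis=1
    )
    passed = pd.concat(
        [t["passed_filter"].rename(lab) for t, lab in zip(tables, labels)], axis=1
    ).fillna(False)
    n = passed.sum(axis=1).astype(int)
    mean = scores.where(passed).mean(axis=1)
    return pd.DataFrame(
        {"score": mean, "n_replicates": n, "passed_filter": n > 0},
        index=scores.index,
    )
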