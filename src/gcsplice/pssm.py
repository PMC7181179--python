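"""Position-specific scoring matrices with exact null p-values.

A PSSM holds per-position nucleotide weights (counts or frequencies, in
A/C/G/T column order).  Offsets are scored additively in log2 odds against
a 0th-order background; the null score distribution is computed exactly by
convolving the per-position score distributions under the background, so a
"match" is any offset whose score has null p-value <= the chosen threshold
(FIMO-like semantics).  Scanning is forward-strand only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["PSSM", "scan_pssm", "POLY_A_PSSM", "SD_PSSM", "ARE_PSSM"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PSSM:
    """Per-position nucleotide weights plus background and pseudocount."""

    matrix: tuple[tuple[float, float, float, float], ...]  # positions x ACGT
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pseudocount: float = 0.1
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "matrix", tuple(tuple(float(x) for x in row) for row in self.matrix)
        )
        object.__setattr__(self, "background", tuple(float(x) for x in self.background))
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("matrix must be positions x 4 (A,C,G,T)")
        if (m < 0).any() or (m.sum(axis=1) <= 0).any():
            raise ValueError("each matrix row needs nonnegative weights, >=1 positive")
        bg = np.asarray(self.background, dtype=float)
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def log_odds(self) -> np.ndarray:
        """positions x 4 array of log2((f + pseudo)/(total + 4*pseudo)/bg)."""
        m = np.asarray(self.matrix, dtype=float)
        probs = (m + self.pseudocount) / (
            m.sum(axis=1, keepdims=True) + 4.0 * self.pseudocount
        )
        return np.log2(probs / np.asarray(self.background))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())


@lru_cache(maxsize=64)
def _null_distribution(pssm: PSSM) -> tuple[np.ndarray, np.ndarray]:
    """Exact null score distribution: (sorted unique scores, P(score >= s)).

    Convolves per-position distributions over the background; scores are
    rounded to 1e-9 when merging to keep float keys stable.
    """
    lo = pssm.log_odds
    bg = np.asarray(pssm.background)
    dist: dict[float, float] = {0.0: 1.0}
    for row in lo:
        nxt: dict[float, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = round(s + row[b], 9)
                nxt[key] = nxt.get(key, 0.0) + p * bg[b]
        dist = nxt
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    tail = probs[::-1].cumsum()[::-1]  # P(score >= s)
    return scores, tail


def score_pvalue(pssm: PSSM, score: float) -> float:
    """Exact P(null score >= score) under the background model."""
    scores, tail = _null_distribution(pssm)
    idx = np.searchsorted(scores, score - 1e-9, side="left")
    return float(tail[idx]) if idx < len(scores) else 0.0


def scan_pssm(
    seq: str, pssm: PSSM, p_threshold: float = 1e-4
) -> tuple[int, float]:
    """Scan a sequence; return (match count, best log-odds score).

    A match is an offset whose score's exact null p-value is at or below
    ``p_threshold``.  Ambiguous bases match nothing (the offset scores
    -inf).  Raises if the sequence is shorter than the motif.
    """
    s = seq.upper()
    L = len(pssm)
    if len(s) < L:
        raise ValueError(f"sequence length {len(s)} < motif length {L}")
    lo = pssm.log_odds
    idx = np.array([_BASE_INDEX.get(c, -1) for c in s])
    n_off = len(s) - L + 1
    offsets = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (offsets >= 0).all(axis=1)
    scores = np.full(n_off, -np.inf)
    if valid.any():
        rows = np.arange(L)
        scores[valid] = lo[rows, offsets[valid]].sum(axis=1)
    null_scores, tail = _null_distribution(pssm)
    # smallest achievable score whose tail probability <= threshold
    ok = tail <= p_threshold
    threshold_score = null_scores[ok][0] if ok.any() else np.inf
    count = int((scores >= threshold_score - 1e-9).sum())
    best = float(scores.max()) if n_off else -np.inf
    return count, best


def _one_hot(pattern: str) -> tuple[tuple[float, float, float, float], ...]:
    rows = []
    for c in pattern:
        row = [0.0, 0.0, 0.0, 0.0]
        row[_BASE_INDEX[c]] = 1.0
        rows.append(tuple(row))
    return tuple(rows)


#: Cryptic polyadenylation-signal matrix (positions x A,C,G,T).
POLY_A_PSSM = PSSM(
    matrix=(
        (47, 3, 0, 50),
        (18, 6, 9, 67),
        (53, 12, 12, 23),
        (59, 6, 0, 35),
        (70, 6, 6, 18),
    ),
    name="Poly_A",
)

#: Splice-donor-like matrix (positions x A,C,G,T).
SD_PSSM = PSSM(
    matrix=(
        (60, 13, 13, 14),
        (9, 3, 80, 7),
        (0, 0, 100, 0),
        (0, 0, 0, 100),
        (53, 3, 42, 3),
        (71, 8, 12, 9),
        (7, 6, 81, 6),
        (16, 17, 21, 46),
    ),
    name="SD_PSSM",
)

#: AU-rich element core motif ATTTA as a degenerate-free matrix.
ARE_PSSM = PSSM(matrix=_one_hot("ATTTA"), name="ARE")
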