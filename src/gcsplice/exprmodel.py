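"""Splicing-stratified regression of expression on GC4, with bootstrap
confidence ellipses, nuclear-export fractions, and decay half-lives.

Expression tables carry one row per transcript with a nonnegative measure
(platform units), an exon count (spliced = more than one exon), and GC4.
Measures of exactly zero are removed, then log2(measure + pseudocount)
is taken (export fractions, already bounded in [0, 1], are exempt from the
log transform).  Within each splicing stratum, the transformed measure is
regressed linearly on GC4; transcripts are then resampled with replacement
and both strata refit per replicate, and the joint cloud of (unspliced,
spliced) coefficients defines a 95% confidence ellipse.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PSEUDOCOUNT",
    "RegressionResult",
    "BootstrapEllipse",
    "DecayFit",
    "prepare_expression",
    "export_fraction",
    "regress_gc4",
    "bootstrap_ellipse",
    "fit_decay",
    "plot_ellipse",
]

DEFAULT_PSEUDOCOUNT = 0.0001


@dataclass
class RegressionResult:
    """OLS slope of log2 expression on GC4 within one splicing stratum."""

    stratum: str
    coefficient: float
    stderr: float
    intercept: float
    n: int


@dataclass
class BootstrapEllipse:
    """Joint bootstrap cloud of (unspliced, spliced) GC4 coefficients.

    The 95% region is the Mahalanobis-quantile ellipse of the replicate
    cloud: center at the cloud mean, shape from the cloud covariance,
    radius at the 95th percentile of replicate Mahalanobis distances (so
    the region encloses >=95% of replicates by construction).
    """

    point_unspliced: RegressionResult
    point_spliced: RegressionResult
    coeffs: np.ndarray  # n_boot x 2, columns (unspliced, spliced)
    center: np.ndarray
    cov: np.ndarray
    radius: float
    n_redrawn: int = 0

    def mahalanobis(self, point: np.ndarray) -> float:
        d = np.asarray(point, dtype=float) - self.center
        cov = self.cov + 1e-18 * np.eye(2)  # guard exact degeneracy
        return float(np.sqrt(d @ np.linalg.solve(cov, d)))

    def contains(self, point) -> bool:
        """Whether a (b_unspliced, b_spliced) pair lies in the 95% region."""
        return self.mahalanobis(np.asarray(point)) <= self.radius + 1e-12

    def boundary(self, n_points: int = 200) -> np.ndarray:
        """Points on the ellipse boundary (for plotting)."""
        vals, vecs = np.linalg.eigh(self.cov)
        vals = np.clip(vals, 0.0, None)
        theta = np.linspace(0, 2 * np.pi, n_points)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        return (self.center[:, None] + self.radius * vecs @ (np.sqrt(vals)[:, None] * circle)).T


@dataclass
class DecayFit:
    """Exponential decay a*e^(k*t) fitted log-linearly."""

    a: float
    k: float
    t_half: float
    rss: float

    @property
    def decaying(self) -> bool:
        return self.k < 0


def prepare_expression(
    records: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    measure_col: str = "measure",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Drop raw-zero measures, then log2-transform with a pseudocount.

    Zeros are removed *before* the pseudocount is added (removal would be
    a no-op the other way around).  Export-fraction measures should be
    passed with ``log_transform=False``; they keep their raw scale.
    Adds a boolean ``spliced`` column (exon_count > 1) when an
    ``exon_count`` column is present.
    """
    out = records.copy()
    m = out[measure_col].to_numpy(dtype=float)
    if (m < 0).any():
        raise ValueError("negative expression measures")
    zeros = m == 0
    if log_transform:
        if zeros.any():
            logger.info("removed %d zero-expression records", int(zeros.sum()))
            out = out[~zeros].copy()
        out[measure_col] = np.log2(out[measure_col].to_numpy(dtype=float) + pseudocount)
    if "exon_count" in out.columns and "spliced" not in out.columns:
        out["spliced"] = out["exon_count"] > 1
    return out


def export_fraction(nuc_tpm, cyto_tpm):
    """Fraction of transcript abundance in the nuclear fraction.

    nuc/(nuc+cyto); the complement of the cytoplasmic-concentration score
    RCC computed on the same quantities.  Both-zero entries yield ``nan``.
    """
    nuc = np.asarray(nuc_tpm, dtype=float)
    cyto = np.asarray(cyto_tpm, dtype=float)
    if (nuc < 0).any() or (cyto < 0).any():
        raise ValueError("negative TPM values")
    total = nuc + cyto
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, nuc / total, np.nan)
    return frac if frac.ndim else float(frac)


def _stratum_frame(records: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if "spliced" not in records.columns:
        records = records.assign(spliced=records["exon_count"] > 1)
    if stratum == "spliced":
        return records[records["spliced"]]
    if stratum == "unspliced":
        return records[~records["spliced"]]
    raise ValueError(f"stratum must be 'spliced' or 'unspliced', got {stratum!r}")


def regress_gc4(
    records: pd.DataFrame, stratum: str, measure_col: str = "measure"
) -> RegressionResult:
    """OLS of the (already transformed) measure on GC4 within a stratum."""
    sub = _stratum_frame(records, stratum)
    if len(sub) < 3:
        raise ValueError(f"stratum {stratum!r} has {len(sub)} records; need >=3")
    x = sub["gc4"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"stratum {stratum!r} has constant GC4; singular fit")
    fit = sm.OLS(sub[measure_col].to_numpy(dtype=float), sm.add_constant(x)).fit()
    return RegressionResult(
        stratum=stratum,
        coefficient=float(fit.params[1]),
        stderr=float(fit.bse[1]),
        intercept=float(fit.params[0]),
        n=len(sub),
    )


def _slopes(x, y, w):
    """Weighted OLS slopes, vectorized over bootstrap replicates (rows).

    ``w`` is a 0/1 stratum mask per replicate; returns nan where a
    replicate's stratum is degenerate (fewer than 3 rows or constant x).
    """
    n = w.sum(axis=1)
    sx = (w * x).sum(axis=1)
    sy = (w * y).sum(axis=1)
    sxx = (w * x * x).sum(axis=1)
    sxy = (w * x * y).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = sxx - sx * sx / n
        slope = (sxy - sx * sy / n) / denom
    slope[(n < 3) | ~np.isfinite(slope) | (denom <= 0)] = np.nan
    return slope


def bootstrap_ellipse(
    records: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    measure_col: str = "measure",
    quantile: float = 0.95,
) -> BootstrapEllipse:
    """Bootstrap the stratified GC4 regression and build the 95% ellipse.

    Transcript rows are resampled with replacement ``n_boot`` times; both
    strata are refit on each resample, giving a joint (unspliced, spliced)
    coefficient cloud.  Replicates in which a stratum degenerates (fewer
    than 3 rows, or constant GC4) are redrawn and counted.  Deterministic
    given ``seed``.
    """
    point_u = regress_gc4(records, "unspliced", measure_col)
    point_s = regress_gc4(records, "spliced", measure_col)
    df = records if "spliced" in records.columns else records.assign(
        spliced=records["exon_count"] > 1
    )
    x = df["gc4"].to_numpy(dtype=float)
    y = df[measure_col].to_numpy(dtype=float)
    spliced = df["spliced"].to_numpy(dtype=bool)
    n = len(df)
    rng = np.random.default_rng(seed)

    coeffs = np.empty((n_boot, 2))
    filled = 0
    redrawn = 0
    while filled < n_boot:
        batch = min(n_boot - filled, 256)
        idx = rng.integers(0, n, size=(batch, n))
        xb, yb, sb = x[idx], y[idx], spliced[idx]
        bu = _slopes(xb, yb, (~sb).astype(float))
        bs = _slopes(xb, yb, sb.astype(float))
        ok = np.isfinite(bu) & np.isfinite(bs)
        redrawn += int((~ok).sum())
        k = int(ok.sum())
        coeffs[filled : filled + k, 0] = bu[ok]
        coeffs[filled : filled + k, 1] = bs[ok]
        filled += k
    if redrawn:
        logger.info("redrew %d degenerate bootstrap replicates", redrawn)

    center = coeffs.mean(axis=0)
    cov = np.cov(coeffs, rowvar=False)
    cov = np.atleast_2d(cov)
    d = coeffs - center
    guarded = cov + 1e-18 * np.eye(2)
    md = np.sqrt(np.einsum("ij,ij->i", d @ np.linalg.inv(guarded), d))
    radius = float(np.quantile(md, quantile))
    return BootstrapEllipse(
        point_unspliced=point_u,
        point_spliced=point_s,
        coeffs=coeffs,
        center=center,
        cov=cov,
        radius=radius,
        n_redrawn=redrawn,
    )


def fit_decay(timepoints, levels) -> DecayFit:
    """Fit a*e^(k*t) by least squares on log levels; t_half = ln2/|k|.

    Requires >=3 timepoints and strictly positive levels.  Non-decaying
    series (k >= 0) are flagged with an infinite half-life.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(levels, dtype=float)
    if len(t) != len(y):
        raise ValueError("timepoints and levels differ in length")
    if len(t) < 3:
        raise ValueError(f"need >=3 timepoints, got {len(t)}")
    if (y <= 0).any():
        raise ValueError("levels must be strictly positive for a log-linear fit")
    if np.ptp(t) == 0:
        raise ValueError("timepoints are all identical")
    k, loga = np.polyfit(t, np.log(y), 1)
    a = math.exp(loga)
    fitted = a * np.exp(k * t)
    rss = float(((y - fitted) ** 2).sum())
    t_half = math.log(2) / abs(k) if k < 0 else math.inf
    return DecayFit(a=float(a), k=float(k), t_half=float(t_half), rss=rss)


def plot_ellipse(result: BootstrapEllipse, ax=None, **kwargs):
    """Draw the bootstrap cloud and 95% ellipse (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.coeffs[:, 0], result.coeffs[:, 1], s=4, alpha=0.3, label="bootstrap")
    b = result.boundary()
    ax.plot(b[:, 0], b[:, 1], color="black", label="95% region", **kwargs)
    ax.plot(
        result.point_unspliced.coefficient,
        result.point_spliced.coefficient,
        "r*",
        markersize=10,
        label="point fit",
    )
    lim = ax.get_xlim() + ax.get_ylim()
    lo, hi = min(lim), max(lim)
    ax.plot([lo, hi], [lo, hi], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("GC4 coefficient, unspliced")
    ax.set_ylabel("GC4 coefficient, spliced")
    ax.legend()
    return ax
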