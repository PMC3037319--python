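"""Regional differential statistics on tiling-array probe intensities.

The analysis follows the standard two-colour/one-colour tiling workflow for
region-level differential signal: log2-transform the raw hybridization
intensities, quantile-normalize all samples of an assay to a common empirical
distribution, then, for each miRNA, fit an ordinary least squares model to the
probes overlapping the +/-500 bp window around the locus center:

    log2 intensity ~ probe + condition

The condition coefficient is the average LNCaP-minus-PrEC change across the
region after adjusting for probe-specific affinity, and its t-statistic is
thresholded at |t| >= 2 to call a region significantly changed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import IntensityMatrix
from .loci import MirnaLocus, ProbeFeature

logger = logging.getLogger(__name__)

#: half-width of the regional-analysis window around the locus center (bp)
REGION_HALF_WIDTH = 500

#: |t| threshold for calling a region significantly changed
T_CUTOFF = 2.0


@dataclass
class RegionStat:
    """Per-locus, per-assay output of the regional linear model."""

    locus_id: str
    assay: str
    n_probes: int
    effect: float       # log2 LNCaP - PrEC, probe-adjusted
    se: float
    t_statistic: float
    df: int
    significant: bool = False
    direction: str = "none"     # up / down / none
    fitted: bool = True


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log2 of raw intensities; rejects nonpositive values."""
    if matrix.log2:
        raise ValueError("matrix is already log2-scaled")
    if (matrix.values.values <= 0).any():
        raise ValueError("cannot log2-transform nonpositive intensities")
    return matrix.copy_with(np.log2(matrix.values), log2=True)


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Force every sample column onto the shared mean empirical distribution.

    Each column's sorted values are replaced by the across-sample mean of
    sorted values; within-sample ranks are preserved and ties receive the
    mean of their tied quantile values.
    """
    values = matrix.values
    if values.shape[1] < 2:
        logger.warning("quantile normalization with a single sample is the identity")
        return matrix.copy_with(values.copy(), log2=matrix.log2)
    arr = values.to_numpy(dtype=float)
    n = arr.shape[0]
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="mergesort")
        col_sorted = arr[order, j]
        i = 0
        while i < n:
            k = i + 1
            while k < n and col_sorted[k] == col_sorted[i]:
                k += 1
            # tied values all receive the mean of their quantile values
            out[order[i:k], j] = ref[i:k].mean()
            i = k
    res = pd.DataFrame(out, index=values.index, columns=values.columns)
    return matrix.copy_with(res, log2=matrix.log2)


def select_region_probes(
    locus: MirnaLocus,
    panel: Sequence[ProbeFeature],
    half_width: int = REGION_HALF_WIDTH,
) -> list[ProbeFeature]:
    """Probes assigned to the locus whose interval overlaps the analysis window.

    The window is [center - half_width, center + half_width); any overlap
    counts (a probe straddling the boundary is included).
    """
    lo = locus.center - half_width
    hi = locus.center + half_width
    return [
        p for p in panel
        if p.locus_id == locus.id and p.start < hi and p.end > lo
    ]


def fit_region_model(
    values: pd.DataFrame, condition: Sequence[int], locus_id: str, assay: str
) -> RegionStat:
    """OLS fit of log2 intensity on probe and condition indicators.

    ``values`` is the region's probes x samples block; ``condition`` labels
    each sample 0 (PrEC) or 1 (LNCaP). The effect is the condition
    coefficient, df = n_obs - n_probes - 1. Probes observed in only one
    condition are dropped (rank deficiency); fewer than 2 usable probes
    yields an unfitted result.
    """
    cond = np.asarray(condition, dtype=float)
    if set(np.unique(cond)) - {0.0, 1.0}:
        raise ValueError("condition labels must be 0/1")
    block = values
    # a probe with data in a single condition makes probe and condition
    # columns collinear for that row-block; drop it
    usable = []
    for pid in block.index:
        row = block.loc[pid].to_numpy(dtype=float)
        if np.isfinite(row[cond == 0]).any() and np.isfinite(row[cond == 1]).any():
            usable.append(pid)
        else:
            logger.warning("probe %s observed in one condition only; dropped", pid)
    block = block.loc[usable]

    n_probes = block.shape[0]
    if n_probes < 2 or len(set(cond)) < 2:
        return RegionStat(
            locus_id=locus_id, assay=assay, n_probes=n_probes,
            effect=np.nan, se=np.nan, t_statistic=np.nan, df=0, fitted=False,
        )

    y = block.to_numpy(dtype=float).ravel()               # probe-major
    n_samples = block.shape[1]
    probe_idx = np.repeat(np.arange(n_probes), n_samples)
    cond_rep = np.tile(cond, n_probes)
    keep = np.isfinite(y)
    y, probe_idx, cond_rep = y[keep], probe_idx[keep], cond_rep[keep]

    # design: intercept + (n_probes - 1) probe dummies + condition
    X = np.zeros((y.size, n_probes + 1))
    X[:, 0] = 1.0
    for k in range(1, n_probes):
        X[probe_idx == k, k] = 1.0
    X[:, n_probes] = cond_rep

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = y.size - (n_probes + 1)
    if df <= 0:
        return RegionStat(
            locus_id=locus_id, assay=assay, n_probes=n_probes,
            effect=float(beta[-1]), se=np.nan, t_statistic=np.nan, df=0,
            fitted=False,
        )
    rss = float(resid @ resid)
    # treat numerically-zero residuals (perfect fit) as degenerate: t = 0
    if rss <= 1e-20 * max(1.0, float(y @ y)):
        rss = 0.0
    s2 = rss / df
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(max(s2, 0.0) * XtX_inv[-1, -1]))
    effect = float(beta[-1])
    # degenerate zero-residual fits report t = 0, not +/-inf
    t = effect / se if se > 0 else 0.0
    return RegionStat(
        locus_id=locus_id, assay=assay, n_probes=n_probes,
        effect=effect, se=se, t_statistic=float(t), df=df,
    )


def call_regions(
    region_stats: Iterable[RegionStat], cutoff: float = T_CUTOFF
) -> list[RegionStat]:
    """Set significance (|t| >= cutoff, boundary inclusive) and direction."""
    out = []
    for rs in region_stats:
        if rs.fitted and abs(rs.t_statistic) >= cutoff:
            rs.significant = True
            rs.direction = "up" if rs.effect > 0 else "down"
        else:
            rs.significant = False
            rs.direction = "none"
        out.append(rs)
    return out


def analyze_assay(
    matrix: IntensityMatrix,
    loci: Sequence[MirnaLocus],
    assay: str,
    half_width: int = REGION_HALF_WIDTH,
    cutoff: float = T_CUTOFF,
    normalize: bool = True,
) -> list[RegionStat]:
    """Full per-assay pipeline: log2 -> quantile normalize -> regional fits.

    Only untreated samples of the given assay enter the PrEC-vs-LNCaP fit.
    """
    cols = [
        s.sample_id for s in matrix.samples
        if s.assay == assay and s.treatment == "none"
    ]
    if not cols:
        raise ValueError(f"no untreated samples for assay {assay!r}")
    mat = matrix if matrix.log2 else log2_transform(matrix)
    if normalize:
        mat = quantile_normalize(mat)
    sub = mat.values[cols]
    meta = {s.sample_id: s for s in matrix.samples}
    condition = [1 if meta[c].cell == "LNCaP" else 0 for c in cols]

    by_locus: dict[str, list[ProbeFeature]] = {}
    for p in matrix.probes:
        by_locus.setdefault(p.locus_id, []).append(p)
    stats_out = []
    for locus in loci:
        region = select_region_probes(locus, by_locus.get(locus.id, ()), half_width)
        ids = [p.probe_id for p in region]
        block = sub.loc[[i for i in ids if i in sub.index]]
        stats_out.append(fit_region_model(block, condition, locus.id, assay))
    return call_regions(stats_out, cutoff)


def region_stats_from_frame(df: pd.DataFrame) -> list[RegionStat]:
    """Inverse of :func:`region_stats_frame` for reloading saved tables."""
    return [
        RegionStat(
            locus_id=str(r.locus_id), assay=str(r.assay),
            n_probes=int(r.n_probes), effect=float(r.effect), se=float(r.se),
            t_statistic=float(r.t), df=int(r.df),
            significant=bool(r.significant), direction=str(r.direction),
        )
        for r in df.itertuples()
    ]


def region_stats_frame(region_stats: Iterable[RegionStat]) -> pd.DataFrame:
    """Flatten RegionStats to the tabular output layout."""
    return pd.DataFrame(
        [
            {
                "locus_id": r.locus_id, "assay": r.assay, "n_probes": r.n_probes,
                "effect": r.effect, "se": r.se, "t": r.t_statistic, "df": r.df,
                "significant": r.significant, "direction": r.direction,
            }
            for r in region_stats
        ]
    )
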