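"""qRT-PCR relative quantification and differential expression.

Two workflows share the ΔCt core:

* TLDA mature-miRNA panels — per-target ΔCt versus a reference small RNA
  (RNU48), contrasts between conditions tested with a moderated t-test whose
  per-target variance is shrunk toward an ensemble prior by empirical Bayes
  (prior estimated by the method of moments on log sample variances), no
  multiple-testing correction; a target is differentially expressed at
  p < 0.05 and fold change >= 1.5 (either direction).
* pri-miRNA singleplex assays — 18S-normalized 2^-ΔCt group summaries with a
  pooled two-sided Student's t-test on ΔCt values.

Tests run on ΔCt values, not 2^-ΔCt quantities: Ct is the measurement scale
and is closer to normal. One log2 unit of expression equals -1 cycle at
amplification efficiency 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CtTable, SampleMeta

P_CUTOFF = 0.05
FC_CUTOFF = 1.5

#: contrast name -> ((cell, treatment) of group A, of group B); fold changes
#: express A relative to B
CONTRASTS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "LvP": (("LNCaP", "none"), ("PrEC", "none")),
    "Lv5Aza": (("LNCaP", "aza"), ("LNCaP", "none")),
    "Pv5Aza": (("PrEC", "aza"), ("PrEC", "none")),
}


@dataclass
class ContrastResult:
    """Per-target qPCR differential result for one contrast."""

    target_id: str
    contrast: str
    fold_change: float      # linear, group A relative to group B
    log2fc: float
    p_value: float
    significant: bool = False
    direction: str = "none"
    method: str = "moderated_t"
    censored: bool = False
    p_bh: float = float("nan")


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes variance prior: d0 prior df (may be inf), s0² scale."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or self.s0_sq <= 0:
            raise ValueError("require d0 >= 0 and s0_sq > 0")


# ---------------------------------------------------------------------------
# ΔCt core

def delta_ct(table: CtTable, reference: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ΔCt(target, sample) = Ct(target) - Ct(reference), reference row dropped.

    Returns (ΔCt frame, censored mask). The reference must amplify in every
    sample; a censored reference well is an error.
    """
    if reference not in table.ct.index:
        raise ValueError(f"reference target {reference!r} absent from table")
    if table.censored.loc[reference].any():
        raise ValueError(f"reference {reference!r} is censored in some sample")
    ref = table.ct.loc[reference]
    dct = table.ct.sub(ref, axis=1).drop(index=reference)
    censored = table.censored.drop(index=reference)
    return dct, censored


def relative_quantity(dct: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative expression 2^-ΔCt."""
    return 2.0 ** (-dct)


def contrast_fold_change(
    dct: pd.DataFrame | pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> tuple[pd.Series, pd.Series] | tuple[float, float]:
    """Fold change of group A relative to group B from ΔCt values.

    log2fc = -(mean ΔCt_A - mean ΔCt_B); fold_change = 2^log2fc.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both contrast groups must be non-empty")
    if isinstance(dct, pd.Series):
        log2fc = -(dct[list(group_a)].mean() - dct[list(group_b)].mean())
        return 2.0 ** log2fc, log2fc
    log2fc = -(
        dct[list(group_a)].mean(axis=1) - dct[list(group_b)].mean(axis=1)
    )
    return 2.0 ** log2fc, log2fc


# ---------------------------------------------------------------------------
# empirical-Bayes moderation

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, monotone)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_moderation_prior(
    s2: Sequence[float], df: Sequence[float] | float
) -> ModerationPrior:
    """Method-of-moments fit of the scaled-F prior on sample variances.

    With z_g = log s_g², e_g = z_g - ψ(d_g/2) + log(d_g/2) has mean
    log s0² + ψ(d0/2) - log(d0/2) and excess variance ψ'(d0/2) beyond the
    sampling term ψ'(d_g/2); matching both moments yields (d0, s0²). When the
    observed variances show no excess dispersion, d0 = ∞ and s0² is the
    bias-corrected geometric mean.
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    ok = (df_arr >= 1) & np.isfinite(s2)
    s2, df_arr = s2[ok], df_arr[ok]
    if s2.size < 10:
        raise ValueError("need >= 10 targets with at least 1 residual df")
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero; degenerate ensemble")
    # guard exact zeros (noiseless fixtures) with the smallest positive variance
    floor = s2[s2 > 0].min() * 1e-12
    z = np.log(np.maximum(s2, floor))
    e = z - special.digamma(df_arr / 2.0) + np.log(df_arr / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    excess = e_var - float(np.mean(special.polygamma(1, df_arr / 2.0)))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(
            e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    a: Sequence[float], b: Sequence[float], prior: ModerationPrior
) -> tuple[float, float, float]:
    """Moderated two-sample t of mean(a) - mean(b); returns (t, df, p).

    The pooled sample variance is shrunk toward the prior:
    s̃² = (d0·s0² + d_g·s_g²)/(d0 + d_g); the statistic is referred to a
    t-distribution with d0 + d_g degrees of freedom (normal when d0 = ∞).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    d_g = n_a + n_b - 2
    if d_g < 1 and prior.d0 == 0:
        raise ValueError("no residual df and no prior df: t undefined")
    s_g2 = 0.0
    if d_g >= 1:
        s_g2 = (
            ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        ) / d_g
    if math.isinf(prior.d0):
        s_tilde2 = prior.s0_sq
        df_total = math.inf
    else:
        s_tilde2 = (prior.d0 * prior.s0_sq + d_g * s_g2) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g
    denom = math.sqrt(s_tilde2 * (1.0 / n_a + 1.0 / n_b))
    diff = float(a.mean() - b.mean())
    t = diff / denom if denom > 0 else 0.0
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        p = 2.0 * stats.t.sf(abs(t), df_total)
    return float(t), float(df_total), float(p)


def student_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Classical pooled two-sample t (two-sided); returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Student's t needs >= 2 observations per group")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(a.size + b.size - 2), float(res.pvalue)


# ---------------------------------------------------------------------------
# TLDA mature-miRNA analysis

def _group_columns(samples: Iterable[SampleMeta], cell: str, treatment: str) -> list[str]:
    return [
        s.sample_id for s in samples if s.cell == cell and s.treatment == treatment
    ]


def mature_contrasts(
    table: CtTable,
    reference: str = "RNU48",
    contrasts: Sequence[str] = ("LvP", "Lv5Aza", "Pv5Aza"),
    p_cut: float = P_CUTOFF,
    fc_cut: float = FC_CUTOFF,
    aza_fc_cut: float = 1.0,
) -> list[ContrastResult]:
    """Run the TLDA panel: ΔCt, moderated t per contrast, differential calls.

    The moderation prior is estimated per contrast over the whole panel. The
    LvP contrast uses the p-and-fold-change rule; 5-Aza contrasts use p < 0.05
    with fold change > ``aza_fc_cut`` (default 1: any induction).
    """
    dct, censored = delta_ct(table, reference)
    results: list[ContrastResult] = []
    for name in contrasts:
        (cell_a, trt_a), (cell_b, trt_b) = CONTRASTS[name]
        cols_a = _group_columns(table.samples, cell_a, trt_a)
        cols_b = _group_columns(table.samples, cell_b, trt_b)
        if not cols_a or not cols_b:
            raise ValueError(f"contrast {name}: missing samples")
        sub_a = dct[cols_a].to_numpy(dtype=float)
        sub_b = dct[cols_b].to_numpy(dtype=float)
        d_g = sub_a.shape[1] + sub_b.shape[1] - 2
        s2 = (
            ((sub_a - sub_a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            + ((sub_b - sub_b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        ) / max(d_g, 1)
        prior = estimate_moderation_prior(s2, d_g)

        fc, log2fc = contrast_fold_change(dct, cols_a, cols_b)
        contrast_results = []
        for i, target in enumerate(dct.index):
            t, df_t, p = moderated_t(sub_a[i], sub_b[i], prior)
            contrast_results.append(
                ContrastResult(
                    target_id=str(target), contrast=name,
                    fold_change=float(fc.iloc[i]), log2fc=float(log2fc.iloc[i]),
                    p_value=p, method="moderated_t",
                    censored=bool(
                        censored.loc[target, cols_a + cols_b].any()
                    ),
                )
            )
        if name == "LvP":
            contrast_results = call_mature_differential(
                contrast_results, p_cut=p_cut, fc_cut=fc_cut
            )
        else:
            contrast_results = call_mature_differential(
                contrast_results, p_cut=p_cut, fc_cut=aza_fc_cut
            )
        _attach_bh(contrast_results)
        results.extend(contrast_results)
    return results


def call_mature_differential(
    results: Iterable[ContrastResult],
    p_cut: float = P_CUTOFF,
    fc_cut: float = FC_CUTOFF,
) -> list[ContrastResult]:
    """Flag targets with p < p_cut and fold change beyond fc_cut either way."""
    out = []
    for r in results:
        if fc_cut > 1.0:
            # inclusive boundary: >= fc_cut up, or <= 1/fc_cut down
            passes_fc = r.fold_change >= fc_cut or r.fold_change <= 1.0 / fc_cut
        else:
            # fc_cut = 1: any change in either direction away from unity
            passes_fc = r.fold_change != 1.0
        r.significant = bool(r.p_value < p_cut and passes_fc)
        r.direction = (
            ("up" if r.fold_change > 1.0 else "down") if r.significant else "none"
        )
        out.append(r)
    return out


def _attach_bh(results: Sequence[ContrastResult]) -> None:
    """Benjamini-Hochberg adjusted p-values, informational only."""
    p = np.array([r.p_value for r in results])
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    for r, q in zip(results, adj):
        r.p_bh = float(q)


# ---------------------------------------------------------------------------
# pri-miRNA quantification

def pri_quantification(
    table: CtTable,
    reference: str = "18S",
    contrasts: Sequence[str] = ("LvP", "Lv5Aza", "Pv5Aza"),
) -> pd.DataFrame:
    """18S-normalized pri-miRNA expression with Student's t per contrast.

    Returns one row per (target, contrast) with group means and SDs of
    2^-ΔCt and the two-sided pooled-t p-value computed on ΔCt values.
    """
    dct, _ = delta_ct(table, reference)
    rq = relative_quantity(dct)
    rows = []
    for name in contrasts:
        (cell_a, trt_a), (cell_b, trt_b) = CONTRASTS[name]
        cols_a = _group_columns(table.samples, cell_a, trt_a)
        cols_b = _group_columns(table.samples, cell_b, trt_b)
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise ValueError(f"contrast {name}: need >= 2 replicates per group")
        for target in dct.index:
            a = dct.loc[target, cols_a].to_numpy(dtype=float)
            b = dct.loc[target, cols_b].to_numpy(dtype=float)
            t, df_t, p = student_t(a, b)
            if math.isnan(p):  # zero pooled variance: treated as no difference
                t, p = 0.0, 1.0
            fc, log2fc = contrast_fold_change(dct.loc[target], cols_a, cols_b)
            rows.append(
                {
                    "target_id": target, "contrast": name,
                    "mean_a": rq.loc[target, cols_a].mean(),
                    "sd_a": rq.loc[target, cols_a].std(ddof=1),
                    "mean_b": rq.loc[target, cols_b].mean(),
                    "sd_b": rq.loc[target, cols_b].std(ddof=1),
                    "fold_change": fc, "log2fc": log2fc,
                    "t": t, "p_value": p,
                    "significant": bool(p < P_CUTOFF),
                }
            )
    return pd.DataFrame(rows)


def contrasts_from_frame(df: pd.DataFrame) -> list[ContrastResult]:
    """Inverse of :func:`contrasts_frame` for reloading saved tables."""
    return [
        ContrastResult(
            target_id=str(r.target_id), contrast=str(r.contrast),
            fold_change=float(r.fold_change), log2fc=float(r.log2fc),
            p_value=float(r.p_value), significant=bool(r.significant),
            direction=str(r.direction), method=str(r.method),
            censored=bool(r.censored), p_bh=float(r.p_bh),
        )
        for r in df.itertuples()
    ]


def contrasts_frame(results: Iterable[ContrastResult]) -> pd.DataFrame:
    """Flatten ContrastResults to the tabular output layout."""
    return pd.DataFrame(
        [
            {
                "target_id": r.target_id, "contrast": r.contrast,
                "fold_change": r.fold_change, "log2fc": r.log2fc,
                "p_value": r.p_value, "p_bh": r.p_bh,
                "significant": r.significant, "direction": r.direction,
                "method": r.method, "censored": r.censored,
            }
            for r in results
        ]
    )
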