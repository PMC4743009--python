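"""Differential junction usage between SF3B1-mutant and wild-type samples.

A deliberately transparent negative-binomial pipeline: median-of-ratios size
factors, per-junction method-of-moments dispersion (var = mu + alpha*mu^2,
floored), a Wald test on the difference of group log-means fitted by Newton
scoring with size-factor offsets, and Benjamini-Hochberg adjustment.
Junctions are called differential at padj <= 1e-5 and |log2FC| >= 1 by
default. This is not a DESeq2 reimplementation — no shrinkage, no Cook's
filtering — so calls on real data will differ in detail from pipelines
built on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .junction_io import SampleSheet

__all__ = [
    "DiffResult",
    "size_factors",
    "estimate_dispersion",
    "nb_test",
    "bh_adjust",
    "select_differential",
    "run_diffsplice",
    "DEFAULT_P_THRESHOLD",
    "DEFAULT_LFC_THRESHOLD",
]

DEFAULT_P_THRESHOLD = 1e-5
DEFAULT_LFC_THRESHOLD = 1.0
MIN_DISPERSION = 1e-8
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DiffResult:
    junction_id: str
    base_mean: float
    log2_fold_change: float | None
    p_value: float | None
    p_adjusted: float | None = None
    selected: bool = False

    @property
    def testable(self) -> bool:
        return self.p_value is not None


def size_factors(counts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios normalisation factors, one per sample (column).

    Each sample's factor is the median, over junctions positive in every
    sample, of that junction's count divided by its across-sample geometric
    mean. Falls back to total-count ratios (scaled to geometric mean 1) with
    a warning when no junction is positive everywhere.
    """
    m = np.asarray(counts, dtype=float)
    if m.ndim == 1:
        m = m[None, :]
    if m.shape[1] == 1:
        return np.ones(1)
    all_pos = np.all(m > 0, axis=1)
    if not np.any(all_pos):
        warnings.warn(
            "no junction with positive counts in all samples; using "
            "total-count size factors",
            stacklevel=2,
        )
        totals = m.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("cannot normalise: a sample has zero total count")
        return totals / np.exp(np.mean(np.log(totals)))
    sub = m[all_pos]
    geo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    factors = np.median(sub / geo, axis=0)
    # normalised to geometric mean 1 so the estimator is exactly idempotent
    return factors / np.exp(np.mean(np.log(factors)))


def estimate_dispersion(y: np.ndarray, is_mut: np.ndarray, sf: np.ndarray) -> np.ndarray:
    """Per-junction method-of-moments NB dispersion, pooled over both groups.

    On normalised counts q = y/s, within-group Var(q) ~= mu * mean(1/s) +
    alpha * mu^2; the excess over the Poisson part, averaged over groups with
    df weights, gives alpha. Floored at ``MIN_DISPERSION``.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    q = y / sf
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for mask in (is_mut, ~is_mut):
        n_g = int(mask.sum())
        if n_g < 2:
            continue
        qg = q[:, mask]
        m = qg.mean(axis=1)
        v = qg.var(axis=1, ddof=1)
        inv_s = np.mean(1.0 / sf[mask])
        df = n_g - 1
        num += df * (v - m * inv_s)
        den += df * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.maximum(alpha, MIN_DISPERSION)


def _fit_log_means(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray):
    """NB log-mean MLE per junction for one group, via Newton scoring.

    Model: y_ij ~ NB(mu_ij = s_j * exp(beta_i), alpha_i). Returns (beta,
    expected information). Groups with zero total count get a half-count
    continuity estimate and the information evaluated there.
    """
    y = np.atleast_2d(y)
    totals = y.sum(axis=1)
    s_tot = sf.sum()
    beta = np.log(np.maximum(totals, PSEUDOCOUNT) / s_tot)
    for _ in range(100):
        mu = sf[None, :] * np.exp(beta)[:, None]
        w = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / w).sum(axis=1)
        fisher = (mu / w).sum(axis=1)
        step = score / np.maximum(fisher, 1e-300)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = sf[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return beta, info


def _wald_table(y: np.ndarray, is_mut: np.ndarray, sf: np.ndarray):
    """Vectorised NB Wald test of MUT vs WT for a count matrix."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    alpha = estimate_dispersion(y, is_mut, sf)
    b_mut, i_mut = _fit_log_means(y[:, is_mut], sf[is_mut], alpha)
    b_wt, i_wt = _fit_log_means(y[:, ~is_mut], sf[~is_mut], alpha)
    se = np.sqrt(1.0 / np.maximum(i_mut, 1e-300) + 1.0 / np.maximum(i_wt, 1e-300))
    z = (b_mut - b_wt) / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    q = y / sf
    m_mut = q[:, is_mut].mean(axis=1)
    m_wt = q[:, ~is_mut].mean(axis=1)
    lfc = np.log2((m_mut + PSEUDOCOUNT) / (m_wt + PSEUDOCOUNT))
    base_mean = q.mean(axis=1)
    untestable = y.sum(axis=1) == 0
    p = np.where(untestable, np.nan, p)
    lfc = np.where(untestable, np.nan, lfc)
    return base_mean, lfc, p, alpha


def nb_test(
    counts: np.ndarray, is_mut: np.ndarray, sf: np.ndarray | None = None
) -> tuple[float | None, float | None]:
    """(log2 fold change, Wald p) for a single junction; (None, None) if untestable."""
    counts = np.asarray(counts, dtype=float)
    is_mut = np.asarray(is_mut, dtype=bool)
    if is_mut.all() or (~is_mut).all():
        raise ValueError("both groups must be non-empty")
    if sf is None:
        sf = np.ones(counts.size)
    _, lfc, p, _ = _wald_table(counts[None, :], is_mut, np.asarray(sf, dtype=float))
    if np.isnan(p[0]):
        return None, None
    return float(lfc[0]), float(p[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries stay NaN and are
    excluded from the number of tests."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def select_differential(
    results: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Flag junctions with padj <= p_threshold and |log2FC| >= lfc_threshold."""
    res = results.copy()
    res["selected"] = (
        (res["padj"] <= p_threshold)
        & (res["log2fc"].abs() >= lfc_threshold)
    ).fillna(False)
    return res


def run_diffsplice(
    junctions: pd.DataFrame,
    sheet: SampleSheet,
    min_total: int = 10,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Full differential table for a junction count frame.

    ``junctions`` must carry ``id, chrom, start, end, strand`` plus one count
    column per sample in sheet order. Junctions with total count below
    ``min_total`` are excluded from testing (and from the BH denominator) but
    kept in the table with NaN statistics.
    """
    count_cols = list(sheet.ids)
    y = junctions[count_cols].to_numpy(dtype=float)
    sf = size_factors(y)
    is_mut = sheet.is_mut()

    tested = y.sum(axis=1) >= min_total
    base_mean = np.full(len(junctions), np.nan)
    lfc = np.full(len(junctions), np.nan)
    p = np.full(len(junctions), np.nan)
    alpha = np.full(len(junctions), np.nan)
    if tested.any():
        bm, l, pv, a = _wald_table(y[tested], is_mut, sf)
        base_mean[tested], lfc[tested], p[tested], alpha[tested] = bm, l, pv, a

    res = junctions[["id", "chrom", "start", "end", "strand"]].copy()
    res["base_mean"] = base_mean
    res["log2fc"] = lfc
    res["pvalue"] = p
    res["dispersion"] = alpha
    res["padj"] = bh_adjust(p)
    res["tested"] = ~np.isnan(p)
    return select_differential(res, p_threshold, lfc_threshold)
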