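"""Normalization and two-group negative-binomial differential expression.

A deliberately transparent stand-in for heavyweight DE frameworks: size
factors by median-of-ratios, per-transcript method-of-moments dispersion,
an NB log-link GLM fit by IRLS with the dispersion held fixed, and Wald
p-values. Externally computed DE tables can be supplied to bypass the stage.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from methlink.io_formats import CountMatrix

logger = logging.getLogger(__name__)

MIN_DISPERSION = 1e-8
IRLS_MAX_ITER = 100
IRLS_TOL = 1e-8

DEFAULT_PADJ_CUT = 0.05
DEFAULT_LFC_CUT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive factor per sample).

    Ratios are taken against the geometric mean across samples, restricted
    to transcripts positive in every sample; if none exists, falls back per
    sample to transcripts positive in that sample, with a warning.
    """
    x = counts.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if all_positive.any():
        ref = x[all_positive]
        geomean = np.exp(np.log(ref).mean(axis=1))
        factors = np.median(ref / geomean[:, None], axis=0)
    else:
        warnings.warn(
            "no transcript with all-positive counts; falling back to "
            "per-sample positive transcripts for size factors"
        )
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log(x), np.nan)
        geomean = np.exp(np.nanmean(logx, axis=1))
        factors = np.empty(x.shape[1])
        for j in range(x.shape[1]):
            r = x[:, j] / geomean
            r = r[(x[:, j] > 0) & np.isfinite(r)]
            if r.size == 0:
                raise ValueError(f"sample {counts.columns[j]!r} has no positive counts")
            factors[j] = np.median(r)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_matrix(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1) per cell — a variance-tamed monotone transform."""
    if factors is None:
        factors = size_factors(counts)
    factors = factors.loc[counts.columns]
    return np.log2(counts / factors.to_numpy()[None, :] + 1.0)


def _mom_dispersion(q: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion per transcript from normalized counts q."""
    mu = q.mean(axis=1)
    s2 = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / np.square(mu)
    alpha = np.where(np.isfinite(alpha), alpha, MIN_DISPERSION)
    return np.maximum(alpha, MIN_DISPERSION)


def nb_wald_de(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    padj_cut: float = DEFAULT_PADJ_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
) -> pd.DataFrame:
    """Two-group NB Wald differential expression, case vs control.

    Per transcript: dispersion alpha = max((s^2 - mu)/mu^2, 1e-8) on
    size-factor-normalized counts; NB log-link GLM on [intercept, group]
    with log(size factor) offset, fit by IRLS with alpha fixed; Wald
    p-value from the standard normal on coefficient/SE. All-zero
    transcripts get log2fc = 0, p = 1; non-converged fits are flagged and
    get p = 1.

    Returns columns: base_mean, log2fc, se, wald_stat, pvalue, padj,
    de_flag, converged.
    """
    counts = cm.counts
    if factors is None:
        factors = size_factors(counts)
    factors = factors.loc[counts.columns]
    y = counts.to_numpy(dtype=float)  # (T, S)
    sf = factors.to_numpy(dtype=float)
    g = (cm.groups.to_numpy() == "case").astype(float)  # (S,)

    q = y / sf[None, :]
    alpha = _mom_dispersion(q)
    base_mean = q.mean(axis=1)

    nonzero = y.sum(axis=1) > 0
    T, S = y.shape
    beta = np.zeros((T, 2))
    se1 = np.full(T, np.nan)
    converged = np.ones(T, dtype=bool)

    if nonzero.any():
        b, s, conv = _irls_two_group(y[nonzero], sf, g, alpha[nonzero])
        beta[nonzero] = b
        se1[nonzero] = s
        converged[nonzero] = conv

    ln2 = np.log(2.0)
    log2fc = np.where(nonzero, beta[:, 1] / ln2, 0.0)
    se_log2 = np.where(nonzero, se1 / ln2, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(nonzero & converged, beta[:, 1] / se1, 0.0)
    from scipy import stats

    pvalue = np.where(
        nonzero & converged,
        2.0 * stats.norm.sf(np.abs(wald)),
        1.0,
    )
    n_bad = int((~converged).sum())
    if n_bad:
        warnings.warn(f"IRLS failed to converge for {n_bad} transcript(s); p set to 1")
    padj = bh_adjust(pvalue)
    de_flag = (padj < padj_cut) & (np.abs(log2fc) > lfc_cut)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se_log2,
            "wald_stat": wald,
            "pvalue": pvalue,
            "padj": padj,
            "de_flag": de_flag,
            "converged": converged,
        },
        index=counts.index.rename("transcript_id"),
    )


def _irls_two_group(
    y: np.ndarray, sf: np.ndarray, g: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for NB GLM with design [1, group] and log(sf) offset.

    Returns (coefficients (T, 2), SE of the group coefficient, converged flags).
    """
    T = y.shape[0]
    offset = np.log(sf)[None, :]  # (1, S)
    eps = 1e-8
    # start from (floored) group means of normalized counts
    q = y / sf[None, :]
    mean_ctrl = np.maximum(q[:, g == 0].mean(axis=1), eps)
    mean_case = np.maximum(q[:, g == 1].mean(axis=1), eps)
    b0 = np.log(mean_ctrl)
    b1 = np.log(mean_case) - np.log(mean_ctrl)
    converged = np.zeros(T, dtype=bool)

    for _ in range(IRLS_MAX_ITER):
        eta = offset + b0[:, None] + b1[:, None] * g[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)  # NB working weights, alpha fixed
        z = (eta - offset) + (y - mu) / mu
        sw = w.sum(axis=1)
        swg = w @ g
        swgg = swg  # g is 0/1 so g^2 = g
        swz = (w * z).sum(axis=1)
        swgz = (w * z * g[None, :]).sum(axis=1)
        det = sw * swgg - swg * swg
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        b0_new = (swgg * swz - swg * swgz) / det
        b1_new = (sw * swgz - swg * swz) / det
        step = np.maximum(np.abs(b0_new - b0), np.abs(b1_new - b1))
        bad = ~np.isfinite(b0_new) | ~np.isfinite(b1_new)
        b0 = np.where(bad, b0, b0_new)
        b1 = np.where(bad, b1, b1_new)
        newly = np.isfinite(step) & (step < IRLS_TOL) & ~bad
        converged |= newly
        if converged.all():
            break

    eta = np.clip(offset + b0[:, None] + b1[:, None] * g[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    sw = w.sum(axis=1)
    swg = w @ g
    det = sw * swg - swg * swg
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = sw / det  # [ (X'WX)^-1 ]_{11}
    se1 = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    converged &= np.isfinite(se1)
    return np.column_stack([b0, b1]), se1, converged


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    adj_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def select_de(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    padj_cut: float = DEFAULT_PADJ_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
) -> dict[str, pd.DataFrame]:
    """Partition DE transcripts (strict padj < cut AND |log2fc| > cut) by biotype.

    ``annotation`` is the frame from
    :func:`methlink.io_formats.annotation_frame`, indexed by transcript_id.
    Returns {"lncRNA": frame, "protein_coding": frame} of DE transcripts
    joined to their coordinates.
    """
    selected = results[(results["padj"] < padj_cut) & (results["log2fc"].abs() > lfc_cut)]
    joined = selected.join(annotation, how="inner")
    missing = len(selected) - len(joined)
    if missing:
        warnings.warn(f"{missing} DE transcript(s) absent from annotation; dropped")
    return {
        "lncRNA": joined[joined["biotype"] == "lncRNA"].copy(),
        "protein_coding": joined[joined["biotype"] == "protein_coding"].copy(),
    }
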