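"""Windowed correlation integration: DMR -> lncRNA -> protein-coding target.

Discovery rule: a lncRNA within 20 kb of a DMR whose normalized expression
is negatively correlated (p < 0.05) with the DMR's per-sample mean
methylation is "DMR-regulated"; a DE protein-coding transcript within
500 kb of such a lncRNA whose expression is negatively correlated
(p < 0.05) with it is a candidate cis target. Output is the triplet table.

Correlation p-values are used raw, matching the discovery rule; BH-adjusted
values are reported as extra columns but never filtered on. Distances are
measured between full feature spans (TSS anchoring available via
``anchor="tss"``), strand-blind, and undefined across chromosomes.
"""

from __future__ import annotations

import logging
import warnings
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from methlink.io_formats import GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_LNC_WINDOW = 20_000
DEFAULT_PROT_WINDOW = 500_000
CORR_P_CUT = 0.05


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bp between two intervals; 0 if they overlap, None across chromosomes."""
    if a.chrom != b.chrom:
        return None
    gap = max(a.start, b.start) - min(a.end, b.end)
    return max(gap, 0)


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float, int]:
    """Correlation between two sample vectors with pairwise NaN removal.

    Returns (r, two-sided p, n used). Pearson p comes from the t
    distribution with n-2 df; |r| = 1 gives p = 0. Raises ValueError for
    n < 3 or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >=3 paired samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p), n


def _feature_intervals(df: pd.DataFrame, anchor: str) -> pd.DataFrame:
    """chrom/start/end columns, optionally collapsed to the TSS point."""
    out = df[["chrom", "start", "end", "strand"]].copy() if "strand" in df else df[["chrom", "start", "end"]].copy()
    if anchor == "tss":
        tss = np.where(out.get("strand", "+") == "-", out["end"] - 1, out["start"])
        out["start"] = tss
        out["end"] = tss + 1
    return out


def window_pairs(
    left: pd.DataFrame,
    right: pd.DataFrame,
    window: int,
    anchor: str = "span",
) -> pd.DataFrame:
    """All (left, right) index pairs with interval distance <= window.

    Both frames need chrom/start/end columns (0-based half-open). Returns
    columns left_id, right_id, distance_bp. Vectorized per chromosome.
    """
    li = _feature_intervals(left, anchor)
    rows = []
    for chrom, lsub in li.groupby("chrom", sort=False):
        rsub = right[right["chrom"] == chrom]
        if rsub.empty:
            continue
        ls = lsub["start"].to_numpy()[:, None]
        le = lsub["end"].to_numpy()[:, None]
        rs = rsub["start"].to_numpy()[None, :]
        re_ = rsub["end"].to_numpy()[None, :]
        gap = np.maximum(np.maximum(ls, rs) - np.minimum(le, re_), 0)
        ii, jj = np.nonzero(gap <= window)
        for i, j in zip(ii, jj):
            rows.append((lsub.index[i], rsub.index[j], int(gap[i, j])))
    return pd.DataFrame(rows, columns=["left_id", "right_id", "distance_bp"])


def pair_lnc_dmr(
    de_lnc: pd.DataFrame,
    dmrs: pd.DataFrame,
    window: int = DEFAULT_LNC_WINDOW,
    anchor: str = "span",
) -> pd.DataFrame:
    """Candidate (lncRNA, DMR) pairs within the cis window.

    ``de_lnc`` is indexed by transcript_id with chrom/start/end columns;
    ``dmrs`` has chrom/start/end/dmr_id. A lncRNA may pair with several
    DMRs and vice versa.
    """
    if de_lnc.empty:
        warnings.warn("empty DE lncRNA set; no DMR-lncRNA pairs")
        return pd.DataFrame(columns=["lnc_transcript_id", "dmr_id", "distance_bp"])
    pairs = window_pairs(de_lnc, dmrs.set_index("dmr_id"), window, anchor=anchor)
    return pairs.rename(columns={"left_id": "lnc_transcript_id", "right_id": "dmr_id"})


def dmr_regulated_lncrnas(
    pairs: pd.DataFrame,
    beta: pd.DataFrame,
    normalized: pd.DataFrame,
    de_results: pd.DataFrame,
    p_cut: float = CORR_P_CUT,
    method: str = "pearson",
) -> pd.DataFrame:
    """Filter candidate pairs to negative methylation-expression correlations.

    Keeps pairs with r < 0 AND p < ``p_cut``; the lncRNA up/down direction
    in the case group comes from its DE log2 fold change. Samples missing
    the region beta are dropped pairwise. Adds a BH-adjusted p column
    (reported, not filtered on).
    """
    common = [s for s in beta.columns if s in normalized.columns]
    rows = []
    for pr in pairs.itertuples(index=False):
        if pr.dmr_id not in beta.index or pr.lnc_transcript_id not in normalized.index:
            continue
        x = beta.loc[pr.dmr_id, common].to_numpy(dtype=float)
        y = normalized.loc[pr.lnc_transcript_id, common].to_numpy(dtype=float)
        try:
            r, p, n = correlate(x, y, method=method)
        except ValueError as exc:
            warnings.warn(
                f"pair ({pr.dmr_id}, {pr.lnc_transcript_id}) excluded: {exc}"
            )
            continue
        rows.append((pr.dmr_id, pr.lnc_transcript_id, pr.distance_bp, r, p, n))
    out = pd.DataFrame(
        rows,
        columns=["dmr_id", "lnc_transcript_id", "distance_bp", "r_meth_lnc",
                 "p_meth_lnc", "n_samples"],
    )
    if out.empty:
        out["padj_meth_lnc"] = []
        out["lnc_de_direction"] = []
        return out
    from methlink.expression import bh_adjust

    out["padj_meth_lnc"] = bh_adjust(out["p_meth_lnc"].to_numpy())
    out = out[(out["r_meth_lnc"] < 0) & (out["p_meth_lnc"] < p_cut)].reset_index(drop=True)
    lfc = de_results["log2fc"]
    out["lnc_de_direction"] = np.where(
        lfc.reindex(out["lnc_transcript_id"]).to_numpy() > 0, "up", "down"
    )
    return out


def pair_lnc_protein(
    dmr_regulated: pd.DataFrame,
    lnc_annotation: pd.DataFrame,
    de_prot: pd.DataFrame,
    window: int = DEFAULT_PROT_WINDOW,
    anchor: str = "span",
) -> pd.DataFrame:
    """Candidate (lncRNA, protein) pairs within 500 kb of DMR-regulated lncRNAs."""
    lnc_ids = dmr_regulated["lnc_transcript_id"].unique()
    lnc = lnc_annotation.loc[[t for t in lnc_ids if t in lnc_annotation.index]]
    if lnc.empty or de_prot.empty:
        if de_prot.empty:
            warnings.warn("empty DE protein-coding set; no lncRNA-protein pairs")
        return pd.DataFrame(columns=["lnc_transcript_id", "prot_transcript_id", "distance_bp"])
    pairs = window_pairs(lnc, de_prot, window, anchor=anchor)
    return pairs.rename(
        columns={"left_id": "lnc_transcript_id", "right_id": "prot_transcript_id"}
    )


def lnc_protein_targets(
    candidates: pd.DataFrame,
    dmr_regulated: pd.DataFrame,
    normalized: pd.DataFrame,
    p_cut: float = CORR_P_CUT,
    method: str = "pearson",
) -> pd.DataFrame:
    """Emit the triplet table: negative lncRNA-protein correlations joined to DMRs.

    Each surviving (lncRNA, protein) pair is joined back to every DMR that
    regulates the lncRNA, yielding one row per
    (DMR, lncRNA, protein) with both correlations, p-values and distances.
    """
    rows = []
    for pr in candidates.itertuples(index=False):
        if pr.lnc_transcript_id not in normalized.index or pr.prot_transcript_id not in normalized.index:
            continue
        x = normalized.loc[pr.lnc_transcript_id].to_numpy(dtype=float)
        y = normalized.loc[pr.prot_transcript_id].to_numpy(dtype=float)
        try:
            r, p, n = correlate(x, y, method=method)
        except ValueError as exc:
            warnings.warn(
                f"pair ({pr.lnc_transcript_id}, {pr.prot_transcript_id}) excluded: {exc}"
            )
            continue
        rows.append((pr.lnc_transcript_id, pr.prot_transcript_id, pr.distance_bp, r, p, n))
    corr = pd.DataFrame(
        rows,
        columns=["lnc_transcript_id", "prot_transcript_id", "dist_lnc_prot",
                 "r_lnc_prot", "p_lnc_prot", "n_samples_prot"],
    )
    if corr.empty:
        return _empty_triplets()
    from methlink.expression import bh_adjust

    corr["padj_lnc_prot"] = bh_adjust(corr["p_lnc_prot"].to_numpy())
    corr = corr[(corr["r_lnc_prot"] < 0) & (corr["p_lnc_prot"] < p_cut)]
    if corr.empty:
        return _empty_triplets()
    trip = dmr_regulated.merge(corr, on="lnc_transcript_id", how="inner")
    trip = trip.rename(columns={"distance_bp": "dist_dmr_lnc"})
    cols = ["dmr_id", "lnc_transcript_id", "prot_transcript_id",
            "lnc_de_direction", "r_meth_lnc", "p_meth_lnc",
            "r_lnc_prot", "p_lnc_prot", "dist_dmr_lnc", "dist_lnc_prot",
            "padj_meth_lnc", "padj_lnc_prot"]
    return trip[cols].reset_index(drop=True)


def _empty_triplets() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["dmr_id", "lnc_transcript_id", "prot_transcript_id",
                 "lnc_de_direction", "r_meth_lnc", "p_meth_lnc",
                 "r_lnc_prot", "p_lnc_prot", "dist_dmr_lnc", "dist_lnc_prot",
                 "padj_meth_lnc", "padj_lnc_prot"]
    )


def attach_dmr_directions(triplets: pd.DataFrame, dmrs: pd.DataFrame) -> pd.DataFrame:
    """Add the hyper/hypo direction of each triplet's DMR."""
    out = triplets.merge(
        dmrs[["dmr_id", "direction"]].rename(columns={"direction": "dmr_direction"}),
        on="dmr_id",
        how="left",
    )
    cols = list(triplets.columns)
    cols.insert(1, "dmr_direction")
    return out[cols]


def audit_triplets(
    triplets: pd.DataFrame,
    lnc_window: int = DEFAULT_LNC_WINDOW,
    prot_window: int = DEFAULT_PROT_WINDOW,
    p_cut: float = CORR_P_CUT,
) -> None:
    """Assert every emitted triplet satisfies the discovery invariants."""
    if triplets.empty:
        return
    checks = {
        "r_meth_lnc < 0": (triplets["r_meth_lnc"] < 0).all(),
        f"p_meth_lnc < {p_cut}": (triplets["p_meth_lnc"] < p_cut).all(),
        "r_lnc_prot < 0": (triplets["r_lnc_prot"] < 0).all(),
        f"p_lnc_prot < {p_cut}": (triplets["p_lnc_prot"] < p_cut).all(),
        f"dist_dmr_lnc <= {lnc_window}": (triplets["dist_dmr_lnc"] <= lnc_window).all(),
        f"dist_lnc_prot <= {prot_window}": (triplets["dist_lnc_prot"] <= prot_window).all(),
    }
    failed = [name for name, ok in checks.items() if not ok]
    if failed:
        raise AssertionError("triplet invariant(s) violated: " + "; ".join(failed))


def region_report(
    dmrs: pd.DataFrame,
    triplets: pd.DataFrame,
    annotation: pd.DataFrame,
    cpg_islands: pd.DataFrame | None = None,
    tss: pd.DataFrame | None = None,
    flank: int = DEFAULT_PROT_WINDOW,
) -> pd.DataFrame:
    """Tabular per-region report: features within ``flank`` of each triplet DMR.

    One row per (DMR, feature); feature kinds are dmr, lncRNA, protein_coding,
    cpg_island and tss. The tabular analog of a genome-browser region figure.
    """
    rows = []
    used = dmrs[dmrs["dmr_id"].isin(triplets["dmr_id"])] if not triplets.empty else dmrs.iloc[:0]
    for dmr in used.itertuples(index=False):
        rows.append((dmr.dmr_id, "dmr", dmr.dmr_id, dmr.chrom, dmr.start, dmr.end, 0))
        window = GenomicInterval(dmr.chrom, max(dmr.start - flank, 0), dmr.end + flank)
        near = annotation[
            (annotation["chrom"] == dmr.chrom)
            & (annotation["end"] > window.start)
            & (annotation["start"] < window.end)
        ]
        for tid, feat in near.iterrows():
            kind = feat["biotype"] if feat["biotype"] in ("lncRNA", "protein_coding") else "other"
            dist = interval_distance(
                GenomicInterval(dmr.chrom, dmr.start, dmr.end),
                GenomicInterval(feat["chrom"], feat["start"], feat["end"]),
            )
            rows.append((dmr.dmr_id, kind, tid, feat["chrom"], feat["start"], feat["end"], dist))
        for name, track in (("cpg_island", cpg_islands), ("tss", tss)):
            if track is None:
                continue
            sub = track[
                (track["chrom"] == dmr.chrom)
                & (track["end"] > window.start)
                & (track["start"] < window.end)
            ]
            for _, feat in sub.iterrows():
                dist = interval_distance(
                    GenomicInterval(dmr.chrom, dmr.start, dmr.end),
                    GenomicInterval(feat["chrom"], feat["start"], feat["end"]),
                )
                rows.append((dmr.dmr_id, name, feat.get("name", name), feat["chrom"],
                             feat["start"], feat["end"], dist))
    return pd.DataFrame(
        rows,
        columns=["dmr_id", "feature_kind", "feature_id", "chrom", "start", "end",
                 "distance_to_dmr"],
    )
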