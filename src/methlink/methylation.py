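"""Coverage filtering, simplified DMR calling and per-region methylation summaries.

The DMR caller here is a deliberately simple, fully specified substitute for
smoothing-based callers: per-CpG group differences are smoothed with a
running mean over k neighboring CpGs, candidate regions are maximal
same-sign runs above a cutoff, and significance comes from a genome-wide
max-statistic label-permutation null with BH-adjusted q-values. Externally
called DMRs can be supplied as a BED file to bypass this stage entirely.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from methlink.io_formats import CytosineTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_COV = 6
DEFAULT_MIN_FRAC = 0.5
DEFAULT_MIN_CPGS = 5
DEFAULT_MAX_GAP = 1000
DEFAULT_CUTOFF = 0.1
DEFAULT_N_PERM = 100
DEFAULT_SMOOTH_K = 5
Q_SIGNIFICANT = 0.05


@dataclass
class SiteMatrix:
    """Multi-sample CpG site matrix.

    ``sites`` has columns chrom, pos (1-based), sorted by (chrom, pos);
    ``meth`` and ``cov`` are (n_sites, n_samples) arrays aligned to
    ``sample_ids``. Entries zeroed by the coverage filter have cov == 0 and
    are treated as missing in all beta computations.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    cov: np.ndarray
    sample_ids: list[str]
    groups: np.ndarray  # "case"/"control" per sample

    @property
    def case_mask(self) -> np.ndarray:
        return self.groups == "case"

    def beta(self) -> np.ndarray:
        """Per-site per-sample methylation fraction; NaN where cov == 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(self.cov > 0, self.meth / np.maximum(self.cov, 1), np.nan)
        return b


def combine_samples(
    tables: Sequence[CytosineTable], labels: Mapping[str, str]
) -> SiteMatrix:
    """Stack per-sample cytosine tables onto the union of (chrom, pos) sites."""
    if not tables:
        raise ValueError("no cytosine tables supplied")
    for t in tables:
        if t.sample_id not in labels:
            raise ValueError(f"sample {t.sample_id!r} missing from labels")
    frames = []
    for t in tables:
        df = t.data[["chrom", "pos", "meth", "unmeth"]].copy()
        df["sample"] = t.sample_id
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    long["cov"] = long["meth"] + long["unmeth"]
    meth_w = long.pivot_table(index=["chrom", "pos"], columns="sample",
                              values="meth", fill_value=0, aggfunc="sum")
    cov_w = long.pivot_table(index=["chrom", "pos"], columns="sample",
                             values="cov", fill_value=0, aggfunc="sum")
    sample_ids = [t.sample_id for t in tables]
    meth_w = meth_w.reindex(columns=sample_ids, fill_value=0).sort_index()
    cov_w = cov_w.reindex(columns=sample_ids, fill_value=0).sort_index()
    sites = meth_w.index.to_frame(index=False)
    groups = np.array([labels[s] for s in sample_ids])
    n_case = int((groups == "case").sum())
    n_ctrl = int((groups == "control").sum())
    if n_case < 2 or n_ctrl < 2:
        raise ValueError(f"need >=2 samples per group, got case={n_case}, control={n_ctrl}")
    return SiteMatrix(
        sites=sites,
        meth=meth_w.to_numpy(dtype=np.int64),
        cov=cov_w.to_numpy(dtype=np.int64),
        sample_ids=sample_ids,
        groups=groups,
    )


def filter_cpg_coverage(
    tables: Sequence[CytosineTable],
    labels: Mapping[str, str],
    min_cov: int = DEFAULT_MIN_COV,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> SiteMatrix:
    """Zero sub-coverage observations and drop sites under-covered in either group.

    Per site, samples with coverage < ``min_cov`` have their counts zeroed
    (treated as missing downstream). A site is retained iff the fraction of
    samples with coverage >= ``min_cov`` is >= ``min_frac`` in the case
    group AND in the control group.
    """
    sm = combine_samples(tables, labels)
    ok = sm.cov >= min_cov
    case = sm.case_mask
    frac_case = ok[:, case].mean(axis=1)
    frac_ctrl = ok[:, ~case].mean(axis=1)
    keep = (frac_case >= min_frac) & (frac_ctrl >= min_frac)
    if not keep.any():
        raise ValueError(
            f"no CpG sites survive the {min_cov}x/{min_frac:.0%} coverage filter; "
            "consider lowering --min-cov or --min-frac"
        )
    meth = np.where(ok, sm.meth, 0)[keep]
    cov = np.where(ok, sm.cov, 0)[keep]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("coverage filter dropped %d/%d sites", n_dropped, len(keep))
    return SiteMatrix(
        sites=sm.sites.loc[keep].reset_index(drop=True),
        meth=meth,
        cov=cov,
        sample_ids=sm.sample_ids,
        groups=sm.groups,
    )


def write_site_matrix(sm: SiteMatrix, path) -> None:
    """Persist a SiteMatrix as wide TSV (meth_<sample>, cov_<sample> columns)."""
    df = sm.sites.copy()
    for j, s in enumerate(sm.sample_ids):
        df[f"meth_{s}"] = sm.meth[:, j]
    for j, s in enumerate(sm.sample_ids):
        df[f"cov_{s}"] = sm.cov[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_site_matrix(path, labels: Mapping[str, str]) -> SiteMatrix:
    df = pd.read_csv(path, sep="\t")
    sample_ids = [c[len("meth_"):] for c in df.columns if c.startswith("meth_")]
    meth = df[[f"meth_{s}" for s in sample_ids]].to_numpy(dtype=np.int64)
    cov = df[[f"cov_{s}" for s in sample_ids]].to_numpy(dtype=np.int64)
    groups = np.array([labels[s] for s in sample_ids])
    return SiteMatrix(
        sites=df[["chrom", "pos"]].copy(), meth=meth, cov=cov,
        sample_ids=sample_ids, groups=groups,
    )


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def _smooth_running_mean(values: np.ndarray, chrom_codes: np.ndarray, k: int) -> np.ndarray:
    """Centered running mean of window k over CpG index, per chromosome.

    Windows are truncated at chromosome edges (mean over available sites).
    """
    out = np.empty_like(values, dtype=float)
    kernel = np.ones(k)
    for code in np.unique(chrom_codes):
        idx = np.where(chrom_codes == code)[0]
        x = values[idx]
        sums = np.convolve(x, kernel, mode="same")
        counts = np.convolve(np.ones_like(x), kernel, mode="same")
        out[idx] = sums / counts
    return out


def _group_diff(beta: np.ndarray, case: np.ndarray) -> np.ndarray:
    """Per-site mean(case beta) - mean(control beta), NaN-aware."""
    filled = np.nan_to_num(beta)
    present = ~np.isnan(beta)
    case_f = case.astype(float)
    ctrl_f = (~case).astype(float)
    sum_case = filled @ case_f
    n_case = present @ case_f
    sum_ctrl = filled @ ctrl_f
    n_ctrl = present @ ctrl_f
    with np.errstate(divide="ignore", invalid="ignore"):
        d = sum_case / n_case - sum_ctrl / n_ctrl
    return d


def _candidate_regions(
    d_smooth: np.ndarray,
    chrom_codes: np.ndarray,
    pos: np.ndarray,
    weights: np.ndarray,
    min_cpgs: int,
    max_gap: int,
    cutoff: float,
    d_raw: np.ndarray | None = None,
) -> pd.DataFrame:
    """Maximal same-sign runs of CpGs with |smoothed difference| > cutoff.

    Runs break at chromosome changes, sign changes and inter-CpG gaps
    greater than max_gap; runs shorter than min_cpgs are discarded.
    Region stat = coverage-weighted mean smoothed difference over the run.
    When ``d_raw`` is given, run edges are trimmed to sites whose raw
    difference also clears the cutoff with the run's sign — smoothing
    bleeds signal into flanking background CpGs and would otherwise
    inflate region boundaries.
    """
    finite = np.isfinite(d_smooth)
    mask = finite & (np.abs(d_smooth) > cutoff)
    if not mask.any():
        return pd.DataFrame(
            columns=["chrom_code", "start_idx", "end_idx", "n_cpgs", "stat"]
        )
    sign = np.sign(d_smooth)
    prev_ok = np.zeros_like(mask)
    prev_ok[1:] = (
        mask[:-1]
        & (chrom_codes[1:] == chrom_codes[:-1])
        & (sign[1:] == sign[:-1])
        & ((pos[1:] - pos[:-1]) <= max_gap)
    )
    starts = mask & ~prev_ok
    run_id = np.cumsum(starts) - 1
    run_id = np.where(mask, run_id, -1)
    contrib = weights * d_smooth
    n_runs = int(starts.sum())
    idx = np.arange(len(mask))
    sel = run_id >= 0
    rid = run_id[sel]
    # stat = coverage-weighted mean smoothed difference over the run; the
    # area-normalized form keeps short and long regions on one scale so the
    # genome-wide max-statistic null does not systematically bury small DMRs
    stat_num = np.bincount(rid, weights=contrib[sel], minlength=n_runs)
    stat_den = np.bincount(rid, weights=weights[sel], minlength=n_runs)
    stat = stat_num / np.maximum(stat_den, 1e-300)
    n_cpgs = np.bincount(rid, minlength=n_runs)
    # first/last site index per run (runs are contiguous so min/max suffice)
    first = np.full(n_runs, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(first, rid, idx[sel])
    last = np.full(n_runs, -1, dtype=np.int64)
    np.maximum.at(last, rid, idx[sel])
    if d_raw is not None:
        first, last, n_cpgs, stat = _trim_runs(
            first, last, d_smooth, d_raw, weights, cutoff
        )
    df = pd.DataFrame(
        {
            "chrom_code": chrom_codes[first],
            "start_idx": first,
            "end_idx": last,
            "n_cpgs": n_cpgs,
            "stat": stat,
        }
    )
    return df[df["n_cpgs"] >= min_cpgs].reset_index(drop=True)


def _trim_runs(
    first: np.ndarray,
    last: np.ndarray,
    d_smooth: np.ndarray,
    d_raw: np.ndarray,
    weights: np.ndarray,
    cutoff: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Shrink each run to its core of raw-signal sites and restate its stat."""
    f_out = first.copy()
    l_out = last.copy()
    n_out = np.zeros_like(first)
    s_out = np.zeros(len(first))
    for i, (f, l) in enumerate(zip(first, last)):
        run_sign = np.sign(d_smooth[f])
        core = run_sign * d_raw[f : l + 1] > cutoff
        if core.any():
            lo = f + int(np.argmax(core))
            hi = f + len(core) - 1 - int(np.argmax(core[::-1]))
        else:  # smoothing-only run; keep as is
            lo, hi = f, l
        f_out[i], l_out[i] = lo, hi
        n_out[i] = hi - lo + 1
        w = weights[lo : hi + 1]
        s_out[i] = float(np.sum(w * d_smooth[lo : hi + 1]) / max(np.sum(w), 1e-300))
    return f_out, l_out, n_out, s_out


def call_dmrs(
    sm: SiteMatrix,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    max_gap: int = DEFAULT_MAX_GAP,
    cutoff: float = DEFAULT_CUTOFF,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
    smooth_k: int = DEFAULT_SMOOTH_K,
) -> pd.DataFrame:
    """Call DMRs from a coverage-filtered site matrix.

    Returns a DataFrame with columns chrom, start, end (0-based half-open),
    dmr_id, n_cpgs, stat, pvalue, qvalue, direction, significant. P-values
    come from a genome-wide max-|stat| permutation null with +1 smoothing;
    q-values are Benjamini-Hochberg over the candidate regions.
    """
    from methlink.expression import bh_adjust

    if rng is None:
        rng = np.random.default_rng()
    case = sm.case_mask
    n_case, n_ctrl = int(case.sum()), int((~case).sum())
    n_distinct = math.comb(n_case + n_ctrl, n_case)
    if n_distinct < 10:
        raise ValueError(
            f"only {n_distinct} distinct group-label permutations possible; "
            "groups too small for a permutation test"
        )

    chroms = sm.sites["chrom"].to_numpy()
    chrom_codes = pd.factorize(chroms)[0]
    pos = sm.sites["pos"].to_numpy()
    beta = sm.beta()
    weights = sm.cov.sum(axis=1).astype(float)

    def regions_for(mask: np.ndarray) -> pd.DataFrame:
        d = _group_diff(beta, mask)
        d_s = _smooth_running_mean(d, chrom_codes, smooth_k)
        return _candidate_regions(d_s, chrom_codes, pos, weights,
                                  min_cpgs, max_gap, cutoff, d_raw=d)

    observed = regions_for(case)
    if observed.empty:
        logger.info("no candidate regions above cutoff %.3g", cutoff)
        return _empty_dmr_frame()

    null_max = np.empty(n_perm)
    labels_idx = np.arange(len(case))
    for b in range(n_perm):
        perm = rng.permutation(labels_idx)
        mask_b = np.zeros_like(case)
        mask_b[perm[:n_case]] = True
        cand = regions_for(mask_b)
        null_max[b] = np.abs(cand["stat"]).max() if len(cand) else 0.0

    obs_stat = np.abs(observed["stat"].to_numpy())
    exceed = (null_max[None, :] >= obs_stat[:, None]).sum(axis=1)
    pvalues = (1.0 + exceed) / (1.0 + n_perm)
    qvalues = bh_adjust(pvalues)

    out = observed.copy()
    out["chrom"] = chroms[out["start_idx"].to_numpy()]
    first_pos = pos[out["start_idx"].to_numpy()]
    last_pos = pos[out["end_idx"].to_numpy()]
    out["start"] = first_pos - 1  # 1-based CpG -> 0-based half-open interval
    out["end"] = last_pos
    out["pvalue"] = pvalues
    out["qvalue"] = qvalues
    out["direction"] = np.where(out["stat"] > 0, "hyper", "hypo")
    out["significant"] = out["qvalue"] < Q_SIGNIFICANT
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    out["dmr_id"] = _name_regions(out["chrom"])
    return out[["chrom", "start", "end", "dmr_id", "n_cpgs", "stat",
                "pvalue", "qvalue", "direction", "significant"]]


def _name_regions(chroms: pd.Series) -> list[str]:
    """Per-chromosome running index, e.g. 'chr3.15'."""
    counters: dict[str, int] = {}
    names = []
    for c in chroms:
        counters[c] = counters.get(c, 0) + 1
        names.append(f"{c}.{counters[c]}")
    return names


def _empty_dmr_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "dmr_id", "n_cpgs", "stat",
                 "pvalue", "qvalue", "direction", "significant"]
    )


# ---------------------------------------------------------------------------
# Region summaries
# ---------------------------------------------------------------------------

def region_beta_matrix(sm: SiteMatrix, regions: pd.DataFrame) -> pd.DataFrame:
    """Mean relative methylation per region per sample.

    Entry (r, s) is the unweighted mean over CpGs inside region r of
    meth/coverage for sample s, skipping zero-coverage (filtered)
    observations; NaN if every site is missing for that sample. Regions
    with no surviving CpGs at all are dropped with a warning.

    Region intervals are 0-based half-open; a 1-based CpG at ``pos`` falls
    inside [start, end) iff start < pos <= end.
    """
    beta = sm.beta()
    chroms = sm.sites["chrom"].to_numpy()
    pos = sm.sites["pos"].to_numpy()
    rows = {}
    dropped = []
    for reg in regions.itertuples(index=False):
        in_region = (chroms == reg.chrom) & (pos > reg.start) & (pos <= reg.end)
        if not in_region.any():
            dropped.append(reg.dmr_id)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            rows[reg.dmr_id] = np.nanmean(beta[in_region], axis=0)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} region(s) with no surviving CpGs: "
            + ", ".join(map(str, dropped[:5]))
        )
    if not rows:
        return pd.DataFrame(columns=sm.sample_ids)
    bm = pd.DataFrame.from_dict(rows, orient="index", columns=sm.sample_ids)
    all_missing = bm.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(f"dropped {int(all_missing.sum())} region(s) missing in all samples")
        bm = bm[~all_missing]
    bm.index.name = "dmr_id"
    return bm


def classify_direction(beta: pd.DataFrame, labels: Mapping[str, str]) -> pd.Series:
    """Per-region 'hyper' (case mean > control mean) or 'hypo' classification."""
    groups = np.array([labels[s] for s in beta.columns])
    case_mean = beta.loc[:, groups == "case"].mean(axis=1, skipna=True)
    ctrl_mean = beta.loc[:, groups == "control"].mean(axis=1, skipna=True)
    ties = case_mean == ctrl_mean
    if ties.any():
        warnings.warn(f"{int(ties.sum())} region(s) with tied group means classified hypo")
    return pd.Series(
        np.where(case_mean > ctrl_mean, "hyper", "hypo"),
        index=beta.index,
        name="direction",
    )
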