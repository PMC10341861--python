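"""Synthetic joint methylation/expression studies with planted regulatory structure.

The generator plants non-overlapping DMRs on a toy genome, simulates
beta-binomial CpG counts per sample (case group shifted by +/- delta_beta
inside DMRs), then couples expression to methylation: each planted lncRNA's
NB log-mean decreases with its DMR's per-sample realized beta, and each
planted protein's log-mean decreases with the standardized log expression
of its lncRNA. Decoy transcripts — some deliberately placed inside the cis
windows — have group-independent means, so window filtering alone cannot
recover the truth. A machine-readable truth table records every planted
(DMR, lncRNA, protein) triplet.

Everything is deterministic given the seed, down to the bytes of the
emitted files (gzip members are written with mtime = 0).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from methlink.io_formats import (
    CountMatrix,
    CytosineTable,
    TranscriptAnnotation,
    write_count_matrix,
    write_cytosine_report,
    write_gtf,
    write_table,
)

logger = logging.getLogger(__name__)

CELL_TYPES = ("epithelial", "fibroblast", "immune")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the reference cohort: 11 case vs 13 control samples,
    planted DMRs averaging 288 bp and 15 CpGs.
    """

    n_case: int = 11
    n_control: int = 13
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 12_000_000),
        ("chr2", 12_000_000),
        ("chr3", 12_000_000),
    )
    n_cpg: int = 4000
    n_planted_dmrs: int = 30
    dmr_mean_len: int = 288
    dmr_mean_cpgs: int = 15
    dmr_fixed_size: bool = False  # use exactly dmr_mean_len/dmr_mean_cpgs
    delta_beta: float = 0.3
    baseline_beta_range: tuple[float, float] = (0.3, 0.7)
    bb_dispersion: float = 0.02
    coverage_mean: float = 30.0
    n_lnc_linked: int = 30
    n_lnc_decoy: int = 150
    n_prot_linked: int = 30
    n_prot_decoy: int = 150
    coupling_lnc: float = -4.0
    coupling_prot: float = -1.5
    nb_dispersion: float = 0.05
    lnc_window: int = 20_000
    prot_window: int = 500_000
    n_external_datasets: int = 2
    external_n_per_group: int = 10
    ref_overlap_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        self.genome = tuple((str(c), int(l)) for c, l in self.genome)
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >=2 samples per group")
        if self.lnc_window > 20_000:
            raise ValueError("lnc_window must be <= 20000")
        if self.prot_window > 500_000:
            raise ValueError("prot_window must be <= 500000")
        lo, hi = self.baseline_beta_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("baseline_beta_range must lie within [0, 1]")
        for name in ("n_cpg", "n_planted_dmrs", "n_lnc_linked", "n_lnc_decoy",
                     "n_prot_linked", "n_prot_decoy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return [f"case_{i+1:02d}" for i in range(self.n_case)] + [
            f"ctrl_{i+1:02d}" for i in range(self.n_control)
        ]

    @property
    def labels(self) -> dict[str, str]:
        return {
            s: ("case" if s.startswith("case") else "control")
            for s in self.sample_ids
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genome"] = [list(g) for g in self.genome]
        d["baseline_beta_range"] = list(self.baseline_beta_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "genome" in d:
            d["genome"] = tuple(tuple(g) for g in d["genome"])
        if "baseline_beta_range" in d:
            d["baseline_beta_range"] = tuple(d["baseline_beta_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class StudyModel:
    """Planted structure of a simulated study (the generator's ground truth)."""

    config: SimulationConfig
    true_dmrs: pd.DataFrame  # chrom,start,end,dmr_id,direction,n_cpgs,baseline_mean
    lnc_assign: pd.DataFrame = field(default=None)  # set by simulate_expression
    prot_assign: pd.DataFrame = field(default=None)


# ---------------------------------------------------------------------------
# Methylation simulation
# ---------------------------------------------------------------------------

def _place_dmrs(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping planted DMRs, spread over the genome in jittered slots.

    Slots keep neighbouring DMRs far enough apart that the 500 kb protein
    windows of different planted chains cannot collide.
    """
    total = sum(l for _, l in config.genome)
    n = config.n_planted_dmrs
    if n == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "dmr_id", "direction", "n_cpgs", "baseline_mean"]
        )
    slot = total / n
    max_len = int(config.dmr_mean_len * 3) + 10
    if slot < max_len + 2 * (slot / 10) + 2:
        raise ValueError(
            "cannot place planted DMRs without overlap; use a larger genome "
            "or fewer DMRs"
        )
    # chromosome offsets in the concatenated coordinate
    offsets = np.cumsum([0] + [l for _, l in config.genome])
    rows = []
    per_chrom_counter: dict[str, int] = {}
    for i in range(n):
        center = (i + 0.5) * slot + rng.uniform(-slot / 10, slot / 10)
        if config.dmr_fixed_size:
            length = config.dmr_mean_len
            n_cpgs = config.dmr_mean_cpgs
        else:
            length = int(np.clip(rng.poisson(config.dmr_mean_len), 40, max_len))
            n_cpgs = max(2, int(rng.poisson(config.dmr_mean_cpgs)))
        n_cpgs = min(n_cpgs, length - 1)
        start_g = int(center - length / 2)
        # locate chromosome
        ci = int(np.searchsorted(offsets, start_g, side="right") - 1)
        ci = min(max(ci, 0), len(config.genome) - 1)
        chrom, chrom_len = config.genome[ci]
        start = start_g - int(offsets[ci])
        start = int(np.clip(start, 1, chrom_len - length - 1))
        direction = "hyper" if rng.random() < 0.5 else "hypo"
        baseline = rng.uniform(*config.baseline_beta_range)
        per_chrom_counter[chrom] = per_chrom_counter.get(chrom, 0) + 1
        rows.append(
            (chrom, start, start + length, f"true_{chrom}.{per_chrom_counter[chrom]}",
             direction, n_cpgs, baseline)
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "dmr_id", "direction", "n_cpgs",
                       "baseline_mean"]
    )
    # same-chromosome overlap should be impossible by construction; verify
    for chrom, sub in df.groupby("chrom"):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise ValueError("planted DMRs overlap; use a larger genome")
    return df


def _cpg_positions(
    config: SimulationConfig, dmrs: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """CpG site layout: clustered inside planted DMRs, uniform elsewhere.

    Returns a frame with chrom, pos (1-based), baseline, delta (signed
    case-group shift, 0 outside DMRs) and dmr_id ("" outside DMRs),
    sorted by (chrom, pos).
    """
    rows = []
    n_planted = 0
    for d in dmrs.itertuples(index=False):
        span = d.end - d.start
        pos0 = rng.choice(span, size=d.n_cpgs, replace=False) + d.start
        sign = 1.0 if d.direction == "hyper" else -1.0
        for p in np.sort(pos0):
            base = float(np.clip(d.baseline_mean + rng.normal(0, 0.03), 0.05, 0.95))
            rows.append((d.chrom, int(p) + 1, base, sign * config.delta_beta, d.dmr_id))
            n_planted += 1
    n_background = config.n_cpg - n_planted
    if n_background < 0:
        raise ValueError(
            f"n_cpg={config.n_cpg} smaller than the {n_planted} planted CpGs"
        )
    lengths = np.array([l for _, l in config.genome], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(config.genome), size=n_background, p=probs)
    dmr_lookup = {
        chrom: list(zip(sub["start"], sub["end"]))
        for chrom, sub in dmrs.groupby("chrom")
    }
    lo, hi = config.baseline_beta_range
    for ci in chrom_idx:
        chrom, chrom_len = config.genome[ci]
        while True:
            p = int(rng.integers(1, chrom_len))
            inside = any(s <= p - 1 < e for s, e in dmr_lookup.get(chrom, ()))
            if not inside:
                break
        rows.append((chrom, p, float(rng.uniform(lo, hi)), 0.0, ""))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "baseline", "delta", "dmr_id"])
    df = df.drop_duplicates(subset=["chrom", "pos"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _beta_binomial(
    mean: np.ndarray, coverage: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Beta-binomial draws with mean ``mean`` and overdispersion rho in [0, 1)."""
    mean = np.clip(mean, 1e-3, 1 - 1e-3)
    if rho <= 0:
        return rng.binomial(coverage, mean)
    conc = 1.0 / rho - 1.0
    p = rng.beta(mean * conc, (1.0 - mean) * conc)
    return rng.binomial(coverage, p)


def simulate_methylation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[CytosineTable], pd.DataFrame, pd.DataFrame, StudyModel]:
    """Simulate per-sample CpG tables with planted DMRs.

    Returns (tables, true DMR frame, realized per-sample DMR beta frame
    [dmr_id x sample], model). The realized beta is the unweighted mean of
    meth/coverage over the DMR's CpGs (all coverage, unfiltered) and is
    what downstream expression simulation couples to.
    """
    dmrs = _place_dmrs(config, rng)
    sites = _cpg_positions(config, dmrs, rng)
    n_sites = len(sites)
    sample_ids = config.sample_ids
    labels = config.labels
    baseline = sites["baseline"].to_numpy()
    delta = sites["delta"].to_numpy()

    tables = []
    betas = {}
    for s in sample_ids:
        is_case = labels[s] == "case"
        mean = np.clip(baseline + (delta if is_case else 0.0), 0.0, 1.0)
        cov = rng.poisson(config.coverage_mean, size=n_sites)
        meth = _beta_binomial(mean, cov, config.bb_dispersion, rng)
        data = pd.DataFrame(
            {
                "chrom": sites["chrom"],
                "pos": sites["pos"],
                "strand": "+",
                "meth": meth,
                "unmeth": cov - meth,
            }
        )
        tables.append(CytosineTable(sample_id=s, data=data))
        with np.errstate(divide="ignore", invalid="ignore"):
            site_beta = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
        betas[s] = site_beta

    beta_arr = np.column_stack([betas[s] for s in sample_ids])
    dmr_beta_rows = {}
    in_dmr = sites["dmr_id"].to_numpy()
    for d in dmrs["dmr_id"]:
        mask = in_dmr == d
        if mask.any():
            dmr_beta_rows[d] = np.nanmean(beta_arr[mask], axis=0)
    dmr_betas = pd.DataFrame.from_dict(dmr_beta_rows, orient="index", columns=sample_ids)
    dmr_betas.index.name = "dmr_id"
    model = StudyModel(config=config, true_dmrs=dmrs)
    return tables, dmrs, dmr_betas, model


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def _nb_draw(mean: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """NB draws with var = mu + alpha mu^2 via the gamma-Poisson mixture."""
    mean = np.maximum(mean, 1e-8)
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def _place_transcript(
    anchor_chrom: str,
    anchor_start: int,
    anchor_end: int,
    max_gap: int,
    length: int,
    chrom_len: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Place a transcript with span gap <= max_gap from the anchor interval."""
    if max_gap < 1:
        raise ValueError("cis window too small for the transcript length")
    gap = int(rng.integers(0, max_gap))
    downstream_first = bool(rng.random() < 0.5)
    for downstream in (downstream_first, not downstream_first):
        start = anchor_end + gap if downstream else anchor_start - gap - length
        if 0 <= start and start + length <= chrom_len:
            return start, start + length
    raise ValueError(
        "cis-window constraint unsatisfiable on this genome; enlarge chromosomes"
    )


def simulate_expression(
    config: SimulationConfig,
    dmr_betas: pd.DataFrame,
    model: StudyModel,
    rng: np.random.Generator,
) -> tuple[CountMatrix, list[TranscriptAnnotation], pd.DataFrame]:
    """Simulate the count matrix, annotation and truth table.

    Planted lncRNA j for DMR d: counts ~ NB with
    log mean = a_j + coupling_lnc * (beta_d,s - mean_s beta_d); planted
    protein k: log mean = c_k + coupling_prot * z_j,s with z the
    standardized log2 lncRNA count. Decoys have constant means; half of
    them are planted inside the cis windows of real DMRs/lncRNAs.
    """
    chrom_len = dict(config.genome)
    dmrs = model.true_dmrs
    if config.n_lnc_linked > 0 and len(dmrs) == 0:
        raise ValueError("cannot link lncRNAs: no planted DMRs")
    sample_ids = list(dmr_betas.columns) if len(dmr_betas) else config.sample_ids
    n_samples = len(sample_ids)

    lnc_rows = []
    for j in range(config.n_lnc_linked):
        d = dmrs.iloc[j % len(dmrs)]
        length = int(rng.integers(500, 3000))
        start, end = _place_transcript(
            d["chrom"], d["start"], d["end"],
            max_gap=config.lnc_window - length - 1,
            length=length, chrom_len=chrom_len[d["chrom"]], rng=rng,
        )
        lnc_rows.append(
            (f"LNCL{j+1:04d}.1", d["dmr_id"], float(np.log(rng.uniform(100, 400))),
             d["chrom"], start, end)
        )
    for j in range(config.n_lnc_decoy):
        if j % 2 == 0 and len(dmrs):  # decoy inside a DMR's cis window
            d = dmrs.iloc[int(rng.integers(0, len(dmrs)))]
            length = int(rng.integers(500, 3000))
            start, end = _place_transcript(
                d["chrom"], d["start"], d["end"],
                max_gap=config.lnc_window - length - 1,
                length=length, chrom_len=chrom_len[d["chrom"]], rng=rng,
            )
            chrom = d["chrom"]
        else:
            ci = int(rng.integers(0, len(config.genome)))
            chrom, cl = config.genome[ci]
            length = int(rng.integers(500, 3000))
            start = int(rng.integers(0, cl - length))
            end = start + length
        lnc_rows.append(
            (f"LNCD{j+1:04d}.1", "", float(np.log(rng.uniform(100, 400))),
             chrom, start, end)
        )
    lnc_assign = pd.DataFrame(
        lnc_rows, columns=["transcript_id", "dmr_id", "base_log_mean",
                           "chrom", "start", "end"]
    )

    # lncRNA counts
    lnc_counts = np.zeros((len(lnc_assign), n_samples), dtype=np.int64)
    lnc_z = {}
    for i, row in enumerate(lnc_assign.itertuples(index=False)):
        if row.dmr_id and row.dmr_id in dmr_betas.index:
            b = dmr_betas.loc[row.dmr_id].to_numpy(dtype=float)
            b = np.where(np.isfinite(b), b, np.nanmean(b))
            log_mu = row.base_log_mean + config.coupling_lnc * (b - b.mean())
        else:
            log_mu = np.full(n_samples, row.base_log_mean)
        lnc_counts[i] = _nb_draw(np.exp(log_mu), config.nb_dispersion, rng)
        logc = np.log2(lnc_counts[i] + 1.0)
        sd = logc.std()
        lnc_z[row.transcript_id] = (logc - logc.mean()) / sd if sd > 0 else logc * 0.0

    # proteins: linked ones anchor on (and couple to) planted lncRNAs
    n_linked_pairs = min(config.n_prot_linked, config.n_lnc_linked)
    prot_rows = []
    for k in range(n_linked_pairs):
        lnc = lnc_assign.iloc[k]
        length = int(rng.integers(1000, 5000))
        max_gap = int(0.6 * config.prot_window) - length - 1
        start, end = _place_transcript(
            lnc["chrom"], lnc["start"], lnc["end"], max_gap=max_gap,
            length=length, chrom_len=chrom_len[lnc["chrom"]], rng=rng,
        )
        prot_rows.append(
            (f"PRTL{k+1:04d}.1", lnc["transcript_id"],
             float(np.log(rng.uniform(150, 600))), lnc["chrom"], start, end)
        )
    for k in range(config.n_prot_decoy):
        if k % 2 == 0 and config.n_lnc_linked:  # decoy inside a lncRNA's window
            lnc = lnc_assign.iloc[int(rng.integers(0, config.n_lnc_linked))]
            length = int(rng.integers(1000, 5000))
            max_gap = int(0.6 * config.prot_window) - length - 1
            start, end = _place_transcript(
                lnc["chrom"], lnc["start"], lnc["end"], max_gap=max_gap,
                length=length, chrom_len=chrom_len[lnc["chrom"]], rng=rng,
            )
            chrom = lnc["chrom"]
        else:
            ci = int(rng.integers(0, len(config.genome)))
            chrom, cl = config.genome[ci]
            length = int(rng.integers(1000, 5000))
            start = int(rng.integers(0, cl - length))
            end = start + length
        prot_rows.append(
            (f"PRTD{k+1:04d}.1", "", float(np.log(rng.uniform(150, 600))),
             chrom, start, end)
        )
    prot_assign = pd.DataFrame(
        prot_rows, columns=["transcript_id", "lnc_transcript_id", "base_log_mean",
                            "chrom", "start", "end"]
    )

    prot_counts = np.zeros((len(prot_assign), n_samples), dtype=np.int64)
    for i, row in enumerate(prot_assign.itertuples(index=False)):
        if row.lnc_transcript_id:
            z = lnc_z[row.lnc_transcript_id]
            log_mu = row.base_log_mean + config.coupling_prot * z
        else:
            log_mu = np.full(n_samples, row.base_log_mean)
        prot_counts[i] = _nb_draw(np.exp(log_mu), config.nb_dispersion, rng)

    counts = pd.DataFrame(
        np.vstack([lnc_counts, prot_counts]),
        index=list(lnc_assign["transcript_id"]) + list(prot_assign["transcript_id"]),
        columns=sample_ids,
    )
    counts.index.name = "transcript_id"
    groups = pd.Series(
        {s: ("case" if s.startswith("case") else "control") for s in sample_ids}
    )
    cm = CountMatrix(counts=counts, groups=groups)

    annotation = [
        TranscriptAnnotation(
            transcript_id=r.transcript_id,
            gene_id=r.transcript_id.split(".")[0],
            gene_name=r.transcript_id.split(".")[0],
            biotype="lncRNA",
            chrom=r.chrom, start=int(r.start), end=int(r.end), strand="+",
        )
        for r in lnc_assign.itertuples(index=False)
    ] + [
        TranscriptAnnotation(
            transcript_id=r.transcript_id,
            gene_id=r.transcript_id.split(".")[0],
            gene_name=r.transcript_id.split(".")[0],
            biotype="protein_coding",
            chrom=r.chrom, start=int(r.start), end=int(r.end), strand="+",
        )
        for r in prot_assign.itertuples(index=False)
    ]

    dir_lookup = dmrs.set_index("dmr_id")["direction"]
    truth_rows = []
    for k in range(n_linked_pairs):
        lnc = lnc_assign.iloc[k]
        prot = prot_assign.iloc[k]
        truth_rows.append(
            (lnc["dmr_id"], lnc["transcript_id"], prot["transcript_id"],
             dir_lookup[lnc["dmr_id"]], True)
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["dmr_id", "lnc_transcript_id", "prot_transcript_id",
                 "dmr_direction", "planted"],
    )
    model.lnc_assign = lnc_assign
    model.prot_assign = prot_assign
    return cm, annotation, truth


def simulate_external_dataset(
    model: StudyModel,
    rng: np.random.Generator,
    n_per_group: int | None = None,
    coupled: bool = True,
) -> pd.DataFrame:
    """An independent normalized expression matrix with the same planted genes.

    Fresh samples get fresh per-sample DMR betas (baseline +/- delta for
    the case group, light noise), then the same lncRNA/protein coupling
    chain (or none, when ``coupled`` is false). Values are log2(count + 1),
    indexed by gene name.
    """
    config = model.config
    if n_per_group is None:
        n_per_group = config.external_n_per_group
    sample_ids = [f"ext_case_{i+1:02d}" for i in range(n_per_group)] + [
        f"ext_ctrl_{i+1:02d}" for i in range(n_per_group)
    ]
    is_case = np.array([s.startswith("ext_case") for s in sample_ids])
    dmrs = model.true_dmrs
    rows = {}
    for d in dmrs.itertuples(index=False):
        sign = config.delta_beta if d.direction == "hyper" else -config.delta_beta
        mean = d.baseline_mean + np.where(is_case, sign, 0.0)
        rows[d.dmr_id] = np.clip(mean + rng.normal(0, 0.03, size=len(sample_ids)), 0, 1)
    dmr_betas = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)

    ext_config = dataclasses.replace(config) if coupled else dataclasses.replace(
        config, coupling_lnc=0.0, coupling_prot=0.0
    )
    ext_model = StudyModel(config=ext_config, true_dmrs=dmrs)
    # reuse transcript layout but regenerate counts for the new samples
    ext_model.lnc_assign = model.lnc_assign
    ext_model.prot_assign = model.prot_assign
    counts = _counts_from_assignments(ext_model, dmr_betas, rng)
    norm = np.log2(counts + 1.0)
    norm.index = [t.split(".")[0] for t in norm.index]  # gene-name namespace
    norm.index.name = "gene_name"
    return norm


def _counts_from_assignments(
    model: StudyModel, dmr_betas: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    config = model.config
    sample_ids = list(dmr_betas.columns)
    n_samples = len(sample_ids)
    lnc_counts = {}
    lnc_z = {}
    for row in model.lnc_assign.itertuples(index=False):
        if row.dmr_id and row.dmr_id in dmr_betas.index and config.coupling_lnc != 0:
            b = dmr_betas.loc[row.dmr_id].to_numpy(dtype=float)
            log_mu = row.base_log_mean + config.coupling_lnc * (b - b.mean())
        else:
            log_mu = np.full(n_samples, row.base_log_mean)
        y = _nb_draw(np.exp(log_mu), config.nb_dispersion, rng)
        lnc_counts[row.transcript_id] = y
        logc = np.log2(y + 1.0)
        sd = logc.std()
        lnc_z[row.transcript_id] = (logc - logc.mean()) / sd if sd > 0 else logc * 0.0
    prot_counts = {}
    for row in model.prot_assign.itertuples(index=False):
        if row.lnc_transcript_id and config.coupling_prot != 0:
            log_mu = row.base_log_mean + config.coupling_prot * lnc_z[row.lnc_transcript_id]
        else:
            log_mu = np.full(n_samples, row.base_log_mean)
        prot_counts[row.transcript_id] = _nb_draw(np.exp(log_mu), config.nb_dispersion, rng)
    all_counts = {**lnc_counts, **prot_counts}
    return pd.DataFrame.from_dict(all_counts, orient="index", columns=sample_ids).astype(float)


# ---------------------------------------------------------------------------
# Reference mixtures for deconvolution
# ---------------------------------------------------------------------------

def simulate_reference_mixtures(
    n_regions: int,
    cell_types: Sequence[str],
    n_samples: int,
    noise_sd: float,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Reference profiles, noisy mixtures and true simplex fractions.

    Reference betas ~ U(0,1); sample beta = reference @ w + N(0, noise_sd)
    clipped to [0,1]; w drawn uniformly on the simplex (Dirichlet(1)) unless
    given.
    """
    cell_types = list(cell_types)
    reference = pd.DataFrame(
        rng.uniform(0, 1, size=(n_regions, len(cell_types))),
        index=[f"region_{i+1}" for i in range(n_regions)],
        columns=cell_types,
    )
    if weights is None:
        weights = rng.dirichlet(np.ones(len(cell_types)), size=n_samples)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n_samples, len(cell_types)):
            raise ValueError("weights must be (n_samples, n_cell_types)")
    mix = reference.to_numpy() @ weights.T
    if noise_sd > 0:
        mix = mix + rng.normal(0, noise_sd, size=mix.shape)
    mix = np.clip(mix, 0, 1)
    sample_ids = [f"mix_{i+1:02d}" for i in range(n_samples)]
    mixtures = pd.DataFrame(mix, index=reference.index, columns=sample_ids)
    fractions = pd.DataFrame(weights, index=sample_ids, columns=cell_types)
    return reference, mixtures, fractions


def _reference_for_dmrs(
    dmrs: pd.DataFrame, overlap_frac: float, rng: np.random.Generator,
    genome: Sequence[tuple[str, int]],
) -> pd.DataFrame:
    """Reference loci hitting ~overlap_frac of the planted DMRs, plus off-target loci."""
    n = len(dmrs)
    n_hit = int(round(overlap_frac * n))
    hit_idx = rng.choice(n, size=n_hit, replace=False)
    rows = []
    for i in sorted(hit_idx):
        d = dmrs.iloc[i]
        pos = int((d["start"] + d["end"]) // 2)
        rows.append((f"probe_{len(rows)+1:04d}", d["chrom"], pos))
    dmr_spans = {c: list(zip(s["start"], s["end"])) for c, s in dmrs.groupby("chrom")}
    n_off = max(n - n_hit, 1)
    for _ in range(n_off):
        ci = int(rng.integers(0, len(genome)))
        chrom, cl = genome[ci]
        while True:
            pos = int(rng.integers(0, cl))
            if not any(s <= pos < e for s, e in dmr_spans.get(chrom, ())):
                break
        rows.append((f"probe_{len(rows)+1:04d}", chrom, pos))
    ref = pd.DataFrame(rows, columns=["locus_id", "chrom", "pos"]).set_index("locus_id")
    for ct in CELL_TYPES:
        ref[ct] = rng.uniform(0, 1, size=len(ref))
    return ref


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

def generate_study(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate a full study directory and return its manifest.

    Emits meth/<sample>.CpG_report.txt.gz, true_dmrs.bed, counts.tsv,
    samples.tsv, annotation.gtf, reference_profiles.tsv, external_*.tsv,
    truth_triplets.tsv and manifest.json. Byte-identical under a fixed seed.
    """
    out_dir = Path(out_dir)
    (out_dir / "meth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    tables, dmrs, dmr_betas, model = simulate_methylation(config, rng)
    cm, annotation, truth = simulate_expression(config, dmr_betas, model, rng)

    files = []
    for t in tables:
        path = out_dir / "meth" / f"{t.sample_id}.CpG_report.txt.gz"
        write_cytosine_report(t, path)
        files.append(str(path.relative_to(out_dir)))

    # same BED6+ layout as called DMRs (stat/p/q are placeholders)
    with open(out_dir / "true_dmrs.bed", "wt") as fh:
        for d in dmrs.itertuples(index=False):
            stat = 1.0 if d.direction == "hyper" else -1.0
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.dmr_id}\t{stat}\t.\t0\t0"
                f"\t{d.direction}\t{d.n_cpgs}\n"
            )
    files.append("true_dmrs.bed")

    write_count_matrix(cm, out_dir / "counts.tsv", out_dir / "samples.tsv")
    files += ["counts.tsv", "samples.tsv"]

    write_gtf(annotation, out_dir / "annotation.gtf")
    files.append("annotation.gtf")

    ref = _reference_for_dmrs(dmrs, config.ref_overlap_frac, rng, config.genome)
    ref.to_csv(out_dir / "reference_profiles.tsv", sep="\t")
    files.append("reference_profiles.tsv")

    for k in range(config.n_external_datasets):
        ext = simulate_external_dataset(model, rng)
        path = out_dir / f"external_ds{k+1}.tsv"
        ext.to_csv(path, sep="\t")
        files.append(path.name)

    write_table(truth, out_dir / "truth_triplets.tsv")
    files.append("truth_triplets.tsv")

    dmr_betas.to_csv(out_dir / "true_dmr_betas.tsv", sep="\t", index_label="dmr_id")
    files.append("true_dmr_betas.tsv")

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "files": sorted(files),
    }
    with open(out_dir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("study written to %s (%d files)", out_dir, len(files))
    return manifest
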