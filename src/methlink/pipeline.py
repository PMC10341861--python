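"""End-to-end orchestration of the discovery pipeline over a study directory.

A study directory follows the layout written by
:func:`methlink.synthetic.generate_study`: ``meth/*.CpG_report.txt[.gz]``,
``counts.tsv``, ``samples.tsv``, ``annotation.gtf`` and optionally
``reference_profiles.tsv`` and ``external_*.tsv``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from methlink import deconvolution, expression, integration, methylation, verification
from methlink.io_formats import (
    annotation_frame,
    read_annotation,
    read_count_matrix,
    read_cytosine_report,
    read_dmr_bed,
    write_dmr_bed,
    write_matrix,
    write_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All intermediate and final tables of one pipeline run."""

    dmrs: pd.DataFrame
    beta: pd.DataFrame
    de_results: pd.DataFrame
    normalized: pd.DataFrame
    dmr_lnc_pairs: pd.DataFrame
    triplets: pd.DataFrame
    fractions: pd.DataFrame | None = None
    fraction_tests: pd.DataFrame | None = None
    verification_long: pd.DataFrame | None = None
    verification_summary: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def load_labels(samples_path: Path) -> dict[str, str]:
    sheet = pd.read_csv(samples_path, sep="\t")
    return dict(zip(sheet["sample_id"], sheet["group"]))


def run_all(
    study_dir: str | Path,
    out_dir: str | Path | None = None,
    seed: int = 0,
    min_cov: int = methylation.DEFAULT_MIN_COV,
    min_frac: float = methylation.DEFAULT_MIN_FRAC,
    n_perm: int = methylation.DEFAULT_N_PERM,
    lnc_window: int = integration.DEFAULT_LNC_WINDOW,
    prot_window: int = integration.DEFAULT_PROT_WINDOW,
    dmr_bed: str | Path | None = None,
    de_table: str | Path | None = None,
    corr_method: str = "pearson",
) -> PipelineResult:
    """Run filter -> DMR calling -> DE -> integration -> deconvolution -> verification."""
    study_dir = Path(study_dir)
    rng = np.random.default_rng(seed)
    labels = load_labels(study_dir / "samples.tsv")

    # methylation stage
    meth_dir = study_dir / "meth"
    report_paths = sorted(meth_dir.glob("*.CpG_report.txt*"))
    if not report_paths:
        raise FileNotFoundError(f"no cytosine reports under {meth_dir}")
    tables = [read_cytosine_report(p) for p in report_paths]
    sm = methylation.filter_cpg_coverage(tables, labels, min_cov=min_cov, min_frac=min_frac)

    if dmr_bed is not None:
        dmrs = read_dmr_bed(dmr_bed)
        dmrs["significant"] = True
        logger.info("using %d externally called DMRs from %s", len(dmrs), dmr_bed)
    else:
        dmrs = methylation.call_dmrs(sm, n_perm=n_perm, rng=rng)
        dmrs = dmrs[dmrs["significant"]].reset_index(drop=True)
    beta = methylation.region_beta_matrix(sm, dmrs)
    dmrs = dmrs[dmrs["dmr_id"].isin(beta.index)].reset_index(drop=True)
    if len(dmrs):
        directions = methylation.classify_direction(beta, labels)
        dmrs["direction"] = directions.loc[dmrs["dmr_id"]].to_numpy()

    # expression stage
    cm = read_count_matrix(study_dir / "counts.tsv", study_dir / "samples.tsv")
    factors = expression.size_factors(cm.counts)
    normalized = expression.normalize_matrix(cm.counts, factors)
    if de_table is not None:
        de = pd.read_csv(de_table, sep="\t", index_col=0)
        logger.info("using external DE table %s", de_table)
    else:
        de = expression.nb_wald_de(cm, factors)
    ann_records = read_annotation(study_dir / "annotation.gtf")
    ann = annotation_frame(ann_records)
    de_sets = expression.select_de(de, ann)

    # integration stage
    pairs = integration.pair_lnc_dmr(de_sets["lncRNA"], dmrs, window=lnc_window)
    regulated = integration.dmr_regulated_lncrnas(
        pairs, beta, normalized, de, method=corr_method
    )
    candidates = integration.pair_lnc_protein(
        regulated, ann, de_sets["protein_coding"], window=prot_window
    )
    triplets = integration.lnc_protein_targets(
        candidates, regulated, normalized, method=corr_method
    )
    integration.audit_triplets(triplets, lnc_window=lnc_window, prot_window=prot_window)
    if len(triplets) and len(dmrs):
        triplets = integration.attach_dmr_directions(triplets, dmrs)

    result = PipelineResult(
        dmrs=dmrs, beta=beta, de_results=de, normalized=normalized,
        dmr_lnc_pairs=regulated, triplets=triplets,
    )

    # deconvolution stage (optional input)
    ref_path = study_dir / "reference_profiles.tsv"
    if ref_path.exists() and len(dmrs):
        reference = pd.read_csv(ref_path, sep="\t", index_col=0)
        cell_cols = [c for c in reference.columns if c not in ("chrom", "pos")]
        try:
            mapping, mapped_frac = deconvolution.map_regions_to_probes(dmrs, reference)
        except ValueError as exc:
            logger.warning("deconvolution skipped: %s", exc)
        else:
            beta_mapped = beta.loc[mapping["dmr_id"]]
            ref_mapped = reference.loc[mapping["locus_id"], cell_cols]
            ref_mapped.index = mapping["dmr_id"]
            result.fractions = deconvolution.rpc_fractions(beta_mapped, ref_mapped)
            result.fraction_tests = deconvolution.compare_fractions(result.fractions, labels)
            result.summary["dmr_probe_mapped_fraction"] = mapped_frac

    # verification stage (optional input)
    ext_paths = sorted(study_dir.glob("external_*.tsv"))
    if ext_paths and len(triplets):
        gene_names = ann["gene_name"]
        vpairs = pd.DataFrame(
            {
                "lnc_id": gene_names.reindex(triplets["lnc_transcript_id"]).to_numpy(),
                "prot_id": gene_names.reindex(triplets["prot_transcript_id"]).to_numpy(),
            }
        ).dropna()
        datasets = [
            verification.ExternalDataset(p.stem, pd.read_csv(p, sep="\t", index_col=0))
            for p in ext_paths
        ]
        long, summary = verification.verify_pairs(vpairs, datasets)
        result.verification_long = long
        result.verification_summary = summary

    result.summary.update(
        {
            "n_sites_filtered": int(len(sm.sites)),
            "n_dmrs": int(len(dmrs)),
            "n_dmrs_hyper": int((dmrs["direction"] == "hyper").sum()) if len(dmrs) else 0,
            "n_dmrs_hypo": int((dmrs["direction"] == "hypo").sum()) if len(dmrs) else 0,
            "n_de_lncrna": int(len(de_sets["lncRNA"])),
            "n_de_protein": int(len(de_sets["protein_coding"])),
            "n_dmr_lnc_pairs": int(len(regulated)),
            "n_dmr_regulated_lncrnas": int(regulated["lnc_transcript_id"].nunique()),
            "n_triplets": int(len(triplets)),
            "n_target_proteins": int(triplets["prot_transcript_id"].nunique()) if len(triplets) else 0,
        }
    )

    if out_dir is not None:
        _write_outputs(result, ann, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, ann: pd.DataFrame, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(result.dmrs):
        write_dmr_bed(result.dmrs, out_dir / "dmrs.bed")
    write_matrix(result.beta, out_dir / "beta.tsv", index_label="dmr_id")
    write_matrix(result.de_results, out_dir / "de_results.tsv", index_label="transcript_id")
    write_matrix(result.normalized, out_dir / "normalized.tsv", index_label="transcript_id")
    write_table(result.dmr_lnc_pairs, out_dir / "dmr_lnc_pairs.tsv")
    write_table(result.triplets, out_dir / "triplets.tsv")
    report = integration.region_report(result.dmrs, result.triplets, ann)
    write_table(report, out_dir / "region_report.tsv")
    if result.fractions is not None:
        write_matrix(result.fractions, out_dir / "fractions.tsv", index_label="sample_id")
        write_table(result.fraction_tests, out_dir / "fractions_tests.tsv")
    if result.verification_long is not None:
        write_table(result.verification_long, out_dir / "verification_long.tsv")
        write_table(result.verification_summary, out_dir / "verification_summary.tsv")
    with open(out_dir / "summary.json", "wt") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def score_against_truth(
    result: PipelineResult, truth: pd.DataFrame, true_dmrs: pd.DataFrame
) -> dict:
    """Recovery metrics of a pipeline run against the planted truth table.

    A planted triplet is recovered when some emitted triplet's DMR
    reciprocally overlaps (>= 50%) the planted DMR and both transcript ids
    match. The decoy fraction counts emitted triplets touching any decoy
    transcript (ids starting LNCD/PRTD).
    """
    trips = result.triplets
    if trips.empty:
        return {"sensitivity": 0.0, "decoy_fraction": 0.0, "n_emitted": 0}
    dmr_match = match_regions(result.dmrs, true_dmrs, min_reciprocal=0.5)
    called_to_true = dict(zip(dmr_match["dmr_id"], dmr_match["true_id"]))
    emitted = {
        (called_to_true.get(t.dmr_id), t.lnc_transcript_id, t.prot_transcript_id)
        for t in trips.itertuples(index=False)
    }
    planted = {
        (t.dmr_id, t.lnc_transcript_id, t.prot_transcript_id)
        for t in truth.itertuples(index=False)
    }
    recovered = planted & emitted
    is_decoy = trips["lnc_transcript_id"].str.startswith("LNCD") | trips[
        "prot_transcript_id"
    ].str.startswith("PRTD")
    return {
        "sensitivity": len(recovered) / len(planted) if planted else float("nan"),
        "decoy_fraction": float(is_decoy.mean()),
        "n_emitted": int(len(trips)),
        "n_planted": int(len(planted)),
        "n_recovered": int(len(recovered)),
    }


def match_regions(
    called: pd.DataFrame, truth: pd.DataFrame, min_reciprocal: float = 0.5
) -> pd.DataFrame:
    """Pair called regions with truth regions at >= min_reciprocal overlap.

    Both frames need chrom/start/end plus dmr_id; returns one row per
    (called, truth) pair meeting the reciprocal-overlap threshold.
    """
    rows = []
    for c in called.itertuples(index=False):
        for t in truth.itertuples(index=False):
            if c.chrom != t.chrom:
                continue
            inter = min(c.end, t.end) - max(c.start, t.start)
            if inter <= 0:
                continue
            if inter >= min_reciprocal * (c.end - c.start) and inter >= min_reciprocal * (
                t.end - t.start
            ):
                rows.append((c.dmr_id, t.dmr_id))
    return pd.DataFrame(rows, columns=["dmr_id", "true_id"])
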