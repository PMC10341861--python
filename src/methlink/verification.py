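"""Cross-dataset verification of lncRNA-protein correlation pairs.

Each (lncRNA, protein) pair from the triplet table is re-correlated in
independent normalized expression matrices; a pair is confirmed in a
dataset when the correlation is negative with p < 0.05 (an "any
significant correlation" two-sided mode is available). Confirmation
fractions per lncRNA are computed only over datasets where both features
were found.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from methlink.integration import CORR_P_CUT, correlate

logger = logging.getLogger(__name__)


@dataclass
class ExternalDataset:
    """A named normalized expression matrix (features x samples)."""

    name: str
    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ValueError(
                f"dataset {self.name!r}: identifier collisions: {list(dup[:5])}"
            )


def verify_pairs(
    pairs: pd.DataFrame,
    datasets: Sequence[ExternalDataset],
    p_cut: float = CORR_P_CUT,
    require_negative: bool = True,
    method: str = "pearson",
    alias: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-test (lnc_id, prot_id) pairs in each external dataset.

    ``pairs`` needs columns lnc_id and prot_id (identifier namespace of the
    datasets, typically gene names); duplicates are collapsed. ``alias``
    optionally maps pipeline identifiers to dataset identifiers; unmatched
    identifiers are surfaced via found_both = False rather than fuzzy-matched.

    Returns (long frame: one row per pair per dataset, summary frame: one
    row per lncRNA with n_datasets_tested, n_confirmed, fraction_confirmed).
    """
    uniq = pairs[["lnc_id", "prot_id"]].drop_duplicates().reset_index(drop=True)
    alias = dict(alias or {})
    long_rows = []
    for ds in datasets:
        if ds.matrix.shape[1] < 3:
            warnings.warn(f"dataset {ds.name!r} has <3 samples; skipped")
            continue
        index = set(ds.matrix.index)
        for pr in uniq.itertuples(index=False):
            lnc = alias.get(pr.lnc_id, pr.lnc_id)
            prot = alias.get(pr.prot_id, pr.prot_id)
            found = lnc in index and prot in index
            r = p = np.nan
            n = 0
            confirmed = False
            if found:
                try:
                    r, p, n = correlate(
                        ds.matrix.loc[lnc].to_numpy(dtype=float),
                        ds.matrix.loc[prot].to_numpy(dtype=float),
                        method=method,
                    )
                except ValueError as exc:
                    warnings.warn(f"{ds.name}: pair ({lnc}, {prot}) not testable: {exc}")
                    found = False
                else:
                    confirmed = p < p_cut and (r < 0 or not require_negative)
            long_rows.append((ds.name, pr.lnc_id, pr.prot_id, found, r, p, n, confirmed))
    long = pd.DataFrame(
        long_rows,
        columns=["dataset", "lnc_id", "prot_id", "found_both", "r", "pvalue",
                 "n_samples", "confirmed"],
    )
    summary = summarize_verification(long)
    return long, summary


def summarize_verification(long: pd.DataFrame) -> pd.DataFrame:
    """Per-lncRNA confirmation summary over datasets where the pair was found.

    A lncRNA counts a dataset as tested if at least one of its pairs was
    found there, and as confirmed if at least one such pair is confirmed.
    fraction_confirmed = n_confirmed / n_datasets_tested (NaN if never found).
    """
    rows = []
    for lnc, sub in long.groupby("lnc_id", sort=True):
        per_ds = sub.groupby("dataset")
        tested = per_ds["found_both"].any()
        confirmed = per_ds["confirmed"].any()
        n_tested = int(tested.sum())
        n_conf = int((confirmed & tested).sum())
        frac = n_conf / n_tested if n_tested else np.nan
        rows.append((lnc, n_tested, n_conf, frac))
    return pd.DataFrame(
        rows,
        columns=["lnc_id", "n_datasets_tested", "n_confirmed", "fraction_confirmed"],
    )
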