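import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methlink.integration import (
    audit_triplets,
    correlate,
    dmr_regulated_lncrnas,
    interval_distance,
    lnc_protein_targets,
    pair_lnc_dmr,
    pair_lnc_protein,
    region_report,
    window_pairs,
)
from methlink.io_formats import GenomicInterval
from methlink.pipeline import run_all


class TestIntervalDistance:
    def test_overlapping_is_zero(self):
        a = GenomicInterval("chr1", 100, 200)
        b = GenomicInterval("chr1", 150, 250)
        assert interval_distance(a, b) == 0

    def test_gap(self):
        a = GenomicInterval("chr1", 100, 200)
        b = GenomicInterval("chr1", 250, 300)
        assert interval_distance(a, b) == 50
        assert interval_distance(b, a) == 50  # symmetric

    def test_adjacent_is_zero(self):
        a = GenomicInterval("chr1", 100, 200)
        b = GenomicInterval("chr1", 200, 300)
        assert interval_distance(a, b) == 0

    def test_cross_chromosome_undefined(self):
        a = GenomicInterval("chr1", 100, 200)
        b = GenomicInterval("chr2", 100, 200)
        assert interval_distance(a, b) is None

    def test_matches_enumeration_oracle(self, rng):
        # enumerate base positions for small random intervals
        for _ in range(50):
            s1, s2 = rng.integers(0, 60, size=2)
            l1, l2 = rng.integers(1, 15, size=2)
            a = GenomicInterval("c", int(s1), int(s1 + l1))
            b = GenomicInterval("c", int(s2), int(s2 + l2))
            pa = set(range(a.start, a.end))
            pb = set(range(b.start, b.end))
            expected = 0 if pa & pb else min(abs(x - y) for x in pa for y in pb) - 1
            assert interval_distance(a, b) == expected


class TestWindowPairing:
    @staticmethod
    def _features(rows, index_name="id"):
        df = pd.DataFrame(rows, columns=[index_name, "chrom", "start", "end"])
        return df.set_index(index_name)

    def test_boundary_in_and_out(self):
        lnc = self._features([("lnc_in", "chr1", 120_000, 121_000),
                              ("lnc_out", "chr1", 220_002, 221_000)])
        dmrs = pd.DataFrame({"chrom": ["chr1", "chr1"],
                             "start": [100_000, 200_000],
                             "end": [100_001, 200_001],
                             "dmr_id": ["d1", "d2"]})
        pairs = pair_lnc_dmr(lnc, dmrs, window=20_000)
        got = set(zip(pairs["lnc_transcript_id"], pairs["dmr_id"]))
        # lnc_in is 18999 bp from d1 (in), 79k from d2 (out)
        # lnc_out is 20001 bp from d2 (out by 1)
        assert got == {("lnc_in", "d1")}

    def test_exact_window_boundary_included(self):
        lnc = self._features([("l", "chr1", 120_000, 121_000)])
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [99_000], "end": [100_001],
                             "dmr_id": ["d"]})
        assert len(pair_lnc_dmr(lnc, dmrs, window=19_999)) == 1
        dmrs2 = dmrs.assign(end=100_000 - 1)
        assert len(pair_lnc_dmr(lnc, dmrs2, window=19_999)) == 0

    def test_empty_de_set_warns(self):
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                             "dmr_id": ["d"]})
        with pytest.warns(UserWarning, match="empty DE lncRNA"):
            pairs = pair_lnc_dmr(self._features([]), dmrs, window=100)
        assert pairs.empty

    def test_matches_brute_force_all_pairs(self, rng):
        chroms = ["chr1", "chr2"]
        left = self._features(
            [(f"L{i}", chroms[int(rng.integers(2))], int(s), int(s) + int(rng.integers(1, 500)))
             for i, s in enumerate(rng.integers(0, 200_000, size=60))]
        )
        right = self._features(
            [(f"R{i}", chroms[int(rng.integers(2))], int(s), int(s) + int(rng.integers(1, 500)))
             for i, s in enumerate(rng.integers(0, 200_000, size=60))],
        )
        window = 10_000
        got = set(map(tuple, window_pairs(left, right, window)[["left_id", "right_id"]].to_numpy()))
        expected = set()
        for li, lrow in left.iterrows():
            for ri, rrow in right.iterrows():
                d = interval_distance(
                    GenomicInterval(lrow["chrom"], lrow["start"], lrow["end"]),
                    GenomicInterval(rrow["chrom"], rrow["start"], rrow["end"]),
                )
                if d is not None and d <= window:
                    expected.add((li, ri))
        assert got == expected


class TestCorrelate:
    def test_perfect_anticorrelation(self):
        r, p, n = correlate([1, 2, 3, 4], [4, 3, 2, 1])
        assert r == pytest.approx(-1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_perfect_correlation(self):
        x = np.array([1.0, 2, 3, 4])
        r, p, n = correlate(x, x)
        assert r == pytest.approx(1.0)

    def test_nan_samples_dropped_pairwise(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, 4, 6, 8, np.nan]
        r, p, n = correlate(x, y)
        assert n == 3 and r == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match=">=3"):
            correlate([1, 2], [2, 1])

    def test_p_matches_permutation_oracle(self, rng):
        x = rng.normal(size=10)
        y = 0.6 * x + rng.normal(size=10)
        r, p, n = correlate(x, y)
        n_perm = 10_000
        perm_r = np.empty(n_perm)
        for b in range(n_perm):
            perm_r[b] = stats.pearsonr(x, rng.permutation(y))[0]
        p_perm = (1 + np.sum(np.abs(perm_r) >= abs(r))) / (n_perm + 1)
        mc_err = 4 * np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / n_perm)
        assert abs(p - p_perm) < mc_err + 0.005


class TestFiltering:
    def _setup(self):
        samples = [f"s{i}" for i in range(8)]
        beta = pd.DataFrame(
            [np.linspace(0.2, 0.9, 8), np.linspace(0.9, 0.2, 8)],
            index=["d_neg", "d_pos"], columns=samples,
        )
        noise = np.array([0.01, -0.02, 0.015, -0.01, 0.02, -0.015, 0.005, -0.005])
        expr = pd.DataFrame(
            [np.linspace(9, 2, 8) + noise, np.linspace(9, 2, 8) + noise],
            index=["lnc_a", "lnc_b"], columns=samples,
        )
        pairs = pd.DataFrame(
            {"lnc_transcript_id": ["lnc_a", "lnc_b"], "dmr_id": ["d_neg", "d_pos"],
             "distance_bp": [100, 100]}
        )
        de = pd.DataFrame({"log2fc": [-1.2, 0.8]}, index=["lnc_a", "lnc_b"])
        return pairs, beta, expr, de

    def test_sign_rule(self):
        pairs, beta, expr, de = self._setup()
        kept = dmr_regulated_lncrnas(pairs, beta, expr, de)
        # lnc_a vs d_neg: strong negative -> kept; lnc_b vs d_pos: positive -> dropped
        assert list(kept["lnc_transcript_id"]) == ["lnc_a"]
        assert kept.iloc[0]["r_meth_lnc"] < 0 and kept.iloc[0]["p_meth_lnc"] < 0.05
        assert kept.iloc[0]["lnc_de_direction"] == "down"

    def test_nonsignificant_negative_dropped(self, rng):
        samples = [f"s{i}" for i in range(8)]
        beta = pd.DataFrame([rng.uniform(0.2, 0.8, 8)], index=["d"], columns=samples)
        expr = pd.DataFrame([rng.normal(5, 1, 8)], index=["l"], columns=samples)
        pairs = pd.DataFrame({"lnc_transcript_id": ["l"], "dmr_id": ["d"],
                              "distance_bp": [0]})
        de = pd.DataFrame({"log2fc": [1.0]}, index=["l"])
        kept = dmr_regulated_lncrnas(pairs, beta, expr, de)
        r, p, _ = correlate(beta.loc["d"].to_numpy(), expr.loc["l"].to_numpy())
        assert len(kept) == (1 if (r < 0 and p < 0.05) else 0)


class TestEndToEndIntegration:
    def test_planted_dmr_lnc_links_recovered(self, default_run):
        res = default_run["result"]
        truth = default_run["truth"]
        # map called DMRs to true ones, then check planted (DMR, lnc) links
        from methlink.pipeline import match_regions

        m = match_regions(res.dmrs, default_run["true_dmrs"])
        called_to_true = dict(zip(m["dmr_id"], m["true_id"]))
        found = {
            (called_to_true.get(r.dmr_id), r.lnc_transcript_id)
            for r in res.dmr_lnc_pairs.itertuples(index=False)
        }
        planted = set(zip(truth["dmr_id"], truth["lnc_transcript_id"]))
        assert len(planted & found) / len(planted) >= 0.8

    def test_triplet_invariants_audited(self, default_run):
        audit_triplets(default_run["result"].triplets)

    def test_sign_coherence_hyper_dmrs_give_down_lncrnas(self, default_run):
        trips = default_run["result"].triplets
        hyper = trips[trips["dmr_direction"] == "hyper"]
        assert len(hyper) > 0
        assert (hyper["lnc_de_direction"] == "down").mean() >= 0.8

    def test_window_monotonicity(self, default_study):
        # enlarging either window never removes a triplet
        small = run_all(default_study["dir"], seed=7, lnc_window=10_000,
                        prot_window=250_000)
        large = run_all(default_study["dir"], seed=7, lnc_window=20_000,
                        prot_window=500_000)
        key = ["dmr_id", "lnc_transcript_id", "prot_transcript_id"]
        small_set = set(map(tuple, small.triplets[key].to_numpy()))
        large_set = set(map(tuple, large.triplets[key].to_numpy()))
        assert small_set <= large_set

    def test_region_report_contains_triplet_features(self, default_run):
        res = default_run["result"]
        ann = pd.DataFrame(
            {
                "gene_id": ["g"], "gene_name": ["g"], "biotype": ["lncRNA"],
                "chrom": [res.dmrs.iloc[0]["chrom"]],
                "start": [int(res.dmrs.iloc[0]["start"]) + 1],
                "end": [int(res.dmrs.iloc[0]["end"]) + 100],
                "strand": ["+"],
            },
            index=pd.Index(["tx_near"], name="transcript_id"),
        )
        report = region_report(res.dmrs, res.triplets, ann)
        if res.dmrs.iloc[0]["dmr_id"] in set(res.triplets["dmr_id"]):
            sub = report[report["dmr_id"] == res.dmrs.iloc[0]["dmr_id"]]
            assert "dmr" in set(sub["feature_kind"])
            assert "tx_near" in set(sub["feature_id"])


class TestProteinStage:
    def test_cross_chromosome_never_paired(self):
        regulated = pd.DataFrame(
            {"lnc_transcript_id": ["l"], "dmr_id": ["d"], "distance_bp": [0],
             "r_meth_lnc": [-0.9], "p_meth_lnc": [0.001], "n_samples": [10],
             "padj_meth_lnc": [0.01], "lnc_de_direction": ["down"]}
        )
        lnc_ann = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000]},
            index=pd.Index(["l"], name="transcript_id"),
        )
        prot = pd.DataFrame(
            {"chrom": ["chr2"], "start": [0], "end": [1000]},
            index=pd.Index(["p"], name="transcript_id"),
        )
        cands = pair_lnc_protein(regulated, lnc_ann, prot)
        assert cands.empty

    def test_triplet_emitted_for_negative_pair(self):
        samples = [f"s{i}" for i in range(10)]
        x = np.linspace(0, 1, 10)
        noise = np.array([0.02, -0.01, 0.015, -0.02, 0.01, -0.015, 0.02, -0.01, 0.005, -0.01])
        norm = pd.DataFrame(
            [5 + 2 * x, 8 - 3 * x + noise], index=["l", "p"], columns=samples
        )
        regulated = pd.DataFrame(
            {"lnc_transcript_id": ["l"], "dmr_id": ["d"], "distance_bp": [10],
             "r_meth_lnc": [-0.9], "p_meth_lnc": [0.001], "n_samples": [10],
             "padj_meth_lnc": [0.01], "lnc_de_direction": ["up"]}
        )
        cands = pd.DataFrame(
            {"lnc_transcript_id": ["l"], "prot_transcript_id": ["p"],
             "distance_bp": [499_000]}
        )
        trips = lnc_protein_targets(cands, regulated, norm)
        assert len(trips) == 1
        assert trips.iloc[0]["r_lnc_prot"] < 0 and trips.iloc[0]["p_lnc_prot"] < 0.05
        audit_triplets(trips)
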