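import numpy as np
import pandas as pd
import pytest

from methlink import methylation
from methlink.io_formats import CytosineTable
from methlink.methylation import (
    SiteMatrix,
    call_dmrs,
    classify_direction,
    filter_cpg_coverage,
    region_beta_matrix,
)
from methlink.pipeline import match_regions
from methlink.synthetic import simulate_methylation
from tests.conftest import tiny_meth_config


def make_tables(meth, cov, sample_ids, chrom="chr1", positions=None):
    """Build CytosineTable fixtures from (site x sample) arrays."""
    n_sites = meth.shape[0]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    tables = []
    for j, s in enumerate(sample_ids):
        data = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": positions,
                "strand": "+",
                "meth": meth[:, j],
                "unmeth": cov[:, j] - meth[:, j],
            }
        )
        tables.append(CytosineTable(sample_id=s, data=data))
    return tables


SIX = ["c1", "c2", "c3", "k1", "k2", "k3"]
SIX_LABELS = {"c1": "case", "c2": "case", "c3": "case",
              "k1": "control", "k2": "control", "k3": "control"}


class TestCoverageFilter:
    def test_fully_covered_site_retained(self):
        cov = np.full((1, 6), 10)
        meth = np.full((1, 6), 5)
        sm = filter_cpg_coverage(make_tables(meth, cov, SIX), SIX_LABELS)
        assert len(sm.sites) == 1

    def test_under_half_case_coverage_dropped(self):
        # 11 case / 13 control; site covered >=6x in only 5/11 cases (45% < 50%)
        ids = [f"case_{i}" for i in range(11)] + [f"ctrl_{i}" for i in range(13)]
        labels = {s: ("case" if s.startswith("case") else "control") for s in ids}
        cov = np.full((2, 24), 10)
        cov[0, 5:11] = 3  # only 5 of 11 case samples at >=6x
        meth = cov // 2
        sm = filter_cpg_coverage(make_tables(meth, cov, ids), labels)
        assert len(sm.sites) == 1  # only the fully covered second site survives
        assert sm.sites.iloc[0]["pos"] == 20

    def test_no_surviving_sites_errors(self):
        cov = np.full((3, 6), 2)  # everything below 6x
        meth = cov // 2
        with pytest.raises(ValueError, match="no CpG sites"):
            filter_cpg_coverage(make_tables(meth, cov, SIX), SIX_LABELS)

    def test_subcoverage_observations_zeroed(self):
        cov = np.full((1, 6), 10)
        cov[0, 0] = 5
        meth = np.full((1, 6), 4)
        sm = filter_cpg_coverage(make_tables(meth, cov, SIX), SIX_LABELS)
        assert sm.cov[0, 0] == 0 and sm.meth[0, 0] == 0
        assert np.isnan(sm.beta()[0, 0])

    def test_matches_brute_force_oracle(self, rng):
        n_sites, min_cov, min_frac = 50, 6, 0.5
        cov = rng.integers(0, 15, size=(n_sites, 6))
        meth = rng.binomial(cov, 0.5)
        tables = make_tables(meth, cov, SIX)
        labels = SIX_LABELS
        # independent site-by-site rule application
        expected = []
        for i in range(n_sites):
            ok = cov[i] >= min_cov
            case_frac = np.mean([ok[j] for j, s in enumerate(SIX) if labels[s] == "case"])
            ctrl_frac = np.mean([ok[j] for j, s in enumerate(SIX) if labels[s] == "control"])
            if case_frac >= min_frac and ctrl_frac >= min_frac:
                expected.append((i + 1) * 10)
        sm = filter_cpg_coverage(tables, labels, min_cov=min_cov, min_frac=min_frac)
        assert list(sm.sites["pos"]) == expected


class TestRegionBeta:
    def _site_matrix(self, meth, cov, positions, sample_ids=SIX):
        sites = pd.DataFrame({"chrom": "chr1", "pos": positions})
        groups = np.array([SIX_LABELS[s] for s in sample_ids])
        return SiteMatrix(sites=sites, meth=meth, cov=cov,
                          sample_ids=sample_ids, groups=groups)

    def test_single_cpg_beta(self):
        sm = self._site_matrix(np.full((1, 6), 8), np.full((1, 6), 10), [150])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200],
                                "dmr_id": ["r1"]})
        bm = region_beta_matrix(sm, regions)
        assert np.allclose(bm.loc["r1"], 0.8)

    def test_two_cpgs_unweighted_mean(self):
        meth = np.array([[2] * 6, [6] * 6])
        cov = np.full((2, 6), 10)
        sm = self._site_matrix(meth, cov, [110, 190])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200],
                                "dmr_id": ["r1"]})
        bm = region_beta_matrix(sm, regions)
        assert np.allclose(bm.loc["r1"], 0.4)  # mean of 0.2 and 0.6, coverage-blind

    def test_half_open_region_boundaries(self):
        # 1-based CpG at pos p is inside 0-based [start, end) iff start < p <= end
        meth = np.full((2, 6), 5)
        cov = np.full((2, 6), 10)
        sm = self._site_matrix(meth, cov, [100, 200])
        regions = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 200], "end": [200, 300],
             "dmr_id": ["r1", "r2"]}
        )
        with pytest.warns(UserWarning, match="no surviving"):
            bm = region_beta_matrix(sm, regions)
        # pos 200 is base index 199, inside [100,200) -> r1; nothing in [200,300)
        assert "r1" in bm.index and "r2" not in bm.index

    def test_matches_brute_force_oracle(self, rng):
        n_sites = 40
        cov = rng.integers(0, 20, size=(n_sites, 6))
        meth = rng.binomial(cov, rng.uniform(0.1, 0.9, size=(n_sites, 1)))
        positions = np.sort(rng.choice(np.arange(1, 2000), size=n_sites, replace=False))
        sm = self._site_matrix(meth, cov, positions)
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 500, 1200], "end": [500, 1200, 2100],
             "dmr_id": ["r1", "r2", "r3"]}
        )
        bm = region_beta_matrix(sm, regions)
        for reg in regions.itertuples(index=False):
            in_reg = [i for i, p in enumerate(positions) if reg.start < p <= reg.end]
            if not in_reg:
                assert reg.dmr_id not in bm.index
                continue
            for j in range(6):
                vals = [meth[i, j] / cov[i, j] for i in in_reg if cov[i, j] > 0]
                expected = np.mean(vals) if vals else np.nan
                got = bm.loc[reg.dmr_id].iloc[j]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_beta_matrix_values_in_unit_interval(self, default_run):
        bm = default_run["result"].beta
        vals = bm.to_numpy()
        vals = vals[np.isfinite(vals)]
        assert ((vals >= 0) & (vals <= 1)).all()


class TestClassifyDirection:
    def test_hyper_and_hypo(self):
        beta = pd.DataFrame(
            {"c1": [0.7, 0.3], "c2": [0.7, 0.3], "k1": [0.3, 0.7], "k2": [0.3, 0.7]},
            index=["r1", "r2"],
        )
        labels = {"c1": "case", "c2": "case", "k1": "control", "k2": "control"}
        d = classify_direction(beta, labels)
        assert d["r1"] == "hyper" and d["r2"] == "hypo"

    def test_tie_broken_hypo_with_warning(self):
        beta = pd.DataFrame({"c1": [0.5], "c2": [0.5], "k1": [0.5], "k2": [0.5]},
                            index=["r1"])
        labels = {"c1": "case", "c2": "case", "k1": "control", "k2": "control"}
        with pytest.warns(UserWarning, match="tied"):
            assert classify_direction(beta, labels)["r1"] == "hypo"

    @pytest.mark.parametrize("seed", range(5))
    def test_direction_consistent_with_region_stat(self, seed):
        cfg = tiny_meth_config(seed=seed, n_planted_dmrs=6, n_cpg=700)
        rng = np.random.default_rng(seed)
        tables, _, _, _ = simulate_methylation(cfg, rng)
        sm = filter_cpg_coverage(tables, cfg.labels)
        called = call_dmrs(sm, n_perm=20, rng=rng)
        if called.empty:
            pytest.skip("no candidates this seed")
        beta = region_beta_matrix(sm, called)
        directions = classify_direction(beta, cfg.labels)
        for row in called.itertuples(index=False):
            if row.dmr_id in directions.index:
                expected = "hyper" if row.stat > 0 else "hypo"
                assert directions[row.dmr_id] == expected


class TestCallDmrs:
    def test_too_few_permutations_error(self):
        ids = ["a", "b", "c", "d"]
        labels = {"a": "case", "b": "case", "c": "control", "d": "control"}
        cov = np.full((20, 4), 10)
        meth = cov // 2
        sm = filter_cpg_coverage(make_tables(meth, cov, ids), labels)
        with pytest.raises(ValueError, match="permutations"):
            call_dmrs(sm, rng=np.random.default_rng(0))

    def test_identity_permutation_reproduces_observed_stat(self):
        cfg = tiny_meth_config(seed=4, n_planted_dmrs=4, n_cpg=500)
        rng = np.random.default_rng(4)
        tables, _, _, _ = simulate_methylation(cfg, rng)
        sm = filter_cpg_coverage(tables, cfg.labels)
        called = call_dmrs(sm, n_perm=20, rng=np.random.default_rng(1))
        # recompute the statistic pipeline by hand with the true labels
        chrom_codes = pd.factorize(sm.sites["chrom"].to_numpy())[0]
        d = methylation._group_diff(sm.beta(), sm.case_mask)
        d_s = methylation._smooth_running_mean(d, chrom_codes, methylation.DEFAULT_SMOOTH_K)
        cand = methylation._candidate_regions(
            d_s, chrom_codes, sm.sites["pos"].to_numpy(),
            sm.cov.sum(axis=1).astype(float),
            methylation.DEFAULT_MIN_CPGS, methylation.DEFAULT_MAX_GAP,
            methylation.DEFAULT_CUTOFF, d_raw=d,
        )
        np.testing.assert_allclose(
            np.sort(called["stat"].to_numpy()), np.sort(cand["stat"].to_numpy())
        )

    def test_single_planted_dmr_recovered(self):
        cfg = tiny_meth_config(seed=6, n_planted_dmrs=1, n_cpg=400,
                               genome=(("chr1", 500_000),))
        rng = np.random.default_rng(6)
        tables, true_dmrs, _, _ = simulate_methylation(cfg, rng)
        sm = filter_cpg_coverage(tables, cfg.labels)
        called = call_dmrs(sm, n_perm=100, rng=rng)
        sig = called[called["significant"]]
        matched = match_regions(sig, true_dmrs, min_reciprocal=0.5)
        assert set(matched["true_id"]) == set(true_dmrs["dmr_id"])
        assert (sig.set_index("dmr_id").loc[matched["dmr_id"], "qvalue"] < 0.05).all()

    def test_null_simulation_mostly_clean(self):
        cfg = tiny_meth_config(seed=31, delta_beta=0.0, n_planted_dmrs=0, n_cpg=800)
        rng = np.random.default_rng(31)
        tables, _, _, _ = simulate_methylation(cfg, rng)
        sm = filter_cpg_coverage(tables, cfg.labels)
        called = call_dmrs(sm, n_perm=50, rng=rng)
        assert called.empty or not called["significant"].any()

    def test_recovery_monotone_in_effect_size(self):
        # recovery rate never decreases as delta_beta grows 0.1 -> 0.2 -> 0.3
        rates = []
        for delta in (0.1, 0.2, 0.3):
            rec = tot = 0
            for rep in range(6):
                cfg = tiny_meth_config(seed=500 + rep, delta_beta=delta,
                                       n_planted_dmrs=6, n_cpg=700)
                rng = np.random.default_rng(900 + rep)
                tables, true_dmrs, _, _ = simulate_methylation(cfg, rng)
                sm = filter_cpg_coverage(tables, cfg.labels)
                called = call_dmrs(sm, n_perm=60, rng=rng)
                sig = called[called["significant"]] if len(called) else called
                matched = match_regions(sig, true_dmrs, min_reciprocal=0.5)
                rec += len(set(matched["true_id"]))
                tot += len(true_dmrs)
            rates.append(rec / tot)
        assert rates[0] <= rates[1] + 1e-9 and rates[1] <= rates[2] + 1e-9
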