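"""Enrichment tests, bootstraps, SNP-adjacent exclusion, and methylation LD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowmeth.resample import (chromosome_binomial_enrichment,
                               encode_methylation_genotypes,
                               exclude_snp_adjacent,
                               focal_background_bootstrap, pairwise_meld,
                               bootstrap_spearman)

import oracles


def _positions(counts):
    rows = []
    for chrom, k in counts.items():
        rows += [(chrom, i) for i in range(k)]
    return pd.DataFrame(rows, columns=["chrom", "pos"])


class TestBinomialEnrichment:
    def test_proportional_distribution_not_enriched(self):
        assayed = _positions({"chr1": 800, "chr2": 200})
        dmps = _positions({"chr1": 80, "chr2": 20})
        out = chromosome_binomial_enrichment(dmps, assayed)
        assert not out["enriched"].any()
        assert out["expected_prop"].sum() == pytest.approx(1.0)

    def test_p_value_equals_exact_tail_summation(self):
        assayed = _positions({"chr1": 30, "chr2": 970})
        dmps = _positions({"chr1": 17, "chr2": 83})
        out = chromosome_binomial_enrichment(dmps, assayed).set_index("chrom")
        row = out.loc["chr1"]
        assert row["p_value"] == pytest.approx(
            oracles.binom_tail_two_sided(17, 100, 0.03), rel=1e-9)
        assert row["enriched"] and row["ci_low"] > 0.03

    def test_zero_dmps_on_chromosome(self):
        assayed = _positions({"chr1": 500, "chr2": 500})
        dmps = _positions({"chr1": 10})
        out = chromosome_binomial_enrichment(dmps, assayed).set_index("chrom")
        assert out.loc["chr2", "ci_low"] == 0.0
        assert not out.loc["chr2", "enriched"]

    def test_dmps_without_assayed_cpgs_error(self):
        with pytest.raises(ValueError, match="no assayed"):
            chromosome_binomial_enrichment(_positions({"chrX": 5}),
                                           _positions({"chr1": 50}))


def _site_table(rng, n_focal=60, n_bg=600, shift=0.0, feature="intergenic"):
    focal = pd.DataFrame({
        "chrom": "chr18", "pos": np.arange(n_focal) + 1000,
        "stat": rng.normal(shift, 1, n_focal), "feature": feature})
    bg = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(n_bg),
        "stat": rng.normal(0, 1, n_bg), "feature": feature})
    return pd.concat([focal, bg], ignore_index=True)


class TestFocalBootstrap:
    region = ("chr18", 0, 10_000)

    def test_planted_shift_detected_only_in_shifted_class(self, rng):
        t1 = _site_table(rng, shift=2.0, feature="intergenic")
        t2 = _site_table(rng, shift=0.0, feature="promoter")
        t = pd.concat([t1, t2], ignore_index=True)
        out = focal_background_bootstrap(t, self.region, B=500, rng=rng)
        assert out["intergenic"].significant
        assert not out["promoter"].significant
        assert out["intergenic"].n_focal == 60

    def test_single_replicate_band_degenerates(self, rng):
        t = _site_table(rng)
        out = focal_background_bootstrap(t, self.region, B=1, rng=rng)
        c = out["intergenic"]
        assert c.lo == c.hi == c.replicate_means[0]

    def test_class_without_focal_cpgs_skipped(self, rng):
        t = _site_table(rng)
        t.loc[t["chrom"] == "chr18", "feature"] = "promoter"
        out = focal_background_bootstrap(t, self.region, B=50, rng=rng)
        assert out["intergenic"] is None

    def test_seed_deterministic_and_row_order_invariant(self, rng):
        t = _site_table(rng)
        a = focal_background_bootstrap(t, self.region, B=200,
                                       rng=np.random.default_rng(5))
        shuffled = t.sample(frac=1, random_state=0).reset_index(drop=True)
        b = focal_background_bootstrap(shuffled, self.region, B=200,
                                       rng=np.random.default_rng(5))
        assert a["intergenic"].focal_mean == pytest.approx(b["intergenic"].focal_mean)
        # background pool ordering differs only by row order; the replicate
        # band must agree to Monte-Carlo accuracy
        assert a["intergenic"].lo == pytest.approx(b["intergenic"].lo, abs=0.15)

    def test_overlap_mode_runs(self, rng):
        t = _site_table(rng, shift=3.0)
        out = focal_background_bootstrap(t, self.region, B=300, rng=rng,
                                         method="overlap")
        assert out["intergenic"].significant

    def test_calibration_under_exchangeable_null(self):
        """~5% of null datasets flag significance (band mode)."""
        hits = 0
        runs = 400
        master = np.random.default_rng(99)
        for _ in range(runs):
            t = _site_table(master, n_focal=40, n_bg=400, shift=0.0)
            out = focal_background_bootstrap(t, self.region, B=200, rng=master)
            hits += out["intergenic"].significant
        rate = hits / runs
        se = np.sqrt(0.05 * 0.95 / runs)
        assert abs(rate - 0.05) < 2.5 * se + 0.01


class TestSnpAdjacent:
    def test_adjacency_examples(self):
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [101, 102, 200]})
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
        out = exclude_snp_adjacent(sites, snps)
        # CpG C at 101: within 1 bp of SNP at 100 -> removed.
        # CpG at 102: dyad (102,103), distance 2 -> retained.
        assert sorted(out["pos"]) == [102, 200]

    def test_dyad_second_position_counts(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [97]})  # dyad (97,98)
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [99]})
        assert len(exclude_snp_adjacent(sites, snps)) == 0

    def test_planted_adjacent_snps_removed_by_truth_count(self, bundle):
        truth = bundle.truth
        sites = truth[["chrom", "pos"]]
        snps = bundle.varsim.variants[["chrom", "pos"]]
        out = exclude_snp_adjacent(sites, snps)
        removed = len(sites) - len(out)
        # every destroyed CpG carries a SNP on its own C -> must be removed
        assert removed >= int(truth["cpg_destroyed"].sum())


class TestBootstrapSpearman:
    def test_perfect_monotone_metric_gives_rho_one(self, rng):
        t = pd.DataFrame({"response": np.arange(50, dtype=float)})
        t["fst"] = np.exp(t["response"])  # strictly monotone
        focal = np.zeros(50, bool)
        focal[:10] = True
        out = bootstrap_spearman(t, focal, ["fst"], B=100, rng=rng)
        assert np.allclose(out["fst"]["inside"]["rho"], 1.0)
        assert out["fst"]["inside"]["significant"]

    def test_too_few_focal_windows_error(self, rng):
        t = pd.DataFrame({"response": np.arange(10.0), "fst": np.arange(10.0)})
        with pytest.raises(ValueError, match="focal"):
            bootstrap_spearman(t, np.array([True, True] + [False] * 8),
                               ["fst"], rng=rng)

    def test_planted_coupling_detected_inside_only(self, rng):
        n_f, n_b = 50, 500
        resp_f = rng.normal(0, 1, n_f)
        t = pd.DataFrame({
            "response": np.concatenate([resp_f, rng.normal(0, 1, n_b)]),
            "dxy": np.concatenate([resp_f * 0.9 + rng.normal(0, 0.3, n_f),
                                   rng.normal(0, 1, n_b)])})
        focal = np.arange(n_f + n_b) < n_f
        out = bootstrap_spearman(t, focal, ["dxy"], B=400, rng=rng)
        assert out["dxy"]["inside"]["significant"]
        assert not out["dxy"]["outside"]["significant"]

    def test_calibration_under_independence(self):
        hits_in = 0
        runs = 400
        master = np.random.default_rng(7)
        for _ in range(runs):
            t = pd.DataFrame({"response": master.normal(size=200),
                              "fst": master.normal(size=200)})
            focal = np.zeros(200, bool)
            focal[:40] = True
            out = bootstrap_spearman(t, focal, ["fst"], B=200, rng=master)
            hits_in += out["fst"]["inside"]["significant"]
        rate = hits_in / runs
        se = np.sqrt(0.05 * 0.95 / runs)
        assert abs(rate - 0.05) < 2.5 * se + 0.01


class TestMethylationGenotypes:
    def test_well_separated_clusters(self):
        states = encode_methylation_genotypes([0.05, 0.08, 0.81, 0.9])
        assert states.tolist() == [0, 0, 1, 1]

    def test_higher_mean_cluster_is_state_one_regardless_of_order(self, rng):
        x = np.concatenate([rng.uniform(0.7, 0.9, 5), rng.uniform(0.0, 0.2, 5)])
        states = encode_methylation_genotypes(x)
        assert (states[:5] == 1).all() and (states[5:] == 0).all()

    def test_symmetric_modes_split_at_midpoint(self, rng):
        lo = 0.45 + rng.normal(0, 0.002, 6)
        hi = 0.55 + rng.normal(0, 0.002, 6)
        x = np.concatenate([lo, hi])
        states = encode_methylation_genotypes(x)
        assert np.array_equal(states, oracles.two_means_exhaustive(x))
        assert (states[:6] == 0).all() and (states[6:] == 1).all()

    def test_identical_values_error(self):
        with pytest.raises(ValueError, match="identical"):
            encode_methylation_genotypes([0.5] * 6)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match=">= 4"):
            encode_methylation_genotypes([0.1, 0.9, np.nan, np.nan])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=12))
    def test_matches_exhaustive_optimal_cut(self, xs):
        x = np.asarray(xs)
        if np.allclose(x, x[0]):
            return
        got = encode_methylation_genotypes(x)
        want = oracles.two_means_exhaustive(x)
        # cluster assignment must agree (both use higher-mean = 1)
        assert np.array_equal(got, want)


class TestMethLD:
    def test_identical_balanced_states_give_maximal_d(self):
        a = np.array([0, 0, 1, 1, 0, 1, 0, 1], float)
        ld = pairwise_meld(a, a)
        assert ld.d == pytest.approx(0.25)
        assert ld.d_prime == pytest.approx(1.0)

    def test_independent_states_average_zero_d(self, rng):
        ds = []
        for _ in range(10_000):
            a = rng.integers(0, 2, 22).astype(float)
            b = rng.integers(0, 2, 22).astype(float)
            ld = pairwise_meld(a, b)
            if ld.defined:
                ds.append(ld.d)
        se = np.std(ds) / np.sqrt(len(ds))
        assert abs(np.mean(ds)) < 3 * se + 1e-3

    def test_monomorphic_is_flagged_not_raised(self):
        ld = pairwise_meld(np.ones(6), np.array([0, 1, 0, 1, 0, 1], float))
        assert not ld.defined and np.isnan(ld.d)

    def test_missing_pairs_excluded(self):
        a = np.array([0, 0, 1, 1, np.nan, 1])
        b = np.array([0, 1, 1, 0, 1, np.nan])
        ld = pairwise_meld(a, b)
        assert ld.n == 4

    def test_d_prime_bounds_and_absent_class_gives_one(self, rng):
        for _ in range(200):
            a = rng.integers(0, 2, 12).astype(float)
            b = a.copy()
            flips = rng.random(12) < 0.2
            b[flips] = 1 - b[flips]
            ld = pairwise_meld(a, b)
            if ld.defined and not np.isnan(ld.d_prime):
                assert -1e-12 <= ld.d_prime <= 1 + 1e-12
        # one joint class absent in the direction of association
        a = np.array([1, 1, 1, 0, 0, 0, 0, 0], float)
        b = np.array([1, 1, 0, 0, 0, 0, 0, 0], float)
        assert pairwise_meld(a, b).d_prime == pytest.approx(1.0)
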