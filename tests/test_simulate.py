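"""Generator contracts: determinism, design invariants, planted effects,
and fixture round-trips."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from crowmeth import methio
from crowmeth.annotate import detect_cpg_islands, to_str
from crowmeth.simulate import (Chrom, SimConfig, SimConfigError, _stream,
                               simulate_bundle, simulate_cohorts,
                               simulate_genome, simulate_methylation,
                               simulate_variants, validate_sample_table,
                               write_fixture_bundle)


def _tiny_config(**kw):
    base = dict(
        chromosomes=[Chrom("chr18", 200_000), Chrom("chr1", 150_000)],
        focal_region=("chr18", 50_000, 120_000),
        n_genes=8, n_repeats=10, n_snps=400, n_cpgs_assayed=600,
        n_age_effects=20, n_sex_effects=10, n_taxon_both=10,
        n_taxon_comgar=3, n_taxon_hybzon=3, n_year_effects=3, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_focal_region_must_be_inside_a_chromosome(self):
        with pytest.raises(SimConfigError, match="focal_region"):
            _tiny_config(focal_region=("chrX", 0, 10)).validate()

    def test_fst_must_be_below_one(self):
        with pytest.raises(SimConfigError, match="fst"):
            _tiny_config(fst_focal=1.0).validate()

    def test_negative_phi_rejected(self):
        with pytest.raises(SimConfigError, match="phi"):
            _tiny_config(phi=-0.1).validate()

    def test_chromosome_too_short_for_genes(self):
        with pytest.raises(SimConfigError, match="shorter"):
            SimConfig(chromosomes=[Chrom("c", 10_000)],
                      focal_region=("c", 0, 5000)).validate()

    def test_too_many_snps_rejected(self):
        cfg = _tiny_config(n_snps=10_000_000)
        genome = simulate_genome(cfg, _stream(cfg, "genome"))
        samples = simulate_cohorts(cfg, _stream(cfg, "cohorts"))
        with pytest.raises(SimConfigError, match="exceeds"):
            simulate_variants(cfg, genome, samples, _stream(cfg, "variants"))


class TestGenome:
    def test_zero_genes_gives_empty_gene_set(self):
        cfg = _tiny_config(n_genes=0)
        g = simulate_genome(cfg, _stream(cfg, "genome"))
        assert len(g.genes) == 0 and len(g.islands) == 0

    def test_designed_islands_all_recovered_by_detector(self):
        cfg = _tiny_config(island_length=300, island_gc=0.65, island_oe=0.8)
        g = simulate_genome(cfg, _stream(cfg, "genome"))
        assert len(g.islands) > 0
        for chrom, sub in g.islands.groupby("chrom"):
            found = detect_cpg_islands(to_str(g.sequences[chrom]))
            for _, isl in sub.iterrows():
                hit = [(s, e) for s, e in found
                       if min(e, isl["end"]) - max(s, isl["start"])
                       >= 0.8 * (isl["end"] - isl["start"])]
                assert hit, f"designed island {isl.tolist()} not recovered"

    def test_repeats_do_not_overlap_cds(self):
        cfg = _tiny_config()
        g = simulate_genome(cfg, _stream(cfg, "genome"))
        for chrom, reps in g.repeats.groupby("chrom"):
            cds = g.cds[g.cds["chrom"] == chrom]
            for _, r in reps.iterrows():
                assert not ((cds["start"] < r["end"]) & (cds["end"] > r["start"])).any()

    def test_genome_deterministic_for_fixed_seed(self):
        cfg = _tiny_config(seed=7)
        g1 = simulate_genome(cfg, _stream(cfg, "genome"))
        g2 = simulate_genome(cfg, _stream(cfg, "genome"))
        for c in g1.sequences:
            assert np.array_equal(g1.sequences[c], g2.sequences[c])
        pd.testing.assert_frame_equal(g1.genes, g2.genes)


class TestCohorts:
    def test_design_arithmetic(self, rng):
        t = simulate_cohorts(SimConfig(), rng)
        validate_sample_table(t)
        cg = t[t["experiment"] == "ComGar"]
        assert len(cg) == 24 and len(t[t["experiment"] == "HybZon"]) == 22
        assert cg.groupby(["taxon", "sex"]).size().eq(6).all()

    def test_hybrid_indices_span_full_range(self, rng):
        t = simulate_cohorts(SimConfig(), rng)
        h = t.loc[t["experiment"] == "HybZon", "hybrid_index"]
        assert h.min() == 0.0 and h.max() == 1.0
        assert ((h > 0.1) & (h < 0.9)).sum() >= 10

    def test_years_from_study_set(self, rng):
        t = simulate_cohorts(SimConfig(), rng)
        assert set(t.loc[t["experiment"] == "HybZon", "year"]) <= {2008, 2013, 2014}


class TestVariants:
    def test_purebred_hybrid_carries_single_ancestry(self):
        cfg = _tiny_config()
        genome = simulate_genome(cfg, _stream(cfg, "genome"))
        samples = simulate_cohorts(cfg, _stream(cfg, "cohorts"))
        vs = simulate_variants(cfg, genome, samples, _stream(cfg, "variants"))
        hz = samples[samples["experiment"] == "HybZon"]
        pure0 = hz[hz["hybrid_index"] == 0.0]["id"].iloc[0]
        assert vs.cohort_focal_ancestry[pure0].tolist() == [0, 0]
        pure1 = hz[hz["hybrid_index"] == 1.0]["id"].iloc[0]
        assert vs.cohort_focal_ancestry[pure1].tolist() == [1, 1]

    def test_transition_fraction_and_alleles(self):
        cfg = _tiny_config(transition_fraction=0.5, n_snps=1000)
        genome = simulate_genome(cfg, _stream(cfg, "genome"))
        samples = simulate_cohorts(cfg, _stream(cfg, "cohorts"))
        vs = simulate_variants(cfg, genome, samples, _stream(cfg, "variants"))
        df = vs.variants
        trans = df[df["is_transition"]]
        assert abs(len(trans) / len(df) - 0.5) < 0.02
        pairs = set(trans["ref"] + trans["alt"])
        assert pairs <= {"CT", "TC", "AG", "GA"}
        tv = df[~df["is_transition"]]
        assert not (tv["ref"] + tv["alt"]).isin(["CT", "TC", "AG", "GA"]).any()

    def test_no_differentiation_limit(self):
        """F close to zero in both regions: genome-wide Hudson F_ST ~ 0."""
        from crowmeth.popgen import hudson_fst, _site_stats
        cfg = _tiny_config(fst_background=0.001, fst_focal=0.001,
                           near_fixed_fraction=0.0, n_snps=5000)
        genome = simulate_genome(cfg, _stream(cfg, "genome"))
        samples = simulate_cohorts(cfg, _stream(cfg, "cohorts"))
        vs = simulate_variants(cfg, genome, samples, _stream(cfg, "variants"))
        pops = np.repeat(vs.panel_pops, 2)
        pi_w, pi_b = _site_stats(vs.panel_haps, pops == "corone", pops == "cornix")
        assert abs(hudson_fst(pi_w, pi_b)) < 0.02


class TestMethylation:
    @staticmethod
    def _pipeline(cfg):
        return simulate_bundle(cfg)

    def test_binomial_limit_at_zero_dispersion(self):
        """phi = 0: variance of m/n at fixed mu, n matches binomial."""
        cfg = _tiny_config(phi=0.0, coverage_shape=1e9, coverage_mean=40,
                           missing_rate=0.0, coverage_outlier_fraction=0.0,
                           baseline_sd=0.0, n_age_effects=0, n_sex_effects=0,
                           n_taxon_both=0, n_taxon_comgar=0, n_taxon_hybzon=0,
                           n_year_effects=0, cpg_snp_fraction=0.0)
        b = self._pipeline(cfg)
        mx = b.matrices["ComGar"]
        lab = b.truth.set_index(["chrom", "pos"]).loc[
            list(zip(mx.sites["chrom"], mx.sites["pos"])), "feature"].to_numpy()
        p = mx.proportions()
        for feat in ("intergenic", "promoter"):
            sel = lab == feat
            if sel.sum() < 30:
                continue
            mu = np.nanmean(p[sel])
            v_obs = np.nanvar(p[sel], axis=1).mean()
            v_bin = mu * (1 - mu) / 40
            assert v_obs == pytest.approx(v_bin, rel=0.25)

    def test_planted_taxon_delta_recovered_by_group_means(self):
        """Direct averaging of group-mean differences at planted taxon CpGs
        recovers the configured delta (Monte-Carlo over seeds)."""
        diffs = []
        for seed in range(10):
            cfg = _tiny_config(seed=seed, taxon_delta=0.40, missing_rate=0.0,
                               cis_linked_fraction=0.0, coverage_mean=30)
            b = self._pipeline(cfg)
            mx = b.matrices["ComGar"]
            keys = pd.MultiIndex.from_frame(mx.sites)
            truth = b.truth.set_index(["chrom", "pos"]).loc[keys]
            sel = ((truth["covariate"] == "taxon")
                   & truth["scope"].isin(["both", "comgar"])).to_numpy()
            p = mx.proportions()
            taxa = b.samples.set_index("id").loc[mx.samples, "taxon"]
            d = (np.nanmean(p[:, (taxa == "cornix").to_numpy()], axis=1)
                 - np.nanmean(p[:, (taxa == "corone").to_numpy()], axis=1))
            signed = d[sel] * np.sign(truth["effect"].to_numpy()[sel])
            diffs.extend(signed.tolist())
        assert np.mean(diffs) == pytest.approx(0.40, abs=0.03)

    def test_dispersion_recovered_by_method_of_moments(self):
        """Empirical per-site dispersion converges to configured phi."""
        rng = np.random.default_rng(0)
        phi, mu, n = 0.10, 0.5, 50
        conc = 1 / phi - 1
        lat = rng.beta(mu * conc, (1 - mu) * conc, size=(300, 200))
        m = rng.binomial(n, lat)
        p_hat = m / n
        v = p_hat.var(axis=1, ddof=1).mean()
        phi_hat = (v * n / (mu * (1 - mu)) - 1) / (n - 1)
        assert phi_hat == pytest.approx(phi, rel=0.2)

    def test_destroyed_cpgs_show_ancestry_methylation_artifact(self):
        cfg = _tiny_config(cpg_snp_fraction=0.2, missing_rate=0.0)
        b = self._pipeline(cfg)
        mx = b.matrices["ComGar"]
        keys = pd.MultiIndex.from_frame(mx.sites)
        truth = b.truth.set_index(["chrom", "pos"]).loc[keys]
        destroyed = truth["cpg_destroyed"].to_numpy()
        assert destroyed.any()
        p = mx.proportions()
        # carriers of the C->T allele read near-fully methylated
        vd = b.varsim.variants
        vkey = {(c, q): i for i, (c, q) in enumerate(zip(vd["chrom"], vd["pos"]))}
        boosted, baseline = [], []
        for i in np.flatnonzero(destroyed):
            vi = vkey[(mx.sites["chrom"].iloc[i], mx.sites["pos"].iloc[i])]
            for j, sid in enumerate(mx.samples):
                g = b.varsim.cohort_haps[sid][:, vi].sum()
                (boosted if g == 2 else baseline if g == 0 else boosted).append(p[i, j])
        if boosted and baseline:
            assert np.nanmean(boosted) > np.nanmean(baseline)


class TestFixtureBundle:
    def test_round_trip_reproduces_matrix(self, small_bundle, tmp_path):
        paths = write_fixture_bundle(small_bundle, tmp_path)
        mx = small_bundle.matrices["ComGar"]
        ids = list(mx.samples)
        raw = methio.read_bismark_cov([paths["cov"][s] for s in ids], ids)
        rebuilt = methio.counts_to_matrix(raw, ids)
        # written sites are those with at least one present entry
        nonempty = ~np.isnan(mx.n).all(axis=1)
        orig = mx.subset_sites(nonempty)
        # reader orders sites lexicographically; align before comparing
        order = np.lexsort((orig.sites["pos"], orig.sites["chrom"]))
        pd.testing.assert_frame_equal(rebuilt.sites,
                                      orig.sites.iloc[order].reset_index(drop=True))
        assert np.array_equal(rebuilt.m, orig.m[order], equal_nan=True)
        assert np.array_equal(rebuilt.n, orig.n[order], equal_nan=True)

    def test_sample_count_and_coverage_files(self, small_bundle, tmp_path):
        paths = write_fixture_bundle(small_bundle, tmp_path)
        assert len(paths["cov"]) == 46

    def test_vcf_is_sorted_and_parse_valid(self, small_bundle, tmp_path):
        import pysam

        paths = write_fixture_bundle(small_bundle, tmp_path)
        vf = pysam.VariantFile(str(paths["vcf"]))
        last = {}
        n = 0
        for rec in vf:
            n += 1
            assert rec.pos >= last.get(rec.chrom, 0)
            last[rec.chrom] = rec.pos
            assert rec.ref in "ACGT" and rec.alts[0] in "ACGT"
        assert n == len(small_bundle.varsim.variants)

    def test_bundle_byte_identical_across_runs(self, tmp_path):
        cfg = _tiny_config(seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture_bundle(simulate_bundle(cfg), d1)
        write_fixture_bundle(simulate_bundle(cfg), d2)
        for rel in ("genome.fa", "variants.vcf", "samples.tsv", "truth.tsv"):
            assert filecmp.cmp(d1 / rel, d2 / rel, shallow=False), rel
        covs = sorted(p.name for p in (d1 / "cov").iterdir())
        assert covs == sorted(p.name for p in (d2 / "cov").iterdir())
        for name in covs:
            assert filecmp.cmp(d1 / "cov" / name, d2 / "cov" / name, shallow=False)
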