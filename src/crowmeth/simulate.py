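"""Synthetic genomes, two-taxon variation, cohorts, and RRBS-like CpG counts.

The generator is the exact inverse of the downstream analysis assumptions:
taxon allele frequencies follow the Balding-Nichols construction (so windowed
F_ST recovers the configured differentiation), methylation counts are
beta-binomial around feature-class baselines with planted age / sex / taxon /
year effects, coverage is negative-binomial with a heavy outlier tail, and a
subset of transition SNPs destroys CpG context to give the SNP-masking
filters real signal. Every planting is recorded in a truth table.

Study designs emulated: a common-garden cohort (ComGar; 8 individuals x 3
age classes at 2x2 taxon/sex parity, 24 libraries) and a hybrid-zone transect
(HybZon; 22 male chicks, hybrid index spanning 0-1, years 2008/2013/2014),
plus a 28-individual resequencing panel (14 per taxon) for population
genetics. Hybrid genomes are ancestry mosaics in 5-kb blocks with the focal
region inherited as a single block.

All randomness flows from one seed through named child streams
(`_stream(config, name)`), so a fixed config reproduces the bundle exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .annotate import (FeatureTrack, as_bytes, build_feature_track,
                       detect_cpg_islands_genome, island_criteria, to_str)
from .methio import MethylationMatrix

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(c) for c in "ACGT")
TRANSITION_PARTNER = {"C": "T", "T": "C", "A": "G", "G": "A"}
AGE_CODE = {"Chick": 0.0, "Yearling": 0.5, "Adult": 1.0}
YEAR_CODE = {2008: 0.0, 2013: 0.5, 2014: 1.0}
EXPERIMENTS = ("ComGar", "HybZon")


class SimConfigError(ValueError):
    pass


@dataclass
class Chrom:
    name: str
    length: int
    is_sex: bool = False


def _default_chromosomes():
    return [Chrom("chr18", 3_000_000), Chrom("chr1", 3_000_000)]


def _default_baselines():
    return {"promoter": 0.08, "repeat": 0.80, "CDS": 0.70,
            "intron": 0.70, "intergenic": 0.75}


@dataclass
class SimConfig:
    """All tunables of the synthetic study. Defaults are the desk-scale
    rendering of the two crow experiments (see docs/methods.md)."""

    chromosomes: list = field(default_factory=_default_chromosomes)
    focal_region: tuple = ("chr18", 1_000_000, 2_000_000)
    # genome
    n_genes: int = 120
    n_repeats: int = 150
    gene_length: int = 6000
    island_fraction: float = 0.7
    island_length: int = 600
    island_gc: float = 0.65
    island_oe: float = 0.8
    gc_content: float = 0.42
    background_cpg_rate: float = 0.010
    # variation
    n_snps: int = 12_000
    transition_fraction: float = 0.66
    cpg_snp_fraction: float = 0.04
    fst_background: float = 0.05
    fst_focal: float = 0.60
    near_fixed_fraction: float = 0.5
    n_reseq_per_taxon: int = 14
    ancestry_block: int = 5000
    # methylation
    n_cpgs_assayed: int = 20_000
    promoter_weight: float = 5.0
    baseline_methylation: dict = field(default_factory=_default_baselines)
    baseline_sd: float = 0.04
    n_age_effects: int = 300
    age_delta: float = 0.30
    n_sex_effects: int = 200
    sex_delta: float = 0.30
    sex_chrom_fraction: float = 0.8
    n_taxon_both: int = 100
    n_taxon_comgar: int = 30
    n_taxon_hybzon: int = 20
    taxon_delta: float = 0.40
    focal_taxon_fraction: float = 0.7
    cis_linked_fraction: float = 0.5
    n_year_effects: int = 30
    year_delta: float = 0.25
    phi: float = 0.05
    coverage_mean: float = 30.0
    coverage_shape: float = 8.0
    coverage_outlier_fraction: float = 0.01
    missing_rate: float = 0.03
    experiment_dropout: float = 0.08
    seed: int = 0

    def chrom_sizes(self) -> dict:
        return {c.name: c.length for c in self.chromosomes}

    def validate(self):
        sizes = self.chrom_sizes()
        fc, fs, fe = self.focal_region
        if fc not in sizes or not (0 <= fs < fe <= sizes[fc]):
            raise SimConfigError("focal_region must lie inside a declared chromosome")
        for name, v in (("island_fraction", self.island_fraction),
                        ("transition_fraction", self.transition_fraction),
                        ("cpg_snp_fraction", self.cpg_snp_fraction),
                        ("near_fixed_fraction", self.near_fixed_fraction),
                        ("missing_rate", self.missing_rate),
                        ("gc_content", self.gc_content)):
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1]")
        for v in self.baseline_methylation.values():
            if not 0.0 <= v <= 1.0:
                raise SimConfigError("baseline methylation proportions must be in [0, 1]")
        if not (0.0 <= self.fst_background < 1.0 and 0.0 <= self.fst_focal < 1.0):
            raise SimConfigError("fst parameters must be in [0, 1)")
        if self.phi < 0:
            raise SimConfigError("dispersion phi must be >= 0")
        min_len = 2 * (self.island_length + self.gene_length)
        for c in self.chromosomes:
            if c.length < min_len:
                raise SimConfigError(
                    f"chromosome {c.name} shorter than 2*(island+gene) = {min_len}")


def _stream(config: SimConfig, name: str) -> np.random.Generator:
    """Named child stream of the config seed (splittable, order-independent)."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


# ---------------------------------------------------------------------------
# genome


@dataclass
class Genome:
    sequences: dict            # chrom -> uint8 array
    genes: pd.DataFrame        # chrom, start, end, strand, name, has_island
    islands: pd.DataFrame      # designed island loci
    cds: pd.DataFrame
    introns: pd.DataFrame
    repeats: pd.DataFrame

    def chrom_sizes(self) -> dict:
        return {c: len(s) for c, s in self.sequences.items()}


def make_island_sequence(length: int, gc: float, oe: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Token-shuffled sequence with designed GC content and CpG O/E ratio.

    Realised O/E lands at or slightly above the design (token shuffling can
    only add CG adjacencies); the construction is retried until the standard
    island composition criteria hold.
    """
    n_c = n_g = int(round(gc * length / 2))
    n_cg = int(round(oe * n_c * n_g / length))
    for _ in range(50):
        tokens = (["CG"] * n_cg + ["C"] * (n_c - n_cg) + ["G"] * (n_g - n_cg))
        n_fill = length - sum(len(t) for t in tokens)
        tokens += list(rng.choice(["A", "T"], size=n_fill))
        rng.shuffle(tokens)
        seq = as_bytes("".join(tokens))[:length]
        nc = int((seq == _C).sum()); ng = int((seq == _G).sum())
        ncg = int(((seq[:-1] == _C) & (seq[1:] == _G)).sum())
        if island_criteria(nc, ng, ncg, length):
            return seq
    raise SimConfigError("island design parameters below the detection thresholds")


def _background_sequence(length: int, gc: float, cpg_rate: float,
                         rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = BASES[rng.choice(4, size=length, p=p)]
    # deplete CpG to the configured background rate (C of CG -> T)
    cg = np.flatnonzero((seq[:-1] == _C) & (seq[1:] == _G))
    keep = min(1.0, cpg_rate / max((gc / 2) ** 2, 1e-12))
    kill = cg[rng.random(len(cg)) >= keep]
    seq[kill] = _T
    return seq


def simulate_genome(config: SimConfig, rng: np.random.Generator) -> Genome:
    config.validate()
    sizes = config.chrom_sizes()
    total = sum(sizes.values())
    sequences, gene_rows, island_rows, cds_rows, intron_rows, repeat_rows = (
        {}, [], [], [], [], [])
    gid = 0
    for c in config.chromosomes:
        seq = _background_sequence(c.length, config.gc_content,
                                   config.background_cpg_rate, rng)
        n_genes_c = int(round(config.n_genes * c.length / total))
        stride = config.gene_length + 2 * 2000 + 1000
        n_slots = max((c.length - 2000) // stride, 0)
        n_genes_c = min(n_genes_c, n_slots)
        slots = rng.choice(n_slots, size=n_genes_c, replace=False) if n_genes_c else []
        for slot in np.sort(slots):
            off = int(rng.integers(0, 1000))
            start = 2000 + slot * stride + off
            end = start + config.gene_length
            strand = "+" if rng.random() < 0.5 else "-"
            has_island = rng.random() < config.island_fraction
            if has_island:
                isl = make_island_sequence(config.island_length, config.island_gc,
                                           config.island_oe, rng)
                span = 2000 - config.island_length
                ioff = int(rng.integers(0, span)) if span > 0 else 0
                istart = (start - 2000 + ioff) if strand == "+" else (end + ioff)
                seq[istart:istart + config.island_length] = isl
                island_rows.append((c.name, istart, istart + config.island_length))
            gene_rows.append((c.name, start, end, strand, f"gene{gid}", has_island))
            # three 400-bp CDS exons, introns between
            mid = (start + end) // 2
            exons = [(start, start + 400), (mid - 200, mid + 200), (end - 400, end)]
            for es, ee in exons:
                cds_rows.append((c.name, es, ee))
            intron_rows.append((c.name, start + 400, mid - 200))
            intron_rows.append((c.name, mid + 200, end - 400))
            gid += 1
        sequences[c.name] = seq
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand",
                                             "name", "has_island"])
    cds = pd.DataFrame(cds_rows, columns=["chrom", "start", "end"])
    introns = pd.DataFrame(intron_rows, columns=["chrom", "start", "end"])
    # repeats: random intervals avoiding CDS
    for c in config.chromosomes:
        n_rep_c = int(round(config.n_repeats * c.length / total))
        csub = cds[cds["chrom"] == c.name]
        placed = 0
        attempts = 0
        while placed < n_rep_c and attempts < 50 * n_rep_c:
            attempts += 1
            rl = int(rng.integers(200, 2000))
            rs = int(rng.integers(0, c.length - rl))
            if ((csub["start"] < rs + rl) & (csub["end"] > rs)).any():
                continue
            repeat_rows.append((c.name, rs, rs + rl))
            placed += 1
    repeats = pd.DataFrame(repeat_rows, columns=["chrom", "start", "end"])
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    return Genome(sequences, genes, islands, cds, introns, repeats)


def annotate_genome(config: SimConfig, genome: Genome) -> FeatureTrack:
    """Run the annotation pipeline on a simulated genome (islands are
    re-detected from sequence, not taken from the design)."""
    from .annotate import call_promoter_islands
    islands = detect_cpg_islands_genome(genome.sequences)
    promoters = call_promoter_islands(islands, genome.genes) if len(genome.genes) else islands.iloc[:0]
    return build_feature_track(promoters, genome.repeats, genome.cds,
                               genome.introns, config.chrom_sizes())


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohorts(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample table for both experiments.

    ComGar: 8 individuals (2 per taxon x sex cell) x 3 age classes = 24 rows.
    HybZon: 22 male chicks; 3 purebreds per taxon plus 16 hybrids whose
    hybrid indices spread across (0, 1); years from {2008, 2013, 2014}.
    """
    rows = []
    ind = 0
    for taxon in ("corone", "cornix"):
        for sex in ("M", "F"):
            for _rep in range(2):
                ind += 1
                for age in ("Chick", "Yearling", "Adult"):
                    rows.append({
                        "id": f"CG{ind:02d}_{age}", "experiment": "ComGar",
                        "individual": f"CG{ind:02d}", "taxon": taxon, "sex": sex,
                        "age": age, "year": 2014,
                        "hybrid_index": 0.0 if taxon == "corone" else 1.0})
    h_hybrids = np.clip(np.linspace(0.06, 0.94, 16) + rng.normal(0, 0.02, 16), 0.02, 0.98)
    h_all = np.concatenate([[0.0, 0.0, 0.0], h_hybrids, [1.0, 1.0, 1.0]])
    years = rng.choice([2008, 2013, 2014], size=22)
    for i, (h, yr) in enumerate(zip(h_all, years), start=1):
        taxon = "corone" if h == 0.0 else ("cornix" if h == 1.0 else "hybrid")
        rows.append({
            "id": f"HZ{i:02d}", "experiment": "HybZon", "individual": f"HZ{i:02d}",
            "taxon": taxon, "sex": "M", "age": "Chick", "year": int(yr),
            "hybrid_index": float(h)})
    return pd.DataFrame(rows)


def validate_sample_table(samples: pd.DataFrame):
    cg = samples[samples["experiment"] == "ComGar"]
    hz = samples[samples["experiment"] == "HybZon"]
    assert len(cg) == 24 and cg["individual"].nunique() == 8
    assert cg.groupby(["taxon", "sex"]).size().eq(6).all()
    assert len(hz) == 22 and (hz["sex"] == "M").all() and (hz["age"] == "Chick").all()
    h = hz["hybrid_index"]
    assert h.notna().all() and h.min() == 0.0 and h.max() == 1.0


# ---------------------------------------------------------------------------
# variants


@dataclass
class VariantSim:
    variants: pd.DataFrame        # chrom,pos,ref,alt,qual,is_transition,on_cpg,
                                  # p_corone,p_cornix,in_focal
    panel_samples: list
    panel_pops: np.ndarray        # per panel sample
    panel_haps: np.ndarray        # (2*n_panel, n_snps) int8
    cohort_haps: dict             # sample id -> (2, n_snps) int8
    cohort_focal_ancestry: dict   # sample id -> (2,) 0=corone 1=cornix

    def cohort_dosage(self, sample_id: str, variant_idx) -> np.ndarray:
        return self.cohort_haps[sample_id][:, variant_idx].sum(axis=0)


def _cpg_positions(seq: np.ndarray) -> np.ndarray:
    return np.flatnonzero((seq[:-1] == _C) & (seq[1:] == _G))


def simulate_variants(config: SimConfig, genome: Genome, samples: pd.DataFrame,
                      rng: np.random.Generator) -> VariantSim:
    sizes = genome.chrom_sizes()
    fc, fs, fe = config.focal_region

    # -- positions
    n_trans = int(round(config.n_snps * config.transition_fraction))
    n_cpg = int(round(n_trans * config.cpg_snp_fraction))
    rows = []
    used = {c: set() for c in sizes}
    cpg_pool = []
    for chrom, seq in genome.sequences.items():
        for p in _cpg_positions(seq):
            cpg_pool.append((chrom, int(p)))
    if n_cpg > len(cpg_pool):
        raise SimConfigError("n_snps CpG subset exceeds available CpG sites")
    for i in rng.choice(len(cpg_pool), size=n_cpg, replace=False):
        chrom, p = cpg_pool[i]
        # C->T on the CpG cytosine itself, or a transition 1 bp away
        if rng.random() < 0.7:
            pos, ref = p, "C"
        else:
            pos = p - 1 if (p > 0 and rng.random() < 0.5) else p + 2
            if not (0 <= pos < sizes[chrom]):
                pos = p
            ref = chr(genome.sequences[chrom][pos])
            if ref == "N":
                pos, ref = p, "C"
        if pos in used[chrom]:
            continue
        used[chrom].add(pos)
        rows.append((chrom, pos, ref, TRANSITION_PARTNER[ref], True, True))
    total_len = sum(sizes.values())
    n_rest = config.n_snps - len(rows)
    if n_rest > total_len - len(rows):
        raise SimConfigError("n_snps exceeds available sites")
    chrom_names = list(sizes)
    chrom_p = np.array([sizes[c] for c in chrom_names], dtype=float)
    chrom_p /= chrom_p.sum()
    n_trans_rest = n_trans - len(rows)
    k = 0
    while k < n_rest:
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
        pos = int(rng.integers(0, sizes[chrom]))
        if pos in used[chrom]:
            continue
        ref = chr(genome.sequences[chrom][pos])
        if ref not in "ACGT":
            continue
        used[chrom].add(pos)
        if k < n_trans_rest:
            alt = TRANSITION_PARTNER[ref]
            is_trans = True
        else:
            alt = rng.choice([b for b in "ACGT" if b != ref and b != TRANSITION_PARTNER[ref]])
            is_trans = False
        rows.append((chrom, pos, ref, alt, is_trans, False))
        k += 1
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "is_transition", "on_cpg"])
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    # -- taxon allele frequencies (Balding-Nichols)
    S = len(df)
    in_focal = ((df["chrom"] == fc) & (df["pos"] >= fs) & (df["pos"] < fe)).to_numpy()
    p_anc = rng.uniform(0.05, 0.95, size=S)
    F = np.where(in_focal, config.fst_focal, config.fst_background)
    p_cor = np.empty(S)
    p_nix = np.empty(S)
    for tgt in (p_cor, p_nix):
        with np.errstate(divide="ignore"):
            a = p_anc * (1 - F) / np.maximum(F, 1e-12)
            b = (1 - p_anc) * (1 - F) / np.maximum(F, 1e-12)
        tgt[:] = np.where(F < 1e-9, p_anc, rng.beta(np.maximum(a, 1e-9),
                                                    np.maximum(b, 1e-9)))
    focal_idx = np.flatnonzero(in_focal)
    n_fix = int(round(len(focal_idx) * config.near_fixed_fraction))
    fix_idx = rng.choice(focal_idx, size=n_fix, replace=False) if n_fix else []
    for i in fix_idx:
        lo, hi = rng.uniform(0, 0.05), rng.uniform(0.95, 1.0)
        if rng.random() < 0.5:
            p_cor[i], p_nix[i] = lo, hi
        else:
            p_cor[i], p_nix[i] = hi, lo
    df["p_corone"] = p_cor
    df["p_cornix"] = p_nix
    df["in_focal"] = in_focal
    df["qual"] = 99.0

    # -- panel haplotypes
    n_panel = 2 * config.n_reseq_per_taxon
    panel_samples = ([f"COR{i:02d}" for i in range(1, config.n_reseq_per_taxon + 1)]
                     + [f"NIX{i:02d}" for i in range(1, config.n_reseq_per_taxon + 1)])
    panel_pops = np.array(["corone"] * config.n_reseq_per_taxon
                          + ["cornix"] * config.n_reseq_per_taxon)
    panel_haps = np.empty((2 * n_panel, S), dtype=np.int8)
    for i, pop in enumerate(panel_pops):
        p = p_cor if pop == "corone" else p_nix
        panel_haps[2 * i] = rng.random(S) < p
        panel_haps[2 * i + 1] = rng.random(S) < p

    # -- cohort haplotypes: ancestry mosaics in 5-kb blocks, focal one block
    pos_arr = df["pos"].to_numpy()
    chrom_arr = df["chrom"].to_numpy()
    block_of = np.empty(S, dtype=np.int64)
    block_base = {}
    nxt = 0
    for chrom in chrom_names:
        msk = chrom_arr == chrom
        blk = pos_arr[msk] // config.ancestry_block
        uniq = np.unique(blk)
        remap = {b: nxt + j for j, b in enumerate(uniq)}
        block_of[msk] = [remap[b] for b in blk]
        nxt += len(uniq)
    focal_block_ids = np.unique(block_of[in_focal])
    n_blocks = nxt
    cohort_haps = {}
    cohort_anc = {}
    for _, row in samples.iterrows():
        h = float(row["hybrid_index"])
        haps = np.empty((2, S), dtype=np.int8)
        anc_focal = np.empty(2, dtype=np.int8)
        for a in range(2):
            anc_block = (rng.random(n_blocks) < h).astype(np.int8)
            focal_state = np.int8(rng.random() < h)
            anc_block[focal_block_ids] = focal_state
            anc_focal[a] = focal_state
            anc_site = anc_block[block_of]
            p_site = np.where(anc_site == 1, p_nix, p_cor)
            haps[a] = rng.random(S) < p_site
        cohort_haps[row["id"]] = haps
        cohort_anc[row["id"]] = anc_focal
    return VariantSim(df, panel_samples, panel_pops, panel_haps,
                      cohort_haps, cohort_anc)


# ---------------------------------------------------------------------------
# methylation


def simulate_methylation(genome: Genome, track: FeatureTrack, varsim: VariantSim,
                         samples: pd.DataFrame, config: SimConfig,
                         rng: np.random.Generator):
    """Beta-binomial CpG counts with planted effects for both experiments.

    Returns ({"ComGar": MethylationMatrix, "HybZon": ...}, truth DataFrame).
    """
    if config.phi < 0:
        raise SimConfigError("phi must be >= 0")
    cfg = config
    # assayed CpGs: weighted toward promoters (RRBS enrichment), forcing in
    # the CpG-destroying SNP sites so masking has signal to remove
    cpgs = []
    for chrom, seq in genome.sequences.items():
        for p in _cpg_positions(seq):
            cpgs.append((chrom, int(p)))
    cpgs = pd.DataFrame(cpgs, columns=["chrom", "pos"])
    labels = track.annotate_positions(cpgs["chrom"].to_numpy(), cpgs["pos"].to_numpy())
    weights = np.where(labels == "promoter", cfg.promoter_weight, 1.0)
    vd = varsim.variants
    destroyer = vd[(vd["on_cpg"]) & (vd["ref"] == "C") & (vd["alt"] == "T")]
    destroyer_keys = set(zip(destroyer["chrom"], destroyer["pos"]))
    is_destroyed = np.fromiter(((c, p) in destroyer_keys
                                for c, p in zip(cpgs["chrom"], cpgs["pos"])),
                               dtype=bool, count=len(cpgs))
    n_assay = min(cfg.n_cpgs_assayed, len(cpgs))
    prob = weights / weights.sum()
    chosen = np.zeros(len(cpgs), dtype=bool)
    chosen[rng.choice(len(cpgs), size=n_assay, replace=False, p=prob)] = True
    chosen |= is_destroyed
    sites = cpgs[chosen].reset_index(drop=True)
    labels = labels[chosen]
    is_destroyed = is_destroyed[chosen]
    S = len(sites)

    fc, fs, fe = cfg.focal_region
    in_focal = ((sites["chrom"] == fc) & (sites["pos"] >= fs)
                & (sites["pos"] < fe)).to_numpy()
    sex_chroms = {c.name for c in cfg.chromosomes if c.is_sex}
    on_sex = sites["chrom"].isin(sex_chroms).to_numpy()

    mu0 = np.array([cfg.baseline_methylation[l] for l in labels])
    mu0 = np.clip(mu0 + rng.normal(0, cfg.baseline_sd, S), 0.02, 0.98)

    truth = pd.DataFrame({
        "chrom": sites["chrom"], "pos": sites["pos"], "feature": labels,
        "covariate": "none", "effect": 0.0, "scope": "", "focal": in_focal,
        "cis_linked": False, "cpg_destroyed": is_destroyed})

    free = ~is_destroyed

    def _signs(idx, delta):
        """Effect direction per site, constrained so the full delta is
        realisable from the site's baseline without clamping."""
        can_up = mu0[idx] + delta <= 0.95
        can_dn = mu0[idx] - delta >= 0.05
        s = rng.choice([-1.0, 1.0], size=len(idx))
        s[can_up & ~can_dn] = 1.0
        s[can_dn & ~can_up] = -1.0
        return s

    def _draw(pool_mask, k):
        pool = np.flatnonzero(pool_mask & free)
        k = min(k, len(pool))
        idx = rng.choice(pool, size=k, replace=False) if k else np.array([], int)
        free[idx] = False
        return idx

    # taxon: enriched in focal region; some tied to cis focal ancestry
    n_taxon = cfg.n_taxon_both + cfg.n_taxon_comgar + cfg.n_taxon_hybzon
    n_focal_eff = int(round(n_taxon * cfg.focal_taxon_fraction))
    idx_focal = _draw(in_focal, n_focal_eff)
    idx_bg = _draw(~in_focal & ~on_sex, n_taxon - len(idx_focal))
    taxon_idx = np.concatenate([idx_focal, idx_bg])
    rng.shuffle(taxon_idx)
    scopes = (["both"] * cfg.n_taxon_both + ["comgar"] * cfg.n_taxon_comgar
              + ["hybzon"] * cfg.n_taxon_hybzon)[:len(taxon_idx)]
    n_cis = int(round(len(idx_focal) * cfg.cis_linked_fraction))
    cis_set = set(rng.choice(idx_focal, size=n_cis, replace=False)) if n_cis else set()
    taxon_sign = _signs(taxon_idx, cfg.taxon_delta)
    for j, (i, sc) in enumerate(zip(taxon_idx, scopes)):
        truth.loc[i, ["covariate", "effect", "scope", "cis_linked"]] = (
            "taxon", taxon_sign[j] * cfg.taxon_delta, sc, i in cis_set)

    # sex: enriched on a declared sex chromosome if any
    if on_sex.any():
        k_z = int(round(cfg.n_sex_effects * cfg.sex_chrom_fraction))
        sex_idx = np.concatenate([_draw(on_sex, k_z),
                                  _draw(~on_sex, cfg.n_sex_effects - k_z)])
    else:
        sex_idx = _draw(np.ones(S, bool), cfg.n_sex_effects)
    for i, sg in zip(sex_idx, _signs(sex_idx, cfg.sex_delta)):
        truth.loc[i, ["covariate", "effect", "scope"]] = ("sex", sg * cfg.sex_delta, "comgar")

    age_idx = _draw(np.ones(S, bool), cfg.n_age_effects)
    for i, sg in zip(age_idx, _signs(age_idx, cfg.age_delta)):
        truth.loc[i, ["covariate", "effect", "scope"]] = ("age", sg * cfg.age_delta, "comgar")

    year_idx = _draw(np.ones(S, bool), cfg.n_year_effects)
    for i, sg in zip(year_idx, _signs(year_idx, cfg.year_delta)):
        truth.loc[i, ["covariate", "effect", "scope"]] = ("year", sg * cfg.year_delta, "hybzon")

    # per-site variant index for destroyed CpGs
    vkey = {(c, p): i for i, (c, p) in enumerate(zip(vd["chrom"], vd["pos"]))}
    destroyed_vidx = np.full(S, -1, dtype=int)
    for i in np.flatnonzero(is_destroyed):
        destroyed_vidx[i] = vkey[(sites["chrom"].iloc[i], sites["pos"].iloc[i])]

    effect = truth["effect"].to_numpy()
    cov = truth["covariate"].to_numpy()
    scope = truth["scope"].to_numpy()
    cis = truth["cis_linked"].to_numpy()

    matrices = {}
    for exp in EXPERIMENTS:
        sub = samples[samples["experiment"] == exp].reset_index(drop=True)
        N = len(sub)
        mu = np.tile(mu0[:, None], (1, N))
        applies = np.isin(scope, ["both", exp.lower()])
        for j, row in sub.iterrows():
            h = float(row["hybrid_index"])
            anc_frac = varsim.cohort_focal_ancestry[row["id"]].mean()
            shift = np.zeros(S)
            tx = (cov == "taxon") & applies
            shift[tx & ~cis] += effect[tx & ~cis] * h
            shift[tx & cis] += effect[tx & cis] * anc_frac
            if exp == "ComGar":
                ag = (cov == "age") & applies
                shift[ag] += effect[ag] * AGE_CODE[row["age"]]
                sx = (cov == "sex") & applies
                shift[sx] += effect[sx] * (row["sex"] == "F")
            else:
                yr = (cov == "year") & applies
                shift[yr] += effect[yr] * YEAR_CODE[int(row["year"])]
            mu[:, j] = np.clip(mu0 + shift, 0.01, 0.99)
        # coverage: negative binomial with outlier tail
        p_nb = cfg.coverage_shape / (cfg.coverage_shape + cfg.coverage_mean)
        n_mat = rng.negative_binomial(cfg.coverage_shape, p_nb, size=(S, N)).astype(float)
        out = rng.random((S, N)) < cfg.coverage_outlier_fraction
        p_out = cfg.coverage_shape / (cfg.coverage_shape + 10 * cfg.coverage_mean)
        n_mat[out] = rng.negative_binomial(cfg.coverage_shape, p_out, size=int(out.sum()))
        n_mat = np.maximum(n_mat, 0)
        # beta-binomial counts
        if cfg.phi > 0:
            conc = 1.0 / cfg.phi - 1.0
            p_lat = rng.beta(np.maximum(mu * conc, 1e-9),
                             np.maximum((1 - mu) * conc, 1e-9))
        else:
            p_lat = mu
        m_mat = rng.binomial(n_mat.astype(int), p_lat).astype(float)
        # CpG-destroying C->T: alt-haplotype reads report as methylated
        for i in np.flatnonzero(is_destroyed):
            vi = destroyed_vidx[i]
            for j, row in sub.iterrows():
                g = int(varsim.cohort_haps[row["id"]][:, vi].sum())
                if g == 0:
                    continue
                n_i = int(n_mat[i, j])
                n_alt = rng.binomial(n_i, g / 2.0)
                m_mat[i, j] = n_alt + rng.binomial(n_i - n_alt, p_lat[i, j])
        # missingness: random entry dropout + whole-site experiment dropout
        miss = (rng.random((S, N)) < cfg.missing_rate) | (n_mat == 0)
        m_mat[miss] = np.nan
        n_mat[miss] = np.nan
        keep_sites = rng.random(S) >= cfg.experiment_dropout
        keep_sites |= (cov == "taxon") & (scope == "both")
        mx = MethylationMatrix(sites.copy(), m_mat, n_mat, list(sub["id"]))
        matrices[exp] = mx.subset_sites(keep_sites)
    return matrices, truth


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimBundle:
    config: SimConfig
    genome: Genome
    track: FeatureTrack
    samples: pd.DataFrame
    varsim: VariantSim
    matrices: dict
    truth: pd.DataFrame


def simulate_bundle(config: Optional[SimConfig] = None) -> SimBundle:
    """Run the full generator from one config; each stage on its own stream."""
    config = config or SimConfig()
    config.validate()
    genome = simulate_genome(config, _stream(config, "genome"))
    track = annotate_genome(config, genome)
    samples = simulate_cohorts(config, _stream(config, "cohorts"))
    varsim = simulate_variants(config, genome, samples, _stream(config, "variants"))
    matrices, truth = simulate_methylation(genome, track, varsim, samples,
                                           config, _stream(config, "methylation"))
    return SimBundle(config, genome, track, samples, varsim, matrices, truth)


def write_fasta(sequences: Mapping[str, np.ndarray], path, width: int = 80):
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            s = to_str(as_bytes(seq))
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def write_vcf(varsim: VariantSim, path):
    """Panel genotypes as a sorted, parse-valid VCF 4.2 text file."""
    df = varsim.variants
    chroms = list(dict.fromkeys(df["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=crowmeth-simulate\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(varsim.panel_samples) + "\n")
        H = varsim.panel_haps
        n = len(varsim.panel_samples)
        for i, row in enumerate(df.itertuples(index=False)):
            gts = []
            for s in range(n):
                a, b = H[2 * s, i], H[2 * s + 1, i]
                gts.append(f"{a}|{b}:15")
            fh.write(f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t"
                     f"{row.qual:.0f}\tPASS\tNS={n}\tGT:DP\t" + "\t".join(gts) + "\n")


def write_bismark_cov(matrix: MethylationMatrix, outdir: Path):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for j, sid in enumerate(matrix.samples):
        path = outdir / f"{sid}.cov"
        with open(path, "w") as fh:
            for i in range(matrix.n_sites):
                n = matrix.n[i, j]
                if np.isnan(n):
                    continue
                m = int(matrix.m[i, j]); n = int(n)
                chrom = matrix.sites["chrom"].iloc[i]
                pos1 = int(matrix.sites["pos"].iloc[i]) + 1
                pct = 100.0 * m / n if n else 0.0
                fh.write(f"{chrom}\t{pos1}\t{pos1}\t{pct:.6g}\t{m}\t{n - m}\n")
        paths[sid] = path
    return paths


def write_fixture_bundle(bundle: SimBundle, outdir) -> dict:
    """Write the full fixture: FASTA, VCF, BEDs, per-sample coverage files,
    sample metadata, and the truth table. Round-trip reading reproduces the
    matrices exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": outdir / "genome.fa", "vcf": outdir / "variants.vcf",
             "genes": outdir / "genes.bed", "repeats": outdir / "repeats.bed",
             "focal": outdir / "focal_region.bed",
             "samples": outdir / "samples.tsv", "truth": outdir / "truth.tsv"}
    write_fasta(bundle.genome.sequences, paths["fasta"])
    write_vcf(bundle.varsim, paths["vcf"])
    g = bundle.genome.genes
    with open(paths["genes"], "w") as fh:
        for r in g.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")
    bundle.genome.repeats.to_csv(paths["repeats"], sep="\t", header=False, index=False)
    fc, fs, fe = bundle.config.focal_region
    with open(paths["focal"], "w") as fh:
        fh.write(f"{fc}\t{fs}\t{fe}\tfocal_region\n")
    bundle.samples.to_csv(paths["samples"], sep="\t", index=False)
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["cov"] = {}
    for exp, mx in bundle.matrices.items():
        paths["cov"].update(write_bismark_cov(mx, outdir / "cov"))
    return paths
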