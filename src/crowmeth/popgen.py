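"""Variant filtering, transition masks, windowed population-genetic
statistics, and focal-region delineation.

Windowed estimators (fixed 5-kb coordinate windows, minimum 1000 genotyped
sites):

* Hudson's F_ST as a ratio of averages, 1 - mean(pi_w) / mean(pi_b);
* D_XY, the mean between-population pairwise difference per genotyped site
  (invariant sites contribute 0 to the numerator, length to the denominator);
* Tajima's D and Fu & Li's D* pooled over all haplotypes, with the standard
  normalising constants; undefined (NaN) when a window has no segregating
  sites;
* haplotype diversity Hd = n/(n-1) (1 - sum f_k^2) over distinct window
  haplotypes (requires phased input).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# variant container and filters


@dataclass
class VariantSet:
    """Biallelic variant records with per-sample genotypes.

    variants: DataFrame chrom, pos (0-based), ref, alt, qual.
    gt: (n_var, n_samples, 2) int8 allele codes, -1 = missing.
    dp: (n_var, n_samples) per-sample depth.
    """

    variants: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray
    samples: list
    pops: Optional[dict] = None  # sample -> population label

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, mask) -> "VariantSet":
        mask = np.asarray(mask)
        return VariantSet(self.variants.loc[mask].reset_index(drop=True),
                          self.gt[mask], self.dp[mask], list(self.samples),
                          self.pops)


def read_vcf(path, pops: Optional[Mapping[str, str]] = None) -> VariantSet:
    """Read a VCF 4.x into a VariantSet (biallelic and multiallelic records
    alike; filtering decides what survives)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, gts, dps = [], [], []
    for lineno, rec in enumerate(vf.fetch() if vf.index else vf, 1):
        alts = rec.alts or ()
        rows.append((rec.chrom, rec.pos - 1, rec.ref,
                     alts[0] if alts else ".", len(alts),
                     rec.qual if rec.qual is not None else np.nan))
        g = np.full((len(samples), 2), -1, dtype=np.int8)
        d = np.zeros(len(samples))
        for j, s in enumerate(samples):
            call = rec.samples[s]
            al = call.get("GT")
            if al is not None:
                for k, a in enumerate(al[:2]):
                    g[j, k] = -1 if a is None else a
            d[j] = call.get("DP") or 0
        gts.append(g)
        dps.append(d)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "n_alt", "qual"])
    return VariantSet(df, np.array(gts, dtype=np.int8), np.array(dps),
                      samples, dict(pops) if pops else None)


def apply_variant_filters(vs: VariantSet, mean_depth: Optional[float] = None,
                          min_qual: float = 20.0, min_gt_depth: float = 3.0,
                          min_called_frac: float = 0.90):
    """Hard site and genotype filters.

    Retains biallelic SNPs with QUAL strictly > min_qual and site depth in
    (0, 2 x mean]; genotypes with per-sample depth < min_gt_depth are set
    missing; sites called in fewer than min_called_frac of samples dropped.
    Returns (VariantSet, report dict of per-rule removal counts).
    """
    df = vs.variants
    report = {"input": vs.n_variants}
    bial = ((df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)
            & (df["alt"] != "."))
    if "n_alt" in df.columns:
        bial &= df["n_alt"] == 1
    report["not_biallelic_snp"] = int((~bial).sum())
    qual_ok = df["qual"] > min_qual
    report["low_qual"] = int((bial & ~qual_ok).sum())
    site_dp = vs.dp.sum(axis=1)
    if mean_depth is None:
        mean_depth = float(site_dp.mean()) if len(site_dp) else 0.0
    dp_ok = (site_dp > 0) & (site_dp <= 2 * mean_depth)
    report["depth"] = int((bial & qual_ok & ~dp_ok).sum())
    keep = (bial & qual_ok & dp_ok).to_numpy()
    out = vs.subset(keep)
    low_gt = out.dp < min_gt_depth
    out.gt[low_gt] = -1
    report["genotypes_masked"] = int(low_gt.sum())
    called = (out.gt[:, :, 0] >= 0).mean(axis=1)
    gt_ok = called >= min_called_frac
    report["low_call_rate"] = int((~gt_ok).sum())
    out = out.subset(gt_ok)
    report["output"] = out.n_variants
    return out, report


def transition_positions(vs: VariantSet) -> pd.DataFrame:
    """Positions of C-T and A-G polymorphisms (for methylation masking)."""
    df = vs.variants
    pair = df["ref"].str.upper() + df["alt"].str.upper()
    is_ts = pair.isin(["CT", "TC", "AG", "GA"])
    return df.loc[is_ts, ["chrom", "pos"]].reset_index(drop=True)


def write_bed(df: pd.DataFrame, path, name: Optional[str] = None):
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            end = getattr(r, "end", r.pos + 1)
            start = getattr(r, "start", r.pos)
            fh.write(f"{r.chrom}\t{start}\t{end}" + (f"\t{name}" if name else "") + "\n")


# ---------------------------------------------------------------------------
# estimators


def harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i ** power for i in range(1, n)))


def tajimas_d(S: int, pi: float, n: int) -> float:
    """Tajima's D from segregating sites S, mean pairwise differences pi
    (total, not per-site), and sample size n haplotypes. NaN when S = 0."""
    if S == 0 or n < 4:
        return float("nan")
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi - S / a1) / np.sqrt(var)


def fu_li_dstar(S: int, eta_s: int, n: int) -> float:
    """Fu & Li's D* (no outgroup) from S and singleton count eta_s."""
    if S == 0 or n < 4:
        return float("nan")
    an = harmonic(n)
    bn = harmonic(n, 2)
    an1 = an + 1.0 / n
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (cn + (n - 2) / (n - 1) ** 2
          + 2 / (n - 1) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n))
    nr = n / (n - 1.0)
    v = (nr ** 2 * bn + an ** 2 * dn - 2 * (n * an * (an + 1)) / (n - 1.0) ** 2) \
        / (an ** 2 + bn)
    u = nr * (an - nr) - v
    num = nr * S - an * eta_s
    return num / np.sqrt(u * S + v * S * S)


def _site_stats(hap: np.ndarray, pop_mask_a: np.ndarray, pop_mask_b: np.ndarray):
    """Per-site within/between heterozygosities for two populations."""
    na = pop_mask_a.sum()
    nb = pop_mask_b.sum()
    pa = hap[pop_mask_a].mean(axis=0)
    pb = hap[pop_mask_b].mean(axis=0)
    pw_a = 2 * pa * (1 - pa) * na / (na - 1)
    pw_b = 2 * pb * (1 - pb) * nb / (nb - 1)
    pi_w = 0.5 * (pw_a + pw_b)
    pi_b = pa * (1 - pb) + pb * (1 - pa)
    return pi_w, pi_b


def hudson_fst(pi_w: np.ndarray, pi_b: np.ndarray) -> float:
    """Ratio-of-averages Hudson F_ST over a set of sites."""
    denom = np.mean(pi_b)
    if denom <= 0:
        return float("nan")
    return 1.0 - np.mean(pi_w) / denom


def haplotype_diversity(hap: np.ndarray) -> float:
    """Hd = n/(n-1) (1 - sum f_k^2) over distinct haplotypes (rows)."""
    n = hap.shape[0]
    if n < 2:
        return float("nan")
    _, counts = np.unique(hap, axis=0, return_counts=True)
    f = counts / n
    return n / (n - 1) * (1 - np.sum(f ** 2))


def window_popgen(haplotypes: np.ndarray, positions: np.ndarray,
                  chroms: np.ndarray, pop_labels: Sequence[str],
                  chrom_sizes: Mapping[str, int], window_size: int = 5000,
                  min_sites: int = 1000,
                  genotyped_sites: Optional[Mapping] = None,
                  window_mode: str = "coords") -> pd.DataFrame:
    """Per-window population-genetic statistics from phased haplotypes.

    haplotypes: (n_hap, n_var) 0/1; positions/chroms per variant (sorted
    within chromosome); pop_labels one of two population names per
    haplotype. genotyped_sites maps (chrom, start) -> number of genotyped
    (variant + invariant) sites in the window; by default every base is
    taken as genotyped (all-sites callable), the synthetic-data convention.
    Windows with fewer than min_sites genotyped sites have their statistics
    flagged absent (NaN).
    """
    if window_mode != "coords":
        raise NotImplementedError("only fixed coordinate windows are supported")
    pop_labels = np.asarray(pop_labels)
    pops = pd.unique(pop_labels)
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    mask_a = pop_labels == pops[0]
    mask_b = pop_labels == pops[1]
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("need >= 2 haplotypes per population")
    n_hap = haplotypes.shape[0]
    rows = []
    for chrom, size in chrom_sizes.items():
        cmask = chroms == chrom
        cpos = positions[cmask]
        chap = haplotypes[:, cmask]
        for start in range(0, size, window_size):
            end = min(start + window_size, size)
            if genotyped_sites is not None:
                L = genotyped_sites.get((chrom, start), 0)
            else:
                L = end - start
            wmask = (cpos >= start) & (cpos < end)
            hap = chap[:, wmask]
            n_snps = hap.shape[1]
            row = {"chrom": chrom, "start": start, "end": end,
                   "n_sites": L, "n_snps": int(n_snps)}
            if L < min_sites:
                row.update({k: np.nan for k in
                            ("fst", "dxy", "tajima_d", "hd", "fu_li_dstar")})
                rows.append(row)
                continue
            if n_snps == 0:
                row.update({"fst": np.nan, "dxy": 0.0, "tajima_d": np.nan,
                            "hd": 0.0, "fu_li_dstar": np.nan})
                rows.append(row)
                continue
            pi_w, pi_b = _site_stats(hap, mask_a, mask_b)
            row["fst"] = hudson_fst(pi_w, pi_b)
            row["dxy"] = float(np.sum(pi_b) / L)
            p = hap.mean(axis=0)
            seg = (p > 0) & (p < 1)
            S = int(seg.sum())
            pi_tot = float(np.sum(2 * p * (1 - p) * n_hap / (n_hap - 1)))
            counts = hap.sum(axis=0)
            eta_s = int(np.sum((counts == 1) | (counts == n_hap - 1)))
            row["tajima_d"] = tajimas_d(S, pi_tot, n_hap)
            row["fu_li_dstar"] = fu_li_dstar(S, eta_s, n_hap)
            row["hd"] = haplotype_diversity(hap)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# focal region


@dataclass
class FocalRegion:
    chrom: Optional[str]
    start: int
    end: int
    n_qualifying_windows: int
    n_qualifying_off_chrom: int
    threshold: float

    @property
    def found(self) -> bool:
        return self.chrom is not None


def delineate_focal_region(window_stats: pd.DataFrame,
                           fst_threshold: float = 0.3) -> FocalRegion:
    """Bound the focal region by the first and last window with F_ST
    strictly above the threshold on the chromosome carrying the most such
    windows."""
    qual = window_stats[window_stats["fst"] > fst_threshold]
    if qual.empty:
        return FocalRegion(None, 0, 0, 0, 0, fst_threshold)
    per_chrom = qual.groupby("chrom").size()
    chrom = per_chrom.idxmax()
    sub = qual[qual["chrom"] == chrom]
    n_on = len(sub)
    return FocalRegion(chrom, int(sub["start"].min()), int(sub["end"].max()),
                       n_on, int(len(qual) - n_on), fst_threshold)
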