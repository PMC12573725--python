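"""Resampling and enrichment machinery: per-chromosome binomial DMP
enrichment, focal-vs-background bootstraps of taxon effects, SNP-adjacent
exclusion, bootstrapped Spearman correlations, and methylation linkage
disequilibrium from k-means-encoded methylation genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# chromosome binomial enrichment


def chromosome_binomial_enrichment(dmp_positions: pd.DataFrame,
                                   assayed_positions: pd.DataFrame,
                                   conf: float = 0.95) -> pd.DataFrame:
    """Exact binomial test of DMP counts per chromosome against the
    proportion of assayed CpGs, with Clopper-Pearson CIs; a chromosome is
    enriched iff the CI lower bound exceeds the expected proportion."""
    assayed = assayed_positions.groupby("chrom").size()
    total_assayed = int(assayed.sum())
    dmps = dmp_positions.groupby("chrom").size()
    N = int(dmps.sum())
    if N < 1:
        raise ValueError("need at least one DMP")
    bad = set(dmps.index) - set(assayed.index)
    if bad:
        raise ValueError(f"chromosomes with DMPs but no assayed CpGs: {sorted(bad)}")
    rows = []
    for chrom in assayed.index:
        p0 = assayed[chrom] / total_assayed
        k = int(dmps.get(chrom, 0))
        test = stats.binomtest(k, N, p0)
        ci = test.proportion_ci(confidence_level=conf, method="exact")
        rows.append({"chrom": chrom, "expected_prop": p0, "observed": k,
                     "total_dmps": N, "observed_prop": k / N,
                     "ci_low": ci.low, "ci_high": ci.high,
                     "p_value": test.pvalue, "enriched": ci.low > p0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# focal-region bootstrap of taxon statistics


@dataclass
class BootstrapComparison:
    feature: str
    focal_mean: float
    n_focal: int
    replicate_means: np.ndarray
    lo: float
    hi: float
    significant: bool


def focal_background_bootstrap(site_table: pd.DataFrame, focal_region: tuple,
                               B: int = 1000,
                               rng: Optional[np.random.Generator] = None,
                               sex_chroms: Iterable[str] = (),
                               stat_col: str = "stat", feature_col: str = "feature",
                               method: str = "band") -> dict:
    """Per feature class, compare the mean taxon statistic of focal-region
    CpGs against B bootstrap means of equally many autosomal background CpGs
    of the same class (sampled with replacement).

    site_table needs chrom, pos, `stat_col`, `feature_col`. method="band"
    (default): significant iff the focal observed mean lies outside the
    [2.5, 97.5] percentile band of background replicates. method="overlap":
    the focal side is bootstrapped too and significance requires the two 95%
    bands to be disjoint.
    """
    rng = rng or np.random.default_rng()
    fc, fs, fe = focal_region
    t = site_table
    in_focal = ((t["chrom"] == fc) & (t["pos"] >= fs) & (t["pos"] < fe)).to_numpy()
    autosomal = ~t["chrom"].isin(set(sex_chroms) | {None}).to_numpy()
    out = {}
    for feat in pd.unique(t[feature_col]):
        fmask = (t[feature_col] == feat).to_numpy()
        focal_stats = t.loc[fmask & in_focal, stat_col].to_numpy(float)
        bg = t.loc[fmask & ~in_focal & autosomal, stat_col].to_numpy(float)
        n_focal = len(focal_stats)
        if n_focal == 0 or len(bg) == 0:
            out[feat] = None  # skipped: no focal CpGs of this class
            continue
        idx = rng.integers(0, len(bg), size=(B, n_focal))
        reps = bg[idx].mean(axis=1)
        lo, hi = np.percentile(reps, [2.5, 97.5])
        focal_mean = float(focal_stats.mean())
        if method == "band":
            sig = focal_mean < lo or focal_mean > hi
        elif method == "overlap":
            fidx = rng.integers(0, n_focal, size=(B, n_focal))
            freps = focal_stats[fidx].mean(axis=1)
            flo, fhi = np.percentile(freps, [2.5, 97.5])
            sig = (fhi < lo) or (flo > hi)
        else:
            raise ValueError(f"unknown method {method!r}")
        out[feat] = BootstrapComparison(feat, focal_mean, n_focal, reps,
                                        float(lo), float(hi), bool(sig))
    return out


def exclude_snp_adjacent(sites: pd.DataFrame, snps: pd.DataFrame,
                         distance: int = 1) -> pd.DataFrame:
    """Drop CpG units where either dyad position (pos, pos+1) lies within
    `distance` bp of any SNP (transitions and transversions alike)."""
    keep = np.ones(len(sites), dtype=bool)
    snp_by_chrom = {c: np.sort(g["pos"].to_numpy())
                    for c, g in snps.groupby("chrom")}
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for chrom, spos in snp_by_chrom.items():
        cmask = chroms == chrom
        if not cmask.any() or len(spos) == 0:
            continue
        for dy in (0, 1):  # both dyad positions
            p = pos[cmask] + dy
            i = np.searchsorted(spos, p)
            near = np.zeros(len(p), dtype=bool)
            left = np.clip(i - 1, 0, len(spos) - 1)
            right = np.clip(i, 0, len(spos) - 1)
            near |= np.abs(spos[left] - p) <= distance
            near |= np.abs(spos[right] - p) <= distance
            keep[np.flatnonzero(cmask)[near]] = False
    return sites.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# bootstrapped Spearman correlations


def _spearman_batch(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho for (B, n) arrays."""
    rx = stats.rankdata(x, axis=1).astype(float)
    ry = stats.rankdata(y, axis=1).astype(float)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_spearman(window_table: pd.DataFrame, focal_mask: np.ndarray,
                       metrics: Sequence[str],
                       response_col: str = "response", B: int = 1000,
                       rng: Optional[np.random.Generator] = None) -> dict:
    """Bootstrap distributions of Spearman's rho between window methylation
    divergence and each population-genetic metric, inside the focal region
    (resampling focal windows) and outside (resampling equally many
    background windows). Significant iff the [2.5, 97.5] quantile interval
    excludes zero."""
    rng = rng or np.random.default_rng()
    focal_mask = np.asarray(focal_mask, dtype=bool)
    n_focal = int(focal_mask.sum())
    if n_focal < 3:
        raise ValueError("need >= 3 focal windows for a rank correlation")
    resp = window_table[response_col].to_numpy(float)
    out = {}
    bg_idx_pool = np.flatnonzero(~focal_mask)
    f_idx_pool = np.flatnonzero(focal_mask)
    idx_in = f_idx_pool[rng.integers(0, n_focal, size=(B, n_focal))]
    idx_out = bg_idx_pool[rng.integers(0, len(bg_idx_pool), size=(B, n_focal))]
    for metric in metrics:
        vals = window_table[metric].to_numpy(float)
        res = {}
        for side, idx in (("inside", idx_in), ("outside", idx_out)):
            rho = _spearman_batch(vals[idx], resp[idx])
            lo, hi = np.nanpercentile(rho, [2.5, 97.5])
            res[side] = {"rho": rho, "lo": float(lo), "hi": float(hi),
                         "significant": bool(lo > 0 or hi < 0)}
        out[metric] = res
    return out


# ---------------------------------------------------------------------------
# methylation genotype encoding and methylation LD


def encode_methylation_genotypes(proportions) -> np.ndarray:
    """Binary methylation states by exact one-dimensional 2-means.

    The optimal 2-means partition of scalars is a cut in sorted order; the
    cut minimising within-cluster SSE is found exhaustively, which removes
    the initialisation nondeterminism of Lloyd's algorithm. The cluster with
    the higher centre is state 1 ("methylated-like"). Missing entries stay
    NaN; at least 4 observed values are required.
    """
    p = np.asarray(proportions, dtype=float)
    obs = ~np.isnan(p)
    x = p[obs]
    if len(x) < 4:
        raise ValueError("need >= 4 non-missing individuals")
    if np.allclose(x, x[0]):
        raise ValueError("all proportions identical: no 2-cluster structure")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csq = np.concatenate([[0.0], np.cumsum(xs ** 2)])
    best_sse, best_k = np.inf, 1
    for k in range(1, n):  # left cluster xs[:k]
        sl, ql = csum[k], csq[k]
        sr, qr = csum[n] - sl, csq[n] - ql
        sse = (ql - sl ** 2 / k) + (qr - sr ** 2 / (n - k))
        if sse < best_sse - 1e-15:
            best_sse, best_k = sse, k
    states_sorted = np.zeros(n)
    states_sorted[best_k:] = 1.0  # higher-mean cluster is state 1
    states = np.empty(n)
    states[order] = states_sorted
    out = np.full(len(p), np.nan)
    out[obs] = states
    return out


@dataclass
class MethLD:
    p_a: float
    p_b: float
    f_11: float
    d: float
    d_prime: float
    n: int
    defined: bool = True


def pairwise_meld(states_a, states_b) -> MethLD:
    """Linkage disequilibrium between two binary methylation-state vectors,
    computed over individuals non-missing at both sites.

    D = f_11 - p_A p_B; D' = |D| / D_max with the standard frequency-bounded
    maximum; D' = 0 when D = 0 by convention. A monomorphic state vector
    yields an undefined (flagged) result rather than an exception.
    """
    a = np.asarray(states_a, dtype=float)
    b = np.asarray(states_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 4:
        raise ValueError("need >= 4 individuals non-missing at both sites")
    p_a = a.mean()
    p_b = b.mean()
    f11 = (a * b).mean()
    d = f11 - p_a * p_b
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return MethLD(p_a, p_b, f11, float("nan"), float("nan"), n, defined=False)
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        return MethLD(p_a, p_b, f11, 0.0, 0.0, n)
    return MethLD(p_a, p_b, f11, float(d), float(abs(d) / d_max), n)
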