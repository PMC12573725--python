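"""Methylation count I/O and the site-filtering cascade.

Counts are held as a :class:`MethylationMatrix`: per-CpG methylated (m) and
total (n) read counts across samples, keyed by the forward-strand C of each
CpG dyad, with NaN marking missing entries. Filtering follows the RRBS
quality cascade: drop unplaced-scaffold sites, drop sites overlapping
transition SNPs, blank entries under 10 reads, blank top-1% coverage
outliers, then drop sites missing in more than three samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import as_bytes

_C, _G = ord("C"), ord("G")


@dataclass
class MethylationMatrix:
    """Per-CpG read counts across samples.

    sites: DataFrame with chrom, pos (0-based forward-strand C), sorted,
    unique. m and n are float arrays (n_sites, n_samples); NaN in n marks a
    missing entry (m is NaN there too).
    """

    sites: pd.DataFrame
    m: np.ndarray
    n: np.ndarray
    samples: list

    def __post_init__(self):
        self.sites = self.sites.reset_index(drop=True)
        assert self.m.shape == self.n.shape == (len(self.sites), len(self.samples))

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.m / self.n

    def present(self) -> np.ndarray:
        return ~np.isnan(self.n)

    def subset_sites(self, mask) -> "MethylationMatrix":
        mask = np.asarray(mask)
        return MethylationMatrix(self.sites.loc[mask].copy(), self.m[mask].copy(),
                                 self.n[mask].copy(), list(self.samples))

    def site_keys(self) -> pd.Index:
        return pd.Index(zip(self.sites["chrom"], self.sites["pos"]))

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for j, s in enumerate(self.samples):
            cols[f"{s}.m"] = self.m[:, j]
            cols[f"{s}.n"] = self.n[:, j]
        return pd.concat([self.sites.reset_index(drop=True), pd.DataFrame(cols)], axis=1)

    def write_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read_tsv(cls, path) -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t", na_values="NA")
        samples = [c[:-2] for c in df.columns if c.endswith(".m")]
        m = df[[f"{s}.m" for s in samples]].to_numpy(float)
        n = df[[f"{s}.n" for s in samples]].to_numpy(float)
        return cls(df[["chrom", "pos"]].copy(), m, n, samples)


def read_bismark_cov(paths: Sequence, sample_ids: Sequence[str]) -> dict:
    """Read Bismark coverage files into per-sample {(chrom, pos0): (m, n)} maps.

    File columns: chrom, start (1-based), end, methylation %, count
    methylated, count unmethylated. The percentage column is ignored in
    favour of the counts, with a warning if they disagree beyond rounding.
    """
    out = {}
    for path, sid in zip(paths, sample_ids):
        counts = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 6:
                    raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
                try:
                    chrom, start, _end, pct, cm, cu = (
                        parts[0], int(parts[1]), int(parts[2]),
                        float(parts[3]), int(parts[4]), int(parts[5]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from None
                total = cm + cu
                if total > 0 and abs(100.0 * cm / total - pct) > 0.51:
                    warnings.warn(f"{path}:{lineno}: % field inconsistent with counts")
                counts[(chrom, start - 1)] = (cm, total)
        out[sid] = counts
    return out


def destrand(raw: Mapping[str, Mapping], genome: Mapping[str, object]) -> dict:
    """Merge counts of each CpG dyad (forward C at p, reverse G at p+1) onto p.

    Positions that are not the C or G of a CpG dyad in the genome are dropped
    with a warning.
    """
    seqs = {c: as_bytes(s) for c, s in genome.items()}
    out = {}
    n_bad = 0
    for sid, counts in raw.items():
        merged = {}
        for (chrom, pos), (m, n) in counts.items():
            seq = seqs.get(chrom)
            if seq is None or pos >= len(seq):
                n_bad += 1
                continue
            base = seq[pos]
            if base == _C and pos + 1 < len(seq) and seq[pos + 1] == _G:
                key = (chrom, pos)
            elif base == _G and pos >= 1 and seq[pos - 1] == _C:
                key = (chrom, pos - 1)
            else:
                n_bad += 1
                continue
            pm, pn = merged.get(key, (0, 0))
            merged[key] = (pm + m, pn + n)
        out[sid] = merged
    if n_bad:
        warnings.warn(f"dropped {n_bad} positions not part of a CpG dyad")
    return out


def counts_to_matrix(per_sample: Mapping[str, Mapping], samples: Sequence[str]) -> MethylationMatrix:
    keys = sorted({k for sid in samples for k in per_sample[sid]})
    sites = pd.DataFrame(keys, columns=["chrom", "pos"])
    S, N = len(keys), len(samples)
    m = np.full((S, N), np.nan)
    n = np.full((S, N), np.nan)
    index = {k: i for i, k in enumerate(keys)}
    for j, sid in enumerate(samples):
        for k, (cm, cn) in per_sample[sid].items():
            i = index[k]
            m[i, j] = cm
            n[i, j] = cn
    return MethylationMatrix(sites, m, n, list(samples))


@dataclass
class FilterReport:
    sites_in: int = 0
    sites_scaffold: int = 0
    sites_snp_overlap: int = 0
    entries_low_coverage: int = 0
    entries_coverage_outlier: int = 0
    coverage_ceiling: float = float("nan")
    sites_missingness: int = 0
    sites_out: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def apply_site_filters(matrix: MethylationMatrix, transition_mask: pd.DataFrame,
                       assembly_chroms: Iterable[str], min_cov: int = 10,
                       top_pct: float = 1.0, max_missing: int = 3):
    """The RRBS site-filter cascade, in order.

    1. sites not on an assembly chromosome (unplaced scaffolds) dropped;
    2. sites whose dyad (pos or pos+1) overlaps a transition-SNP position dropped;
    3. entries with coverage < min_cov set missing;
    4. entries above the (100 - top_pct) coverage percentile of retained
       entries set missing;
    5. sites missing in more than max_missing samples dropped.
    Returns (filtered matrix, FilterReport).
    """
    rep = FilterReport(sites_in=matrix.n_sites)
    chrom_set = set(assembly_chroms)
    keep = matrix.sites["chrom"].isin(chrom_set).to_numpy()
    rep.sites_scaffold = int((~keep).sum())
    mx = matrix.subset_sites(keep)

    if len(transition_mask):
        bad_chroms = set(transition_mask["chrom"]) - chrom_set
        if bad_chroms and not (set(transition_mask["chrom"]) & chrom_set):
            raise ValueError(f"transition mask chromosomes unmatched: {sorted(bad_chroms)}")
        snp = set(zip(transition_mask["chrom"], transition_mask["pos"]))
        hit = np.fromiter(
            (((c, p) in snp) or ((c, p + 1) in snp)
             for c, p in zip(mx.sites["chrom"], mx.sites["pos"])),
            dtype=bool, count=mx.n_sites)
    else:
        hit = np.zeros(mx.n_sites, dtype=bool)
    rep.sites_snp_overlap = int(hit.sum())
    mx = mx.subset_sites(~hit)

    low = mx.n < min_cov  # NaN compares False
    rep.entries_low_coverage = int(np.nansum(low))
    mx.m[low] = np.nan
    mx.n[low] = np.nan

    cov = mx.n[~np.isnan(mx.n)]
    if cov.size:
        ceiling = np.percentile(cov, 100.0 - top_pct)
        high = mx.n > ceiling
        rep.coverage_ceiling = float(ceiling)
        rep.entries_coverage_outlier = int(np.nansum(high))
        mx.m[high] = np.nan
        mx.n[high] = np.nan

    missing = np.isnan(mx.n).sum(axis=1)
    drop = missing > max_missing
    rep.sites_missingness = int(drop.sum())
    mx = mx.subset_sites(~drop)
    rep.sites_out = mx.n_sites
    return mx, rep


def flag_invariable(matrix: MethylationMatrix, delta: float = 0.10):
    """Flag sites whose observed methylation proportion range is < delta.

    Returns (invariable, indeterminate_input) boolean arrays; sites with
    fewer than 2 non-missing samples are indeterminate-input and belong to
    neither class.
    """
    p = matrix.proportions()
    n_obs = (~np.isnan(p)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rng = np.nanmax(p, axis=1) - np.nanmin(p, axis=1)
    indeterminate = n_obs < 2
    invariable = (~indeterminate) & (rng < delta)
    return invariable, indeterminate
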