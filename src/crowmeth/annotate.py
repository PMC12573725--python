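"""Genome annotation: CpG islands, promoter islands, and the priority feature track.

The annotation strategy mirrors standard RRBS practice: CpG islands are
called by composition thresholds (length > 200 bp, GC > 50%, observed/expected
CpG > 60%) with a 200-bp sliding-window scan; islands overlapping the
strand-aware 2-kb region upstream of a gene start become promoters; and the
genome is partitioned into non-overlapping features with the priority
promoter > repeat > CDS > intron > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import _intervals

FEATURE_LABELS = ("promoter", "repeat", "CDS", "intron", "intergenic")

_A, _C, _G, _T, _N = (ord(c) for c in "ACGTN")


def as_bytes(seq) -> np.ndarray:
    """Coerce a sequence (str / bytes / uint8 array) to an upper-case uint8 array."""
    if isinstance(seq, np.ndarray):
        arr = seq.astype(np.uint8, copy=False)
    elif isinstance(seq, (bytes, bytearray)):
        arr = np.frombuffer(bytes(seq), dtype=np.uint8).copy()
    else:
        arr = np.frombuffer(str(seq).encode("ascii"), dtype=np.uint8).copy()
    lower = (arr >= ord("a")) & (arr <= ord("z"))
    arr[lower] -= 32
    return arr


def to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


def _composition(arr: np.ndarray):
    """Cumulative counts of C, G, CG-dinucleotide starts, and N."""
    is_c = arr == _C
    is_g = arr == _G
    is_n = arr == _N
    is_cg = np.zeros(len(arr), dtype=bool)
    if len(arr) > 1:
        is_cg[:-1] = is_c[:-1] & is_g[1:]
    zeros = np.zeros(1, dtype=np.int64)
    return tuple(
        np.concatenate([zeros, np.cumsum(x)]) for x in (is_c, is_g, is_cg, is_n)
    )


def _interval_stats(cum, start: int, end: int):
    """(nC, nG, nCG, nN) for [start, end); CG dinucleotides fully inside."""
    cc, cg_, ccg, cn = cum
    n_c = int(cc[end] - cc[start])
    n_g = int(cg_[end] - cg_[start])
    # dinucleotide starts in [start, end-1)
    n_cg = int(ccg[end - 1] - ccg[start]) if end - start >= 2 else 0
    n_n = int(cn[end] - cn[start])
    return n_c, n_g, n_cg, n_n


def island_criteria(n_c: int, n_g: int, n_cg: int, length: int,
                    min_gc: float = 0.50, min_oe: float = 0.60) -> bool:
    """Composition part of the island definition (strict inequalities)."""
    if length <= 0 or n_c == 0 or n_g == 0:
        return False
    gc = (n_c + n_g) / length
    oe = n_cg * length / (n_c * n_g)
    return gc > min_gc and oe > min_oe


def detect_cpg_islands(seq, min_length: int = 200, min_gc: float = 0.50,
                       min_oe: float = 0.60, window: int = 200) -> np.ndarray:
    """Call CpG islands on one sequence.

    A 200-bp window slides with step 1; windows passing both composition
    criteria (GC > min_gc, O/E > min_oe) and containing no N are retained,
    overlapping windows merged, and each merged interval re-checked against
    all three criteria (length strictly > min_length, so an isolated single
    qualifying window is rejected). Returns an (k, 2) array of half-open
    intervals.
    """
    arr = as_bytes(seq)
    L = len(arr)
    if L < window:
        return np.empty((0, 2), dtype=int)
    cum = _composition(arr)
    cc, cg_, ccg, cn = cum
    starts = np.arange(0, L - window + 1)
    ends = starts + window
    n_c = cc[ends] - cc[starts]
    n_g = cg_[ends] - cg_[starts]
    n_cg = ccg[ends - 1] - ccg[starts]
    n_n = cn[ends] - cn[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = (n_c + n_g) / window
        oe = np.where((n_c > 0) & (n_g > 0), n_cg * window / (n_c * n_g), 0.0)
    ok = (gc > min_gc) & (oe > min_oe) & (n_n == 0)
    if not ok.any():
        return np.empty((0, 2), dtype=int)
    qual = np.stack([starts[ok], ends[ok]], axis=1)
    merged = _intervals.merge(qual)
    is_cg = (arr == _C) | (arr == _G)
    keep = []
    for s, e in merged:
        s, e = _trim_island(cum, is_cg, int(s), int(e), min_length, min_gc, min_oe)
        if s is not None:
            keep.append((s, e))
    return np.array(keep, dtype=int) if keep else np.empty((0, 2), dtype=int)


def _trim_island(cum, is_cg, s, e, min_length, min_gc, min_oe):
    """Trim a merged candidate until the whole interval qualifies.

    Non-C/G terminal bases are stripped first; if the interval still fails,
    it is shrunk deterministically from the start. Returns (start, end) or
    (None, None) if nothing above min_length qualifies.
    """
    def ok(a, b):
        nc, ng, ncg, nn = _interval_stats(cum, a, b)
        return nn == 0 and island_criteria(nc, ng, ncg, b - a, min_gc, min_oe)

    while e - s > min_length:
        if not is_cg[s]:
            s += 1
            continue
        if not is_cg[e - 1]:
            e -= 1
            continue
        if ok(s, e):
            return s, e
        s += 1
    return None, None


def detect_cpg_islands_genome(genome: Mapping[str, object], **kw) -> pd.DataFrame:
    rows = []
    for chrom in genome:
        for s, e in detect_cpg_islands(genome[chrom], **kw):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def upstream_window(start: int, end: int, strand: str, size: int = 2000):
    """Strand-aware upstream window of a gene, half-open, clipped at 0."""
    if strand == "+":
        return max(0, start - size), start
    if strand == "-":
        return end, end + size
    raise ValueError(f"gene has invalid strand {strand!r}")


def call_promoter_islands(islands: pd.DataFrame, genes: pd.DataFrame,
                          size: int = 2000) -> pd.DataFrame:
    """CpG islands with >= 1 bp overlap of a strand-aware 2-kb upstream gene window.

    Each qualifying island is reported once even if it serves several genes.
    """
    if "strand" not in genes.columns or genes["strand"].isna().any():
        raise ValueError("genes require a strand column with no missing values")
    out_idx = set()
    for chrom, gsub in genes.groupby("chrom", sort=False):
        isub = islands[islands["chrom"] == chrom]
        if isub.empty:
            continue
        ist = isub["start"].to_numpy()
        ien = isub["end"].to_numpy()
        for _, g in gsub.iterrows():
            ws, we = upstream_window(int(g["start"]), int(g["end"]), g["strand"], size)
            hit = (ist < we) & (ien > ws)
            out_idx.update(isub.index[hit])
    out = islands.loc[sorted(out_idx)].copy()
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class FeatureTrack:
    """Non-overlapping, genome-covering annotation intervals.

    intervals: DataFrame with chrom, start, end, label; sorted, a partition
    of every chromosome in chrom_sizes.
    """

    intervals: pd.DataFrame
    chrom_sizes: dict = field(default_factory=dict)

    def __post_init__(self):
        self._index = {}
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            self._index[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["label"].to_numpy(),
            )

    def labels_at(self, chrom: str, positions) -> np.ndarray:
        if chrom not in self._index:
            raise KeyError(f"chromosome {chrom!r} not covered by feature track")
        starts, ends, labels = self._index[chrom]
        pos = np.asarray(positions, dtype=int)
        idx = np.searchsorted(starts, pos, side="right") - 1
        if (idx < 0).any() or (pos >= ends[np.clip(idx, 0, len(ends) - 1)]).any():
            raise ValueError(f"positions outside covered range on {chrom}")
        return labels[idx]

    def annotate_positions(self, chroms, positions) -> np.ndarray:
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=int)
        out = np.empty(len(chroms), dtype=object)
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            out[mask] = self.labels_at(chrom, positions[mask])
        return out

    def label_intervals(self, chrom: str, label: str) -> np.ndarray:
        starts, ends, labels = self._index[chrom]
        m = labels == label
        return np.stack([starts[m], ends[m]], axis=1) if m.any() else np.empty((0, 2), dtype=int)


def build_feature_track(promoters, repeats, cds, introns,
                        chrom_sizes: Mapping[str, int]) -> FeatureTrack:
    """Partition each chromosome by priority promoter > repeat > CDS > intron > intergenic."""
    by_label = {"promoter": promoters, "repeat": repeats, "CDS": cds, "intron": introns}
    rows = []
    for chrom, size in chrom_sizes.items():
        taken = np.empty((0, 2), dtype=int)
        for label in ("promoter", "repeat", "CDS", "intron"):
            df = by_label[label]
            if df is None or len(df) == 0:
                continue
            sub = df[df["chrom"] == chrom]
            if sub.empty:
                continue
            iv = sub[["start", "end"]].to_numpy(dtype=int)
            if (iv[:, 0] < 0).any() or (iv[:, 1] > size).any():
                raise ValueError(f"{label} interval outside {chrom} bounds (size {size})")
            free = _intervals.subtract(iv, taken)
            for s, e in free:
                rows.append((chrom, int(s), int(e), label))
            taken = _intervals.merge(np.vstack([taken, iv]) if len(taken) else iv)
        for s, e in _intervals.subtract(np.array([[0, size]]), taken):
            rows.append((chrom, int(s), int(e), "intergenic"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return FeatureTrack(df, dict(chrom_sizes))


def window_properties(genome: Mapping[str, object], track: FeatureTrack,
                      window_size: int = 5000) -> pd.DataFrame:
    """Per-window genome properties: GC content (N ignored), relative
    chromosomal position, chromosome length, and feature-class fractions.

    The final partial window of each chromosome is retained with its true
    length so the tiling stays a partition.
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom, seq in genome.items():
        arr = as_bytes(seq)
        L = len(arr)
        cum = _composition(arr)
        cc, cg_, _, cn = cum
        label_iv = {lab: track.label_intervals(chrom, lab) for lab in FEATURE_LABELS
                    if chrom in track._index}
        for start in range(0, L, window_size):
            end = min(start + window_size, L)
            wlen = end - start
            n_c = int(cc[end] - cc[start])
            n_g = int(cg_[end] - cg_[start])
            n_n = int(cn[end] - cn[start])
            eff = wlen - n_n
            gc = (n_c + n_g) / eff if eff > 0 else np.nan
            fr = {}
            for lab in FEATURE_LABELS:
                iv = label_iv.get(lab, np.empty((0, 2), dtype=int))
                fr[lab] = _intervals.overlap_length(iv, start, end) / wlen
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "gc": gc,
                "rel_pos": ((start + end) / 2) / L,
                "chrom_length": L,
                **{f"frac_{lab}": fr[lab] for lab in FEATURE_LABELS},
            })
    return pd.DataFrame(rows)
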