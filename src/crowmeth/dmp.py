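"""Per-CpG beta-binomial differential methylation: arcsine-link regression,
FDR correction, DMP classification, and cross-experiment intersection.

Model
-----
For site j with methylated/total counts (m_i, n_i) across samples i, the
transformed response y_i = arcsin(2 (m_i + 0.5) / (n_i + 1) - 1) has
approximate variance (1 + (n_i - 1) phi) / n_i under a beta-binomial with
dispersion phi — the arcsine transform removes the mean-variance dependence,
so a weighted least-squares fit with weights w_i = n_i / (1 + (n_i - 1) phi)
gives asymptotically correct Wald statistics per covariate. phi is estimated
per site by method of moments from the residual variance of a preliminary
unweighted fit (floored at 0, capped at 0.99).

Classification of a site (after BH FDR per covariate): a covariate label is
assigned iff its q < 0.01, every other covariate's q > 0.01, and — for
factor covariates only — the maximum absolute pairwise group-mean proportion
difference exceeds 0.25; otherwise the site is invariable (< 10% observed
range, flagged upstream) or indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methio import MethylationMatrix

FACTOR_COVARIATES = {"age", "sex", "taxon", "year"}
CONTINUOUS_COVARIATES = {"hybrid_index"}


def build_design(samples: pd.DataFrame, experiment: str):
    """Treatment-coded design matrix and covariate -> column map.

    ComGar: age (Chick reference), sex (Female reference), taxon (corone
    reference). HybZon: hybrid index (continuous) and year (treatment-coded,
    earliest year reference).
    """
    n = len(samples)
    cols = {"intercept": np.ones(n)}
    terms = {}
    if experiment == "ComGar":
        cols["age_Yearling"] = (samples["age"] == "Yearling").astype(float).to_numpy()
        cols["age_Adult"] = (samples["age"] == "Adult").astype(float).to_numpy()
        cols["sex_M"] = (samples["sex"] == "M").astype(float).to_numpy()
        cols["taxon_cornix"] = (samples["taxon"] == "cornix").astype(float).to_numpy()
        terms = {"age": ["age_Yearling", "age_Adult"], "sex": ["sex_M"],
                 "taxon": ["taxon_cornix"]}
    elif experiment == "HybZon":
        cols["hybrid_index"] = samples["hybrid_index"].astype(float).to_numpy()
        years = sorted(samples["year"].unique())
        for y in years[1:]:
            cols[f"year_{y}"] = (samples["year"] == y).astype(float).to_numpy()
        terms = {"hybrid_index": ["hybrid_index"],
                 "year": [f"year_{y}" for y in years[1:]]}
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    X = pd.DataFrame(cols, index=samples.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, terms


def arcsine_transform(m: np.ndarray, n: np.ndarray) -> np.ndarray:
    """y = arcsin(2 (m + 0.5)/(n + 1) - 1); the +0.5/+1 pseudocounts keep
    the transform finite at p in {0, 1}."""
    return np.arcsin(2.0 * (m + 0.5) / (n + 1.0) - 1.0)


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaN p-values are excluded from the
    ranking and propagate as NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


class DifferentialMethylation:
    """Beta-binomial (arcsine link) differential-methylation model.

    Parameters
    ----------
    matrix : MethylationMatrix (filtered, destranded)
    samples : metadata rows aligned with matrix.samples
    experiment : "ComGar" or "HybZon" (chooses the design), or pass
        design/terms explicitly.
    """

    def __init__(self, matrix: MethylationMatrix, samples: pd.DataFrame,
                 experiment: Optional[str] = None,
                 design: Optional[pd.DataFrame] = None,
                 terms: Optional[Mapping[str, Sequence[str]]] = None):
        samples = samples.set_index("id").loc[matrix.samples].reset_index()
        self.matrix = matrix
        self.samples = samples
        self.experiment = experiment
        if design is None:
            design, terms = build_design(samples, experiment)
        self.design = design
        self.terms = dict(terms)

    def fit(self, min_samples: int = 8) -> "DMResults":
        X_full = self.design.to_numpy(float)
        colnames = list(self.design.columns)
        k = X_full.shape[1]
        m, n = self.matrix.m, self.matrix.n
        S, N = m.shape
        present = ~np.isnan(n)
        # absent entries get a placeholder transform; they are never indexed
        y = arcsine_transform(np.nan_to_num(m), np.where(present, n, 1.0))

        beta = np.full((S, k), np.nan)
        se = np.full((S, k), np.nan)
        phi = np.full(S, np.nan)
        resid_df = np.full(S, np.nan)
        n_used = present.sum(axis=1)
        skip_reason = np.full(S, "", dtype=object)
        cov_names = list(self.terms)
        cov_p = np.full((S, len(cov_names)), np.nan)

        patt, inv = np.unique(present, axis=0, return_inverse=True)
        for g, mask in enumerate(patt):
            sites = np.flatnonzero(inv == g)
            ng = int(mask.sum())
            if ng < max(min_samples, k + 1):
                skip_reason[sites] = "too_few_samples"
                continue
            Xg = X_full[mask]
            if np.linalg.matrix_rank(Xg) < k:
                skip_reason[sites] = "rank_deficient"
                continue
            yg = y[np.ix_(sites, np.flatnonzero(mask))]
            ng_mat = n[np.ix_(sites, np.flatnonzero(mask))]
            # preliminary OLS and method-of-moments dispersion
            pinv = np.linalg.pinv(Xg)
            b0 = yg @ pinv.T
            resid = yg - b0 @ Xg.T
            dof = ng - k
            rss = (resid ** 2).sum(axis=1)
            mean_inv = (1.0 / ng_mat).mean(axis=1)
            mean_frac = ((ng_mat - 1.0) / ng_mat).mean(axis=1)
            ph = np.clip((rss / dof - mean_inv) / np.maximum(mean_frac, 1e-12),
                         0.0, 0.99)
            w = ng_mat / (1.0 + (ng_mat - 1.0) * ph[:, None])
            xtwx = np.einsum("ik,si,il->skl", Xg, w, Xg)
            xtwy = np.einsum("ik,si,si->sk", Xg, w, yg)
            try:
                cov = np.linalg.inv(xtwx)
            except np.linalg.LinAlgError:
                skip_reason[sites] = "singular"
                continue
            b = np.einsum("skl,sl->sk", cov, xtwy)
            beta[sites] = b
            se[sites] = np.sqrt(np.maximum(np.einsum("skk->sk", cov), 0.0))
            phi[sites] = ph
            resid_df[sites] = ng - k
            # covariate-level Wald test against an F reference with the
            # residual degrees of freedom (== two-sided t for one column);
            # a Gaussian/chi-square reference is anticonservative at n ~ 22
            for ci, cname in enumerate(cov_names):
                J = [colnames.index(c) for c in self.terms[cname]]
                bj = b[:, J]
                cjj = cov[:, J][:, :, J]
                try:
                    cinv = np.linalg.inv(cjj)
                except np.linalg.LinAlgError:
                    continue
                w2 = np.einsum("sj,sjk,sk->s", bj, cinv, bj)
                cov_p[sites, ci] = stats.f.sf(w2 / len(J), len(J), ng - k)
        z = beta / se
        with np.errstate(invalid="ignore"):
            p_col = 2.0 * stats.t.sf(np.abs(z), resid_df[:, None])
        cov_q = np.column_stack([fdr_adjust(cov_p[:, i])
                                 for i in range(len(cov_names))]) \
            if len(cov_names) else cov_p
        return DMResults(self, beta, se, z, p_col, phi, n_used, skip_reason,
                         cov_names, cov_p, cov_q, resid_df)


@dataclass
class DMResults:
    """Per-site fits of a DifferentialMethylation model."""

    model: DifferentialMethylation
    beta: np.ndarray          # (S, k) arcsine-scale effects
    se: np.ndarray
    z: np.ndarray             # Wald statistics per column
    p: np.ndarray             # two-sided per column
    phi: np.ndarray           # (S,) dispersion
    n_used: np.ndarray
    skip_reason: np.ndarray
    covariates: list
    covariate_p: np.ndarray   # (S, n_cov) joint Wald p per covariate
    covariate_q: np.ndarray   # BH q per covariate
    dof: np.ndarray = None    # residual degrees of freedom per site

    @property
    def sites(self) -> pd.DataFrame:
        return self.model.matrix.sites

    def column_index(self, col: str) -> int:
        return list(self.model.design.columns).index(col)

    def covariate_stat(self, covariate: str) -> np.ndarray:
        """Wald z of a single-column covariate (e.g., taxon, hybrid_index)."""
        cols = self.model.terms[covariate]
        if len(cols) != 1:
            raise ValueError(f"covariate {covariate} has {len(cols)} columns")
        return self.z[:, self.column_index(cols[0])]

    def to_frame(self) -> pd.DataFrame:
        out = self.sites.copy()
        for j, c in enumerate(self.model.design.columns):
            out[f"beta_{c}"] = self.beta[:, j]
            out[f"z_{c}"] = self.z[:, j]
        for i, c in enumerate(self.covariates):
            out[f"p_{c}"] = self.covariate_p[:, i]
            out[f"q_{c}"] = self.covariate_q[:, i]
        out["phi"] = self.phi
        out["n_used"] = self.n_used
        return out

    def group_mean_difference(self, covariate: str) -> np.ndarray:
        """Max absolute pairwise difference of group-mean raw proportions
        across the levels of a factor covariate (unweighted sample means)."""
        samples = self.model.samples
        p = self.model.matrix.proportions()
        levels = pd.unique(samples[covariate])
        means = []
        for lev in levels:
            mask = (samples[covariate] == lev).to_numpy()
            with np.errstate(invalid="ignore"):
                means.append(np.nanmean(p[:, mask], axis=1))
        means = np.column_stack(means)
        diff = np.zeros(len(p))
        for a in range(means.shape[1]):
            for b in range(a + 1, means.shape[1]):
                diff = np.fmax(diff, np.abs(means[:, a] - means[:, b]))
        return diff

    def classify(self, invariable: np.ndarray,
                 indeterminate_input: Optional[np.ndarray] = None,
                 alpha: float = 0.01, delta: float = 0.25) -> pd.DataFrame:
        return classify_sites(self, invariable, indeterminate_input,
                              alpha=alpha, delta=delta)

    def summary(self) -> str:
        lines = [f"DifferentialMethylation ({self.model.experiment}) — "
                 f"{len(self.sites)} sites, {len(self.model.samples)} samples",
                 f"design columns: {', '.join(self.model.design.columns)}",
                 f"fitted: {int(np.isfinite(self.phi).sum())}  "
                 f"skipped: {int((self.skip_reason != '').sum())}",
                 f"median dispersion phi: {np.nanmedian(self.phi):.4f}"]
        for i, c in enumerate(self.covariates):
            nsig = int(np.nansum(self.covariate_q[:, i] < 0.01))
            lines.append(f"  {c:>14}: q<0.01 at {nsig} sites")
        return "\n".join(lines)


def classify_sites(results: DMResults, invariable: np.ndarray,
                   indeterminate_input: Optional[np.ndarray] = None,
                   alpha: float = 0.01, delta: float = 0.25) -> pd.DataFrame:
    """Assign each site one label: a covariate, invariable, or indeterminate.

    A covariate qualifies iff its q < alpha, every other covariate's q is
    strictly > alpha, and (factor covariates only) the max pairwise
    group-mean proportion difference is strictly > delta. Continuous
    covariates (hybrid index) need only the q conditions.
    """
    S = len(results.sites)
    labels = np.full(S, "indeterminate", dtype=object)
    invariable = np.asarray(invariable, dtype=bool)
    q = results.covariate_q
    covs = results.covariates
    diffs = {}
    for ci, cname in enumerate(covs):
        if cname in FACTOR_COVARIATES:
            diffs[cname] = results.group_mean_difference(cname)
    stat_cols = {c: results.z[:, results.column_index(results.model.terms[c][0])]
                 for c in covs}
    for ci, cname in enumerate(covs):
        qc = q[:, ci]
        others = [q[:, cj] for cj in range(len(covs)) if cj != ci]
        ok = (qc < alpha)
        for qo in others:
            ok &= np.isnan(qo) | (qo > alpha)
        if cname in diffs:
            ok &= diffs[cname] > delta
        labels[ok] = cname
    labels[invariable] = "invariable"
    if indeterminate_input is not None:
        labels[np.asarray(indeterminate_input, dtype=bool)] = "indeterminate"
    out = results.sites.copy()
    out["label"] = labels
    for ci, cname in enumerate(covs):
        out[f"q_{cname}"] = q[:, ci]
        out[f"stat_{cname}"] = stat_cols[cname]
    for cname, d in diffs.items():
        out[f"meandiff_{cname}"] = d
    return out


def intersect_taxon_dmps(class_comgar: pd.DataFrame, class_hybzon: pd.DataFrame,
                         label_a: str = "taxon",
                         label_b: str = "hybrid_index") -> pd.DataFrame:
    """Base-pair-resolution intersection of taxon DMPs across experiments.

    Sites labelled `taxon` in ComGar are matched against sites labelled
    `hybrid_index` in HybZon at identical (chrom, pos); effect directions of
    both experiments are reported.
    """
    a = class_comgar[class_comgar["label"] == label_a]
    b = class_hybzon[class_hybzon["label"] == label_b]
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_comgar", "_hybzon"))
    out = merged[["chrom", "pos"]].copy()
    sa = f"stat_{label_a}_comgar" if f"stat_{label_a}_comgar" in merged else f"stat_{label_a}"
    sb = f"stat_{label_b}_hybzon" if f"stat_{label_b}_hybzon" in merged else f"stat_{label_b}"
    if sa in merged:
        out["direction_comgar"] = np.sign(merged[sa])
    if sb in merged:
        out["direction_hybzon"] = np.sign(merged[sb])
    return out.reset_index(drop=True)
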