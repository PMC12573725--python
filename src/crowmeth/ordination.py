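"""Distance-based redundancy analysis (dbRDA) with permutation ANOVA by term.

The model embeds the sample distance matrix by principal coordinates (Gower
double-centering) and constrains the embedding on an explanatory design;
with Euclidean distances this is numerically identical to classical RDA on
the column-centered data matrix, which serves as the module's correctness
oracle. Covariate columns are standardised ("scaled" ordination); term
significance uses sequential (Type-I) sums of squares with unrestricted row
permutations of the response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


def build_constraints(covariates: pd.DataFrame, terms: Sequence[str],
                      scale: bool = True):
    """Per-term standardised design blocks (treatment-coded factors)."""
    blocks = []
    for term in terms:
        col = covariates[term]
        if pd.api.types.is_numeric_dtype(col):
            X = col.to_numpy(float)[:, None]
            names = [term]
        else:
            levels = pd.unique(col)
            X = np.column_stack([(col == lev).astype(float) for lev in levels[1:]])
            names = [f"{term}[{lev}]" for lev in levels[1:]]
        if X.shape[1] == 0:
            raise ValueError(f"term {term!r} has a single level")
        blocks.append((term, X, names))
    out = []
    for term, X, names in blocks:
        X = X - X.mean(axis=0)
        if scale:
            sd = X.std(axis=0, ddof=1)
            if (sd == 0).any():
                raise ValueError(f"constant constraint column in term {term!r}")
            X = X / sd
        out.append((term, X, names))
    return out


class DBRDA:
    """Constrained ordination of a sample distance matrix.

    Parameters
    ----------
    data : (n_samples, n_features) matrix (e.g., methylation proportions;
        no missing entries) or a precomputed condensed/square distance matrix
        with distance="precomputed".
    covariates : DataFrame of per-sample explanatory variables.
    terms : ordered covariate names entering the sequential ANOVA.
    """

    def __init__(self, data, covariates: pd.DataFrame, terms: Sequence[str],
                 distance: str = "euclidean", scale: bool = True):
        data = np.asarray(data, dtype=float)
        if np.isnan(data).any():
            raise ValueError("data contains missing entries; filter sites first")
        if distance == "precomputed":
            D = squareform(data) if data.ndim == 1 else data
        else:
            D = squareform(pdist(data, metric=distance))
        n = D.shape[0]
        if len(covariates) != n:
            raise ValueError("covariates and data disagree on sample count")
        self.n = n
        self.distance = distance
        self.blocks = build_constraints(covariates, terms, scale=scale)
        self.terms = list(terms)
        m = sum(X.shape[1] for _, X, _ in self.blocks)
        if m > n - 1:
            raise ValueError("more constraint columns than samples - 1")
        # Gower double-centering and principal-coordinate embedding
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (D ** 2) @ J
        G = (G + G.T) / 2
        lam, vec = np.linalg.eigh(G)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        keep = lam > max(lam.max(), 0) * 1e-10
        if not keep.any() or lam[keep].sum() <= 0:
            raise ValueError("zero total inertia")
        if (lam < -1e-8 * max(lam.max(), 1)).any():
            # negative eigenvalues (non-Euclidean distances) are dropped
            pass
        self.coords = vec[:, keep] * np.sqrt(lam[keep])
        self.eigenvalues = lam[keep]
        self.total_inertia = float(lam[keep].sum())

    def _orthonormal_blocks(self):
        """Sequentially orthonormalised basis per term (Type-I ordering)."""
        qs = []
        prev = np.empty((self.n, 0))
        for term, X, _ in self.blocks:
            Xr = X - prev @ (prev.T @ X) if prev.shape[1] else X
            q, r = np.linalg.qr(Xr)
            keep = np.abs(np.diag(r)) > 1e-10
            q = q[:, keep]
            qs.append((term, q))
            prev = np.hstack([prev, q])
        return qs, prev

    def fit(self, n_permutations: int = 999,
            rng: Optional[np.random.Generator] = None) -> "OrdinationResult":
        rng = rng or np.random.default_rng()
        C = self.coords
        n = self.n
        qs, Q_full = self._orthonormal_blocks()
        m = Q_full.shape[1]
        df_res = n - 1 - m
        if df_res <= 0:
            raise ValueError("no residual degrees of freedom")

        def term_ss(Cmat):
            return np.array([np.sum((q.T @ Cmat) ** 2) for _, q in qs])

        ss_terms = term_ss(C)
        ss_full = float(ss_terms.sum())
        ss_res = self.total_inertia - ss_full
        dfs = np.array([q.shape[1] for _, q in qs])
        F_terms = (ss_terms / dfs) / (ss_res / df_res)
        F_overall = (ss_full / m) / (ss_res / df_res)

        exceed = np.zeros(len(qs))
        exceed_overall = 0
        for _ in range(n_permutations):
            Cp = C[rng.permutation(n)]
            ssp = term_ss(Cp)
            ssr = self.total_inertia - ssp.sum()
            Fp = (ssp / dfs) / (ssr / df_res)
            exceed += Fp >= F_terms
            Fpo = (ssp.sum() / m) / (ssr / df_res)
            exceed_overall += Fpo >= F_overall
        p_terms = (1.0 + exceed) / (n_permutations + 1.0)
        p_overall = (1.0 + exceed_overall) / (n_permutations + 1.0)

        r2 = ss_full / self.total_inertia
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - m)
        fitted = Q_full @ (Q_full.T @ C)
        sv = np.linalg.svd(fitted, compute_uv=False)
        constrained_eig = (sv ** 2)[sv ** 2 > 1e-12]
        svr = np.linalg.svd(C - fitted, compute_uv=False)
        unconstrained_eig = (svr ** 2)[svr ** 2 > 1e-12]
        u, s, _ = np.linalg.svd(fitted, full_matrices=False)
        scores = u[:, : len(constrained_eig)] * s[: len(constrained_eig)]
        anova = pd.DataFrame({
            "term": [t for t, _ in qs], "df": dfs, "ss": ss_terms,
            "F": F_terms, "p": p_terms})
        return OrdinationResult(self, constrained_eig, unconstrained_eig,
                                scores, r2, adj_r2, float(F_overall),
                                float(p_overall), anova, n_permutations)


@dataclass
class OrdinationResult:
    model: DBRDA
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    sample_scores: np.ndarray
    r2: float
    adj_r2: float
    f_overall: float
    p_overall: float
    anova: pd.DataFrame
    n_permutations: int

    def summary(self) -> str:
        lines = [f"dbRDA ({self.model.distance} distance, n = {self.model.n})",
                 f"R2 = {self.r2:.4f}   adjusted R2 = {self.adj_r2:.4f}",
                 f"overall F = {self.f_overall:.3f}, "
                 f"p = {self.p_overall:.4g} ({self.n_permutations} permutations)",
                 self.anova.to_string(index=False,
                                      float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)
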