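"""Window-level predictability of methylation divergence.

Builds the 5-kb window feature table (log-transformed aggregate |taxon
statistic| as response; genome properties and population-genetic metrics as
predictors, with nearest-window imputation of missing metrics) and runs the
tuned-learner permutation-importance protocol: 75/25 stratified split,
5-fold cross-validated random grid search, test-set permutation importance
scaled to sum to 1 within each replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import RandomizedSearchCV, train_test_split

POPGEN_METRICS = ("fst", "dxy", "tajima_d", "hd", "fu_li_dstar")
GENOME_PREDICTORS = ("gc", "chrom_length", "rel_pos", "frac_promoter",
                     "frac_repeat", "frac_CDS", "frac_intron", "frac_intergenic")


def build_feature_table(window_stats: pd.DataFrame, window_props: pd.DataFrame,
                        site_stats: pd.DataFrame, focal_region: tuple,
                        agg: str = "mean", window_size: int = 5000,
                        eps: float = 1e-6) -> pd.DataFrame:
    """Per-window response and predictors.

    site_stats: chrom, pos, stat (the per-CpG taxon Wald statistic).
    Response = log(agg(|stat|) + eps). Windows without assayed CpGs are
    excluded; missing population-genetic metrics are imputed from the
    nearest populated window on the same chromosome (ties to the left);
    the imputed fraction is recorded in DataFrame.attrs.
    """
    if agg not in ("mean", "max"):
        raise ValueError("agg must be mean or max")
    if site_stats["stat"].isna().any():
        raise ValueError("site stats contain missing values (upstream inconsistency)")
    ss = site_stats.copy()
    ss["start"] = (ss["pos"] // window_size) * window_size
    ss["absstat"] = ss["stat"].abs()
    aggfun = {"mean": "mean", "max": "max"}[agg]
    resp = (ss.groupby(["chrom", "start"])["absstat"].agg(aggfun)
            .rename("divergence").reset_index())
    resp["response"] = np.log(resp["divergence"] + eps)

    tbl = resp.merge(window_props, on=["chrom", "start"], how="left")
    tbl = tbl.merge(window_stats[["chrom", "start"] + list(POPGEN_METRICS)],
                    on=["chrom", "start"], how="left")
    # nearest-window imputation per metric, same chromosome, ties -> left
    n_imputed = 0
    for metric in POPGEN_METRICS:
        miss = tbl[metric].isna()
        if not miss.any():
            continue
        for chrom, sub in tbl.groupby("chrom"):
            have = sub[~sub[metric].isna()]
            need = sub[sub[metric].isna()]
            if need.empty:
                continue
            if have.empty:
                raise ValueError(f"no populated windows for {metric} on {chrom}")
            mid_have = (have["start"] + window_size / 2).to_numpy()
            for i, row in need.iterrows():
                mid = row["start"] + window_size / 2
                dist = np.abs(mid_have - mid)
                j = int(np.flatnonzero(dist == dist.min())[0])  # tie -> left
                tbl.loc[i, metric] = have[metric].iloc[j]
                n_imputed += 1
    fc, fs, fe = focal_region
    tbl["focal"] = ((tbl["chrom"] == fc) & (tbl["start"] >= fs)
                    & (tbl["start"] < fe))
    tbl.attrs["imputed_fraction"] = n_imputed / max(len(tbl) * len(POPGEN_METRICS), 1)
    tbl.attrs["agg"] = agg
    return tbl


_GRIDS = {
    "rf": (RandomForestRegressor,
           {"n_estimators": [100, 200, 300], "min_samples_leaf": [1, 2, 5],
            "max_features": [0.3, 0.6, 1.0]}),
    "gbm": (GradientBoostingRegressor,
            {"n_estimators": [100, 200], "learning_rate": [0.03, 0.1, 0.3],
             "max_depth": [2, 3, 4], "min_samples_leaf": [1, 5]}),
}


@dataclass
class ImportanceProfile:
    """Scaled permutation importances per replicate (rows sum to 1)."""
    importances: pd.DataFrame   # replicate x predictor
    rmse: list
    learner: str

    def mean_importance(self) -> pd.Series:
        return self.importances.mean(axis=0).sort_values(ascending=False)


def permutation_importance_run(table: pd.DataFrame, learner: str = "rf",
                               predictors: Optional[Sequence[str]] = None,
                               split: float = 0.75, cv_folds: int = 5,
                               replicates: int = 10, n_shuffles: int = 10,
                               grid_iter: int = 8,
                               rng: Optional[np.random.Generator] = None,
                               classification: bool = False) -> ImportanceProfile:
    """Tuned-learner test-set permutation importance over replicate seeds.

    Per replicate: 75/25 split, random grid search with cross-validation on
    the training fold, test RMSE (or accuracy for the binary-response
    variant), then per predictor the mean increase in test loss over
    n_shuffles random permutations of that predictor's test values, floored
    at 0 and scaled to sum to 1.
    """
    rng = rng or np.random.default_rng()
    if predictors is None:
        predictors = [c for c in GENOME_PREDICTORS + POPGEN_METRICS
                      if c in table.columns]
    Est, grid = _GRIDS[learner]
    X = table[list(predictors)].to_numpy(float)
    y = table["response"].to_numpy(float)
    if classification:
        y = (y > np.median(y)).astype(int)
    rows, rmses = [], []
    for _rep in range(replicates):
        seed = int(rng.integers(0, 2 ** 31 - 1))
        if np.var(y) == 0:
            continue  # degenerate response
        Xtr, Xte, ytr, yte = train_test_split(X, y, train_size=split,
                                              random_state=seed)
        search = RandomizedSearchCV(Est(random_state=seed), grid,
                                    n_iter=grid_iter, cv=cv_folds,
                                    random_state=seed, n_jobs=1)
        search.fit(Xtr, ytr)
        est = search.best_estimator_
        pred = est.predict(Xte)
        if classification:
            base_loss = 1.0 - np.mean(np.round(pred) == yte)
        else:
            base_loss = float(np.sqrt(np.mean((pred - yte) ** 2)))
        rmses.append(base_loss)
        local = np.random.default_rng(seed)
        raw = np.zeros(len(predictors))
        for j in range(len(predictors)):
            losses = []
            for _ in range(n_shuffles):
                Xp = Xte.copy()
                Xp[:, j] = local.permutation(Xp[:, j])
                pp = est.predict(Xp)
                if classification:
                    losses.append(1.0 - np.mean(np.round(pp) == yte))
                else:
                    losses.append(float(np.sqrt(np.mean((pp - yte) ** 2))))
            raw[j] = np.mean(losses) - base_loss
        raw = np.maximum(raw, 0.0)
        total = raw.sum()
        rows.append(raw / total if total > 0 else np.full_like(raw, 1 / len(raw)))
    imp = pd.DataFrame(rows, columns=list(predictors))
    return ImportanceProfile(imp, rmses, learner)
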