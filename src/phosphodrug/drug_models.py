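"""Feature-drug association models.

Pairwise Pearson screening with a minimum pairwise-complete rule,
elastic-net marker frequency ranking, exhaustive random-forest subset
models for small metabolic panels, and the regulatory-p-site screen.
All directions refer to the canonical orientation (higher = more
sensitive): a positive correlation is a sensitivity marker, a negative
one a resistance marker. No value is ever imputed for the screens;
filtering is pairwise- or row-complete only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .core_io import DEFAULT_MIN_N, REJECTED, pairwise_complete_filter
from .datatypes import DataError, DrugResponseMatrix, IntensityMatrix, PsiteAnnotation
from . import stats

logger = logging.getLogger(__name__)


def correlation_screen(
    features: IntensityMatrix,
    drugs: DrugResponseMatrix,
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """Pearson screen of every feature-drug pair with enough complete pairs.

    Pairs with fewer than ``min_n`` pairwise-complete observations are
    dropped entirely. BH adjustment is applied within each drug. Returns
    the marker table (feature, drug, r, p, q, n, direction, method).
    """
    canon = drugs.canonical()
    shared = [c for c in features.cell_lines if c in canon.values.columns]
    if len(shared) < min_n:
        raise DataError("fewer shared cell lines than min_n")
    fv = features.values[shared]
    dv = canon.values[shared]

    rows = []
    for drug in dv.index:
        y = dv.loc[drug].to_numpy(dtype=float)
        drug_rows = []
        for feat in fv.index:
            x = fv.loc[feat].to_numpy(dtype=float)
            idx = pairwise_complete_filter(x, y, min_n=min_n)
            if isinstance(idx, str) and idx == REJECTED:
                continue
            res = stats.pearson_test(x[idx], y[idx])
            if res.undefined:
                continue
            drug_rows.append(
                {"feature": feat, "drug": drug, "r": res.effect, "p": res.p,
                 "n": res.n,
                 "direction": "sensitivity" if res.effect > 0 else "resistance",
                 "method": "correlation"}
            )
        if drug_rows:
            qs = stats.bh_adjust([r["p"] for r in drug_rows])
            for r, q in zip(drug_rows, qs):
                r["q"] = float(q)
            rows.extend(drug_rows)
    if not rows:
        raise DataError("no feature-drug pair had enough pairwise-complete observations")
    return pd.DataFrame(rows)[
        ["feature", "drug", "r", "p", "q", "n", "direction", "method"]
    ]


@dataclass
class ElasticNetResult:
    coefficients: pd.DataFrame        # features x drugs, sparse betas
    frequency: pd.DataFrame           # feature, sensitivity_count, resistance_count, total
    chosen_lambda: dict[str, float]
    skipped_drugs: list[str]


def _enet_lambda_path(X: np.ndarray, y: np.ndarray, l1_ratio: float, n: int = 50):
    lam_max = np.abs(X.T @ y).max() / (len(y) * max(l1_ratio, 1e-3))
    return np.geomspace(lam_max, lam_max * 1e-3, n)


def enet_markers(
    features: IntensityMatrix,
    drugs: DrugResponseMatrix,
    l1_ratio: float = 0.5,
    cv_folds: int = 5,
    seed: int = 0,
    min_cell_lines: int = 20,
    lambdas: Sequence[float] | None = None,
) -> ElasticNetResult:
    """Per-drug elastic net with CV + 1-SE lambda, and marker frequencies.

    For each drug the rows are the cell lines with an observed response;
    only features fully observed on those rows enter the design (no
    imputation). The frequency of a feature is the number of drugs for
    which its coefficient is nonzero with a given sign; the ranking is
    by total frequency, descending.
    """
    canon = drugs.canonical()
    shared = [c for c in features.cell_lines if c in canon.values.columns]
    fv = features.values[shared]
    dv = canon.values[shared]

    coef_cols: dict[str, pd.Series] = {}
    chosen: dict[str, float] = {}
    skipped: list[str] = []
    rng = np.random.default_rng(seed)
    for drug in dv.index:
        y_all = dv.loc[drug]
        rows = y_all.notna()
        Xf = fv.loc[:, rows.to_numpy()]
        usable = Xf.notna().all(axis=1)
        Xf = Xf.loc[usable]
        if rows.sum() < min_cell_lines or Xf.shape[0] == 0:
            skipped.append(drug)
            logger.warning("drug %s skipped: not enough complete cell lines/features", drug)
            continue
        y = y_all[rows].to_numpy(dtype=float)
        if np.std(y) == 0:
            skipped.append(drug)
            logger.warning("drug %s skipped: constant response", drug)
            continue
        X = Xf.T.to_numpy(dtype=float)   # cells x features
        Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
        ys = (y - y.mean()) / y.std()

        lam_grid = (
            np.asarray(lambdas, dtype=float)
            if lambdas is not None
            else _enet_lambda_path(Xs, ys, l1_ratio)
        )
        kf = KFold(n_splits=cv_folds, shuffle=True,
                   random_state=int(rng.integers(2**31 - 1)))
        mse = np.zeros((len(lam_grid), cv_folds))
        for j, (tr, te) in enumerate(kf.split(Xs)):
            for i, lam in enumerate(lam_grid):
                model = ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=5000)
                model.fit(Xs[tr], ys[tr])
                pred = model.predict(Xs[te])
                mse[i, j] = float(np.mean((ys[te] - pred) ** 2))
        mean_mse = mse.mean(axis=1)
        se = mse.std(axis=1, ddof=1) / np.sqrt(cv_folds)
        best = int(np.argmin(mean_mse))
        limit = mean_mse[best] + se[best]
        # 1-SE rule: sparsest lambda whose cv error is within 1 SE of the min
        one_se = int(min(i for i in range(len(lam_grid)) if mean_mse[i] <= limit))
        lam = float(lam_grid[one_se])
        final = ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=10000)
        final.fit(Xs, ys)
        coef_cols[drug] = pd.Series(final.coef_, index=Xf.index)
        chosen[drug] = lam

    if not coef_cols:
        raise DataError("elastic net produced no models (all drugs skipped)")
    coefficients = pd.DataFrame(coef_cols).fillna(0.0)
    sens = (coefficients > 0).sum(axis=1)
    res = (coefficients < 0).sum(axis=1)
    frequency = pd.DataFrame(
        {"feature": coefficients.index,
         "sensitivity_count": sens.to_numpy(),
         "resistance_count": res.to_numpy(),
         "total": (sens + res).to_numpy()}
    ).sort_values(["total", "feature"], ascending=[False, True]).reset_index(drop=True)
    return ElasticNetResult(coefficients, frequency, chosen, skipped)


def enumerate_subsets(panel: Sequence[str], sizes: Sequence[int]) -> list[tuple[str, ...]]:
    """All feature subsets of the panel at the requested sizes."""
    if max(sizes) > len(panel):
        raise DataError(
            f"subset size {max(sizes)} exceeds panel of {len(panel)} features"
        )
    out: list[tuple[str, ...]] = []
    for k in sizes:
        out.extend(combinations(panel, k))
    return out


@dataclass
class SubsetModelResult:
    ranking: pd.DataFrame          # subset, size, cv_r
    top_models: pd.DataFrame       # top_k per size
    holdout: pd.DataFrame | None   # subset, holdout_r


def rf_subset_models(
    features: IntensityMatrix,
    drug_response: pd.Series,
    panel: Sequence[str],
    sizes: Sequence[int] = (3, 4, 5, 6, 7),
    cv_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 500,
    top_k: int = 5,
    holdout: tuple[IntensityMatrix, pd.Series] | None = None,
) -> SubsetModelResult:
    """Exhaustive random-forest models over small feature subsets.

    Every subset of ``panel`` at each size is fit as a random-forest
    regressor and ranked by the cross-validated Pearson r between
    predicted and observed response. The top ``top_k`` models per size
    are reported and optionally evaluated on a held-out panel.
    """
    subsets = enumerate_subsets(panel, sizes)
    values = features.values
    missing_panel = [f for f in panel if f not in values.index]
    if missing_panel:
        raise DataError(f"panel features absent from the matrix: {missing_panel}")
    y_all = drug_response.reindex(values.columns)
    base = values.loc[list(panel)]
    usable_cells = base.notna().all(axis=0) & y_all.notna()
    if int(usable_cells.sum()) < 15:
        raise DataError(
            f"response/panel complete for only {int(usable_cells.sum())} cell lines (< 15)"
        )
    X_full = base.loc[:, usable_cells].T.to_numpy(dtype=float)
    y = y_all[usable_cells].to_numpy(dtype=float)
    col_of = {f: i for i, f in enumerate(panel)}

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X_full))
    rows = []
    for subset in subsets:
        cols = [col_of[f] for f in subset]
        X = X_full[:, cols]
        pred = np.empty_like(y)
        for tr, te in folds:
            model = RandomForestRegressor(
                n_estimators=n_estimators, random_state=seed, n_jobs=1
            )
            model.fit(X[tr], y[tr])
            pred[te] = model.predict(X[te])
        r = float(np.corrcoef(pred, y)[0, 1])
        rows.append({"subset": "+".join(subset), "size": len(subset), "cv_r": r})
    ranking = pd.DataFrame(rows).sort_values(
        ["cv_r", "subset"], ascending=[False, True]
    ).reset_index(drop=True)
    top_models = pd.concat(
        [ranking[ranking["size"] == k].head(top_k) for k in sorted(set(sizes))],
        ignore_index=True,
    )

    holdout_frame = None
    if holdout is not None:
        ho_feats, ho_response = holdout
        hv = ho_feats.values
        ho_y = ho_response.reindex(hv.columns)
        ho_base = hv.reindex(list(panel))
        ok = ho_base.notna().all(axis=0) & ho_y.notna()
        ho_rows = []
        for _, mrow in top_models.iterrows():
            subset = tuple(mrow["subset"].split("+"))
            cols = [col_of[f] for f in subset]
            model = RandomForestRegressor(
                n_estimators=n_estimators, random_state=seed, n_jobs=1
            )
            model.fit(X_full[:, cols], y)
            Xh = ho_base.loc[list(subset), ok].T.to_numpy(dtype=float)
            pred = model.predict(Xh)
            r = float(np.corrcoef(pred, ho_y[ok].to_numpy(dtype=float))[0, 1])
            ho_rows.append({"subset": mrow["subset"], "size": mrow["size"],
                            "holdout_r": r, "n_holdout": int(ok.sum())})
        holdout_frame = pd.DataFrame(ho_rows)
    return SubsetModelResult(ranking=ranking, top_models=top_models, holdout=holdout_frame)


def regulatory_site_screen(
    psites: IntensityMatrix,
    drugs: DrugResponseMatrix,
    annotation: Sequence[PsiteAnnotation],
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """Correlation screen restricted to regulatory (activity-annotated) sites.

    Only sites with regulatory class "activating" or "inhibitory" are
    screened; the output carries the class so co-treatment hypotheses can
    be formed from, e.g., inhibitory-site/resistance combinations.
    """
    classes = {a.psite_id: a.regulatory_class for a in annotation}
    keep = [f for f in psites.features if classes.get(f) in ("activating", "inhibitory")]
    if not keep:
        raise DataError("no p-sites with regulatory class annotation")
    table = correlation_screen(psites.subset_features(keep), drugs, min_n=min_n)
    table["regulatory_class"] = table["feature"].map(classes)
    table["method"] = "regulatory-correlation"
    return table
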