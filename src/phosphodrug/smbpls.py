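"""Sparse multiblock partial least squares regression.

NIPALS-style latent components with soft-thresholded (L1-sparse) feature
weights per block, nonnegative block combination weights, and sparse
drug weights, so each component defines a drug cluster (drugs with
nonzero weight) and its shared marker set.

Sparsity parameters are RELATIVE: the soft threshold applied to a weight
vector v is lambda * max|v|, which makes the same lambda meaningful
across blocks of different scale. lambda = 0 with a single block reduces
each component to the PLS-SVD solution (leading singular vectors of
X'Y); lambda >= 1 zeroes the whole vector and raises
OverSparsifiedError.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import REJECTED, pairwise_complete_filter
from .datatypes import DataError, DrugResponseMatrix, IntensityMatrix
from . import stats

logger = logging.getLogger(__name__)


class OverSparsifiedError(DataError):
    """A soft threshold zeroed an entire weight vector."""


def soft_threshold(x, threshold: float):
    """S(x, t) = sign(x) * max(|x| - t, 0)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - threshold, 0.0)


@dataclass
class Component:
    block_weights: list[pd.Series]      # sparse, unit-norm per block
    block_scores: list[np.ndarray]
    block_combination: np.ndarray       # nonnegative, sums to 1
    super_score: np.ndarray
    drug_weights: pd.Series             # sparse, unit-norm
    drug_score: np.ndarray
    x_loadings: list[np.ndarray]        # deflation loadings per block
    y_loadings: np.ndarray
    iterations: int
    converged: bool
    residual_norms: dict[str, float]


@dataclass
class SmbplsModel:
    components: list[Component]
    block_names: list[str]
    feature_names: list[pd.Index]
    drug_names: pd.Index
    cell_lines: pd.Index
    lambda_blocks: list[float]
    lambda_y: float
    n_imputed: dict[str, int] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.components)


def _as_cells_by_features(block) -> pd.DataFrame:
    if isinstance(block, IntensityMatrix):
        return block.values.T
    return pd.DataFrame(block)


def _standardize_and_fill(df: pd.DataFrame, name: str, counts: dict[str, int]) -> pd.DataFrame:
    mu = df.mean(axis=0, skipna=True)
    sd = df.std(axis=0, ddof=0, skipna=True).replace(0.0, np.nan)
    z = df.sub(mu, axis=1).div(sd, axis=1)
    n_missing = int(z.isna().sum().sum())
    counts[name] = n_missing
    if n_missing:
        logger.info("%s: zero-filled %d missing standardized entries", name, n_missing)
    return z.fillna(0.0)


def fit_smbpls(
    blocks: Sequence[IntensityMatrix | pd.DataFrame],
    y: DrugResponseMatrix | pd.DataFrame,
    n_components: int = 2,
    lambda_blocks: Sequence[float] | float = 0.0,
    lambda_y: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    block_names: Sequence[str] | None = None,
) -> SmbplsModel:
    """Fit the sparse multiblock PLS model.

    Blocks are cell lines x features after transposition from the
    feature-major IntensityMatrix layout; columns are standardized and
    missing entries zero-filled afterwards (mean-imputation equivalent,
    counted and logged). ``y`` is used in canonical orientation.

    Per component the update loop is: u <- first left singular vector of
    Y; for each block b: w_b <- soft_threshold(X_b'u, lambda_b * max|.|)
    normalized, t_b <- X_b w_b; a_b proportional to max(cov(t_b, u), 0),
    normalized to sum 1; t <- sum a_b t_b; q <- soft_threshold(Y't,
    lambda_y * max|.|) normalized; u <- Y q; until successive super
    scores change by less than ``tol``. Both X blocks and Y are deflated
    on the super score. Sign indeterminacy is resolved by making the
    largest-magnitude drug weight positive.
    """
    if isinstance(y, DrugResponseMatrix):
        ydf = y.canonical().values.T            # cells x drugs
    else:
        ydf = pd.DataFrame(y)
    dfs = [_as_cells_by_features(b) for b in blocks]
    names = list(block_names) if block_names else [f"block{i}" for i in range(len(dfs))]
    if len(names) != len(dfs):
        raise DataError("block_names length mismatch")
    if np.isscalar(lambda_blocks):
        lambda_blocks = [float(lambda_blocks)] * len(dfs)
    lambda_blocks = [float(v) for v in lambda_blocks]
    if len(lambda_blocks) != len(dfs):
        raise DataError("lambda_blocks length mismatch")
    for lam in [*lambda_blocks, lambda_y]:
        if lam < 0.0:
            raise DataError(f"relative sparsity parameters must be >= 0, got {lam}")

    shared = ydf.index
    for df in dfs:
        shared = shared.intersection(df.index)
    if len(shared) < 3:
        raise DataError("fewer than 3 shared cell lines across blocks and Y")
    shared = pd.Index(sorted(shared))
    counts: dict[str, int] = {}
    X = [
        _standardize_and_fill(df.loc[shared], name, counts).to_numpy(dtype=float)
        for df, name in zip(dfs, names)
    ]
    Y = _standardize_and_fill(ydf.loc[shared], "Y", counts).to_numpy(dtype=float)
    feature_names = [df.columns for df in dfs]
    drug_names = ydf.columns
    n = len(shared)

    components: list[Component] = []
    for comp_idx in range(n_components):
        u = np.linalg.svd(Y, full_matrices=False)[0][:, 0]
        t_prev = None
        converged = False
        iterations = 0
        delta = np.inf
        for iterations in range(1, max_iter + 1):
            ws, ts = [], []
            for b, Xb in enumerate(X):
                v = Xb.T @ u
                w = soft_threshold(v, lambda_blocks[b] * np.abs(v).max())
                norm = np.linalg.norm(w)
                if norm == 0.0:
                    raise OverSparsifiedError(
                        f"component {comp_idx + 1}: lambda={lambda_blocks[b]} zeroed"
                        f" all feature weights of {names[b]}"
                    )
                w /= norm
                ws.append(w)
                ts.append(Xb @ w)
            a = np.array([max(float(tb @ u) / max(n - 1, 1), 0.0) for tb in ts])
            if a.sum() == 0.0:
                a = np.ones(len(X))
            a /= a.sum()
            t = sum(ab * tb for ab, tb in zip(a, ts))
            vy = Y.T @ t
            q = soft_threshold(vy, lambda_y * np.abs(vy).max())
            qnorm = np.linalg.norm(q)
            if qnorm == 0.0:
                raise OverSparsifiedError(
                    f"component {comp_idx + 1}: lambda_y={lambda_y} zeroed all drug weights"
                )
            q /= qnorm
            u = Y @ q
            if t_prev is not None:
                denom = np.linalg.norm(t) or 1.0
                delta = np.linalg.norm(t - t_prev) / denom
                if delta < tol:
                    converged = True
                    break
            t_prev = t
        if not converged:
            logger.warning(
                "component %d did not converge after %d iterations (last delta %.2e)",
                comp_idx + 1, max_iter, delta,
            )
        # resolve sign indeterminacy: largest-magnitude drug weight positive
        if q[int(np.argmax(np.abs(q)))] < 0:
            q, u, t = -q, -u, -t
            ws = [-w for w in ws]
            ts = [-tb for tb in ts]

        tt = float(t @ t)
        if tt == 0.0:
            logger.warning("component %d has a zero super score; stopping", comp_idx + 1)
            break
        p_loadings = [Xb.T @ t / tt for Xb in X]
        c_loading = Y.T @ t / tt
        X = [Xb - np.outer(t, pb) for Xb, pb in zip(X, p_loadings)]
        Y = Y - np.outer(t, c_loading)
        components.append(
            Component(
                block_weights=[
                    pd.Series(w, index=idx) for w, idx in zip(ws, feature_names)
                ],
                block_scores=ts,
                block_combination=a,
                super_score=t,
                drug_weights=pd.Series(q, index=drug_names),
                drug_score=u,
                x_loadings=[np.asarray(pb) for pb in p_loadings],
                y_loadings=np.asarray(c_loading),
                iterations=iterations,
                converged=converged,
                residual_norms={
                    **{names[b]: float(np.linalg.norm(X[b])) for b in range(len(X))},
                    "Y": float(np.linalg.norm(Y)),
                },
            )
        )
    return SmbplsModel(
        components=components,
        block_names=names,
        feature_names=feature_names,
        drug_names=drug_names,
        cell_lines=shared,
        lambda_blocks=lambda_blocks,
        lambda_y=float(lambda_y),
        n_imputed=counts,
    )


def predict_y(model: SmbplsModel, blocks: Sequence[IntensityMatrix | pd.DataFrame]) -> pd.DataFrame:
    """Reconstruct standardized Y for new cell lines from fitted components."""
    dfs = [_as_cells_by_features(b) for b in blocks]
    shared = dfs[0].index
    for df in dfs[1:]:
        shared = shared.intersection(df.index)
    counts: dict[str, int] = {}
    X = [
        _standardize_and_fill(df.loc[shared], name, counts).to_numpy(dtype=float)
        for df, name in zip(dfs, model.block_names)
    ]
    yhat = np.zeros((len(shared), len(model.drug_names)))
    for comp in model.components:
        ts = [Xb @ comp.block_weights[b].to_numpy() for b, Xb in enumerate(X)]
        t = sum(ab * tb for ab, tb in zip(comp.block_combination, ts))
        yhat += np.outer(t, comp.y_loadings)
        X = [Xb - np.outer(t, pb) for Xb, pb in zip(X, comp.x_loadings)]
    return pd.DataFrame(yhat, index=shared, columns=model.drug_names)


@dataclass
class ClusterReport:
    component: int
    drugs: list[str]
    drug_scores: pd.Series              # |q| restricted to the cluster
    markers: pd.DataFrame               # feature, block, weight, direction
    edges: pd.DataFrame                 # drug_i, drug_j, r, n


def report_clusters(
    model: SmbplsModel,
    y: DrugResponseMatrix,
    min_abs_q: float = 0.0,
    min_n: int = 7,
) -> list[ClusterReport]:
    """Per-component drug clusters, marker directions and drug-drug edges.

    A drug belongs to a component's cluster when |q| > min_abs_q. Marker
    direction is sensitivity when sign(w) * sign(q_dominant) > 0 under
    canonical orientation. Edges are pairwise Pearson correlations of the
    observed (uncentered) canonical sensitivity profiles within the
    cluster, over pairwise-complete cell lines.
    """
    canon = y.canonical().values
    reports: list[ClusterReport] = []
    for k, comp in enumerate(model.components):
        q = comp.drug_weights
        cluster = q[np.abs(q) > min_abs_q]
        if cluster.empty:
            logger.warning("component %d: empty drug cluster, skipped", k + 1)
            continue
        dominant = float(np.sign(cluster.iloc[int(np.argmax(np.abs(cluster.to_numpy())))]))
        marker_rows = []
        for b, w in enumerate(comp.block_weights):
            for feat, weight in w[w != 0].items():
                marker_rows.append(
                    {"feature": feat, "block": model.block_names[b],
                     "weight": float(weight),
                     "direction": "sensitivity" if weight * dominant > 0 else "resistance"}
                )
        markers = pd.DataFrame(
            marker_rows, columns=["feature", "block", "weight", "direction"]
        )
        edge_rows = []
        drugs = list(cluster.index)
        for i in range(len(drugs)):
            for j in range(i + 1, len(drugs)):
                xi = canon.loc[drugs[i]].to_numpy(dtype=float)
                xj = canon.loc[drugs[j]].to_numpy(dtype=float)
                idx = pairwise_complete_filter(xi, xj, min_n=min_n)
                if isinstance(idx, str) and idx == REJECTED:
                    continue
                res = stats.pearson_test(xi[idx], xj[idx])
                if not res.undefined:
                    edge_rows.append(
                        {"drug_i": drugs[i], "drug_j": drugs[j],
                         "r": res.effect, "n": res.n}
                    )
        reports.append(
            ClusterReport(
                component=k + 1,
                drugs=drugs,
                drug_scores=cluster.abs(),
                markers=markers,
                edges=pd.DataFrame(edge_rows, columns=["drug_i", "drug_j", "r", "n"]),
            )
        )
    return reports


def select_sparsity(
    blocks: Sequence[IntensityMatrix | pd.DataFrame],
    y: DrugResponseMatrix | pd.DataFrame,
    grid: Sequence[float],
    cv_folds: int = 5,
    seed: int = 0,
    n_components: int = 2,
) -> tuple[float, float]:
    """Choose a shared relative sparsity level by cross-validation.

    Each grid value is applied to every block and to the drug weights.
    The point minimizing the cross-validated Y-reconstruction error is
    found, then the 1-SE rule moves toward sparser (larger lambda).
    Returns (lambda_blocks_value, lambda_y_value).
    """
    grid = sorted(set(float(g) for g in grid))
    if not grid:
        raise DataError("empty sparsity grid")
    if isinstance(y, DrugResponseMatrix):
        ydf = y.canonical().values.T
    else:
        ydf = pd.DataFrame(y)
    dfs = [_as_cells_by_features(b) for b in blocks]
    shared = ydf.index
    for df in dfs:
        shared = shared.intersection(df.index)
    shared = pd.Index(sorted(shared))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(shared))
    folds = np.array_split(perm, cv_folds)

    errors = np.full((len(grid), cv_folds), np.nan)
    for gi, lam in enumerate(grid):
        try:
            for fi, test_idx in enumerate(folds):
                test_cells = shared[np.sort(test_idx)]
                train_cells = shared.difference(test_cells)
                model = fit_smbpls(
                    [df.loc[train_cells] for df in dfs],
                    ydf.loc[train_cells],
                    n_components=n_components,
                    lambda_blocks=lam,
                    lambda_y=lam,
                    seed=seed,
                )
                yhat = predict_y(model, [df.loc[test_cells] for df in dfs])
                mu = ydf.loc[train_cells].mean(axis=0)
                sd = ydf.loc[train_cells].std(axis=0, ddof=0).replace(0.0, 1.0)
                ytest = ((ydf.loc[test_cells] - mu) / sd).fillna(0.0)
                errors[gi, fi] = float(((ytest - yhat) ** 2).mean().mean())
        except OverSparsifiedError:
            errors[gi, :] = np.nan
    mean_err = np.nanmean(errors, axis=1) if not np.isnan(errors).all() else None
    if mean_err is None or np.isnan(mean_err).all():
        raise OverSparsifiedError("every grid point over-sparsified a weight vector")
    valid = ~np.isnan(mean_err)
    best = int(np.nanargmin(mean_err))
    se = np.nanstd(errors[best], ddof=1) / np.sqrt(cv_folds)
    limit = mean_err[best] + se
    chosen = best
    for gi in range(len(grid) - 1, -1, -1):   # sparsest (largest lambda) first
        if valid[gi] and mean_err[gi] <= limit:
            chosen = gi
            break
    lam = grid[chosen]
    return lam, lam
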