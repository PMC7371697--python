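"""Pathway and kinase relative-activity scoring, landscapes, waterfalls.

Raw activity of an entity (pathway or kinase) in a cell line is the mean
z-score of its member evidence, optionally integrated over channels
(protein abundance, p-sites on the entity, substrate p-sites). Relative
activity is the per-entity min-max rescaling of the raw score to [0, 1]
across cell lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DataError,
    IntensityMatrix,
    PsiteAnnotation,
    SetCollection,
    parse_psite_id,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_MEMBERS = 3


@dataclass
class ActivityMatrix:
    """Entities x cell lines activity scores.

    ``relative`` is min-max rescaled per entity; entities whose raw score
    is constant across cell lines are flagged FLAT and carry NaN relative
    scores.
    """

    raw: pd.DataFrame
    relative: pd.DataFrame
    provenance: dict[str, dict] = field(default_factory=dict)
    flat: set[str] = field(default_factory=set)

    @property
    def entities(self) -> list[str]:
        return list(self.raw.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.raw.columns)


@dataclass
class Landscape:
    """2D embedding of cell lines plus per-entity smoothed height fields."""

    coordinates: pd.DataFrame          # cell lines x (x, y)
    grid_x: np.ndarray
    grid_y: np.ndarray
    heights: dict[str, np.ndarray]     # entity -> (len(grid_y), len(grid_x))
    bandwidth: float
    seed: int = 0


def zscore_features(matrix: IntensityMatrix) -> pd.DataFrame:
    """Per-feature z-score across cell lines using observed entries only."""
    v = matrix.values
    mu = v.mean(axis=1, skipna=True)
    sd = v.std(axis=1, ddof=0, skipna=True)
    z = v.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z


def _relative_from_raw(raw: pd.DataFrame) -> tuple[pd.DataFrame, set[str]]:
    lo = raw.min(axis=1, skipna=True)
    hi = raw.max(axis=1, skipna=True)
    span = hi - lo
    flat = set(raw.index[(span == 0) | span.isna()])
    rel = raw.sub(lo, axis=0).div(span.replace(0.0, np.nan), axis=0)
    rel.loc[list(flat)] = np.nan
    return rel, flat


def _sites_by_host(
    psite_features: Sequence[str],
    annotation: Sequence[PsiteAnnotation] | None,
) -> dict[str, list[str]]:
    mapping: dict[str, list[str]] = {}
    annotated = {a.psite_id: a.protein_id for a in (annotation or [])}
    for site in psite_features:
        host = annotated.get(site)
        if host is None:
            parsed = parse_psite_id(site)
            host = parsed[0] if parsed else None
        if host is not None:
            mapping.setdefault(host, []).append(site)
    return mapping


def pathway_activity(
    protein: IntensityMatrix,
    psite: IntensityMatrix | None,
    pathways: SetCollection,
    annotation: Sequence[PsiteAnnotation] | None = None,
    min_members: int = DEFAULT_MIN_MEMBERS,
) -> ActivityMatrix:
    """Score pathway activity by integrating member proteins and their p-sites.

    The raw score of a pathway in a cell line is the mean z-score over
    member proteins and p-sites on member proteins observed there.
    Pathways with fewer than ``min_members`` resolvable member features
    are dropped with a warning.
    """
    if len(pathways) == 0:
        raise DataError("empty pathway collection")
    if protein.shape[1] < 2:
        raise DataError("pathway_activity needs >= 2 cell lines")
    zp = zscore_features(protein)
    zs = zscore_features(psite) if psite is not None else None
    host_sites = _sites_by_host(psite.features, annotation) if psite is not None else {}

    raw_rows = {}
    provenance = {}
    for name, members in pathways.items():
        feats = [f for f in members if f in zp.index]
        sites = [s for m in members for s in host_sites.get(m, [])]
        if len(feats) + len(sites) < min_members:
            logger.warning(
                "pathway %s dropped: %d resolvable members < %d",
                name, len(feats) + len(sites), min_members,
            )
            continue
        parts = [zp.loc[feats]]
        if sites and zs is not None:
            parts.append(zs.loc[sites])
        stacked = pd.concat(parts, axis=0)
        raw_rows[name] = stacked.mean(axis=0, skipna=True)
        provenance[name] = {
            "proteins": feats,
            "member_psites": sites,
            "channels": ["protein"] + (["member-psite"] if sites else []),
        }
    if not raw_rows:
        raise DataError("no pathway had enough resolvable members")
    raw = pd.DataFrame(raw_rows).T
    raw.index.name = "entity"
    rel, flat = _relative_from_raw(raw)
    return ActivityMatrix(raw=raw, relative=rel, provenance=provenance, flat=flat)


def kinase_activity(
    protein: IntensityMatrix,
    psite: IntensityMatrix,
    kinase_substrates: SetCollection,
    annotation: Sequence[PsiteAnnotation] | None = None,
) -> ActivityMatrix:
    """Score kinase activity from three evidence channels.

    Channels per cell line: z of kinase protein abundance; mean z of
    p-sites on the kinase itself; mean z of the kinase's substrate
    p-sites (sites annotated inhibitory contribute with negated z). The
    combined raw score is the unweighted mean of the channels available
    for that kinase. Kinases with no channel are dropped with a warning.
    """
    zp = zscore_features(protein)
    zs = zscore_features(psite)
    host_sites = _sites_by_host(psite.features, annotation)
    reg_class = {a.psite_id: a.regulatory_class for a in (annotation or [])}

    raw_rows = {}
    provenance = {}
    for kinase, substrates in kinase_substrates.items():
        channels: dict[str, pd.Series] = {}
        if kinase in zp.index:
            channels["abundance"] = zp.loc[kinase]
        own = host_sites.get(kinase, [])
        if own:
            channels["own-psites"] = zs.loc[own].mean(axis=0, skipna=True)
        subs = [s for s in substrates if s in zs.index]
        if subs:
            signs = pd.Series(
                [-1.0 if reg_class.get(s) == "inhibitory" else 1.0 for s in subs],
                index=subs,
            )
            channels["substrates"] = zs.loc[subs].mul(signs, axis=0).mean(
                axis=0, skipna=True
            )
        if not channels:
            logger.warning("kinase %s dropped: no evidence channel available", kinase)
            continue
        combined = pd.concat(channels.values(), axis=1).mean(axis=1, skipna=True)
        raw_rows[kinase] = combined
        provenance[kinase] = {
            "channels": sorted(channels),
            "own_psites": own,
            "substrates": subs,
        }
    if not raw_rows:
        raise DataError("no kinase had any evidence channel")
    raw = pd.DataFrame(raw_rows).T
    raw.index.name = "entity"
    rel, flat = _relative_from_raw(raw)
    return ActivityMatrix(raw=raw, relative=rel, provenance=provenance, flat=flat)


def waterfall(activity: ActivityMatrix, cell_line: str) -> pd.DataFrame:
    """Entities of one cell line ordered by descending relative activity.

    Ties are broken lexicographically by entity id. FLAT entities are
    excluded.
    """
    if cell_line not in activity.relative.columns:
        raise DataError(f"unknown cell line {cell_line!r}")
    col = activity.relative[cell_line].drop(labels=list(activity.flat), errors="ignore")
    col = col.dropna()
    frame = pd.DataFrame({"entity": col.index, "relative": col.to_numpy()})
    frame = frame.sort_values(
        ["relative", "entity"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame


def build_landscape(
    activity: ActivityMatrix,
    grid: int = 50,
    bandwidth: float | None = None,
    seed: int = 0,
) -> Landscape:
    """Embed cell lines in 2D (PCA of relative scores) and smooth per-entity
    height fields over a grid with a Nadaraya-Watson Gaussian kernel.

    The embedding sign convention makes the largest-magnitude loading of
    each component positive, so layouts are reproducible.
    """
    rel = activity.relative.drop(index=list(activity.flat), errors="ignore")
    rel = rel.fillna(0.5)
    n_cells = rel.shape[1]
    if n_cells < 3:
        raise DataError("landscape needs >= 3 cell lines")

    X = rel.T.to_numpy(dtype=float)           # cells x entities
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(2, s.size)
    coords = u[:, :k] * s[:k]
    if k < 2:
        coords = np.column_stack([coords, np.zeros(n_cells)])
        vt = np.vstack([vt, np.zeros(vt.shape[1])])
    for j in range(2):
        loadings = vt[j]
        top = np.argmax(np.abs(loadings))
        if loadings[top] < 0:
            coords[:, j] *= -1.0
    coordinates = pd.DataFrame(coords[:, :2], index=rel.columns, columns=["x", "y"])

    span = max(
        float(coords[:, 0].max() - coords[:, 0].min()),
        float(coords[:, 1].max() - coords[:, 1].min()),
        1e-9,
    )
    if bandwidth is None:
        bandwidth = 0.2 * span
    pad = 0.1 * span
    grid_x = np.linspace(coords[:, 0].min() - pad, coords[:, 0].max() + pad, grid)
    grid_y = np.linspace(coords[:, 1].min() - pad, coords[:, 1].max() + pad, grid)
    gx, gy = np.meshgrid(grid_x, grid_y)
    d2 = (
        (gx[..., None] - coords[:, 0]) ** 2 + (gy[..., None] - coords[:, 1]) ** 2
    )
    w = np.exp(-0.5 * d2 / bandwidth**2)
    w_sum = w.sum(axis=-1)
    heights = {}
    for entity in rel.index:
        vals = rel.loc[entity].to_numpy(dtype=float)
        h = (w * vals).sum(axis=-1) / np.where(w_sum == 0, np.nan, w_sum)
        heights[entity] = np.clip(np.nan_to_num(h, nan=0.0), 0.0, 1.0)
    return Landscape(
        coordinates=coordinates,
        grid_x=grid_x,
        grid_y=grid_y,
        heights=heights,
        bandwidth=float(bandwidth),
        seed=seed,
    )
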