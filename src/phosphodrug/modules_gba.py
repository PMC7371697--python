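"""Correlation-network module detection and guilt-by-association transfer.

Features (proteins and p-sites concatenated) are clustered by the
topological overlap of their soft-thresholded correlation network;
modules, functional sets and a binary phenotype are then linked into a
three-axis association structure, from which unannotated features
inherit candidate annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import REJECTED, pairwise_complete_filter
from .datatypes import DataError, IntensityMatrix, SetCollection
from . import stats

logger = logging.getLogger(__name__)

DEFAULT_BETA = 6.0
DEFAULT_MIN_SIZE = 10
DEFAULT_CUT_FRACTION = 0.5


@dataclass
class ModulePartition:
    """Feature -> module assignment (label 0 = unassigned) plus eigenfeatures."""

    labels: pd.Series                      # feature -> int
    beta: float
    min_size: int
    eigenfeatures: dict[int, pd.Series] = field(default_factory=dict)
    tom: pd.DataFrame | None = None

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class HiveEdge:
    kind: str                              # set-module | module-phenotype | set-phenotype
    a: str
    b: str
    q: float
    direction: str | None                  # up-in-positive | up-in-negative | None


@dataclass
class HiveAssociation:
    axis_sets: list[str]
    axis_modules: list[int]
    axis_phenotype: list[str]
    edges: list[HiveEdge]
    member_tests: pd.DataFrame             # per-feature moderated-t results
    q_threshold: float

    def edges_of_kind(self, kind: str) -> list[HiveEdge]:
        return [e for e in self.edges if e.kind == kind]


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    The adjacency diagonal is ignored; TOM_ii is set to 1.
    """
    a = np.array(adjacency, dtype=float)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    matrix: IntensityMatrix | pd.DataFrame,
    beta: float = DEFAULT_BETA,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_fraction: float = DEFAULT_CUT_FRACTION,
    min_observed_frac: float = 0.5,
    min_pairs: int = 3,
) -> ModulePartition:
    """Detect co-abundance modules via unsigned WGCNA-style clustering.

    Adjacency is |cor|^beta over pairwise-complete entries; features are
    clustered by average linkage on 1 - TOM and the tree is cut at the
    fixed height d_min + cut_fraction * (d_max - d_min) interpolated
    between the extremes of the pairwise dissimilarities (a plain
    quantile cut lands inside the background-noise mass and glues
    uncorrelated features into one giant module). Clusters of at least
    ``min_size`` features become modules (labels 1.. by decreasing
    size); everything else is label 0.
    """
    values = matrix.values if isinstance(matrix, IntensityMatrix) else matrix
    if values.shape[1] < 8:
        raise DataError("detect_modules needs >= 8 cell lines")
    if beta < 1:
        raise DataError(f"soft power beta must be >= 1, got {beta}")
    all_missing = list(values.index[values.isna().all(axis=1)])
    if all_missing:
        raise DataError(f"features with no observed values: {all_missing}")
    frac = values.notna().mean(axis=1)
    dropped = list(values.index[frac < min_observed_frac])
    if dropped:
        logger.warning(
            "dropping %d features with < %.0f%% observed values",
            len(dropped), 100 * min_observed_frac,
        )
    kept = values.loc[frac >= min_observed_frac]
    if kept.shape[0] < 2:
        raise DataError("fewer than 2 features left after missingness filter")

    corr = kept.T.corr(min_periods=min_pairs).to_numpy(dtype=float)
    corr = np.nan_to_num(corr, nan=0.0)
    adjacency = np.abs(corr) ** beta
    tom = topological_overlap(adjacency)
    dissim = 1.0 - tom
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    cut_height = float(condensed.min() + cut_fraction * (condensed.max() - condensed.min()))
    raw_labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    sizes = pd.Series(raw_labels).value_counts()
    big = [lab for lab in sizes.index if sizes[lab] >= min_size]
    big.sort(key=lambda lab: (-sizes[lab], lab))
    relabel = {lab: i + 1 for i, lab in enumerate(big)}
    labels = pd.Series(
        [relabel.get(lab, 0) for lab in raw_labels], index=kept.index, dtype=int
    )
    full_labels = labels.reindex(values.index, fill_value=0).astype(int)

    partition = ModulePartition(
        labels=full_labels,
        beta=beta,
        min_size=min_size,
        tom=pd.DataFrame(tom, index=kept.index, columns=kept.index),
    )
    for mod in partition.module_ids:
        member_vals = values.loc[partition.members(mod)]
        partition.eigenfeatures[mod] = module_eigenfeature(member_vals)
    return partition


def module_eigenfeature(member_values: pd.DataFrame) -> pd.Series:
    """First principal component of standardized member profiles.

    Unit norm over cell lines, sign oriented to correlate positively
    with the module's mean standardized profile. Missing entries enter
    as 0 after standardization.
    """
    mu = member_values.mean(axis=1, skipna=True)
    sd = member_values.std(axis=1, ddof=0, skipna=True).replace(0.0, np.nan)
    z = member_values.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    u, s, vt = np.linalg.svd(z.to_numpy(dtype=float), full_matrices=False)
    eig = pd.Series(vt[0], index=member_values.columns)
    eig /= np.linalg.norm(eig) or 1.0
    mean_profile = z.mean(axis=0)
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    return eig


def _member_direction_edge(
    member_tests: pd.DataFrame,
    members: Sequence[str],
    q_threshold: float,
    member_frac: float,
) -> tuple[float, str] | None:
    """Edge decision for a feature group vs the phenotype.

    Significant when at least ``member_frac`` of the group's testable
    members pass q < q_threshold with a common effect sign. Returns
    (median q of those members, direction) or None.
    """
    sub = member_tests.loc[[m for m in members if m in member_tests.index]]
    sub = sub[sub["q"].notna()]
    if len(sub) == 0:
        return None
    sig = sub[sub["q"] < q_threshold]
    up = sig[sig["effect"] > 0]
    down = sig[sig["effect"] < 0]
    best = up if len(up) >= len(down) else down
    if len(best) / len(sub) < member_frac:
        return None
    direction = "up-in-positive" if best is up else "up-in-negative"
    return float(best["q"].median()), direction


def associate_axes(
    partition: ModulePartition,
    sets: SetCollection,
    phenotype: pd.Series,
    feature_matrix: IntensityMatrix | pd.DataFrame,
    q_threshold: float = 0.05,
    member_frac: float = 0.5,
    level: Literal["member", "eigenfeature"] = "member",
) -> HiveAssociation:
    """Assemble the three-axis association structure.

    set<->module edges come from hypergeometric enrichment over the
    analyzed feature universe (BH-adjusted); module<->phenotype and
    set<->phenotype edges from moderated t-tests on member features
    (or the module eigenfeature when level="eigenfeature").
    """
    values = (
        feature_matrix.values
        if isinstance(feature_matrix, IntensityMatrix)
        else feature_matrix
    )
    phenotype = phenotype.reindex(values.columns)
    class_sizes = phenotype.value_counts()
    if set(class_sizes.index) != {0, 1} or (class_sizes < 3).any():
        raise DataError("phenotype needs both classes with >= 3 cell lines each")

    universe = list(partition.labels.index)
    uni_set = set(universe)
    member_tests = stats.moderated_t_matrix(values.loc[universe], phenotype)

    edges: list[HiveEdge] = []

    # axis 1 <-> axis 2: set enrichment in modules
    tests: list[tuple[str, int, stats.TestResult]] = []
    for name in sets.names:
        members = sets.members(name) & uni_set
        for mod in partition.module_ids:
            mod_members = set(partition.members(mod))
            res = stats.hypergeom_enrich(
                overlap=len(members & mod_members),
                set_size=len(members),
                group_size=len(mod_members),
                universe=len(universe),
            )
            tests.append((name, mod, res))
    if tests:
        qs = stats.bh_adjust([r.p for _, _, r in tests])
        for (name, mod, res), q in zip(tests, qs):
            res.q = float(q)

    module_pheno_dir: dict[int, str] = {}
    for mod in partition.module_ids:
        if level == "eigenfeature":
            eig = partition.eigenfeatures[mod]
            res = stats.moderated_t(eig[phenotype == 1], eig[phenotype == 0])
            hit = (res.p, "up-in-positive" if res.effect > 0 else "up-in-negative") \
                if res.p < q_threshold else None
        else:
            hit = _member_direction_edge(
                member_tests, partition.members(mod), q_threshold, member_frac
            )
        if hit is not None:
            q, direction = hit
            edges.append(HiveEdge("module-phenotype", str(mod), "phenotype", q, direction))
            module_pheno_dir[mod] = direction

    for name in sets.names:
        hit = _member_direction_edge(
            member_tests, sorted(sets.members(name) & uni_set), q_threshold, member_frac
        )
        if hit is not None:
            q, direction = hit
            edges.append(HiveEdge("set-phenotype", name, "phenotype", q, direction))

    for (name, mod, res) in [t for t in tests]:
        if not np.isnan(res.q) and res.q < q_threshold and res.statistic > 0:
            edges.append(
                HiveEdge("set-module", name, str(mod), res.q, module_pheno_dir.get(mod))
            )

    return HiveAssociation(
        axis_sets=sets.names,
        axis_modules=partition.module_ids,
        axis_phenotype=["positive", "negative"],
        edges=edges,
        member_tests=member_tests,
        q_threshold=q_threshold,
    )


def guilt_by_association(
    assoc: HiveAssociation,
    sets: SetCollection,
    partition: ModulePartition,
) -> pd.DataFrame:
    """Candidate functional annotations from significant set<->module edges.

    For every significant (set, module) edge whose module is itself
    phenotype-associated, emit the module members that are individually
    significant in the same phenotype direction and are NOT already
    members of the set. Returns columns (feature, set, module, evidence_q).
    """
    rows = []
    module_dirs = {
        int(e.a): e.direction for e in assoc.edges_of_kind("module-phenotype")
    }
    for edge in assoc.edges_of_kind("set-module"):
        mod = int(edge.b)
        direction = module_dirs.get(mod)
        if direction is None:
            continue
        want_sign = 1 if direction == "up-in-positive" else -1
        set_members = sets.members(edge.a)
        for feat in partition.members(mod):
            if feat in set_members or feat not in assoc.member_tests.index:
                continue
            row = assoc.member_tests.loc[feat]
            if (
                pd.notna(row["q"])
                and row["q"] < assoc.q_threshold
                and np.sign(row["effect"]) == want_sign
            ):
                rows.append(
                    {"feature": feat, "set": edge.a, "module": mod,
                     "evidence_q": float(row["q"]), "direction": direction}
                )
    return pd.DataFrame(rows, columns=["feature", "set", "module", "evidence_q", "direction"])


@dataclass
class RecapitulationResult:
    recapitulated: dict[str, set[tuple[str, str]]]
    testable: dict[str, set[tuple[str, str]]]
    overlap_fraction: float
    enrichment: dict[str, pd.DataFrame]


def recapitulation_overlap(
    protein: IntensityMatrix,
    phosphoprotein: IntensityMatrix,
    pairs: Iterable[tuple[str, str]],
    pathways: SetCollection | None = None,
    min_n: int = 7,
    q_threshold: float = 0.05,
) -> RecapitulationResult:
    """Which annotated protein pairs are recapitulated at each level.

    A pair is recapitulated at a level when the Pearson correlation over
    pairwise-complete entries (at least ``min_n``) is positive with BH
    q < ``q_threshold`` within that level. The overlap fraction is the
    share of phosphoprotein-recapitulated pairs that are also
    protein-recapitulated. When ``pathways`` is given, each pathway is
    tested for enrichment among recapitulated pairs per level (a pair
    belongs to a pathway when both partners do).
    """
    pairs = [tuple(p) for p in pairs]
    levels = {"protein": protein, "phosphoprotein": phosphoprotein}
    recapitulated: dict[str, set] = {}
    testable: dict[str, set] = {}
    any_testable = False
    for level, matrix in levels.items():
        values = matrix.values
        tested: list[tuple[tuple[str, str], stats.TestResult]] = []
        for a, b in pairs:
            if a not in values.index or b not in values.index:
                continue
            idx = pairwise_complete_filter(values.loc[a], values.loc[b], min_n=min_n)
            if idx is REJECTED or isinstance(idx, str):
                continue
            res = stats.pearson_test(
                values.loc[a].to_numpy()[idx], values.loc[b].to_numpy()[idx]
            )
            if not res.undefined:
                tested.append(((a, b), res))
        testable[level] = {p for p, _ in tested}
        if tested:
            any_testable = True
            qs = stats.bh_adjust([r.p for _, r in tested])
            recapitulated[level] = {
                p for (p, r), q in zip(tested, qs) if r.effect > 0 and q < q_threshold
            }
        else:
            recapitulated[level] = set()
    if not any_testable:
        raise DataError("no testable pairs at either level")

    phospho = recapitulated["phosphoprotein"]
    overlap = phospho & recapitulated["protein"]
    fraction = len(overlap) / len(phospho) if phospho else float("nan")

    enrichment: dict[str, pd.DataFrame] = {}
    if pathways is not None:
        for level in levels:
            uni = testable[level]
            recap = recapitulated[level]
            rows = []
            for name in pathways.names:
                members = pathways.members(name)
                in_path = {p for p in uni if p[0] in members and p[1] in members}
                res = stats.hypergeom_enrich(
                    overlap=len(in_path & recap),
                    set_size=len(in_path),
                    group_size=len(recap),
                    universe=len(uni),
                )
                rows.append(
                    {"pathway": name, "overlap": int(res.statistic),
                     "set_size": len(in_path), "p": res.p}
                )
            frame = pd.DataFrame(rows)
            if len(frame):
                frame["q"] = stats.bh_adjust(frame["p"].to_numpy())
            enrichment[level] = frame
    return RecapitulationResult(
        recapitulated=recapitulated,
        testable=testable,
        overlap_fraction=fraction,
        enrichment=enrichment,
    )
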