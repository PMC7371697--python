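"""Single-cell-line outlier detection and incidence clustering.

A feature is called an outlier in a cell line when its abundance there
exceeds the leave-one-out median of the other observed cell lines by at
least log10(threshold_fold). Features observed in exactly one cell line
above a noise floor are reported as detection-only events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datatypes import DataError, IntensityMatrix

DEFAULT_THRESHOLD_FOLD = 5.0
DEFAULT_MIN_OBSERVED = 10


@dataclass(frozen=True)
class OutlierCall:
    feature: str
    cell_line: str
    excess: float            # log10 units above the leave-one-out median
    detection_only: bool
    n_observed: int


def call_outliers(
    matrix: IntensityMatrix,
    threshold_fold: float = DEFAULT_THRESHOLD_FOLD,
    min_observed: int = DEFAULT_MIN_OBSERVED,
) -> list[OutlierCall]:
    """Call single-cell-line high-abundance outliers.

    Threshold calls require at least ``min_observed`` observed cell lines
    for the feature; detection-only calls require observation in exactly
    one cell line with a value above the matrix-wide 25th intensity
    percentile.
    """
    if threshold_fold <= 1.0:
        raise DataError(f"threshold_fold must be > 1, got {threshold_fold}")
    log_threshold = np.log10(threshold_fold)
    values = matrix.values
    floor = float(np.nanpercentile(values.to_numpy(dtype=float), 25))

    calls: list[OutlierCall] = []
    arr = values.to_numpy(dtype=float)
    features = values.index.to_numpy()
    cell_lines = values.columns.to_numpy()
    for i in range(arr.shape[0]):
        row = arr[i]
        obs = np.flatnonzero(~np.isnan(row))
        if obs.size == 1:
            j = obs[0]
            if row[j] > floor:
                calls.append(
                    OutlierCall(str(features[i]), str(cell_lines[j]),
                                excess=float("nan"), detection_only=True, n_observed=1)
                )
            continue
        if obs.size < min_observed:
            continue
        vals = row[obs]
        order = np.argsort(vals)
        top = obs[order[-1]]
        # leave-one-out median only matters for the top candidate; values
        # below the overall median cannot exceed it by a positive margin
        others = np.delete(vals, order[-1])
        excess = float(row[top] - np.median(others))
        if excess >= log_threshold:
            calls.append(
                OutlierCall(str(features[i]), str(cell_lines[top]),
                            excess=excess, detection_only=False,
                            n_observed=int(obs.size))
            )
            # secondary outliers in the same feature (rare): check the rest
            for j in obs[order[:-1]][::-1]:
                rest = vals[obs != j]
                exc = float(row[j] - np.median(rest))
                if exc >= log_threshold:
                    calls.append(
                        OutlierCall(str(features[i]), str(cell_lines[j]),
                                    excess=exc, detection_only=False,
                                    n_observed=int(obs.size))
                    )
    return calls


def calls_to_frame(calls: list[OutlierCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [c.feature for c in calls],
            "cell_line": [c.cell_line for c in calls],
            "excess_log10": [c.excess for c in calls],
            "detection_only": [c.detection_only for c in calls],
            "n_observed": [c.n_observed for c in calls],
        }
    )


@dataclass
class OutlierClustering:
    feature_order: list[str]
    cell_line_order: list[str]
    incidence: pd.DataFrame
    feature_labels: pd.Series            # cluster label per feature
    co_outlier_groups: list[list[str]]   # same cluster AND >= 1 shared cell line


def cluster_outlier_matrix(
    calls: list[OutlierCall],
    cut_height: float = 0.5,
) -> OutlierClustering:
    """Cluster the binary outlier incidence matrix on Jaccard distance.

    Both axes are ordered by average-linkage dendrograms. Feature groups
    in the same cluster sharing at least one outlier cell line are
    reported as candidate co-regulated sets.
    """
    frame = calls_to_frame(calls)
    features = sorted(frame["feature"].unique())
    if len(features) < 2:
        raise DataError("cluster_outlier_matrix needs >= 2 called features")
    cells = sorted(frame["cell_line"].unique())
    incidence = pd.DataFrame(0, index=features, columns=cells, dtype=int)
    for _, row in frame.iterrows():
        incidence.loc[row["feature"], row["cell_line"]] = 1

    fdist = pdist(incidence.to_numpy(dtype=bool), metric="jaccard")
    flink = hierarchy.linkage(fdist, method="average")
    feature_order = [features[i] for i in hierarchy.leaves_list(flink)]
    if len(cells) >= 2:
        cdist = pdist(incidence.T.to_numpy(dtype=bool), metric="jaccard")
        clink = hierarchy.linkage(cdist, method="average")
        cell_order = [cells[i] for i in hierarchy.leaves_list(clink)]
    else:
        cell_order = cells

    labels = pd.Series(
        hierarchy.fcluster(flink, t=cut_height, criterion="distance"),
        index=features,
    )
    groups: list[list[str]] = []
    for lab in sorted(labels.unique()):
        members = list(labels.index[labels == lab])
        if len(members) < 2:
            continue
        sub = incidence.loc[members]
        if (sub.sum(axis=0) >= 2).any():
            groups.append(members)
    return OutlierClustering(
        feature_order=feature_order,
        cell_line_order=cell_order,
        incidence=incidence,
        feature_labels=labels,
        co_outlier_groups=groups,
    )
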