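"""Readers/writers for the standard text formats plus the small numeric
conventions the rest of the pipeline relies on: phosphopeptide->phosphoprotein
aggregation, median centering, pairwise-complete filtering and linear
fold-change reporting.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DataError,
    DrugResponseMatrix,
    FeatureKind,
    IntensityMatrix,
    PsiteAnnotation,
    SetCollection,
    parse_psite_id,
)

#: Sentinel returned by pairwise_complete_filter when too few complete pairs.
REJECTED = "REJECTED"

DEFAULT_MIN_N = 7


# ---------------------------------------------------------------------------
# Readers / writers (TSV with "NA" for missing, standard GMT)
# ---------------------------------------------------------------------------

def read_intensity_tsv(path: str | Path, kind: FeatureKind) -> IntensityMatrix:
    """Read a features x cell-lines TSV (first column = feature id, NA = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=True)
    return IntensityMatrix(df, kind)


def write_intensity_tsv(matrix: IntensityMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="feature")


def read_drug_tsv(path: str | Path, higher_is_sensitive: bool) -> DrugResponseMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=True)
    return DrugResponseMatrix(df, higher_is_sensitive)


def write_drug_tsv(drugs: DrugResponseMatrix, path: str | Path) -> None:
    drugs.values.to_csv(path, sep="\t", na_rep="NA", index_label="drug")


def read_gmt(path: str | Path) -> SetCollection:
    """Read a GMT file: name TAB description TAB member TAB member ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name = parts[0]
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [p for p in parts[2:] if p]
            descriptions[name] = parts[1]
    return SetCollection(sets, descriptions=descriptions)


def write_gmt(collection: SetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            desc = collection.description(name) or "na"
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_psite_annotation(path: str | Path) -> list[PsiteAnnotation]:
    """Read an annotation TSV with columns: site, protein, residue, position, class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"site", "protein", "residue", "position", "class"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"annotation file lacks columns: {sorted(missing)}")
    return [
        PsiteAnnotation(
            psite_id=row["site"],
            protein_id=row["protein"],
            residue=row["residue"],
            position=int(row["position"]),
            regulatory_class=row["class"],
        )
        for _, row in df.iterrows()
    ]


def write_psite_annotation(annotation: Sequence[PsiteAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site": [a.psite_id for a in annotation],
            "protein": [a.protein_id for a in annotation],
            "residue": [a.residue for a in annotation],
            "position": [a.position for a in annotation],
            "class": [a.regulatory_class for a in annotation],
        }
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path: str | Path) -> pd.Series:
    """Read a two-column TSV (cell_line, label) into a 0/1 Series."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    ser = pd.Series(df.iloc[:, 1].astype(int).to_numpy(), index=df.iloc[:, 0].astype(str))
    ser.name = df.columns[1]
    return ser


def write_phenotype_tsv(phenotype: pd.Series, path: str | Path) -> None:
    pd.DataFrame(
        {"cell_line": phenotype.index, phenotype.name or "phenotype": phenotype.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Numeric conventions
# ---------------------------------------------------------------------------

def aggregate_phosphoprotein(
    psite_matrix: IntensityMatrix,
    annotation: Sequence[PsiteAnnotation],
    infer_unannotated: bool = True,
) -> IntensityMatrix:
    """Sum p-site intensities (on linear scale) per protein group and cell line.

    The result for a (protein group, cell line) pair is
    log10(sum over observed member sites of 10**x); it is missing iff every
    member site is missing in that cell line.

    Parameters
    ----------
    psite_matrix : IntensityMatrix
        Must have kind "p-site".
    annotation : sequence of PsiteAnnotation
        Maps every p-site to exactly one protein group. Sites absent from
        the annotation are parsed from the ``GENE_p<RES><POS>`` id grammar
        when ``infer_unannotated`` is true.

    Raises
    ------
    DataError
        If any p-site cannot be mapped to a protein group; the message
        lists the offenders.
    """
    if psite_matrix.kind != "p-site":
        raise DataError(f"expected a p-site matrix, got kind={psite_matrix.kind!r}")
    mapping = {a.psite_id: a.protein_id for a in annotation}
    unmapped: list[str] = []
    groups: dict[str, str] = {}
    for site in psite_matrix.features:
        protein = mapping.get(site)
        if protein is None and infer_unannotated:
            parsed = parse_psite_id(site)
            if parsed is not None:
                protein = parsed[0]
        if protein is None:
            unmapped.append(site)
        else:
            groups[site] = protein
    if unmapped:
        raise DataError(f"p-sites without a protein group mapping: {unmapped}")

    linear = psite_matrix.to_linear()
    # min_count=1 keeps the "missing iff ALL member sites missing" contract
    summed = linear.groupby(pd.Series(groups)).sum(min_count=1)
    return IntensityMatrix(np.log10(summed), "phosphoprotein")


def fold_change(
    low: float,
    high: float,
    mode: Literal["fold", "ratio"] = "fold",
    rounded: bool = False,
) -> float:
    """Linear fold change between two values.

    mode="fold" treats inputs as log10 intensities and returns
    10**(high - low); mode="ratio" treats inputs as linear values and
    returns high / low. Rounding, when requested, is half-away-from-zero
    to the nearest integer.
    """
    if not (math.isfinite(low) and math.isfinite(high)):
        raise DataError(f"fold_change requires finite inputs, got ({low}, {high})")
    if mode == "fold":
        if high < low:
            raise DataError(f"mode='fold' requires high >= low, got ({low}, {high})")
        fc = 10.0 ** (high - low)
    elif mode == "ratio":
        if low == 0:
            raise DataError("mode='ratio' requires a nonzero denominator")
        fc = high / low
    else:
        raise DataError(f"unknown fold_change mode {mode!r}")
    if rounded:
        return float(math.floor(fc + 0.5)) if fc >= 0 else -float(math.floor(-fc + 0.5))
    return float(fc)


def median_center(matrix: IntensityMatrix) -> IntensityMatrix:
    """Center every cell-line column to median 0 over its observed entries."""
    values = matrix.values
    empty = [c for c in values.columns if values[c].notna().sum() == 0]
    if empty:
        raise DataError(f"cell lines with no observed values: {empty}")
    centered = values - values.median(axis=0, skipna=True)
    return IntensityMatrix(centered, matrix.kind)


def pairwise_complete_filter(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    min_n: int = DEFAULT_MIN_N,
):
    """Indices observed in both series, or REJECTED if fewer than min_n.

    Returns an integer position array into the common axis, or the
    REJECTED sentinel when the number of pairwise-complete observations
    is below ``min_n`` (default 7).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise DataError(f"length mismatch: {xv.shape} vs {yv.shape}")
    idx = np.flatnonzero(~np.isnan(xv) & ~np.isnan(yv))
    if idx.size < min_n:
        return REJECTED
    return idx
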