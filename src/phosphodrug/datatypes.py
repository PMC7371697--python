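"""Shared container types used across the pipeline.

All intensity values are stored on log10 scale; missing entries are NaN
(never 0 — zero on the log scale is a real, finite intensity).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

FeatureKind = Literal["protein", "p-site", "phosphoprotein"]

#: p-site identifier grammar: <PROTEIN>_p<RES><POS>, e.g. MAPK1_pY187
PSITE_ID_RE = re.compile(r"^(?P<protein>.+)_p(?P<residue>[STY])(?P<position>\d+)$")


class PhosphodrugError(Exception):
    """Base class for all package errors."""


class ConfigError(PhosphodrugError):
    """Invalid configuration; the message names the offending field."""


class DataError(PhosphodrugError):
    """Malformed or inconsistent input data."""


def _check_unique(ids: Iterable[str], axis_name: str) -> None:
    ids = list(ids)
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise DataError(f"duplicate {axis_name} ids: {sorted(map(str, dups))}")


class IntensityMatrix:
    """Features x cell lines matrix of log10 intensities.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features, columns are cell lines. Missing entries are NaN.
    kind : {"protein", "p-site", "phosphoprotein"}
        What the features are. Fixed after construction.
    """

    def __init__(self, values: pd.DataFrame, kind: FeatureKind) -> None:
        if kind not in ("protein", "p-site", "phosphoprotein"):
            raise DataError(f"unknown feature kind: {kind!r}")
        _check_unique(values.index, "feature")
        _check_unique(values.columns, "cell line")
        arr = values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise DataError("non-finite (infinite) intensity values present")
        self._values = values.astype(float)
        self._kind: FeatureKind = kind

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def kind(self) -> FeatureKind:
        return self._kind

    @property
    def features(self) -> list[str]:
        return list(self._values.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self._values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._values.shape

    def observed_mask(self) -> pd.DataFrame:
        return self._values.notna()

    def subset_features(self, features: Iterable[str]) -> "IntensityMatrix":
        return IntensityMatrix(self._values.loc[list(features)], self._kind)

    def subset_cell_lines(self, cell_lines: Iterable[str]) -> "IntensityMatrix":
        return IntensityMatrix(self._values[list(cell_lines)], self._kind)

    def to_linear(self) -> pd.DataFrame:
        """Return linear-scale intensities (10**x); NaN stays NaN."""
        return 10.0 ** self._values

    def __repr__(self) -> str:  # pragma: no cover
        nf, nc = self.shape
        return f"IntensityMatrix(kind={self._kind!r}, {nf} features x {nc} cell lines)"


class SetCollection:
    """Named feature sets (pathways, kinase->substrate maps) with a universe.

    The universe defaults to the union of all member sets; enrichment tests
    may override it with the analyzed feature universe.
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
        universe: Iterable[str] | None = None,
    ) -> None:
        self._sets: dict[str, frozenset[str]] = {
            str(name): frozenset(map(str, members)) for name, members in sets.items()
        }
        self._descriptions = {str(k): str(v) for k, v in (descriptions or {}).items()}
        if universe is None:
            uni: set[str] = set()
            for members in self._sets.values():
                uni |= members
            self._universe = frozenset(uni)
        else:
            self._universe = frozenset(map(str, universe))

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    @property
    def universe(self) -> frozenset[str]:
        return self._universe

    def members(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def description(self, name: str) -> str:
        return self._descriptions.get(name, "")

    def items(self):
        return self._sets.items()

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def restrict(self, features: Iterable[str]) -> "SetCollection":
        """Intersect every set (and the universe) with `features`."""
        feats = frozenset(features)
        return SetCollection(
            {n: m & feats for n, m in self._sets.items()},
            descriptions=self._descriptions,
            universe=self._universe & feats,
        )


class DrugResponseMatrix:
    """Drugs x cell lines sensitivity values with a declared orientation.

    The internal canonical form has higher = more sensitive; GI50-like
    inputs (lower = more sensitive) are negated on ingest by
    :meth:`canonical`.
    """

    def __init__(self, values: pd.DataFrame, higher_is_sensitive: bool) -> None:
        _check_unique(values.index, "drug")
        _check_unique(values.columns, "cell line")
        self._values = values.astype(float)
        self.higher_is_sensitive = bool(higher_is_sensitive)

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def drugs(self) -> list[str]:
        return list(self._values.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self._values.columns)

    def canonical(self) -> "DrugResponseMatrix":
        """Return a copy in canonical orientation (higher = more sensitive)."""
        if self.higher_is_sensitive:
            return DrugResponseMatrix(self._values.copy(), True)
        return DrugResponseMatrix(-self._values, True)

    def __repr__(self) -> str:  # pragma: no cover
        nd, nc = self._values.shape
        orient = "higher=sensitive" if self.higher_is_sensitive else "lower=sensitive"
        return f"DrugResponseMatrix({nd} drugs x {nc} cell lines, {orient})"


@dataclass(frozen=True)
class PsiteAnnotation:
    """Annotation of a single phosphorylation site.

    regulatory_class is "activating", "inhibitory" or "unknown".
    """

    psite_id: str
    protein_id: str
    residue: str
    position: int
    regulatory_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise DataError(f"{self.psite_id}: residue must be S, T or Y, got {self.residue!r}")
        if self.position < 1:
            raise DataError(f"{self.psite_id}: position must be >= 1, got {self.position}")
        if self.regulatory_class not in ("activating", "inhibitory", "unknown"):
            raise DataError(
                f"{self.psite_id}: bad regulatory class {self.regulatory_class!r}"
            )


def parse_psite_id(psite_id: str) -> tuple[str, str, int] | None:
    """Parse ``<PROTEIN>_p<RES><POS>`` into (protein, residue, position).

    Returns None when the id does not follow the grammar.
    """
    m = PSITE_ID_RE.match(psite_id)
    if m is None:
        return None
    return m.group("protein"), m.group("residue"), int(m.group("position"))
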