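"""Partition breeding values into per-path contributions.

Writing breeding values as a = Tw (T the gene-flow matrix, w the Mendelian
sampling terms) and splitting individuals into p analyst-defined paths with
0/1 diagonal selectors P_j summing to I, the contribution of path j is
a_j = T P_j w, and Σ_j a_j = a exactly.  A contribution is attributed to
the path of the individual whose Mendelian term it carries, so each path's
stream collects the segregation deviations expressed by that group and
disseminated to descendants.

The dense products are never formed: a single pass over the ordered
pedigree applies the recursion
a_{k,·} = ½ a_{sire(k),·} + ½ a_{dam(k),·} + e_{path(k)} w_k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .pedigree import Pedigree


@dataclass
class PathAssignment:
    """One path label per individual, with a fixed level order."""

    labels: np.ndarray
    levels: list

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.levels = list(self.levels)
        unknown = set(self.labels) - set(self.levels)
        if unknown:
            raise ValueError(f"labels outside declared levels: {sorted(map(str, unknown))}")
        self.codes = np.fromiter(
            (self.levels.index(l) for l in self.labels),
            dtype=np.int64,
            count=len(self.labels),
        )

    @classmethod
    def from_labels(cls, labels: Sequence) -> "PathAssignment":
        labels = np.asarray(labels, dtype=object)
        levels = sorted(set(labels), key=str)
        return cls(labels, levels)

    @property
    def n_paths(self) -> int:
        return len(self.levels)


@dataclass
class PartitionedBV:
    """Per-path contributions for one breeding-value column.

    ``contributions`` has shape (n, p) in pedigree order; row sums
    reproduce the input column.  ``mendelian`` holds the Mendelian
    sampling terms w.
    """

    ped: Pedigree
    paths: PathAssignment
    contributions: np.ndarray
    mendelian: np.ndarray
    column: str = "bv"

    @property
    def total(self) -> np.ndarray:
        return self.contributions.sum(axis=1)

    def to_wide(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": self.ped.ids})
        for j, level in enumerate(self.paths.levels):
            out[f"{self.column}:{level}"] = self.contributions[:, j]
        out[f"{self.column}:w"] = self.mendelian
        return out

    def to_long(self) -> pd.DataFrame:
        n, p = self.contributions.shape
        return pd.DataFrame(
            {
                "id": np.repeat(self.ped.ids, p),
                "column": self.column,
                "path": np.tile(np.asarray(self.paths.levels, dtype=object), n),
                "contribution": self.contributions.ravel(),
                "w": np.repeat(self.mendelian, p),
            }
        )


def compute_mendelian_terms(ped: Pedigree, values: np.ndarray) -> np.ndarray:
    """w_k = a_k − ½ a_sire − ½ a_dam; unknown parents contribute 0.

    ``values`` is (n,) or (n, S) aligned to pedigree order; the result has
    the same shape.  Founders keep their full breeding value as w.
    """
    a = np.asarray(values, dtype=float)
    if a.shape[0] != ped.n:
        raise ValueError(f"values rows ({a.shape[0]}) do not match pedigree ({ped.n})")
    sire_a = np.where((ped.sire >= 0)[..., None] if a.ndim == 2 else ped.sire >= 0,
                      a[np.maximum(ped.sire, 0)], 0.0)
    dam_a = np.where((ped.dam >= 0)[..., None] if a.ndim == 2 else ped.dam >= 0,
                     a[np.maximum(ped.dam, 0)], 0.0)
    return a - 0.5 * sire_a - 0.5 * dam_a


@njit(cache=True)
def _partition_kernel(sire, dam, codes, w, out):
    n, p = out.shape[0], out.shape[1]
    for k in range(n):
        s = sire[k]
        d = dam[k]
        if s >= 0:
            for j in range(p):
                out[k, j] += 0.5 * out[s, j]
        if d >= 0:
            for j in range(p):
                out[k, j] += 0.5 * out[d, j]
        out[k, codes[k]] += w[k]


def partition_breeding_values(
    ped: Pedigree,
    values: np.ndarray,
    paths: PathAssignment,
    column: str = "bv",
) -> PartitionedBV:
    """Decompose one column of breeding values into path contributions.

    Equivalent to the dense products T P_j w but computed by the sparse
    recursion over the ordered pedigree in O(n·p).
    """
    a = np.asarray(values, dtype=float)
    if a.ndim != 1:
        raise ValueError("one column expected; use partition_many for several")
    w = compute_mendelian_terms(ped, a)
    out = np.zeros((ped.n, paths.n_paths))
    _partition_kernel(ped.sire, ped.dam, paths.codes, w, out)
    return PartitionedBV(ped, paths, out, w, column=column)


def partition_many(
    ped: Pedigree,
    values: np.ndarray | pd.DataFrame,
    paths: PathAssignment,
    columns: Sequence[str] | None = None,
) -> Iterator[PartitionedBV]:
    """Partition several value columns (traits or posterior samples).

    Yields one :class:`PartitionedBV` per column in order, holding memory
    for a single column at a time so thousands of posterior samples can be
    streamed through a summary.
    """
    if isinstance(values, pd.DataFrame):
        columns = list(values.columns) if columns is None else list(columns)
        values = values.to_numpy(dtype=float)
    a = np.atleast_2d(np.asarray(values, dtype=float))
    if a.shape[0] == 1 and ped.n != 1:
        a = a.T
    if a.shape[0] != ped.n:
        raise ValueError("value rows do not match pedigree")
    if columns is None:
        columns = [f"bv{i}" for i in range(a.shape[1])]
    if len(columns) != a.shape[1]:
        raise ValueError("column names do not match number of value columns")
    for i, name in enumerate(columns):
        yield partition_breeding_values(ped, a[:, i], paths, column=str(name))
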