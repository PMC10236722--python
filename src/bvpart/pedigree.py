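"""Pedigree parsing, validation, ordering and structural matrices.

A pedigree is the carrier of the gene-flow structure of the infinitesimal
model: every individual's breeding value is half the sire's plus half the
dam's plus an independent Mendelian sampling deviation.  This module builds
the sparse matrices that encode that recursion (T⁻¹), the diagonal Mendelian
sampling variance coefficients (W), inbreeding coefficients (F, by the
Meuwissen–Luo algorithm) and the inverse numerator relationship matrix
(A⁻¹, by Henderson's rank-one updates with inbreeding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

UNKNOWN = -1
#: parent tokens normalised to "unknown" when reading tables
UNKNOWN_TOKENS = {"", "0", "NA", "na", "NaN", "nan", ".", "none", "None"}


class PedigreeError(ValueError):
    """Invalid pedigree input (duplicate ids, cycles, undefined parents)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree with dense integer parent indices.

    Attributes
    ----------
    ids : ndarray of object
        Individual identifiers in processing order (parents before
        offspring).
    sire, dam : ndarray of int64
        Position of each individual's parents in ``ids``; ``-1`` when the
        parent is unknown.
    path : ndarray of object, optional
        Partition variable (one label per individual).
    group : ndarray, optional
        Grouping variable used for summaries (generation, year, ...).
    sex : ndarray of object, optional
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    path: np.ndarray | None = None
    group: np.ndarray | None = None
    sex: np.ndarray | None = None
    index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(self.sire) != n or len(self.dam) != n:
            raise PedigreeError("ids, sire and dam must have equal length")
        order = np.arange(n)
        if np.any(self.sire >= order) or np.any(self.dam >= order):
            raise PedigreeError("pedigree not ordered: parent at or after offspring")
        self.index = {ident: k for k, ident in enumerate(self.ids)}
        if len(self.index) != n:
            raise PedigreeError("duplicate individual identifiers")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def positions(self, idents) -> np.ndarray:
        """Map identifiers to 0-based positions in pedigree order."""
        try:
            return np.fromiter(
                (self.index[i] for i in idents), dtype=np.int64, count=len(idents)
            )
        except KeyError as err:  # pragma: no cover - message path
            raise KeyError(f"identifier {err} not in pedigree") from None

    def to_frame(self) -> pd.DataFrame:
        """Round-trip the pedigree to a DataFrame (unknown parents as 0)."""
        out = pd.DataFrame(
            {
                "id": self.ids,
                "sire": np.where(self.sire >= 0, self.ids[np.maximum(self.sire, 0)], 0),
                "dam": np.where(self.dam >= 0, self.ids[np.maximum(self.dam, 0)], 0),
            }
        )
        for name in ("path", "group", "sex"):
            val = getattr(self, name)
            if val is not None:
                out[name] = val
        return out


def _normalise_id(value) -> str:
    if isinstance(value, float) and value.is_integer():
        value = int(value)
    return str(value).strip()


def _normalise_parent(value) -> object:
    if pd.isna(value):
        return None
    if isinstance(value, float) and value.is_integer():
        value = int(value)
    s = str(value).strip()
    if s in UNKNOWN_TOKENS:
        return None
    return s


def read_pedigree(
    source,
    column_map: dict | None = None,
    sep: str | None = None,
    on_missing_parent: str = "add",
) -> Pedigree:
    """Read a pedigree from a delimited file or DataFrame.

    Parameters
    ----------
    source : path or DataFrame
        Table with at least id/sire/dam columns.  CSV/TSV autodetected from
        the extension when ``sep`` is not given.
    column_map : dict, optional
        Maps the roles ``id, sire, dam, path, group, sex`` to column names
        in the table.  Roles absent from the map default to their own name
        when that column exists.
    on_missing_parent : {"add", "fail"}
        Parents referenced but never defined as individuals are either
        auto-added as founders or rejected.

    Returns
    -------
    Pedigree
        Validated and topologically ordered (a stable re-sort is applied
        when offspring precede their parents in the file).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        if sep is None:
            sep = "\t" if str(source).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(source, sep=sep)

    column_map = dict(column_map or {})
    roles = {}
    for role in ("id", "sire", "dam", "path", "group", "sex"):
        col = column_map.get(role, role)
        if col in df.columns:
            roles[role] = col
        elif role in ("id", "sire", "dam"):
            raise PedigreeError(f"required column for role '{role}' not found: {col}")

    ids = [_normalise_id(v) for v in df[roles["id"]]]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)
        dup = dup[dup.duplicated()].iloc[0]
        raise PedigreeError(f"duplicate id: {dup!r}")
    sires = [_normalise_parent(v) for v in df[roles["sire"]]]
    dams = [_normalise_parent(v) for v in df[roles["dam"]]]

    known = set(ids)
    referenced = {p for p in sires + dams if p is not None}
    missing = sorted(referenced - known)
    extra: dict[str, None] = {}
    if missing:
        if on_missing_parent == "fail":
            raise PedigreeError(f"parents never defined as individuals: {missing}")
        extra = {m: None for m in missing}

    for ident, s, d in zip(ids, sires, dams):
        if ident == s or ident == d:
            raise PedigreeError(f"individual {ident!r} is its own parent")

    all_ids = list(extra) + ids
    parent_of = dict(zip(ids, zip(sires, dams)))
    order = _topological_order(all_ids, parent_of)

    pos = {ident: k for k, ident in enumerate(order)}
    n = len(order)
    sire_idx = np.full(n, UNKNOWN, dtype=np.int64)
    dam_idx = np.full(n, UNKNOWN, dtype=np.int64)
    for ident in ids:
        s, d = parent_of[ident]
        k = pos[ident]
        if s is not None:
            sire_idx[k] = pos[s]
        if d is not None:
            dam_idx[k] = pos[d]

    def _optional(role):
        if role not in roles:
            return None
        series = df[roles[role]]
        vals = np.empty(n, dtype=object)
        vals[:] = None
        for ident, v in zip(ids, series):
            vals[pos[ident]] = v
        return vals

    return Pedigree(
        ids=np.asarray(order, dtype=object),
        sire=sire_idx,
        dam=dam_idx,
        path=_optional("path"),
        group=_optional("group"),
        sex=_optional("sex"),
    )


def _topological_order(ids, parent_of) -> list:
    """Stable Kahn ordering: parents before offspring, input order preserved
    among individuals whose parents are already placed."""
    remaining = dict.fromkeys(ids)
    placed: set = set()
    order: list = []
    while remaining:
        progressed = False
        still = []
        for ident in remaining:
            s, d = parent_of.get(ident, (None, None))
            if (s is None or s in placed) and (d is None or d in placed):
                order.append(ident)
                placed.add(ident)
                progressed = True
            else:
                still.append(ident)
        if not progressed:
            raise PedigreeError(
                f"pedigree contains a cycle involving: {sorted(still)[:5]}"
            )
        remaining = dict.fromkeys(still)
    return order


@njit(cache=True)
def _inbreeding_kernel(sire, dam, F, start):
    """Meuwissen–Luo: F[k] = a_kk − 1 = Σ_j L_j² D_j over ancestors j.

    F[:start] is taken as already computed (incremental use by the
    simulator).  L is accumulated by a downward index scan, which also
    resets the workspace, so each animal costs O(k).
    """
    n = sire.shape[0]
    L = np.zeros(n)
    for k in range(start, n):
        s = sire[k]
        d = dam[k]
        if s < 0 or d < 0:
            F[k] = 0.0
            continue
        fi = -1.0
        L[k] = 1.0
        for j in range(k, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            sj = sire[j]
            dj = dam[j]
            if sj >= 0:
                L[sj] += 0.5 * lj
            if dj >= 0:
                L[dj] += 0.5 * lj
            if sj >= 0 and dj >= 0:
                dcoef = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj >= 0:
                dcoef = 0.75 - 0.25 * F[sj]
            elif dj >= 0:
                dcoef = 0.75 - 0.25 * F[dj]
            else:
                dcoef = 1.0
            fi += lj * lj * dcoef
            L[j] = 0.0
        F[k] = fi
    return F


def compute_inbreeding(ped: Pedigree, F_known: np.ndarray | None = None) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen–Luo algorithm.

    An individual with any unknown parent gets F = 0 (the unknown parent is
    treated as an unrelated base individual).  ``F_known`` allows incremental
    extension: its values are trusted for the first ``len(F_known)`` animals.
    """
    F = np.zeros(ped.n)
    start = 0
    if F_known is not None:
        start = len(F_known)
        F[:start] = F_known
    return _inbreeding_kernel(ped.sire, ped.dam, F, start)


def mendelian_variance_coeffs(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Diagonal of W: Mendelian sampling variance in units of σ²_a.

    1 for founders; 0.75 − 0.25·F_parent with one known parent;
    0.5 − 0.25·(F_sire + F_dam) with both known.
    """
    s, d = ped.sire, ped.dam
    Fs = np.where(s >= 0, F[np.maximum(s, 0)], 0.0)
    Fd = np.where(d >= 0, F[np.maximum(d, 0)], 0.0)
    both = (s >= 0) & (d >= 0)
    one = (s >= 0) ^ (d >= 0)
    w = np.ones(ped.n)
    w[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    w[one] = 0.75 - 0.25 * (Fs[one] + Fd[one])
    if np.any(w <= 0):
        raise PedigreeError("non-positive Mendelian variance coefficient")
    return w


def build_T_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse T⁻¹: unit diagonal, −0.5 at each known parent column."""
    n = ped.n
    rows = [np.arange(n)]
    cols = [np.arange(n)]
    vals = [np.ones(n)]
    for parent in (ped.sire, ped.dam):
        mask = parent >= 0
        rows.append(np.nonzero(mask)[0])
        cols.append(parent[mask])
        vals.append(np.full(mask.sum(), -0.5))
    m = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return m.tocsr()


def build_A_inverse(ped: Pedigree, F: np.ndarray) -> sparse.csr_matrix:
    """Sparse A⁻¹ with inbreeding (Henderson's rules).

    Per individual k with Mendelian variance coefficient w_k, add
    α = 1/w_k at (k,k), −α/2 between k and each known parent, and α/4
    within the known-parent block.
    """
    w = mendelian_variance_coeffs(ped, F)
    alpha = 1.0 / w
    n = ped.n
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    arange = np.arange(n)
    add(arange, arange, alpha)
    for parent in (ped.sire, ped.dam):
        mask = parent >= 0
        k = arange[mask]
        p = parent[mask]
        a = alpha[mask]
        add(k, p, -a / 2)
        add(p, k, -a / 2)
        add(p, p, a / 4)
    both = (ped.sire >= 0) & (ped.dam >= 0)
    k = arange[both]
    a = alpha[both]
    add(ped.sire[both], ped.dam[both], a / 4)
    add(ped.dam[both], ped.sire[both], a / 4)
    m = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return m.tocsr()
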