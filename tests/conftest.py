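"""Shared fixtures: random pedigrees and dense matrix oracles.

The oracles deliberately use the naive dense constructions (recursive
tabular relationship matrix, explicit gene-flow matrix products) so they
are independent of the sparse recursions they check.
"""

import numpy as np
import pandas as pd
import pytest

from bvpart.pedigree import Pedigree


def random_pedigree(
    rng: np.random.Generator,
    n: int = 100,
    p_founder: float = 0.2,
    p_single_parent: float = 0.1,
    n_paths: int = 3,
    n_groups: int = 4,
) -> Pedigree:
    """Random valid pedigree: each non-founder draws parents among earlier
    individuals, occasionally with one parent unknown."""
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for k in range(1, n):
        u = rng.random()
        if u < p_founder:
            continue
        s = int(rng.integers(0, k))
        d = int(rng.integers(0, k))
        if u < p_founder + p_single_parent:
            if rng.random() < 0.5:
                sire[k] = s
            else:
                dam[k] = d
        else:
            sire[k] = s
            dam[k] = d
    path = rng.choice([f"p{j}" for j in range(n_paths)], n).astype(object)
    group = rng.integers(0, n_groups, n)
    return Pedigree(
        ids=np.array([f"i{k}" for k in range(n)], dtype=object),
        sire=sire,
        dam=dam,
        path=path,
        group=group,
    )


def dense_T(ped: Pedigree) -> np.ndarray:
    """Gene-flow matrix by its defining recursion: row k is the average of
    the parents' rows plus the unit vector e_k."""
    n = ped.n
    T = np.zeros((n, n))
    for k in range(n):
        if ped.sire[k] >= 0:
            T[k] += 0.5 * T[ped.sire[k]]
        if ped.dam[k] >= 0:
            T[k] += 0.5 * T[ped.dam[k]]
        T[k, k] = 1.0
    return T


def dense_A_tabular(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method."""
    n = ped.n
    A = np.zeros((n, n))
    for k in range(n):
        s, d = ped.sire[k], ped.dam[k]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[k, k] = 1.0 + 0.5 * a_sd
        for j in range(k):
            a_js = A[j, s] if s >= 0 else 0.0
            a_jd = A[j, d] if d >= 0 else 0.0
            A[k, j] = A[j, k] = 0.5 * (a_js + a_jd)
    return A


def recursive_bv(ped: Pedigree, w: np.ndarray) -> np.ndarray:
    """a_k = ½ a_sire + ½ a_dam + w_k, the defining recursion."""
    a = np.zeros(ped.n)
    for k in range(ped.n):
        if ped.sire[k] >= 0:
            a[k] += 0.5 * a[ped.sire[k]]
        if ped.dam[k] >= 0:
            a[k] += 0.5 * a[ped.dam[k]]
        a[k] += w[k]
    return a


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def trio_frame():
    return pd.DataFrame(
        {"id": ["1", "2", "3"], "sire": ["0", "0", "1"], "dam": ["0", "0", "2"]}
    )
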