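"""Aggregate path contributions by a grouping variable.

For a category t with n_k members, the mean of each path contribution and
the population-denominator variance/covariance of the contributions are
reported, so that the decomposition

    Var(a_t) = Σ_j Var(a_{j,t}) + 2 ΣΣ_{j<j'} Cov(a_{j,t}, a_{j',t})

holds exactly per category.  With posterior samples of breeding values the
same summaries computed per sample give posterior distributions of every
cell, summarised here by the posterior mean with equal-tailed or
highest-posterior-density intervals.
"""

from __future__ import annotations

from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .partition import PartitionedBV

COLLAPSED_COV = "cov"
TOTAL = "total"


def _categories(by: Sequence) -> tuple[np.ndarray, list]:
    """Category code per individual plus natural-sorted category list,
    keeping declared-but-empty categories when ``by`` is Categorical."""
    if isinstance(by, pd.Categorical) or isinstance(
        getattr(by, "dtype", None), pd.CategoricalDtype
    ):
        cat = pd.Categorical(by)
        levels = sorted(cat.categories.tolist())
        codes = np.array([levels.index(v) if v is not np.nan else -1
                          for v in cat.astype(object)])
        return codes, levels
    by = np.asarray(by, dtype=object)
    levels = sorted(set(by.tolist()))
    lookup = {v: i for i, v in enumerate(levels)}
    codes = np.fromiter((lookup[v] for v in by), dtype=np.int64, count=len(by))
    return codes, levels


def summarize_partitions(
    part: PartitionedBV,
    by: Sequence | None = None,
    statistic: str | Callable = "mean",
    cov_mode: str = "collapsed",
) -> pd.DataFrame:
    """Per-category summary of path contributions.

    Parameters
    ----------
    part : PartitionedBV
    by : sequence, optional
        Grouping labels aligned to the pedigree; defaults to the
        pedigree's own ``group`` column.
    statistic : "mean", "var" or callable
        "var" adds covariance columns; a callable is applied per path and
        to the total (no covariances).
    cov_mode : {"collapsed", "pairwise"}
        Collapsed: one column with 2·ΣΣ_{j<j'} Cov.  Pairwise: one column
        ``cov:j:j'`` per pair, each holding 2·Cov(a_j, a_j').

    Returns
    -------
    DataFrame with one row per category (empty categories yield null
    rows), columns: group, n, one per path, covariance column(s) for
    "var", and the total.
    """
    if by is None:
        if part.ped.group is None:
            raise ValueError("no grouping labels: pass `by` or set pedigree group")
        by = part.ped.group
    if len(by) != part.ped.n:
        raise ValueError("grouping labels do not align with the pedigree")
    if cov_mode not in ("collapsed", "pairwise"):
        raise ValueError(f"unknown cov_mode: {cov_mode}")
    if callable(statistic) and cov_mode == "pairwise":
        raise ValueError("pairwise covariances are defined only for statistic='var'")

    codes, levels = _categories(by)
    contrib = part.contributions
    p = part.paths.n_paths
    pnames = part.paths.levels
    pairs = list(combinations(range(p), 2))

    rows = []
    for t, level in enumerate(levels):
        mask = codes == t
        n_k = int(mask.sum())
        row: dict = {"group": level, "n": n_k}
        if n_k == 0:
            rows.append(row)  # reported, not silently dropped
            continue
        x = contrib[mask]
        total = x.sum(axis=1)
        if statistic == "mean":
            for j in range(p):
                row[pnames[j]] = x[:, j].mean()
            row[TOTAL] = total.mean()
        elif statistic == "var":
            xc = x - x.mean(axis=0)
            cov = xc.T @ xc / n_k  # population denominator: exact additivity
            for j in range(p):
                row[pnames[j]] = cov[j, j]
            if cov_mode == "pairwise":
                for j, jp in pairs:
                    row[f"cov:{pnames[j]}:{pnames[jp]}"] = 2.0 * cov[j, jp]
            else:
                row[COLLAPSED_COV] = 2.0 * sum(cov[j, jp] for j, jp in pairs)
            tc = total - total.mean()
            row[TOTAL] = tc @ tc / n_k
        elif callable(statistic):
            for j in range(p):
                row[pnames[j]] = statistic(x[:, j])
            row[TOTAL] = statistic(total)
        else:
            raise ValueError(f"unknown statistic: {statistic}")
        rows.append(row)
    return pd.DataFrame(rows)


def hpd_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` mass of an empirical sample."""
    xs = np.sort(np.asarray(samples, dtype=float))
    s = xs.size
    m = max(1, int(np.ceil(level * s)))
    if m >= s:
        return float(xs[0]), float(xs[-1])
    widths = xs[m - 1:] - xs[: s - m + 1]
    i = int(np.argmin(widths))
    return float(xs[i]), float(xs[i + m - 1])


def summarize_posterior(
    summaries: Sequence[pd.DataFrame],
    level: float = 0.95,
    interval_kind: str = "equal-tailed",
) -> pd.DataFrame:
    """Combine per-sample summaries into posterior point/interval estimates.

    Each input frame is one posterior sample's output of
    :func:`summarize_partitions`; all must share the same rows and
    columns.  Returns a tidy frame with columns group, statistic, point,
    lower, upper.
    """
    if len(summaries) == 0:
        raise ValueError("no summaries given")
    s = len(summaries)
    if s == 1 and interval_kind is not None:
        raise ValueError("intervals require at least 2 posterior samples")
    base = summaries[0]
    value_cols = [c for c in base.columns if c not in ("group", "n")]
    stack = np.stack(
        [df[value_cols].to_numpy(dtype=float) for df in summaries]
    )  # (S, rows, cells)
    alpha = 1.0 - level
    records = []
    for r, group in enumerate(base["group"]):
        for c, colname in enumerate(value_cols):
            draws = stack[:, r, c]
            if np.isnan(draws).all():
                records.append((group, colname, np.nan, np.nan, np.nan))
                continue
            point = float(np.mean(draws))
            if interval_kind == "equal-tailed":
                lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
            elif interval_kind == "hpd":
                lo, hi = hpd_interval(draws, level)
            else:
                raise ValueError(f"unknown interval_kind: {interval_kind}")
            records.append((group, colname, point, float(lo), float(hi)))
    return pd.DataFrame(
        records, columns=["group", "statistic", "point", "lower", "upper"]
    )


def correlation_between_paths(
    part: PartitionedBV,
    by: Sequence | None = None,
    path_a: str | None = None,
    path_b: str | None = None,
) -> pd.Series:
    """Per-category Pearson correlation between two path contributions.

    Population denominators; categories where either contribution is
    constant yield NaN (the correlation is undefined there).
    """
    if by is None:
        by = part.ped.group
    levels_p = part.paths.levels
    ja, jb = levels_p.index(path_a), levels_p.index(path_b)
    codes, levels = _categories(by)
    out = {}
    for t, level in enumerate(levels):
        mask = codes == t
        if mask.sum() == 0:
            out[level] = np.nan
            continue
        x = part.contributions[mask, ja]
        y = part.contributions[mask, jb]
        xc, yc = x - x.mean(), y - y.mean()
        vx, vy = xc @ xc, yc @ yc
        out[level] = np.nan if vx == 0 or vy == 0 else (xc @ yc) / np.sqrt(vx * vy)
    return pd.Series(out, name=f"corr:{path_a}:{path_b}")
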