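"""Agreement between true and estimated trajectories.

Lin's concordance correlation coefficient ρc penalises both imprecision
(Pearson ρ) and deviation from the identity line (the bias correction
factor C_b), with ρc = ρ·C_b.  All moments use the population (1/m)
convention consistently; ρc is invariant to that choice only when it is
applied to σ₁², σ₂² and σ₁₂ alike, so one code path computes all three.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def _paired(y1, y2) -> tuple[np.ndarray, np.ndarray]:
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("paired series must be 1-D and of equal length")
    if y1.size < 2:
        raise ValueError("need at least two pairs")
    if not (np.isfinite(y1).all() and np.isfinite(y2).all()):
        raise ValueError("non-finite values in paired series")
    return y1, y2


def concordance(y1: Sequence, y2: Sequence) -> dict:
    """Concordance correlation between a reference and a comparison series.

    Returns ``rho_c``, Pearson ``rho``, bias correction ``C_b``, the scale
    shift ``v = σ₁/σ₂`` and the location shift ``u = (μ₁−μ₂)/√(σ₁σ₂)``
    (both in standard-deviation units).
    When either series is constant, ``rho`` (and the shifts that divide by
    a standard deviation) are NaN while ``rho_c`` is still evaluated from
    its definition whenever its denominator is positive.
    """
    y1, y2 = _paired(y1, y2)
    m1, m2 = y1.mean(), y2.mean()
    d1, d2 = y1 - m1, y2 - m2
    m = y1.size
    s1, s2 = d1 @ d1 / m, d2 @ d2 / m
    s12 = d1 @ d2 / m
    denom = s1 + s2 + (m1 - m2) ** 2
    if denom == 0.0:
        raise ZeroDivisionError("concordance undefined: both series constant and equal")
    rho_c = 2.0 * s12 / denom
    if s1 > 0 and s2 > 0:
        sd1, sd2 = np.sqrt(s1), np.sqrt(s2)
        rho = s12 / (sd1 * sd2)
        # Lin's shifts: v and u in standard-deviation units, the only
        # convention under which rho_c = rho * C_b is an identity
        v = sd1 / sd2
        u = (m1 - m2) / np.sqrt(sd1 * sd2)
        c_b = 2.0 / (v + 1.0 / v + u * u)
    else:
        rho = v = u = c_b = np.nan
    return {"rho_c": float(rho_c), "rho": float(rho), "C_b": float(c_b),
            "v": float(v), "u": float(u)}


def rmsd(y1: Sequence, y2: Sequence) -> float:
    """Root mean square deviation between the comparison and the reference."""
    y1, y2 = _paired(y1, y2)
    d = y2 - y1
    return float(np.sqrt(d @ d / d.size))


def truth_vs_estimate_differences(
    truth: Sequence[pd.DataFrame],
    estimates: Sequence[pd.DataFrame],
    level: float = 0.95,
) -> pd.DataFrame:
    """Across-replicate distribution of (true − estimated) per category.

    ``truth`` and ``estimates`` are aligned lists (one frame per
    replicate) with columns ``group`` plus one column per summary cell;
    differences are computed cell-wise and summarised across replicates by
    their mean and an equal-tailed quantile band.  With a well-calibrated
    model the bands straddle zero.
    """
    if len(truth) != len(estimates) or len(truth) == 0:
        raise ValueError("need equally many (≥1) truth and estimate frames")
    diffs = []
    base = truth[0]
    cols = [c for c in base.columns if c not in ("group", "n")]
    for tr, est in zip(truth, estimates):
        if not np.array_equal(np.asarray(tr["group"]), np.asarray(est["group"])):
            raise ValueError("category mismatch between truth and estimates")
        diffs.append(tr[cols].to_numpy(float) - est[cols].to_numpy(float))
    stack = np.stack(diffs)  # (reps, rows, cells)
    alpha = 1.0 - level
    lo, hi = np.quantile(stack, [alpha / 2, 1 - alpha / 2], axis=0)
    mean = stack.mean(axis=0)
    records = []
    for r, group in enumerate(base["group"]):
        for c, name in enumerate(cols):
            records.append((group, name, mean[r, c], lo[r, c], hi[r, c]))
    return pd.DataFrame(
        records, columns=["group", "statistic", "mean_diff", "lower", "upper"]
    )
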