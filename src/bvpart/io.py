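"""Delimited-table round-tripping shared by the command-line workflow.

CSV by default; TSV autodetected from the ``.tsv``/``.txt`` extension or
forced with ``sep``.  Floats are written with Python's shortest-repr
formatting, which round-trips IEEE doubles exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _sep_for(path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_table(path, sep: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path, sep))


def write_table(df: pd.DataFrame, path, sep: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path, sep), index=False)


def align_values(
    values: pd.DataFrame, ped, id_col: str = "id"
) -> tuple[np.ndarray, list, dict]:
    """Inner-join value columns onto the pedigree order.

    Returns the (n, S) value matrix in pedigree order, the value column
    names, and a report of dropped rows — ids in the value table missing
    from the pedigree and pedigree individuals without values.  Silent
    row loss is the classic failure mode of partitioning runs, so the
    report is always produced and any loss must be acknowledged by the
    caller.
    """
    ids = [str(v) for v in values[id_col]]
    in_ped = np.array([i in ped.index for i in ids])
    matched = values.loc[in_ped]
    matched_ids = [str(v) for v in matched[id_col]]
    pos = ped.positions(matched_ids)
    cols = [c for c in values.columns if c != id_col]
    report = {
        "n_values": len(values),
        "n_matched": int(in_ped.sum()),
        "n_value_rows_dropped": int((~in_ped).sum()),
        "n_pedigree_unmatched": ped.n - len(set(pos.tolist())),
    }
    if report["n_matched"] == 0:
        raise ValueError("join of values with pedigree is empty")
    if report["n_pedigree_unmatched"] > 0:
        raise ValueError(
            f"{report['n_pedigree_unmatched']} pedigree individuals lack values; "
            "partitioning requires a value for every individual"
        )
    mat = np.empty((ped.n, len(cols)))
    mat[pos] = matched[cols].to_numpy(dtype=float)
    return mat, cols, report
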