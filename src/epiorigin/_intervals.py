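"""Point-in-interval assignment over disjoint half-open intervals."""

from __future__ import annotations

import numpy as np
import pandas as pd


def assign_intervals(
    chroms: np.ndarray, positions: np.ndarray, intervals: pd.DataFrame
) -> np.ndarray:
    """Map each (chrom, pos) point to the row position of the containing
    interval in ``intervals`` (columns chrom/start/end, disjoint within a
    chromosome), or -1 when no interval contains it.

    Containment is half-open: start ≤ pos < end.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    out = np.full(len(positions), -1, dtype=np.int64)
    iv_chrom = intervals["chrom"].to_numpy()
    iv_start = intervals["start"].to_numpy()
    iv_end = intervals["end"].to_numpy()
    row_pos = np.arange(len(intervals))
    for chrom in np.unique(chroms):
        sel = iv_chrom == chrom
        if not sel.any():
            continue
        starts, ends, rows = iv_start[sel], iv_end[sel], row_pos[sel]
        order = np.argsort(starts)
        starts, ends, rows = starts[order], ends[order], rows[order]
        mask = chroms == chrom
        pos = positions[mask]
        idx = np.searchsorted(starts, pos, side="right") - 1
        hit = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        res = np.full(len(pos), -1, dtype=np.int64)
        res[hit] = rows[idx[hit]]
        out[mask] = res
    return out
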