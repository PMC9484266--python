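"""Differential chromatin accessibility between two cell clusters and
hypergeometric motif over-representation in the resulting peak sets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

NS = "NS"  # not significant / not class-assigned


@dataclass
class DiffPeakTable:
    """Per-region differential-accessibility results.

    Columns: detect_frac_<undiff/diff>, log2fc (undiff over diff,
    pseudocount 1 on depth-normalized means), p, q, peak_class (UK when
    more accessible in the undifferentiated cluster, DK in the
    differentiated one, NS otherwise).
    """

    table: pd.DataFrame
    undiff_label: str
    diff_label: str

    def regions_for_class(self, cls: str) -> pd.Index:
        return self.table.index[self.table["peak_class"] == cls]


def differential_peaks(
    counts: pd.DataFrame,
    labels: pd.Series,
    undiff_label: str | None = None,
    min_frac: float = 0.05,
    lfc_thresh: float = 0.25,
    alpha: float = 0.05,
) -> DiffPeakTable:
    """Wilcoxon rank-sum differential accessibility on depth-normalized
    counts.

    ``counts`` is regions × cells; ``labels`` assigns each cell to one of
    two clusters, with ``undiff_label`` naming the undifferentiated one
    (default: the lexicographically smaller level).  A region is called
    iff q < ``alpha``, |log2FC| > ``lfc_thresh`` and its detection
    fraction in the favored cluster ≥ ``min_frac``; its class follows the
    sign of the fold change (UK = up in undifferentiated).
    """
    labels = labels.reindex(counts.columns).dropna()
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two cluster labels, got {levels}")
    if undiff_label is None:
        undiff_label = levels[0]
    if undiff_label not in levels:
        raise ValueError(f"undiff label {undiff_label!r} not among {levels}")
    diff_label = [l for l in levels if l != undiff_label][0]
    cells_u = labels.index[labels == undiff_label]
    cells_d = labels.index[labels == diff_label]
    if len(cells_u) < 2 or len(cells_d) < 2:
        raise ValueError("each cluster needs at least two cells")

    raw = counts.to_numpy(dtype=float)
    depth = raw.sum(axis=0)
    if (depth == 0).any():
        raise ValueError("cells with zero total counts cannot be depth-normalized")
    norm = raw / depth * np.median(depth)
    norm_df = pd.DataFrame(norm, index=counts.index, columns=counts.columns)
    U = norm_df[cells_u].to_numpy()
    D = norm_df[cells_d].to_numpy()

    res = stats.mannwhitneyu(
        U, D, axis=1, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate rows (identical pooled values, e.g. all zeros) carry no signal
    pooled_const = np.ptp(np.concatenate([U, D], axis=1), axis=1) == 0
    p[pooled_const] = 1.0
    q = bh_adjust(p)

    mean_u, mean_d = U.mean(axis=1), D.mean(axis=1)
    log2fc = np.log2(mean_u + 1.0) - np.log2(mean_d + 1.0)
    frac_u = (counts[cells_u].to_numpy() > 0).mean(axis=1)
    frac_d = (counts[cells_d].to_numpy() > 0).mean(axis=1)
    favored_frac = np.where(log2fc > 0, frac_u, frac_d)
    passed = (q < alpha) & (np.abs(log2fc) > lfc_thresh) & (favored_frac >= min_frac)
    peak_class = np.where(passed, np.where(log2fc > 0, "UK", "DK"), NS)

    table = pd.DataFrame(
        {
            "detect_frac_undiff": frac_u,
            "detect_frac_diff": frac_d,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "peak_class": peak_class,
        },
        index=counts.index,
    )
    return DiffPeakTable(table=table, undiff_label=undiff_label, diff_label=diff_label)


@dataclass
class MotifEnrichment:
    """Hypergeometric motif over-representation in a foreground peak set."""

    table: pd.DataFrame  # per motif: k, n, K, N, fold_enrichment, p, q


def motif_enrichment(
    fg_regions,
    bg_regions,
    motif_occurrence: pd.DataFrame,
) -> MotifEnrichment:
    """Upper-tail hypergeometric test per motif.

    ``motif_occurrence`` is a binary regions × motifs table.  The universe
    is foreground ∪ background (N regions); for each motif with K
    occurrences in the universe and k in the n foreground regions,
    p = P[X ≥ k], X ~ Hypergeometric(N, K, n), BH-corrected across motifs.
    Fold enrichment is (k/n)/(K/N).
    """
    fg = pd.Index(fg_regions)
    if len(fg) == 0:
        raise ValueError("empty foreground region set")
    universe = fg.union(pd.Index(bg_regions))
    missing = universe.difference(motif_occurrence.index)
    if len(missing):
        raise KeyError(f"regions absent from occurrence table: {list(missing[:10])}")
    occ = motif_occurrence.loc[universe]
    vals = occ.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("motif occurrence table must be binary")

    N = len(universe)
    n = len(fg)
    K = occ.sum(axis=0).to_numpy()
    k = occ.loc[fg].sum(axis=0).to_numpy()
    p = stats.hypergeom.sf(k - 1, N, K, n)
    p = np.minimum(p, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(K > 0, (k / n) / (K / N), np.nan)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"k": k, "n": n, "K": K, "N": N, "fold_enrichment": fold, "p": p, "q": q},
        index=occ.columns,
    ).sort_values("p")
    return MotifEnrichment(table=table)
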