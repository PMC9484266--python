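"""Reference-based deconvolution of bulk methylomes into keratinocyte
population fractions.

An expression reference nominates cell-type marker genes (with a maximum
marker specificity score capping how many types a marker may be active in);
a paired promoter-methylation table turns retained markers — those whose
methylation anti-correlates with expression across types, the
promoter-methylation-silences assumption — into a methylation reference.
Bulk promoter β is then decomposed by weighted non-negative least squares
and projected onto the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from ._stats import rank_sum_test

DEFAULT_MSS = 3  # maximum marker specificity score
DEFAULT_FOLD = 2.0  # top type must exceed runner-up this many fold


@dataclass
class ExpressionReference:
    """Marker genes × cell types mean expression, with per-marker
    specificity score (number of types above the expression threshold)
    and weight = 1/score."""

    means: pd.DataFrame  # markers × cell types
    designated_type: pd.Series  # per marker (argmax expression)
    specificity_score: pd.Series  # per marker, integer ≥ 1
    weight: pd.Series  # per marker, in (0, 1]


def build_expression_reference(
    expr: pd.DataFrame,
    mss: int = DEFAULT_MSS,
    expr_threshold: float | None = None,
    fold: float = DEFAULT_FOLD,
) -> ExpressionReference:
    """Select marker genes from a genes × cell-types mean-expression table.

    A gene is a marker for its argmax type iff that expression is at least
    ``fold`` times the second-highest type and its specificity score (the
    number of types above ``expr_threshold``; default threshold = 10% of
    the table's maximum) is between 1 and ``mss``.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two cell types")
    if expr_threshold is None:
        expr_threshold = 0.1 * float(expr.to_numpy().max())
    vals = expr.to_numpy(dtype=float)
    order = np.sort(vals, axis=1)
    top, second = order[:, -1], order[:, -2]
    score = (vals > expr_threshold).sum(axis=1)
    is_marker = (top >= fold * second) & (score >= 1) & (score <= mss) & (top > 0)
    markers = expr.index[is_marker]
    if len(markers) == 0:
        raise ValueError("no marker genes survive the specificity filters")
    designated = expr.loc[markers].idxmax(axis=1)
    missing = [t for t in expr.columns if t not in set(designated)]
    if missing:
        raise ValueError(f"cell types without any marker gene: {missing}")
    score_s = pd.Series(score[is_marker], index=markers, name="specificity_score")
    return ExpressionReference(
        means=expr.loc[markers].copy(),
        designated_type=designated.rename("designated_type"),
        specificity_score=score_s,
        weight=(1.0 / score_s).rename("weight"),
    )


@dataclass
class MethylationReference:
    """Markers × cell types promoter methylation with carried-over weights."""

    meth: pd.DataFrame
    weight: pd.Series
    designated_type: pd.Series

    @property
    def cell_types(self) -> pd.Index:
        return self.meth.columns


def impute_methylation_reference(
    exr: ExpressionReference, paired: pd.DataFrame
) -> MethylationReference:
    """Restrict markers to those with paired promoter methylation whose
    methylation anti-correlates with expression across cell types
    (Spearman ρ < 0); wrong-sign or flat markers are dropped."""
    shared = exr.means.index.intersection(paired.index)
    kept = []
    for gene in shared:
        e = exr.means.loc[gene].to_numpy(dtype=float)
        m = paired.loc[gene, exr.means.columns].to_numpy(dtype=float)
        rho = stats.spearmanr(e, m).statistic
        if np.isnan(rho) or rho >= 0:
            continue
        kept.append(gene)
    if not kept:
        raise ValueError("no anti-correlated markers with paired methylation")
    meth = paired.loc[kept, exr.means.columns].copy()
    designated = exr.designated_type.loc[kept]
    lost = [t for t in exr.means.columns if t not in set(designated)]
    if lost:
        raise ValueError(f"cell types losing all markers: {lost}")
    return MethylationReference(
        meth=meth, weight=exr.weight.loc[kept], designated_type=designated
    )


@dataclass
class FractionEstimate:
    """Samples × cell types fractions on the simplex, with fit residuals."""

    fractions: pd.DataFrame
    residual: pd.Series


def estimate_fractions(
    bulk_promoter_beta: pd.DataFrame, ref: MethylationReference
) -> FractionEstimate:
    """Weighted non-negative least squares of bulk promoter β on the
    reference columns, renormalized to the simplex.

    ``bulk_promoter_beta`` is markers × samples; rows are matched to the
    reference markers.  Errors when fewer markers than cell types are
    shared or when the reference is rank-deficient across types.
    """
    shared = ref.meth.index.intersection(bulk_promoter_beta.index)
    n_types = ref.meth.shape[1]
    if len(shared) < n_types:
        raise ValueError(
            f"{len(shared)} shared markers < {n_types} cell types"
        )
    R = ref.meth.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < n_types:
        raise ValueError("methylation reference is rank-deficient across cell types")
    w = np.sqrt(ref.weight.loc[shared].to_numpy(dtype=float))
    Rw = R * w[:, None]
    fractions, residuals = [], []
    for sample in bulk_promoter_beta.columns:
        y = bulk_promoter_beta.loc[shared, sample].to_numpy(dtype=float)
        coef, rnorm = nnls(Rw, y * w)
        total = coef.sum()
        frac = coef / total if total > 0 else np.full(n_types, 1.0 / n_types)
        fractions.append(frac)
        residuals.append(rnorm)
    return FractionEstimate(
        fractions=pd.DataFrame(
            fractions, index=bulk_promoter_beta.columns, columns=ref.meth.columns
        ),
        residual=pd.Series(residuals, index=bulk_promoter_beta.columns, name="residual"),
    )


def compare_fractions(fr: FractionEstimate, groups: pd.Series) -> pd.DataFrame:
    """Two-sided rank-sum test per cell type between two sample groups.
    Returns group means and p per type."""
    groups = groups.reindex(fr.fractions.index).dropna()
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    rows = []
    for ct in fr.fractions.columns:
        x = fr.fractions.loc[groups.index[groups == levels[0]], ct].to_numpy()
        y = fr.fractions.loc[groups.index[groups == levels[1]], ct].to_numpy()
        if len(x) == 0 or len(y) == 0:
            raise ValueError("each group needs at least one sample")
        _, p = rank_sum_test(x, y)
        rows.append(
            {
                "cell_type": ct,
                f"mean_{levels[0]}": float(np.mean(x)),
                f"mean_{levels[1]}": float(np.mean(y)),
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")
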