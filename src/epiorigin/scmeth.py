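"""Integration of sparse single-cell methylomes with bulk methylomes.

Bulk β values are binarized (≥0.5 → 1) to match the binary nature of
single-cell calls; all entities are then compared with a normalized-Hamming
dissimilarity (mismatch fraction over the sites covered in both) and
embedded with classical (Torgerson) MDS.  Cells are assigned to the tumor
subclass whose bulk methylomes they are closest to, and methylation is
summarized over ChromHMM chromatin states (states 4-5 = strong enhancers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import assign_intervals
from ._stats import rank_sum_test
from .model import (
    N_CHROMHMM_STATES,
    BetaMatrix,
    ProbeManifest,
    ScMethProfile,
    Segmentation,
)
from .stratify import EPSC_LIKE, HEALTHY_REF, KER_LIKE, SubclassAssignment

DEFAULT_MIN_SHARED = 50  # minimum co-covered sites for a trustworthy distance

EPSC_CELL = "EpSC"
KER_CELL = "Keratinocyte"
UNCLASSIFIABLE = "Unclassifiable"


def binarize(beta: BetaMatrix) -> pd.DataFrame:
    """Threshold β at 0.5 (inclusive above): ≥0.5 → 1, <0.5 → 0.
    Missing values stay missing."""
    v = beta.values.to_numpy(dtype=float)
    out = np.where(np.isnan(v), np.nan, (v >= 0.5).astype(float))
    return pd.DataFrame(out, index=beta.probe_ids, columns=beta.sample_ids)


def combine_profiles(
    profiles: Sequence[ScMethProfile],
    bulk_binary: pd.DataFrame,
    manifest: ProbeManifest,
) -> pd.DataFrame:
    """Assemble a positions × entities call matrix (0/1, NaN = uncovered)
    from single-cell profiles and binarized bulk columns.

    Bulk probes are placed at their manifest CpG positions; cell calls
    outside the manifest universe are ignored.
    """
    pos_index = pd.MultiIndex.from_arrays(
        [manifest.df["chrom"], manifest.df["pos"]], names=("chrom", "pos")
    )
    names = [str(s) for s in bulk_binary.columns] + [p.cell_id for p in profiles]
    X = np.full((len(pos_index), len(names)), np.nan, dtype=np.float32)
    bulk = bulk_binary.reindex(manifest.df.index)
    X[:, : bulk.shape[1]] = bulk.to_numpy(dtype=np.float32)
    for j, p in enumerate(profiles, start=bulk.shape[1]):
        loc = pos_index.get_indexer(p.calls.index)
        ok = loc >= 0  # calls outside the universe are ignored
        X[loc[ok], j] = p.calls.to_numpy(dtype=np.float32)[ok]
    return pd.DataFrame(X, index=pos_index, columns=names)


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with per-pair shared-site counts.

    Entries are NaN where fewer than ``min_shared`` sites were co-covered.
    """

    values: pd.DataFrame
    shared_counts: pd.DataFrame
    min_shared: int

    @property
    def entity_ids(self) -> pd.Index:
        return self.values.index

    def imputed(self) -> pd.DataFrame:
        """Complete matrix: missing pairs filled with the maximum observed
        dissimilarity (a conservative 'no evidence of affinity' fill)."""
        v = self.values.to_numpy().copy()
        mask = np.isnan(v)
        np.fill_diagonal(mask, False)
        if mask.any():
            fill = np.nanmax(v) if not np.isnan(v).all() else 1.0
            v[mask] = fill
        np.fill_diagonal(v, 0.0)
        return pd.DataFrame(v, index=self.values.index, columns=self.values.columns)


def pairwise_dissimilarity(
    calls: pd.DataFrame, min_shared: int = DEFAULT_MIN_SHARED
) -> DissimilarityMatrix:
    """Normalized Hamming dissimilarity between every pair of entities:
    the fraction of mismatching binary calls over sites covered in both.

    ``calls`` is positions × entities with values in {0, 1, NaN}.  Pairs
    sharing fewer than ``min_shared`` sites are reported missing (NaN).
    """
    X = calls.to_numpy(dtype=np.float32)
    covered = ~np.isnan(X)
    if not covered.any(axis=0).all():
        empty = calls.columns[~covered.any(axis=0)]
        raise ValueError(f"entities with zero covered sites: {list(empty[:10])}")
    C = covered.astype(np.float32)
    M = np.where(covered, X, 0.0).astype(np.float32)  # methylated indicator
    U = C - M  # unmethylated indicator
    shared = C.T @ C
    agree = M.T @ M + U.T @ U
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (shared - agree) / shared
    d[shared < min_shared] = np.nan
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry despite float accumulation order
    ids = calls.columns
    return DissimilarityMatrix(
        values=pd.DataFrame(d, index=ids, columns=ids),
        shared_counts=pd.DataFrame(shared.astype(np.int64), index=ids, columns=ids),
        min_shared=min_shared,
    )


# ------------------------------------------------------------------------ MDS


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # entities × dims
    eigenvalues: np.ndarray  # all eigenvalues of the doubly-centered matrix


def classical_mds(d, n_components: int = 2) -> EmbeddingResult:
    """Torgerson classical MDS: eigendecomposition of −½ J D² J.

    Accepts a DissimilarityMatrix (missing pairs imputed with the maximum
    observed value first) or a complete symmetric DataFrame/array.  Axes are
    oriented so each one's largest-magnitude coordinate is positive;
    negative eigenvalues contribute zero coordinates.
    """
    if isinstance(d, DissimilarityMatrix):
        dmat = d.imputed()
    else:
        dmat = pd.DataFrame(d)
    D = dmat.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, n_components))
    # eigenvalues at round-off scale are zero-dimensional directions
    eig_tol = max(float(evals.max()), 0.0) * 1e-12
    for j in range(min(n_components, n)):
        if evals[j] > eig_tol:
            coords[:, j] = evecs[:, j] * np.sqrt(evals[j])
        if np.abs(coords[:, j]).max() > 0 and coords[
            np.argmax(np.abs(coords[:, j])), j
        ] < 0:
            coords[:, j] *= -1
    return EmbeddingResult(
        coordinates=pd.DataFrame(
            coords,
            index=dmat.index,
            columns=[f"MDS{j + 1}" for j in range(n_components)],
        ),
        eigenvalues=evals,
    )


# -------------------------------------------------------- cell classification


def classify_cells(
    d: DissimilarityMatrix,
    bulk_labels: SubclassAssignment | pd.Series,
    cell_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assign each cell to the nearer tumor subclass.

    Per cell: mean dissimilarity to the EpSC-like bulks versus to the
    keratinocyte-like + healthy bulks; the label is the argmin.  Ties break
    to Keratinocyte (the majority class in epidermis) and are flagged, as
    are cells with no usable distance to one side.  Returns a DataFrame with
    label, the two mean distances, the margin (ker − epsc side), and flags.
    """
    labels = (
        bulk_labels.labels if isinstance(bulk_labels, SubclassAssignment) else bulk_labels
    )
    epsc_bulks = [s for s in labels.index if labels[s] == EPSC_LIKE and s in d.entity_ids]
    ker_bulks = [
        s
        for s in labels.index
        if labels[s] in (KER_LIKE, HEALTHY_REF) and s in d.entity_ids
    ]
    if not epsc_bulks or not ker_bulks:
        raise ValueError("need at least one bulk sample on each subclass side")
    if cell_ids is None:
        cell_ids = [e for e in d.entity_ids if e not in set(labels.index)]
    rows = []
    for cell in cell_ids:
        to_epsc = d.values.loc[cell, epsc_bulks].mean(skipna=True)
        to_ker = d.values.loc[cell, ker_bulks].mean(skipna=True)
        if np.isnan(to_epsc) or np.isnan(to_ker):
            rows.append((cell, UNCLASSIFIABLE, to_epsc, to_ker, np.nan, True, False))
            continue
        tie = to_epsc == to_ker
        label = EPSC_CELL if to_epsc < to_ker else KER_CELL
        rows.append((cell, label, to_epsc, to_ker, to_ker - to_epsc, False, tie))
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "label",
            "dist_epsc_like",
            "dist_ker_like",
            "margin",
            "unclassifiable",
            "tie",
        ],
    ).set_index("cell_id")


# ------------------------------------------------------- chromatin-state means


def chromhmm_state_means(
    entities: Mapping[str, pd.Series] | pd.DataFrame,
    seg: Segmentation,
    manifest: ProbeManifest | None = None,
):
    """Mean methylation per ChromHMM state (1..15) for each entity.

    ``entities`` is either a mapping entity → sparse call/β Series indexed
    by (chrom, pos), or a probes × entities DataFrame accompanied by a
    ``manifest`` giving probe positions.  Returns (state × entity means,
    state × entity covered-CpG counts); a state with no covered CpG for an
    entity is missing.
    """
    if isinstance(entities, pd.DataFrame):
        if manifest is None:
            raise ValueError("probe-indexed matrix input requires a manifest")
        pos = manifest.df.loc[entities.index]
        series_map = {}
        idx = pd.MultiIndex.from_arrays(
            [pos["chrom"], pos["pos"]], names=("chrom", "pos")
        )
        for col in entities.columns:
            series_map[str(col)] = pd.Series(
                entities[col].to_numpy(dtype=float), index=idx
            ).dropna()
        entities = series_map

    states = np.arange(1, N_CHROMHMM_STATES + 1)
    seg_states = seg.df["state"].to_numpy()
    means = {}
    counts = {}
    for name, series in entities.items():
        series = series.dropna()
        if series.empty:
            means[name] = pd.Series(np.nan, index=states)
            counts[name] = pd.Series(0, index=states)
            continue
        chroms = series.index.get_level_values("chrom").to_numpy()
        poss = series.index.get_level_values("pos").to_numpy()
        hit = assign_intervals(chroms, poss, seg.df)
        ok = hit >= 0
        vals = series.to_numpy(dtype=float)[ok]
        st = seg_states[hit[ok]]
        grouped = pd.Series(vals).groupby(st)
        means[name] = grouped.mean().reindex(states)
        counts[name] = grouped.size().reindex(states, fill_value=0)
    mean_df = pd.DataFrame(means)
    count_df = pd.DataFrame(counts)
    mean_df.index.name = count_df.index.name = "state"
    return mean_df, count_df


def compare_enhancer_states(
    state_means: pd.DataFrame,
    groups: pd.Series,
    states: Sequence[int] = (4, 5),
):
    """Two-sided rank-sum test between two entity groups on the per-entity
    average methylation across the strong-enhancer states (4 and 5 by
    default).  Returns (p, group means dict, per-entity scores)."""
    bad = [s for s in states if not 1 <= s <= N_CHROMHMM_STATES]
    if bad:
        raise ValueError(f"states outside 1..{N_CHROMHMM_STATES}: {bad}")
    scores = state_means.loc[list(states)].mean(axis=0)
    groups = groups.reindex(scores.index).dropna()
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two entity groups, got {levels}")
    x = scores[groups == levels[0]].dropna().to_numpy()
    y = scores[groups == levels[1]].dropna().to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("each group needs at least one entity with state coverage")
    _, p = rank_sum_test(x, y)
    return p, {levels[0]: float(np.mean(x)), levels[1]: float(np.mean(y))}, scores
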