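"""Cell-of-origin stratification of bulk methylomes.

The core procedure: map array probes into accessibility-defined regulatory
regions (UK = undifferentiated-keratinocyte-specific, DK =
differentiated-keratinocyte-specific), average β per region and sample,
cluster samples hierarchically (complete linkage, Euclidean) and cut into
two subclasses.  The cluster holding the strict majority of healthy
epidermis samples defines the keratinocyte-like side — healthy epidermis
mostly reflects the methylome of terminally differentiated keratinocytes —
and tumors in the opposite cluster are called EpSC-like (epidermal-stem-cell
like).

Supporting statistics: PCA overviews, probe genomic-context fractions,
moderated-t differential methylation, and promoter marker-region scoring
(e.g. the MIR200C/141 cluster and MIR205 promoters, whose hypermethylation
marks the EpSC-like subclass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from ._intervals import assign_intervals
from ._stats import bh_adjust, rank_sum_test, trigamma_inverse
from .model import ISLAND_RELATIONS, REGION_CLASSES, BetaMatrix, ProbeManifest, RegionSet

EPSC_LIKE = "EpSC-like"
KER_LIKE = "Keratinocyte-like"
HEALTHY_REF = "Healthy-reference"


class AmbiguousHealthyAnchorError(ValueError):
    """Healthy samples split evenly between the two clusters."""


# ------------------------------------------------------------ probe → region


@dataclass
class ProbeRegionMap:
    """Probe→region assignments; a probe maps to ≤1 region per class."""

    pairs: pd.DataFrame  # columns probe_id, region_id, region_class
    region_probe_counts: pd.Series  # per region_id
    region_class: pd.Series  # per region_id

    def class_probe_totals(self) -> pd.Series:
        return self.pairs.groupby("region_class").size()

    def probes_for_class(self, region_class: str) -> pd.Index:
        sel = self.pairs["region_class"] == region_class
        return pd.Index(self.pairs.loc[sel, "probe_id"].unique())


def map_probes_to_regions(manifest: ProbeManifest, regions: RegionSet) -> ProbeRegionMap:
    """Assign each probe to the region containing it (start ≤ pos < end),
    separately per region class; probes overlapping both a UK and a DK
    region contribute to both."""
    chroms = manifest.df["chrom"].to_numpy()
    positions = manifest.df["pos"].to_numpy()
    frames = []
    for cls in REGION_CLASSES:
        sub = regions.df[regions.df["region_class"] == cls]
        if sub.empty:
            continue
        hit = assign_intervals(chroms, positions, sub)
        ok = hit >= 0
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": manifest.df.index[ok],
                    "region_id": sub.index.to_numpy()[hit[ok]],
                    "region_class": cls,
                }
            )
        )
    pairs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["probe_id", "region_id", "region_class"])
    )
    counts = pairs.groupby("region_id").size()
    return ProbeRegionMap(
        pairs=pairs,
        region_probe_counts=counts,
        region_class=regions.df["region_class"].copy(),
    )


@dataclass
class RegionBetaMatrix:
    """Regions × samples mean β plus the per-region probe count used."""

    values: pd.DataFrame
    probe_counts: pd.Series
    region_class: pd.Series

    def by_class(self, region_class: str) -> pd.DataFrame:
        if region_class == "both":
            return self.values
        keep = self.region_class.reindex(self.values.index) == region_class
        return self.values.loc[keep]


def region_beta(beta: BetaMatrix, prmap: ProbeRegionMap) -> RegionBetaMatrix:
    """Arithmetic mean β over the non-missing probes of each region, per
    sample.  Regions with no mapped probe (in the matrix) are absent; a
    region is missing for a sample only when all its probes are missing."""
    if prmap.pairs.empty:
        raise ValueError("probe-region map is empty")
    pairs = prmap.pairs[prmap.pairs["probe_id"].isin(beta.probe_ids)]
    if pairs.empty:
        raise ValueError("no mapped probes present in the β matrix")
    expanded = beta.values.loc[pairs["probe_id"]]
    values = expanded.groupby(pairs["region_id"].to_numpy()).mean()
    values.index.name = "region_id"
    counts = pairs.groupby("region_id").size().reindex(values.index)
    return RegionBetaMatrix(
        values=values,
        probe_counts=counts,
        region_class=prmap.region_class.reindex(values.index),
    )


# -------------------------------------------------------------- stratification


@dataclass
class SubclassAssignment:
    """Two-way cell-of-origin assignment with the supporting dendrogram."""

    labels: pd.Series  # EpSC-like / Keratinocyte-like / Healthy-reference
    linkage: np.ndarray  # scipy linkage matrix over the clustered samples
    sample_ids: list  # leaves of the dendrogram, in linkage order
    dropped_samples: list = field(default_factory=list)
    k: int = 2

    def tumor_labels(self) -> pd.Series:
        return self.labels[self.labels != HEALTHY_REF]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as depths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{parent_height:.6g}"
            left = walk(node.left, node.dist - node.left.dist)
            right = walk(node.right, node.dist - node.right.dist)
            return f"({left},{right}):{parent_height - node.dist:.6g}"

        inner = (
            f"({walk(tree.left, tree.dist - tree.left.dist)},"
            f"{walk(tree.right, tree.dist - tree.right.dist)})"
        )
        return inner + ";"


def hierarchical_stratify(
    rbeta: RegionBetaMatrix | pd.DataFrame,
    healthy_ids: Sequence[str],
    region_class_filter: str = "both",
    max_missing_frac: float = 0.2,
) -> SubclassAssignment:
    """Complete-linkage Euclidean clustering of samples over region mean β,
    cut at the final merge into k=2 clusters.

    Samples missing more than ``max_missing_frac`` of the selected regions
    are dropped with a warning; remaining regions with any missing value are
    excluded so the distance computation sees complete vectors.
    """
    if region_class_filter not in (*REGION_CLASSES, "both"):
        raise ValueError(f"unknown region class filter {region_class_filter!r}")
    mat = (
        rbeta.by_class(region_class_filter)
        if isinstance(rbeta, RegionBetaMatrix)
        else rbeta
    )
    healthy_ids = [h for h in healthy_ids if h in mat.columns]
    if not healthy_ids:
        raise ValueError("need at least one healthy sample present in the matrix")

    missing_frac = mat.isna().mean(axis=0)
    dropped = list(mat.columns[missing_frac > max_missing_frac])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) missing >"
            f"{max_missing_frac:.0%} of regions: {dropped[:5]}",
            stacklevel=2,
        )
        mat = mat.drop(columns=dropped)
        healthy_ids = [h for h in healthy_ids if h in mat.columns]
    mat = mat.dropna(axis=0)
    if mat.shape[0] == 0:
        raise ValueError("no complete regions left after missing-value filtering")
    tumor_ids = [s for s in mat.columns if s not in healthy_ids]
    if len(tumor_ids) < 2:
        raise ValueError("need at least two tumor samples to stratify")

    X = mat.to_numpy(dtype=float).T  # samples × regions
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    assign = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    if len(np.unique(assign)) < 2:
        raise ValueError("clustering produced fewer than 2 clusters at the cut")

    sample_ids = list(mat.columns)
    cluster = pd.Series(assign, index=sample_ids)
    healthy_in_1 = int((cluster.loc[healthy_ids] == 1).sum())
    healthy_in_2 = len(healthy_ids) - healthy_in_1
    if healthy_in_1 == healthy_in_2:
        raise AmbiguousHealthyAnchorError(
            f"healthy samples split {healthy_in_1}/{healthy_in_2} between clusters"
        )
    ker_cluster = 1 if healthy_in_1 > healthy_in_2 else 2

    labels = pd.Series(index=sample_ids, dtype=object, name="subclass")
    labels.loc[healthy_ids] = HEALTHY_REF
    for s in tumor_ids:
        labels.loc[s] = KER_LIKE if cluster.loc[s] == ker_cluster else EPSC_LIKE
    return SubclassAssignment(
        labels=labels, linkage=Z, sample_ids=sample_ids, dropped_samples=dropped
    )


def classify_cohort(
    new_beta: BetaMatrix,
    healthy_ref: BetaMatrix,
    regions: RegionSet,
    manifest: ProbeManifest,
    region_class_filter: str = "both",
    min_overlap: float = 0.5,
) -> SubclassAssignment:
    """Classify an external cohort by co-clustering it with the healthy
    reference over the shared region-mapped probes.

    Errors when fewer than ``min_overlap`` of the reference's region-mapped
    probes are present in the new cohort.
    """
    prmap = map_probes_to_regions(manifest, regions)
    mapped = pd.Index(prmap.pairs["probe_id"].unique())
    ref_mapped = mapped.intersection(healthy_ref.probe_ids)
    if len(ref_mapped) == 0:
        raise ValueError("reference cohort has no region-mapped probes")
    shared = ref_mapped.intersection(new_beta.probe_ids)
    overlap = len(shared) / len(ref_mapped)
    if overlap < min_overlap:
        raise ValueError(
            f"probe overlap {overlap:.1%} below the {min_overlap:.0%} floor"
        )
    combined = pd.concat(
        [healthy_ref.values.loc[shared], new_beta.values.loc[shared]], axis=1
    )
    groups = pd.concat([healthy_ref.sample_group, new_beta.sample_group])
    rbeta = region_beta(BetaMatrix(combined, groups), prmap)
    return hierarchical_stratify(
        rbeta, healthy_ids=list(healthy_ref.sample_ids),
        region_class_filter=region_class_filter,
    )


# ------------------------------------------------------------------ overviews


def pca_overview(beta: BetaMatrix, n_components: int = 2):
    """Centered PCA over samples (probes as features).

    Probes with any missing value are excluded.  Component signs are fixed
    so the largest-magnitude loading of each axis is positive.  Returns
    (coordinates samples × PCs, explained-variance fractions).
    """
    if beta.values.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    complete = beta.values.dropna(axis=0)
    X = complete.to_numpy(dtype=float).T
    if np.allclose(X, X[0], atol=0.0):
        raise ValueError("constant β matrix: no variance to decompose")
    n_components = min(n_components, min(X.shape) - 0)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
            pca.components_[j] *= -1
    coord_df = pd.DataFrame(
        coords,
        index=beta.sample_ids,
        columns=[f"PC{j + 1}" for j in range(coords.shape[1])],
    )
    return coord_df, pca.explained_variance_ratio_.copy()


def probe_context_fractions(probe_ids, manifest: ProbeManifest) -> pd.Series:
    """Fractions of probes per island relation (Island/Shore/Shelf/OpenSea),
    summing to 1."""
    probe_ids = pd.Index(probe_ids)
    if len(probe_ids) == 0:
        raise ValueError("empty probe list")
    sub = manifest.subset(probe_ids)
    counts = sub.df["island_relation"].value_counts()
    return counts.reindex(ISLAND_RELATIONS, fill_value=0) / len(probe_ids)


# ------------------------------------------------------ differential probes


@dataclass
class DMPTable:
    """Differentially methylated probes under a moderated two-group t."""

    table: pd.DataFrame  # mean_diff, t, p, q, significant
    prior_df: float
    prior_var: float
    residual_df: int


def dmp_test(
    beta: BetaMatrix,
    groups: pd.Series,
    p_threshold: float = 0.05,
    prior_df: float | None = None,
) -> DMPTable:
    """Per-probe two-group linear model with empirical-Bayes variance
    shrinkage and BH correction.

    Residual variances are shrunk toward a pooled prior: the prior degrees
    of freedom d0 and prior variance s0² are fitted by method of moments on
    the log residual variances (mean/variance of log s² under the scaled-F
    sampling model).  ``prior_df`` overrides the fit: 0 recovers the
    ordinary per-probe t, ``inf`` gives every probe the pooled prior
    variance.  The ``significant`` flag applies the raw p < ``p_threshold``
    rule; BH-adjusted q values are reported alongside.
    """
    groups = groups.reindex(beta.sample_ids).dropna()
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    ids_a = groups.index[groups == levels[0]]
    ids_b = groups.index[groups == levels[1]]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each group needs at least two samples")

    complete = beta.values[list(ids_a) + list(ids_b)].dropna(axis=0)
    A = complete[list(ids_a)].to_numpy(dtype=float)
    B = complete[list(ids_b)].to_numpy(dtype=float)
    n1, n2 = A.shape[1], B.shape[1]
    d = n1 + n2 - 2
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    diff = mean_b - mean_a
    rss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + (
        (B - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = rss / d

    pos = s2 > 0
    if pos.any():
        z = np.log(s2[pos])
        evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, d / 2)) if len(z) > 1 else 0.0
        if prior_df is None:
            d0 = 2.0 * trigamma_inverse(evar) if evar > 0 else np.inf
        else:
            d0 = float(prior_df)
        if d0 <= 0:
            s0_2 = 0.0
        else:
            correction = (
                0.0
                if np.isinf(d0)
                else float(special.digamma(d0 / 2) - np.log(d0 / 2))
            )
            s0_2 = float(
                np.exp(np.mean(z) - special.digamma(d / 2) + np.log(d / 2) + correction)
            )
    else:  # all residual variances zero: no information to pool
        d0 = float(prior_df) if prior_df is not None else np.inf
        s0_2 = 0.0

    if d0 == 0:
        s2_post = s2
        df_total = float(d)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = float(d0 + d)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "mean_diff": diff,
            "t": t,
            "p": p,
            "q": q,
            "significant": p < p_threshold,
        },
        index=complete.index,
    )
    return DMPTable(table=table, prior_df=float(d0), prior_var=s0_2, residual_df=d)


# -------------------------------------------------------------- marker scores


def markers_from_gene_symbols(
    manifest: ProbeManifest,
    genes: Mapping[str, Sequence[str]],
    promoter_only: bool = True,
) -> dict[str, list[str]]:
    """Build a marker spec (name → probe ids) from gene symbols, keeping
    promoter-context probes (TSS200/TSS1500/FirstExon/UTR5) by default."""
    promoter = {"TSS200", "TSS1500", "FirstExon", "UTR5"}
    spec: dict[str, list[str]] = {}
    for name, symbols in genes.items():
        sel = manifest.df["gene_symbol"].isin(symbols)
        if promoter_only:
            sel &= manifest.df["gene_regions"].map(lambda g: bool(g & promoter))
        spec[name] = list(manifest.df.index[sel])
    return spec


def marker_region_score(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    marker_spec: Mapping[str, Sequence[str]],
    groups: pd.Series,
    compare: tuple[str, str] | None = None,
):
    """Mean β per sample over each marker's promoter probes, plus a
    two-sided rank-sum test between two groups per marker.

    Returns (scores markers × samples, tests DataFrame with group means and
    p per marker).  ``compare`` names the two group levels; defaults to the
    first two levels encountered.
    """
    groups = groups.reindex(beta.sample_ids)
    if compare is None:
        levels = [g for g in pd.unique(groups.dropna())]
        if len(levels) < 2:
            raise ValueError("need two groups to compare")
        compare = (levels[0], levels[1])
    score_rows, test_rows = {}, []
    for name, probes in marker_spec.items():
        probes = [p for p in probes if p in beta.probe_ids]
        if not probes:
            raise ValueError(f"marker {name!r} has no probes present in the matrix")
        manifest.subset(probes)  # validates presence in the manifest
        scores = beta.values.loc[probes].mean(axis=0)
        score_rows[name] = scores
        x = scores[groups == compare[0]].dropna().to_numpy()
        y = scores[groups == compare[1]].dropna().to_numpy()
        _, p = rank_sum_test(x, y)
        test_rows.append(
            {
                "marker": name,
                f"mean_{compare[0]}": float(np.mean(x)),
                f"mean_{compare[1]}": float(np.mean(y)),
                "p": p,
            }
        )
    scores_df = pd.DataFrame(score_rows).T
    tests_df = pd.DataFrame(test_rows).set_index("marker")
    return scores_df, tests_df
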