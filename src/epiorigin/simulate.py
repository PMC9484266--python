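"""Synthetic-data generators with known ground truth.

Every generator is a pure function of its config (including the seed) and
emulates the statistical structure the analysis assumes: a cohort of 12
healthy / 55 tumor methylomes whose tumors split into EpSC-like and
keratinocyte-like subclasses at ~914 UK and ~864 DK regulatory regions
(~2,925 / ~1,426 mapped probes); sparse single-cell methylomes at 0.14-6.88%
CpG coverage (mean 0.85%) with ~1% EpSC prevalence; mitotic-clock cohorts
with class-specific stem-cell division rates; expression/methylation
deconvolution references with planted markers; and overdispersed
region × cell accessibility counts with planted fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .clock import ClockModel
from .model import (
    BetaMatrix,
    ProbeManifest,
    RegionSet,
    ScMethProfile,
    Segmentation,
)
from .stratify import map_probes_to_regions

# per-stage RNG stream keys, so stages stay independent under one seed
_REGIONS, _BULK, _CELLS, _CLOCK, _DECONV, _ATAC = range(1, 7)

HEALTHY, EPSC_LIKE_TRUTH, KER_LIKE_TRUTH = "healthy", "epsc_like", "ker_like"
MARKER_GENES = ("MIR200C", "MIR205")
BACKGROUND = "background"
MARKER = "marker"


@dataclass
class SynthConfig:
    """Generator defaults emulate the study conditions; see docs/methods.md
    for the rationale behind each free parameter."""

    seed: int = 0

    # cohort
    n_healthy: int = 12
    n_tumor_epsc: int = 22
    n_tumor_ker: int = 33
    n_ak: int = 20  # entity labels (AK vs cSCC), orthogonal to subclass
    # regions & probes
    n_uk_regions: int = 914
    n_dk_regions: int = 864
    uk_region_length: int = 501
    dk_region_length: int = 301
    uk_probes_total: float = 2925.0  # expected mapped-probe totals
    dk_probes_total: float = 1426.0
    n_background_probes: int = 32_000
    n_sex_probes: int = 25
    n_snp_probes: int = 25
    n_marker_probes: int = 8  # per marker gene
    # bulk β structure: mean per (region class, sample class)
    beta_means: dict = field(
        default_factory=lambda: {
            ("UK", HEALTHY): 0.60,
            ("UK", KER_LIKE_TRUTH): 0.60,
            ("UK", EPSC_LIKE_TRUTH): 0.20,
            ("DK", HEALTHY): 0.25,
            ("DK", KER_LIKE_TRUTH): 0.25,
            ("DK", EPSC_LIKE_TRUTH): 0.70,
        }
    )
    background_mean: float = 0.5
    marker_mean_epsc: float = 0.80
    marker_mean_other: float = 0.20
    beta_precision: float = 30.0
    # single cells
    n_cells: int = 554
    epsc_cell_fraction: float = 0.01
    coverage_min: float = 0.0014
    coverage_max: float = 0.0688
    coverage_mean: float = 0.0085
    cell_call_means: dict = field(
        default_factory=lambda: {
            ("UK", "EpSC"): 0.05,
            ("UK", "Keratinocyte"): 0.95,
            ("DK", "EpSC"): 0.95,
            ("DK", "Keratinocyte"): 0.05,
        }
    )
    cell_background_mean: float = 0.5
    reads_per_coverage: float = 1.2e8  # maps coverage to a plausible read count
    # mitotic clock
    n_clock_cpgs: int = 500
    clock_delta_range: tuple = (0.0, 0.2)
    clock_p_range: tuple = (1e-4, 1e-3)
    clock_noise_precision: float = 200.0
    clock_rates: dict = field(
        default_factory=lambda: {
            HEALTHY: 10.35,
            EPSC_LIKE_TRUTH: 25.0,
            KER_LIKE_TRUTH: 39.7,
        }
    )
    clock_age_range: tuple = (30.0, 90.0)
    # deconvolution
    deconv_cell_types: tuple = ("Basal1", "Basal2", "Spinous", "Granular")
    deconv_markers_per_type: int = 20
    deconv_housekeeping: int = 10
    deconv_expr_high: float = 10.0
    deconv_expr_low: float = 0.5
    deconv_meth_low: float = 0.10
    deconv_meth_high: float = 0.80
    deconv_meth_jitter: float = 0.05
    deconv_bulk_noise_sd: float = 0.02
    deconv_n_mixtures: int = 50
    deconv_alpha_epsc: tuple = (6.0, 2.0, 2.0, 2.0)  # Basal1-heavy
    deconv_alpha_ker: tuple = (2.0, 2.0, 4.0, 4.0)
    # accessibility
    atac_cells_per_cluster: int = 200
    atac_n_null_regions: int = 1000
    atac_base_rate: float = 1.0
    atac_fold: float = 4.0
    atac_dispersion: float = 10.0
    atac_depth_sigma: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_tumor_epsc", "n_tumor_ker", "n_cells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.epsc_cell_fraction <= 1.0:
            raise ValueError("epsc_cell_fraction must lie in [0, 1]")
        if not (
            0.0 < self.coverage_min <= self.coverage_mean <= self.coverage_max <= 1.0
        ):
            raise ValueError("coverage range must satisfy 0 < min ≤ mean ≤ max ≤ 1")
        for mean in self.beta_means.values():
            if not 0.0 < mean < 1.0:
                raise ValueError("β means must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "beta_means" in raw:
            raw["beta_means"] = {
                (k.split("/")[0], k.split("/")[1]): v
                for k, v in raw["beta_means"].items()
            }
        if "cell_call_means" in raw:
            raw["cell_call_means"] = {
                (k.split("/")[0], k.split("/")[1]): v
                for k, v in raw["cell_call_means"].items()
            }
        return cls(**raw)


@dataclass
class GroundTruth:
    """Known truth accompanying each generated object."""

    sample_subclass: pd.Series | None = None  # per bulk sample
    cell_type: pd.Series | None = None  # per single cell
    region_class: pd.Series | None = None  # per region
    probe_class: pd.Series | None = None  # per probe: UK/DK/marker/background
    mixing_fractions: pd.DataFrame | None = None  # per deconvolution sample
    mixture_group: pd.Series | None = None
    mitotic_age: pd.Series | None = None
    ages: pd.Series | None = None
    clock_model: ClockModel | None = None
    atac_region_class: pd.Series | None = None


def _rng(cfg: SynthConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stage])


def _beta_draw(rng, mean, precision):
    mean = np.clip(np.asarray(mean, dtype=float), 1e-6, 1.0 - 1e-6)
    if np.isinf(precision):  # noiseless limit: means recovered exactly
        return mean.copy()
    return rng.beta(mean * precision, (1.0 - mean) * precision)


# ------------------------------------------------------ regions and manifest


def generate_regions_and_manifest(cfg: SynthConfig):
    """Lay out non-overlapping UK/DK regions over chr1-22, drop probes into
    them (Poisson counts tuned to the configured expected totals, with the
    UK→island/promoter and DK→open-sea/body context bias), and add
    background, marker-promoter, and flagged probes."""
    rng = _rng(cfg, _REGIONS)
    chroms = [f"chr{i}" for i in range(1, 23)]
    cursor = {c: 10_000 for c in chroms}
    gap = 10_000

    rows = []
    specs = [("UK", cfg.n_uk_regions, cfg.uk_region_length), (
        "DK", cfg.n_dk_regions, cfg.dk_region_length)]
    for cls, n, length in specs:
        for i in range(n):
            chrom = chroms[i % len(chroms)]
            start = cursor[chrom]
            rows.append((f"{cls}_{i + 1:05d}", chrom, start, start + length, cls))
        # advance cursors only after interleaving within the class
            cursor[chrom] = start + length + gap
    region_df = pd.DataFrame(
        rows, columns=["region_id", "chrom", "start", "end", "region_class"]
    ).set_index("region_id")
    regions = RegionSet(region_df)

    probe_rows = []  # (probe_id, chrom, pos, island, gene_regions, symbol, flags, class)
    pid = 0

    island_bias = {
        "UK": ([0.70, 0.15, 0.05, 0.10], [("TSS200",), ("TSS1500",), ("Body",), ("Intergenic",)], [0.45, 0.25, 0.20, 0.10]),
        "DK": ([0.10, 0.10, 0.10, 0.70], [("TSS200",), ("TSS1500",), ("Body",), ("Intergenic",)], [0.05, 0.05, 0.45, 0.45]),
    }
    relations = ["Island", "Shore", "Shelf", "OpenSea"]
    mean_per_region = {
        "UK": cfg.uk_probes_total / max(cfg.n_uk_regions, 1),
        "DK": cfg.dk_probes_total / max(cfg.n_dk_regions, 1),
    }
    for rid, row in region_df.iterrows():
        cls = row["region_class"]
        n_probes = min(rng.poisson(mean_per_region[cls]), row["end"] - row["start"])
        if n_probes == 0:
            continue
        pos = np.sort(
            rng.choice(row["end"] - row["start"], size=n_probes, replace=False)
        ) + row["start"]
        rel_p, ctx_choices, ctx_p = island_bias[cls]
        for p in pos:
            pid += 1
            probe_rows.append(
                (
                    f"cg{pid:08d}",
                    row["chrom"],
                    int(p),
                    relations[rng.choice(4, p=rel_p)],
                    frozenset(ctx_choices[rng.choice(4, p=ctx_p)]),
                    None,
                    frozenset(),
                    cls,
                )
            )

    # background probes live in a band beyond every region on each chromosome
    band_start = {c: cursor[c] + gap for c in chroms}
    band_width = max(50 * (cfg.n_background_probes // len(chroms) + 1), 10_000)
    bg_chrom_idx = rng.integers(0, len(chroms), size=cfg.n_background_probes)
    contexts = [("TSS1500",), ("Body",), ("Intergenic",), ("UTR5",), ("FirstExon",)]
    taken: dict[str, set] = {c: set() for c in chroms}
    for ci in bg_chrom_idx:
        chrom = chroms[ci]
        while True:
            p = int(band_start[chrom] + rng.integers(0, band_width))
            if p not in taken[chrom]:
                taken[chrom].add(p)
                break
        pid += 1
        probe_rows.append(
            (
                f"cg{pid:08d}",
                chrom,
                p,
                relations[rng.integers(0, 4)],
                frozenset(contexts[rng.integers(0, len(contexts))]),
                None,
                frozenset(),
                BACKGROUND,
            )
        )

    # marker promoter blocks (MIR200C/141 cluster and MIR205)
    marker_cursor = band_start["chr1"] + band_width + gap
    for gene in MARKER_GENES:
        for j in range(cfg.n_marker_probes):
            pid += 1
            probe_rows.append(
                (
                    f"cg{pid:08d}",
                    "chr1",
                    marker_cursor + 10 * j,
                    "Island",
                    frozenset({"TSS200"}),
                    gene,
                    frozenset(),
                    MARKER,
                )
            )
        marker_cursor += 5_000

    # flagged probes: excluded by filter_probes, present for realism
    for i in range(cfg.n_sex_probes):
        pid += 1
        probe_rows.append(
            (f"cg{pid:08d}", "chrX", 1_000 + 100 * i, "OpenSea",
             frozenset({"Intergenic"}), None, frozenset({"SexChrom"}), "flagged")
        )
    for i in range(cfg.n_snp_probes):
        pid += 1
        flag = "SNPAssociated" if i % 2 == 0 else "CrossReactive"
        probe_rows.append(
            (f"cg{pid:08d}", "chr2", band_start["chr2"] + band_width + gap + 100 * i,
             "OpenSea", frozenset({"Intergenic"}), None, frozenset({flag}), "flagged")
        )

    probe_df = pd.DataFrame(
        probe_rows,
        columns=[
            "probe_id", "chrom", "pos", "island_relation", "gene_regions",
            "gene_symbol", "flags", "probe_class",
        ],
    ).set_index("probe_id")
    manifest = ProbeManifest.from_frame(probe_df.drop(columns="probe_class"))
    truth = GroundTruth(
        region_class=region_df["region_class"].copy(),
        probe_class=probe_df["probe_class"].copy(),
    )
    return regions, manifest, truth


def _probe_classes(manifest: ProbeManifest, regions: RegionSet) -> pd.Series:
    """Per-probe class (UK/DK/marker/background) derived by interval
    mapping, so generators agree exactly with the analysis-side mapping."""
    prmap = map_probes_to_regions(manifest, regions)
    cls = pd.Series(BACKGROUND, index=manifest.df.index)
    for rc in ("UK", "DK"):
        cls.loc[prmap.probes_for_class(rc)] = rc
    cls.loc[manifest.df["gene_symbol"].isin(MARKER_GENES)] = MARKER
    return cls


# -------------------------------------------------------------------- bulk β


def generate_bulk(cfg: SynthConfig, regions: RegionSet, manifest: ProbeManifest):
    """Bulk cohort β: per-probe beta noise around the class-mean table.

    Healthy and keratinocyte-like samples share means at both region
    classes; EpSC-like differs (hypermethylated DK/enhancer regions,
    hypomethylated UK regions, hypermethylated marker-miR promoters)."""
    rng = _rng(cfg, _BULK)
    probe_class = _probe_classes(manifest, regions)

    healthy_ids = [f"H{i + 1:02d}" for i in range(cfg.n_healthy)]
    n_tumors = cfg.n_tumor_epsc + cfg.n_tumor_ker
    tumor_ids = [f"T{i + 1:02d}" for i in range(n_tumors)]
    subclass = np.array(
        [EPSC_LIKE_TRUTH] * cfg.n_tumor_epsc + [KER_LIKE_TRUTH] * cfg.n_tumor_ker
    )
    rng.shuffle(subclass)
    sample_class = pd.Series(
        [HEALTHY] * cfg.n_healthy + list(subclass), index=healthy_ids + tumor_ids
    )
    entity = np.array(
        ["AK"] * min(cfg.n_ak, n_tumors) + ["cSCC"] * max(n_tumors - cfg.n_ak, 0)
    )
    rng.shuffle(entity)
    groups = pd.Series(
        ["Healthy"] * cfg.n_healthy + list(entity), index=sample_class.index
    )

    mean_mat = np.empty((len(manifest), len(sample_class)))
    pc = probe_class.to_numpy()
    for j, sc in enumerate(sample_class):
        col = np.full(len(manifest), cfg.background_mean)
        for rc in ("UK", "DK"):
            col[pc == rc] = cfg.beta_means[(rc, sc)]
        col[pc == MARKER] = (
            cfg.marker_mean_epsc if sc == EPSC_LIKE_TRUTH else cfg.marker_mean_other
        )
        col[pc == "flagged"] = cfg.background_mean
        mean_mat[:, j] = col
    values = _beta_draw(rng, mean_mat, cfg.beta_precision)
    beta = BetaMatrix(
        pd.DataFrame(values, index=manifest.df.index, columns=sample_class.index),
        groups,
    )
    truth = GroundTruth(sample_subclass=sample_class, probe_class=probe_class)
    return beta, truth


# -------------------------------------------------------------- single cells


def generate_cells(cfg: SynthConfig, manifest: ProbeManifest, regions: RegionSet):
    """Sparse binary single-cell methylomes over the manifest universe.

    Cell type is EpSC with probability ``epsc_cell_fraction``; covered
    positions are sampled per a beta-distributed coverage fraction on
    [coverage_min, coverage_max]; each covered probe's call is Bernoulli
    with the cell-type-specific mean of the probe's region class.
    """
    rng = _rng(cfg, _CELLS)
    probe_class = _probe_classes(manifest, regions).to_numpy()
    n_probes = len(manifest)
    pos_index = pd.MultiIndex.from_arrays(
        [manifest.df["chrom"], manifest.df["pos"]], names=("chrom", "pos")
    )

    degenerate = cfg.coverage_max == cfg.coverage_min
    if not degenerate:
        mu = (cfg.coverage_mean - cfg.coverage_min) / (
            cfg.coverage_max - cfg.coverage_min
        )
        mu = min(max(mu, 1e-6), 1.0 - 1e-6)
        a = 2.0
        b = a * (1.0 - mu) / mu

    profiles, types = [], []
    for i in range(cfg.n_cells):
        cell_id = f"C{i + 1:04d}"
        ctype = "EpSC" if rng.random() < cfg.epsc_cell_fraction else "Keratinocyte"
        coverage = (
            cfg.coverage_min
            if degenerate
            else cfg.coverage_min
            + rng.beta(a, b) * (cfg.coverage_max - cfg.coverage_min)
        )
        n_cov = max(int(round(coverage * n_probes)), 1)
        idx = np.sort(rng.choice(n_probes, size=n_cov, replace=False))
        means = np.full(n_cov, cfg.cell_background_mean)
        pc = probe_class[idx]
        for rc in ("UK", "DK"):
            means[pc == rc] = cfg.cell_call_means[(rc, ctype)]
        calls = (rng.random(n_cov) < means).astype(np.int8)
        profiles.append(
            ScMethProfile(
                cell_id=cell_id,
                calls=pd.Series(calls, index=pos_index[idx]),
                n_reads=int(round(coverage * cfg.reads_per_coverage)),
                coverage_fraction=n_cov / n_probes,
            )
        )
        types.append(ctype)
    truth = GroundTruth(
        cell_type=pd.Series(types, index=[p.cell_id for p in profiles])
    )
    return profiles, truth


def generate_segmentation(
    cfg: SynthConfig, regions: RegionSet, manifest: ProbeManifest
) -> Segmentation:
    """Chromatin-state segmentation consistent with the planted biology:
    UK regions become promoter states (1-2), DK regions strong-enhancer
    states (4-5), and the background probe band is tiled with 1 kb windows
    cycling through the remaining states."""
    rows = []
    for i, (rid, row) in enumerate(regions.df.iterrows()):
        if row["region_class"] == "UK":
            state = 1 + i % 2
        else:
            state = 4 + i % 2
        rows.append((row["chrom"], row["start"], row["end"], state))
    in_region = _probe_classes(manifest, regions).isin(["UK", "DK"])
    bg = manifest.df.loc[~in_region & ~manifest.df["chrom"].isin(["chrX", "chrY"])]
    other_states = [3, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
    for chrom, sub in bg.groupby("chrom"):
        lo, hi = int(sub["pos"].min()), int(sub["pos"].max()) + 1
        edges = np.arange(lo, hi + 1000, 1000)
        for w, start in enumerate(edges[:-1]):
            rows.append(
                (chrom, int(start), int(edges[w + 1]), other_states[w % len(other_states)])
            )
    return Segmentation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    )


# --------------------------------------------------------------------- clock


def generate_clock_samples(cfg: SynthConfig):
    """Clock-CpG β for a cohort with class-specific division rates.

    β_i = δ_i + (1 − δ_i)(1 − (1 − p_i)^T_s) + bounded beta noise, with
    T_s = rate(class) × age_s.  Returns (BetaMatrix, ages, GroundTruth
    carrying the true mitotic ages and the generating ClockModel)."""
    rng = _rng(cfg, _CLOCK)
    n = cfg.n_clock_cpgs
    delta = rng.uniform(*cfg.clock_delta_range, size=n)
    lo, hi = cfg.clock_p_range
    p = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    cpg_ids = [f"clk{i + 1:05d}" for i in range(n)]
    model = ClockModel(pd.DataFrame({"delta": delta, "p": p}, index=pd.Index(cpg_ids, name="cpg_id")))

    classes = (
        [HEALTHY] * cfg.n_healthy
        + [EPSC_LIKE_TRUTH] * cfg.n_tumor_epsc
        + [KER_LIKE_TRUTH] * cfg.n_tumor_ker
    )
    sample_ids = [f"S{i + 1:03d}" for i in range(len(classes))]
    ages = pd.Series(
        rng.uniform(*cfg.clock_age_range, size=len(classes)), index=sample_ids, name="age"
    )
    true_t = pd.Series(
        [cfg.clock_rates[c] * ages.iloc[i] for i, c in enumerate(classes)],
        index=sample_ids,
        name="mitotic_age",
    )
    values = np.empty((n, len(sample_ids)))
    for j, t in enumerate(true_t):
        mean = delta + (1.0 - delta) * (1.0 - (1.0 - p) ** t)
        values[:, j] = (
            _beta_draw(rng, mean, cfg.clock_noise_precision)
            if cfg.clock_noise_precision < np.inf
            else mean
        )
    beta = BetaMatrix(pd.DataFrame(values, index=cpg_ids, columns=sample_ids))
    truth = GroundTruth(
        sample_subclass=pd.Series(classes, index=sample_ids),
        mitotic_age=true_t,
        ages=ages,
        clock_model=model,
    )
    return beta, ages, truth


# ------------------------------------------------------------- deconvolution


def generate_deconv_inputs(cfg: SynthConfig):
    """Planted deconvolution problem.

    Returns (expression genes × types, paired methylation genes × types,
    bulk β markers × samples, GroundTruth with the mixing fractions).
    Marker genes are high in exactly their type; promoter methylation is
    anti-correlated (low where expressed).  Bulk β are simplex mixtures of
    the methylation columns plus clipped Gaussian noise; the first half of
    the mixtures is drawn basal-heavy (EpSC-like), the second half
    suprabasal-heavy (keratinocyte-like).
    """
    rng = _rng(cfg, _DECONV)
    types = list(cfg.deconv_cell_types)
    genes, expr_rows, meth_rows = [], [], []
    for t_idx, ctype in enumerate(types):
        for j in range(cfg.deconv_markers_per_type):
            genes.append(f"G_{ctype}_{j + 1:03d}")
            e = np.full(len(types), cfg.deconv_expr_low)
            e *= rng.uniform(0.5, 1.5, size=len(types))
            e[t_idx] = cfg.deconv_expr_high * rng.uniform(0.8, 1.2)
            expr_rows.append(e)
            m = np.full(len(types), cfg.deconv_meth_high)
            m[t_idx] = cfg.deconv_meth_low
            m = np.clip(
                m + rng.uniform(-cfg.deconv_meth_jitter, cfg.deconv_meth_jitter, len(types)),
                0.0,
                1.0,
            )
            meth_rows.append(m)
    for j in range(cfg.deconv_housekeeping):  # broadly expressed, never markers
        genes.append(f"G_HK_{j + 1:03d}")
        expr_rows.append(cfg.deconv_expr_high * rng.uniform(0.8, 1.2, size=len(types)))
        meth_rows.append(np.full(len(types), cfg.deconv_meth_low))
    expr = pd.DataFrame(expr_rows, index=genes, columns=types)
    paired = pd.DataFrame(meth_rows, index=genes, columns=types)

    n_mix = cfg.deconv_n_mixtures
    n_epsc = n_mix // 2
    w_epsc = rng.dirichlet(cfg.deconv_alpha_epsc, size=n_epsc)
    w_ker = rng.dirichlet(cfg.deconv_alpha_ker, size=n_mix - n_epsc)
    w = np.vstack([w_epsc, w_ker])
    sample_ids = [f"M{i + 1:03d}" for i in range(n_mix)]
    group = pd.Series(
        [EPSC_LIKE_TRUTH] * n_epsc + [KER_LIKE_TRUTH] * (n_mix - n_epsc),
        index=sample_ids,
    )
    marker_meth = paired.loc[[g for g in genes if not g.startswith("G_HK_")]]
    bulk = marker_meth.to_numpy() @ w.T
    bulk = np.clip(
        bulk + rng.normal(0.0, cfg.deconv_bulk_noise_sd, size=bulk.shape), 0.0, 1.0
    )
    bulk_df = pd.DataFrame(bulk, index=marker_meth.index, columns=sample_ids)
    truth = GroundTruth(
        mixing_fractions=pd.DataFrame(w, index=sample_ids, columns=types),
        mixture_group=group,
    )
    return expr, paired, bulk_df, truth


# -------------------------------------------------------------- accessibility


def generate_atac(cfg: SynthConfig, regions: RegionSet):
    """Overdispersed region × cell accessibility counts with planted
    class-specific fold changes: UK regions elevated in the
    undifferentiated cluster (cluster2), DK in the differentiated one
    (cluster3), plus flat null regions."""
    rng = _rng(cfg, _ATAC)
    if cfg.atac_cells_per_cluster < 1:
        raise ValueError("each cluster needs at least one cell")
    region_ids = list(regions.df.index) + [
        f"NULL_{i + 1:05d}" for i in range(cfg.atac_n_null_regions)
    ]
    region_cls = pd.Series(
        list(regions.df["region_class"]) + ["null"] * cfg.atac_n_null_regions,
        index=region_ids,
    )
    n_per = cfg.atac_cells_per_cluster
    cell_ids = [f"A{i + 1:04d}" for i in range(2 * n_per)]
    labels = pd.Series(["cluster2"] * n_per + ["cluster3"] * n_per, index=cell_ids)

    rate = np.full((len(region_ids), 2 * n_per), cfg.atac_base_rate)
    cls_arr = region_cls.to_numpy()
    rate[np.ix_(cls_arr == "UK", np.arange(n_per))] *= cfg.atac_fold
    rate[np.ix_(cls_arr == "DK", np.arange(n_per, 2 * n_per))] *= cfg.atac_fold
    depth = rng.lognormal(0.0, cfg.atac_depth_sigma, size=2 * n_per)
    lam = rate * depth
    if cfg.atac_dispersion < np.inf:  # gamma-Poisson overdispersion
        lam = lam * rng.gamma(cfg.atac_dispersion, 1.0 / cfg.atac_dispersion, size=lam.shape)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=region_ids, columns=cell_ids)
    truth = GroundTruth(atac_region_class=region_cls)
    return counts_df, labels, truth


# -------------------------------------------------------------- orchestration


def write_all(cfg: SynthConfig, outdir) -> None:
    """Generate every synthetic input and write the standard-format files
    plus ``truth.json`` (used by the CLI `simulate` command)."""
    import json

    from . import io as eio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions, manifest, truth_r = generate_regions_and_manifest(cfg)
    bulk, truth_b = generate_bulk(cfg, regions, manifest)
    cells, truth_c = generate_cells(cfg, manifest, regions)
    seg = generate_segmentation(cfg, regions, manifest)
    clock_beta, ages, truth_k = generate_clock_samples(cfg)
    expr, paired, mix_bulk, truth_d = generate_deconv_inputs(cfg)
    atac_counts, atac_labels, truth_a = generate_atac(cfg, regions)

    eio.write_regions_bed(regions, outdir / "regions.bed")
    eio.write_manifest(manifest, outdir / "manifest.tsv")
    eio.write_beta(bulk, outdir / "beta.tsv", outdir / "sample_groups.json")
    eio.write_scmeth(cells, outdir / "cells", outdir / "cells_meta.tsv")
    eio.write_segmentation_bed(seg, outdir / "segmentation.bed")
    eio.write_beta(clock_beta, outdir / "clock_beta.tsv")
    truth_k.clock_model.write_tsv(outdir / "clock_params.tsv")
    ages.rename("age").to_csv(outdir / "ages.tsv", sep="\t", index_label="sample_id")
    expr.to_csv(outdir / "deconv_expression.tsv", sep="\t", index_label="gene")
    paired.to_csv(outdir / "deconv_paired_methylation.tsv", sep="\t", index_label="gene")
    mix_bulk.to_csv(outdir / "deconv_bulk_beta.tsv", sep="\t", index_label="gene")
    atac_counts.to_csv(outdir / "atac_counts.tsv", sep="\t", index_label="region_id")
    atac_labels.rename("cluster").to_csv(
        outdir / "atac_cells.tsv", sep="\t", index_label="cell_id"
    )
    truth = {
        "sample_subclass": truth_b.sample_subclass.to_dict(),
        "cell_type": truth_c.cell_type.to_dict(),
        "region_class": truth_r.region_class.to_dict(),
        "mitotic_age": truth_k.mitotic_age.to_dict(),
        "mixing_fractions": truth_d.mixing_fractions.to_dict(),
        "atac_region_class": truth_a.atac_region_class.to_dict(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
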