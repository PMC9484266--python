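"""Core domain containers.

Conventions used throughout the package:

* all genomic coordinates are 0-based, half-open ``[start, end)``;
* methylation fractions (β values) live in ``[0, 1]`` with ``NaN`` meaning
  "not measured" — a missing value is never conflated with hypomethylation;
* single-cell methylation calls are binary (0 = unmethylated, 1 = methylated)
  and sparse over the CpG universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
GENE_REGIONS = ("TSS1500", "TSS200", "FirstExon", "UTR5", "Body", "Intergenic")
PROBE_FLAGS = ("SexChrom", "SNPAssociated", "CrossReactive")
SAMPLE_GROUPS = ("Healthy", "AK", "cSCC", "BD", "BCC", "SK", "Other")
REGION_CLASSES = ("UK", "DK")
SEX_CHROMS = frozenset({"chrX", "chrY"})
N_CHROMHMM_STATES = 15


def _check_disjoint(df: pd.DataFrame, what: str) -> None:
    """Raise if any two intervals of ``df`` (chrom/start/end) overlap."""
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        bad = s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]
        if bad.any():
            raise ValueError(f"{what}: overlapping intervals on {chrom}")


@dataclass
class ProbeManifest:
    """Array probe annotations: the universe against which regions and
    filters act.

    ``df`` is indexed by probe id with columns ``chrom``, ``pos`` (0-based
    CpG coordinate), ``island_relation`` (one of Island/Shore/Shelf/OpenSea),
    ``gene_regions`` (frozenset of gene-region contexts), ``gene_symbol``
    (optional) and ``flags`` (frozenset drawn from SexChrom / SNPAssociated /
    CrossReactive).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "island_relation", "gene_regions", "flags"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if not self.df.index.is_unique:
            raise ValueError("probe ids must be unique")
        if (self.df["pos"] < 0).any():
            raise ValueError("probe positions must be non-negative")
        bad = ~self.df["island_relation"].isin(ISLAND_RELATIONS)
        if bad.any():
            raise ValueError(
                f"unknown island relation: {self.df.loc[bad, 'island_relation'].unique()!r}"
            )
        if "gene_symbol" not in self.df.columns:
            self.df = self.df.assign(gene_symbol=None)
        # SexChrom flag must mirror the chromosome, in both directions
        is_sex = self.df["chrom"].isin(SEX_CHROMS)
        has_flag = self.df["flags"].map(lambda f: "SexChrom" in f)
        if (is_sex != has_flag).any():
            raise ValueError("SexChrom flag inconsistent with chromosome")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeManifest":
        """Build a manifest, filling the SexChrom flag from the chromosome."""
        df = df.copy()
        if "flags" not in df.columns:
            df["flags"] = [frozenset() for _ in range(len(df))]
        is_sex = df["chrom"].isin(SEX_CHROMS)
        df["flags"] = [
            frozenset(f) | {"SexChrom"} if sex else frozenset(f) - {"SexChrom"}
            for f, sex in zip(df["flags"], is_sex)
        ]
        return cls(df)

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def positions(self) -> pd.DataFrame:
        return self.df[["chrom", "pos"]]

    def subset(self, probe_ids) -> "ProbeManifest":
        missing = pd.Index(probe_ids).difference(self.df.index)
        if len(missing):
            raise KeyError(f"probes absent from manifest: {list(missing[:10])}")
        return ProbeManifest(self.df.loc[probe_ids])

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class RegionSet:
    """Labeled genomic intervals, class UK (undifferentiated-keratinocyte-
    specific) or DK (differentiated-keratinocyte-specific).

    Regions of the same class must be non-overlapping so that a probe maps
    to at most one region per class.
    """

    df: pd.DataFrame  # index region_id; columns chrom, start, end, region_class

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "region_class"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"region set missing columns: {sorted(missing)}")
        if not self.df.index.is_unique:
            raise ValueError("region ids must be unique")
        if (self.df["start"] >= self.df["end"]).any():
            bad = self.df.index[self.df["start"] >= self.df["end"]]
            raise ValueError(f"empty or inverted regions: {list(bad[:10])}")
        bad_cls = ~self.df["region_class"].isin(REGION_CLASSES)
        if bad_cls.any():
            raise ValueError(
                f"unknown region class: {self.df.loc[bad_cls, 'region_class'].unique()!r}"
            )
        for cls in REGION_CLASSES:
            _check_disjoint(self.df[self.df["region_class"] == cls], f"{cls} regions")

    def by_class(self, region_class: str) -> "RegionSet":
        if region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {region_class!r}")
        return RegionSet(self.df[self.df["region_class"] == region_class])

    @property
    def region_ids(self) -> pd.Index:
        return self.df.index

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class BetaMatrix:
    """Probes × samples methylation fractions with per-sample group labels.

    ``values`` is a float DataFrame in [0, 1] (NaN allowed); ``sample_group``
    maps every sample to one of the cohort groups (Healthy, AK, cSCC, ...).
    """

    values: pd.DataFrame
    sample_group: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v, initial=0.0) < 0 or np.nanmax(v, initial=0.0) > 1:
                raise ValueError("β values must lie in [0, 1]")
        if self.sample_group is None:
            self.sample_group = pd.Series("Other", index=self.values.columns)
        else:
            self.sample_group = self.sample_group.reindex(self.values.columns)
            unknown = ~self.sample_group.dropna().isin(SAMPLE_GROUPS)
            if unknown.any():
                raise ValueError(
                    f"unknown sample groups: {self.sample_group.dropna()[unknown].unique()!r}"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[probe_ids], self.sample_group)

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.values[list(sample_ids)], self.sample_group.loc[list(sample_ids)])


@dataclass
class IntensityPair:
    """Raw methylated/unmethylated signal intensities, probes × samples."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.methylated.index.equals(self.unmethylated.index) or not (
            self.methylated.columns.equals(self.unmethylated.columns)
        ):
            raise ValueError("methylated/unmethylated matrices must be aligned")
        if (self.methylated.to_numpy() < 0).any() or (
            self.unmethylated.to_numpy() < 0
        ).any():
            raise ValueError("intensities must be non-negative")


@dataclass
class Segmentation:
    """Chromatin-state segmentation: non-overlapping intervals carrying an
    HMM state in 1..15."""

    df: pd.DataFrame  # columns chrom, start, end, state

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "state"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"segmentation missing columns: {sorted(missing)}")
        states = self.df["state"]
        if ((states < 1) | (states > N_CHROMHMM_STATES)).any():
            raise ValueError(f"states must lie in 1..{N_CHROMHMM_STATES}")
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("empty or inverted segmentation intervals")
        _check_disjoint(self.df, "segmentation")


@dataclass
class ScMethProfile:
    """One cell's sparse binary methylation calls.

    ``calls`` is an int8 Series of {0, 1} indexed by (chrom, pos);
    ``coverage_fraction`` is |calls| / |CpG universe|.
    """

    cell_id: str
    calls: pd.Series
    n_reads: int
    coverage_fraction: float

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if len(vals) and not np.isin(vals, (0, 1)).all():
            raise ValueError(f"cell {self.cell_id}: calls must be binary")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must lie in [0, 1]")

    @property
    def n_calls(self) -> int:
        return len(self.calls)
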