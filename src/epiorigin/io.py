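"""Readers and writers for the plain-text formats the pipeline consumes.

β matrices and manifests travel as TSV, regions and segmentations as BED
(0-based half-open), per-cell methylation calls as one TSV per cell plus a
cells-metadata TSV, and sample groups as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    REGION_CLASSES,
    BetaMatrix,
    ProbeManifest,
    RegionSet,
    ScMethProfile,
    Segmentation,
)

DEFAULT_MIN_READS = 100_000  # single-cell sequencing-read QC threshold


class BedParseError(ValueError):
    pass


# ---------------------------------------------------------------- β matrices


def read_beta(path, groups_path=None) -> BetaMatrix:
    """Read a probes × samples β TSV (first column ``probe_id``); sample
    groups come from an optional JSON sidecar mapping sample id → group."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    groups = None
    if groups_path is not None:
        with open(groups_path) as fh:
            mapping = json.load(fh)
        groups = pd.Series(mapping).reindex(values.columns)
    return BetaMatrix(values, groups)


def write_beta(beta: BetaMatrix, path, groups_path=None) -> None:
    beta.values.to_csv(path, sep="\t", index_label="probe_id")
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            json.dump(beta.sample_group.to_dict(), fh, indent=1)


# ----------------------------------------------------------------- manifests


def read_manifest(path, one_based: bool = False) -> ProbeManifest:
    """Read a probe manifest TSV.

    Columns: probe_id, chrom, pos, island_relation, gene_regions
    (``;``-separated), gene_symbol, flags (``;``-separated).  Pass
    ``one_based=True`` for manifests delivered in 1-based coordinates; they
    are converted to the package's 0-based convention on load.
    """
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    if one_based:
        df["pos"] = df["pos"] - 1
    df["gene_regions"] = [
        frozenset(str(s).split(";")) if isinstance(s, str) and s else frozenset()
        for s in df.get("gene_regions", pd.Series("", index=df.index))
    ]
    df["flags"] = [
        frozenset(str(s).split(";")) if isinstance(s, str) and s else frozenset()
        for s in df.get("flags", pd.Series("", index=df.index))
    ]
    if "gene_symbol" in df.columns:
        df["gene_symbol"] = df["gene_symbol"].where(df["gene_symbol"].notna(), None)
    return ProbeManifest.from_frame(df)


def write_manifest(manifest: ProbeManifest, path) -> None:
    df = manifest.df.copy()
    df["gene_regions"] = df["gene_regions"].map(lambda s: ";".join(sorted(s)))
    df["flags"] = df["flags"].map(lambda s: ";".join(sorted(s)))
    df.to_csv(path, sep="\t", index_label="probe_id")


# ----------------------------------------------------------------------- BED


def _parse_bed_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: empty or inverted interval [{start}, {end})"
                )
            yield lineno, fields[0], start, end, fields[3:]


def read_regions_bed(path) -> RegionSet:
    """Read a region BED.  Column 4 is either the region class (UK/DK; ids
    are auto-generated) or the region id, with the class in column 5."""
    ids, chroms, starts, ends, classes = [], [], [], [], []
    for lineno, chrom, start, end, rest in _parse_bed_lines(path):
        if len(rest) >= 2 and rest[1] in REGION_CLASSES:
            rid, cls = rest[0], rest[1]
        elif rest and rest[0] in REGION_CLASSES:
            rid, cls = f"{rest[0]}_{lineno:06d}", rest[0]
        else:
            raise BedParseError(
                f"{path}:{lineno}: no region class (UK/DK) in columns 4-5"
            )
        ids.append(rid)
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
        classes.append(cls)
    df = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "region_class": classes},
        index=pd.Index(ids, name="region_id"),
    )
    return RegionSet(df)


def write_regions_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for rid, row in regions.df.iterrows():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{rid}\t{row.region_class}\n"
            )


def read_segmentation_bed(path) -> Segmentation:
    """Read a ChromHMM-style segmentation BED; column 4 holds the state,
    either as a bare integer or a label such as ``4_Strong_Enhancer``."""
    rows = []
    for lineno, chrom, start, end, rest in _parse_bed_lines(path):
        if not rest:
            raise BedParseError(f"{path}:{lineno}: segmentation needs a state column")
        token = rest[0].split("_")[0].lstrip("E")
        try:
            state = int(token)
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: unparseable state {rest[0]!r}") from exc
        rows.append((chrom, start, end, state))
    return Segmentation(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))


def write_segmentation_bed(seg: Segmentation, path) -> None:
    seg.df[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# --------------------------------------------------------------- single cells


def read_scmeth(
    calls_dir,
    meta_path,
    universe: pd.MultiIndex,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[ScMethProfile]:
    """Read per-cell methylation-call TSVs and apply the read-count QC.

    ``calls_dir`` holds one ``<cell_id>.tsv`` per cell with columns
    chrom, pos, call (0/1); ``meta_path`` is a TSV with columns cell_id,
    n_reads.  Cells with fewer than ``min_reads`` sequencing reads are
    dropped.  ``universe`` (a (chrom, pos) MultiIndex) defines the CpG
    space used for the coverage fraction.
    """
    calls_dir = Path(calls_dir)
    meta = pd.read_csv(meta_path, sep="\t")
    profiles = []
    for _, row in meta.iterrows():
        cell_id, n_reads = str(row["cell_id"]), int(row["n_reads"])
        if n_reads < min_reads:
            continue
        table = pd.read_csv(calls_dir / f"{cell_id}.tsv", sep="\t")
        calls_arr = table["call"].to_numpy()
        if len(calls_arr) and not np.isin(calls_arr, (0, 1)).all():
            raise ValueError(f"cell {cell_id}: non-binary methylation call")
        calls = pd.Series(
            calls_arr.astype(np.int8),
            index=pd.MultiIndex.from_arrays(
                [table["chrom"], table["pos"]], names=("chrom", "pos")
            ),
        )
        profiles.append(
            ScMethProfile(
                cell_id=cell_id,
                calls=calls,
                n_reads=n_reads,
                coverage_fraction=len(calls) / len(universe),
            )
        )
    return profiles


def write_scmeth(profiles: list[ScMethProfile], calls_dir, meta_path) -> None:
    calls_dir = Path(calls_dir)
    calls_dir.mkdir(parents=True, exist_ok=True)
    meta = []
    for p in profiles:
        table = p.calls.rename("call").reset_index()
        table.to_csv(calls_dir / f"{p.cell_id}.tsv", sep="\t", index=False)
        meta.append({"cell_id": p.cell_id, "n_reads": p.n_reads})
    pd.DataFrame(meta).to_csv(meta_path, sep="\t", index=False)
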