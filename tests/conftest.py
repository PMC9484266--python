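import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from epiorigin import simulate as sim
from epiorigin import stratify as strat
from epiorigin.model import BetaMatrix, ProbeManifest, RegionSet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def toy_manifest(rows):
    """rows: (probe_id, chrom, pos[, island, gene_regions, symbol, flags])."""
    full = []
    for r in rows:
        r = list(r) + [None] * (7 - len(r))
        full.append(
            {
                "probe_id": r[0],
                "chrom": r[1],
                "pos": r[2],
                "island_relation": r[3] or "OpenSea",
                "gene_regions": frozenset(r[4] or ()),
                "gene_symbol": r[5],
                "flags": frozenset(r[6] or ()),
            }
        )
    return ProbeManifest.from_frame(pd.DataFrame(full).set_index("probe_id"))


def toy_regions(rows):
    """rows: (region_id, chrom, start, end, region_class)."""
    df = pd.DataFrame(
        rows, columns=["region_id", "chrom", "start", "end", "region_class"]
    ).set_index("region_id")
    return RegionSet(df)


@pytest.fixture(scope="session")
def cfg():
    return sim.SynthConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(cfg):
    """One default synthetic cohort shared across read-only tests."""
    regions, manifest, truth_r = sim.generate_regions_and_manifest(cfg)
    bulk, truth_b = sim.generate_bulk(cfg, regions, manifest)
    prmap = strat.map_probes_to_regions(manifest, regions)
    return {
        "cfg": cfg,
        "regions": regions,
        "manifest": manifest,
        "bulk": bulk,
        "prmap": prmap,
        "truth_regions": truth_r,
        "truth_bulk": truth_b,
        "healthy_ids": [s for s in bulk.sample_ids if truth_b.sample_subclass[s] == "healthy"],
    }
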