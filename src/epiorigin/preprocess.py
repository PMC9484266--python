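"""Probe-level preprocessing: β computation and probe filtering."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import BetaMatrix, IntensityPair, ProbeManifest

BETA_OFFSET = 100.0  # stabilising offset in the β denominator

EXCLUDE_FLAGS = frozenset({"SexChrom", "SNPAssociated", "CrossReactive"})


def beta_from_intensities(
    intensities: IntensityPair, sample_group: pd.Series | None = None
) -> BetaMatrix:
    """β = M / (M + U + 100) per probe and sample.

    The offset keeps the denominator away from zero at low signal, so β is
    bounded strictly below 1 for finite intensities and is 0 when both
    channels read 0.
    """
    m = intensities.methylated.astype(float)
    u = intensities.unmethylated.astype(float)
    beta = m / (m + u + BETA_OFFSET)
    return BetaMatrix(beta, sample_group)


def filter_probes(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    detection_fail: pd.Series | None = None,
) -> BetaMatrix:
    """Drop sex-chromosome, SNP-associated, cross-reactive and
    detection-failed probes; probe order is preserved.

    ``detection_fail`` is an optional boolean Series (per probe) marking
    low-detected probes, precomputed upstream.
    """
    missing = beta.probe_ids.difference(manifest.df.index)
    if len(missing):
        raise KeyError(f"probes absent from manifest: {list(missing[:10])}")
    flags = manifest.df.loc[beta.probe_ids, "flags"]
    keep = flags.map(lambda f: not (f & EXCLUDE_FLAGS)).to_numpy()
    if detection_fail is not None:
        failed = detection_fail.reindex(beta.probe_ids, fill_value=False).astype(bool)
        keep &= ~failed.to_numpy()
    return BetaMatrix(beta.values.loc[keep], beta.sample_group)
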