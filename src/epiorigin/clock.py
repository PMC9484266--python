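"""Mitotic epigenetic clock: cumulative stem-cell divisions from clock-CpG
methylation.

The model: each clock CpG i starts at a ground-state methylation δ_i and
gains methylation with probability p_i per stem-cell division, so after T
divisions its expected β is

    β_i(T) = δ_i + (1 − δ_i) · (1 − (1 − p_i)^T).

T is estimated per sample by bounded least squares over the clock CpGs; the
per-CpG closed-form inversion is exposed for diagnostics.  The stem-cell
division rate (SCDR) divides the mitotic age by chronological age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .model import BetaMatrix

MIN_CLOCK_CPGS = 10


@dataclass
class ClockModel:
    """Per-CpG ground-state methylation δ ∈ [0, 1) and per-division gain
    probability p ∈ (0, 1)."""

    params: pd.DataFrame  # index cpg_id; columns delta, p

    def __post_init__(self) -> None:
        d = self.params["delta"].to_numpy()
        p = self.params["p"].to_numpy()
        if ((d < 0) | (d >= 1)).any():
            raise ValueError("delta must lie in [0, 1)")
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("p must lie in (0, 1)")

    @classmethod
    def read_tsv(cls, path) -> "ClockModel":
        return cls(pd.read_csv(path, sep="\t", index_col="cpg_id"))

    def write_tsv(self, path) -> None:
        self.params.to_csv(path, sep="\t", index_label="cpg_id")

    def expected_beta(self, T: float) -> np.ndarray:
        d = self.params["delta"].to_numpy()
        p = self.params["p"].to_numpy()
        return d + (1.0 - d) * (1.0 - (1.0 - p) ** T)


@dataclass
class MitoticAgeEstimate:
    """Per-sample mitotic age (cumulative divisions) with fit diagnostics."""

    table: pd.DataFrame  # columns: mitotic_age, residual, n_cpgs, at_floor


def invert_single(beta: float, delta: float, p: float) -> float:
    """Closed-form per-CpG inversion: the T at which the model mean equals
    ``beta``; β below the ground state clamps to 0."""
    excess = max(beta - delta, 0.0)
    frac = excess / (1.0 - delta)
    if frac >= 1.0:
        return np.inf
    return float(np.log1p(-frac) / np.log1p(-p))


def _fit_one(beta: np.ndarray, delta: np.ndarray, p: np.ndarray):
    log1mp = np.log1p(-p)

    def ssr(T: float) -> float:
        model = delta + (1.0 - delta) * (1.0 - np.exp(T * log1mp))
        return float(((beta - model) ** 2).sum())

    if (beta <= delta).all():
        return 0.0, ssr(0.0), True
    finite = [
        invert_single(b, d, pp)
        for b, d, pp in zip(beta, delta, p)
        if invert_single(b, d, pp) < np.inf
    ]
    hi = max(2.0 * max(finite, default=1.0), 100.0)
    # coarse grid guards against the (rare) multi-modal SSR, Brent refines
    grid = np.linspace(0.0, hi, 200)
    best = grid[int(np.argmin([ssr(t) for t in grid]))]
    span = hi / 199.0
    res = minimize_scalar(
        ssr,
        bounds=(max(best - span, 0.0), min(best + span, hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    t_hat, f_hat = float(res.x), float(res.fun)

    # Newton polish on dSSR/dT: Brent's bracketing stalls at sqrt(eps)
    # relative precision, which is too coarse at large T
    one_minus_d = 1.0 - delta
    for _ in range(8):
        e = np.exp(t_hat * log1mp)
        f = delta + one_minus_d * (1.0 - e)
        fp = -one_minus_d * log1mp * e
        fpp = -one_minus_d * log1mp**2 * e
        g = 2.0 * np.sum((f - beta) * fp)
        gp = 2.0 * np.sum(fp**2 + (f - beta) * fpp)
        if gp <= 0:
            break
        step = g / gp
        t_new = min(max(t_hat - step, 0.0), hi)
        if ssr(t_new) <= f_hat:
            t_hat, f_hat = t_new, ssr(t_new)
        if abs(step) < 1e-12 * max(t_hat, 1.0):
            break

    if ssr(0.0) <= f_hat:  # floor wins
        return 0.0, ssr(0.0), True
    return t_hat, f_hat, False


def fit_mitotic_age(beta_clock: BetaMatrix, model: ClockModel) -> MitoticAgeEstimate:
    """Least-squares mitotic age per sample over the clock CpGs.

    Requires ≥10 clock CpGs with non-missing β per sample; samples whose
    β never exceeds the ground state return T̂ = 0 with ``at_floor`` set.
    """
    shared = model.params.index.intersection(beta_clock.probe_ids)
    if len(shared) < MIN_CLOCK_CPGS:
        raise ValueError(
            f"only {len(shared)} clock CpGs present; need ≥{MIN_CLOCK_CPGS}"
        )
    delta_all = model.params.loc[shared, "delta"].to_numpy()
    p_all = model.params.loc[shared, "p"].to_numpy()
    rows = []
    for sample in beta_clock.sample_ids:
        b = beta_clock.values.loc[shared, sample].to_numpy(dtype=float)
        ok = ~np.isnan(b)
        if ok.sum() < MIN_CLOCK_CPGS:
            raise ValueError(
                f"sample {sample}: only {int(ok.sum())} usable clock CpGs"
            )
        t_hat, resid, at_floor = _fit_one(b[ok], delta_all[ok], p_all[ok])
        rows.append((sample, t_hat, resid, int(ok.sum()), at_floor))
    table = pd.DataFrame(
        rows, columns=["sample_id", "mitotic_age", "residual", "n_cpgs", "at_floor"]
    ).set_index("sample_id")
    return MitoticAgeEstimate(table=table)


def scdr(estimate: MitoticAgeEstimate, ages: pd.Series) -> pd.Series:
    """Stem-cell division rate per sample: mitotic age / chronological age
    (divisions per stem cell and year)."""
    ages = ages.reindex(estimate.table.index)
    if ages.isna().any():
        missing = list(ages.index[ages.isna()][:5])
        raise ValueError(f"missing ages for samples: {missing}")
    if (ages <= 0).any():
        raise ValueError("chronological ages must be positive")
    return (estimate.table["mitotic_age"] / ages).rename("scdr")


def group_scdr(rates: pd.Series, groups: pd.Series) -> pd.Series:
    """Per-group SCDR summarized as the median over samples (robust to the
    heavy right skew of mitotic-age distributions)."""
    groups = groups.reindex(rates.index)
    return rates.groupby(groups).median()
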