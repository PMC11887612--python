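"""Total effect, controlled direct effects, and percent attributable.

The total effect (TE) is the marginal race contrast in outcome probability,
``Prob(Y)|X=2 - Prob(Y)|X=1``, with both mediators marginalized. A
controlled direct effect (CDE) fixes one or both mediators at their optimal
level (class 1) and treats the remaining index as missing:

    {M1}:     PO[2,1,NA] - PO[1,1,NA]
    {M2}:     PO[2,NA,1] - PO[1,NA,1]
    {M1,M2}:  PO[2,1,1]  - PO[1,1,1]

Percent attributable, PA = 100 * (TE - CDE) / TE, is the share of the
disparity eliminated by optimizing the mediator(s); a negative PA means
the disparity would grow. PA is computed per posterior draw and then
summarized — medians do not commute with ratios.

Seed policy: one master seed; every potential-outcome quantity gets a
deterministic substream derived from (master seed, outcome label, PO
label), so a PO reused by several contrasts contributes identical draws
(paired sampling, as a single chain evaluating all nodes would give).
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .po_inference import (
    DEFAULT_BURN_IN,
    DEFAULT_DRAWS,
    MarginSpec,
    PosteriorDraws,
    sample_posterior_rate,
)
from .record_prep import CellCounts
from .synthetic_data import normalize_margin

logger = logging.getLogger(__name__)

#: MarginSpec pairs (x=2 minus x=1) defining each CDE, mediators at optimal.
CDE_SPECS = {
    "M1": (MarginSpec(2, 1, None), MarginSpec(1, 1, None)),
    "M2": (MarginSpec(2, None, 1), MarginSpec(1, None, 1)),
    "M1M2": (MarginSpec(2, 1, 1), MarginSpec(1, 1, 1)),
}

TE_SPECS = (MarginSpec(2, None, None), MarginSpec(1, None, None))


def substream_seed(master: int, *labels) -> int:
    """Deterministic per-quantity sub-seed (always below 2^31)."""
    text = "/".join(str(lab) for lab in labels)
    return (int(master) * 0x9E3779B1 + zlib.crc32(text.encode())) % (2**31 - 1)


def _po_draws(cells, spec, S, master_seed, engine, burn_in, chains):
    seed = substream_seed(master_seed, cells.outcome, spec.label())
    r, n = cells.collapse(spec.x, spec.m1, spec.m2)
    if n == 0:
        logger.warning("%s: empty collapse (n=0); Uniform prior used", spec.label())
    return sample_posterior_rate(
        r, n, S=S, seed=seed, engine=engine,
        burn_in=burn_in, chains=chains, label=spec.label(),
    )


def total_effect(
    cells: CellCounts,
    S: int = DEFAULT_DRAWS,
    seed: int = 0,
    engine: str = "conjugate",
    burn_in: int = DEFAULT_BURN_IN,
    chains: int = 2,
) -> PosteriorDraws:
    """Draw-wise posterior of the marginal race contrast."""
    hi, lo = (
        _po_draws(cells, spec, S, seed, engine, burn_in, chains) for spec in TE_SPECS
    )
    return PosteriorDraws(hi.values - lo.values, seed=seed, label=f"TE[{cells.outcome}]")


def controlled_direct_effect(
    cells: CellCounts,
    margin,
    S: int = DEFAULT_DRAWS,
    seed: int = 0,
    engine: str = "conjugate",
    burn_in: int = DEFAULT_BURN_IN,
    chains: int = 2,
) -> PosteriorDraws:
    """Draw-wise posterior of the CDE for {M1}, {M2} or {M1,M2}."""
    margin = normalize_margin(margin)
    spec_hi, spec_lo = CDE_SPECS[margin]
    hi = _po_draws(cells, spec_hi, S, seed, engine, burn_in, chains)
    lo = _po_draws(cells, spec_lo, S, seed, engine, burn_in, chains)
    return PosteriorDraws(
        hi.values - lo.values, seed=seed, label=f"CDE_{margin}[{cells.outcome}]"
    )


def percent_attributable(te: PosteriorDraws, cde: PosteriorDraws) -> PosteriorDraws:
    """Draw-wise PA = 100 (TE - CDE) / TE over paired draws.

    Draws where TE is exactly zero are undefined; they propagate as NaN and
    are excluded from summaries with a logged count.
    """
    if te.S != cde.S:
        raise ValueError("te and cde must have the same number of draws")
    te_vals = te.values
    undefined = te_vals == 0.0
    n_undef = int(undefined.sum())
    if n_undef == te.S:
        raise ValueError("all TE draws are exactly zero; PA undefined")
    if n_undef:
        logger.info("percent_attributable: %d draws with TE=0 excluded", n_undef)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(undefined, np.nan, 100.0 * (te_vals - cde.values) / te_vals)
    return PosteriorDraws(values, seed=te.seed, label=f"PA({cde.label})")


@dataclass(frozen=True)
class EffectEstimate:
    """Posterior median and equal-tailed 95% interval of one effect."""

    median: float
    ci_low: float
    ci_high: float
    significant: bool
    scale: str = "raw"
    n_undefined: int = 0

    def __post_init__(self):
        if not self.ci_low <= self.median <= self.ci_high:
            raise ValueError("need ci_low <= median <= ci_high")


_SCALE_FACTOR = {"raw": 1.0, "per-1000": 1000.0, "percent": 1.0}


def summarize(draws: PosteriorDraws, scale: str = "raw") -> EffectEstimate:
    """Median and 2.5/97.5 percentiles; significant iff the interval
    excludes zero. ``per-1000`` multiplies by 1000 (case-count contrast per
    1000 births); ``percent`` tags an already-percent quantity such as PA.
    """
    if scale not in _SCALE_FACTOR:
        raise ValueError(f"scale must be one of {sorted(_SCALE_FACTOR)}")
    vals = draws.values
    n_undef = int(np.isnan(vals).sum())
    finite = vals[~np.isnan(vals)]
    if finite.size == 0:
        raise ValueError("no defined draws to summarize")
    lo, med, hi = np.percentile(finite, [2.5, 50.0, 97.5]) * _SCALE_FACTOR[scale]
    return EffectEstimate(
        median=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        significant=not (lo <= 0.0 <= hi),
        scale=scale,
        n_undefined=n_undef,
    )


def run_analysis(
    cells_by_outcome: Mapping[str, CellCounts],
    S: int = DEFAULT_DRAWS,
    seed: int = 0,
    engine: str = "conjugate",
    burn_in: int = DEFAULT_BURN_IN,
    chains: int = 2,
) -> pd.DataFrame:
    """Per-outcome report: TE (per 1000) and PA for the three margins.

    Returns a tidy frame with columns outcome, estimate_type (TE, PA_M1,
    PA_M2, PA_M1M2), median, ci_low, ci_high, significant, stable, scale,
    n_undefined. ``stable`` is False on PA rows whose TE interval includes
    zero (the PA ratio is then poorly identified).
    """
    if not cells_by_outcome:
        raise ValueError("need at least one outcome")
    if S < 100:
        raise ValueError("S must be >= 100 for stable percentile summaries")
    rows = []
    for outcome, cells in cells_by_outcome.items():
        te = total_effect(cells, S=S, seed=seed, engine=engine, burn_in=burn_in, chains=chains)
        te_est = summarize(te, scale="per-1000")
        rows.append(
            {"outcome": outcome, "estimate_type": "TE", "stable": True, **te_est.__dict__}
        )
        for margin in ("M1", "M2", "M1M2"):
            cde = controlled_direct_effect(
                cells, margin, S=S, seed=seed, engine=engine, burn_in=burn_in, chains=chains
            )
            pa_est = summarize(percent_attributable(te, cde), scale="percent")
            rows.append(
                {
                    "outcome": outcome,
                    "estimate_type": f"PA_{margin}",
                    "stable": te_est.significant,
                    **pa_est.__dict__,
                }
            )
    report = pd.DataFrame(rows)
    return report[
        [
            "outcome", "estimate_type", "median", "ci_low", "ci_high",
            "significant", "stable", "scale", "n_undefined",
        ]
    ]
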