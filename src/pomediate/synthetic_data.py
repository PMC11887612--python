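"""Synthetic natality-like data with known causal ground truth.

Two generators share one configuration: a record-level generator that emits
birth records whose anthropometric fields back-solve to a drawn mediator
combination, and a cell-level generator that draws the eight-cell binomial
count table directly. A calibration solver inverts the total-effect and
controlled-direct-effect contrasts so simulations can be pinned to chosen
effect sizes: given a reference-race baseline rate, a target total effect,
and optional CDE targets per margin, it returns cell outcome probabilities
whose forward-computed contrasts hit the targets exactly.

Calibration parameterization: all reference-race (x=1) cells sit at the
baseline rate; x=2 cells constrained by a CDE target are set (or solved)
so the margin contrast equals its target; all remaining x=2 cells share a
single common rate solved linearly from the total-effect target. This is
minimal, always linear, and uniquely solvable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .record_prep import (
    ANTHRO_FIELDS,
    DEFAULT_RULES,
    MEDIATOR_COMBOS,
    CellCounts,
    PrevalenceTable,
)

logger = logging.getLogger(__name__)

MARGIN_KEYS = ("M1", "M2", "M1M2")

#: Sampling intervals used to back-solve anthropometrics from the drawn class.
BMI_OPTIMAL_INTERVAL = (18.5, 25.0)
BMI_NONOPT_INTERVALS = ((15.0, 18.5), (25.0, 45.0))
GWG_OPTIMAL_INTERVAL = (11.5, 16.0)
GWG_NONOPT_INTERVALS = ((0.0, 11.5), (16.0, 30.0))
GESTATION_INTERVAL = (37.0, 42.0)
HEIGHT_INTERVAL = (150.0, 180.0)


class ConfigError(ValueError):
    """Invalid generator configuration."""


class CalibrationError(ValueError):
    """The requested contrasts are not achievable with probabilities in [0, 1]."""


def normalize_margin(key) -> str:
    """Canonicalize a margin spec ({M1}, {M2} or {M1,M2}) to M1 / M2 / M1M2."""
    if isinstance(key, str):
        k = key.upper().replace(" ", "").replace(",", "").replace("{", "").replace("}", "")
    elif isinstance(key, (set, frozenset, tuple, list)):
        k = "".join(sorted(str(s).upper() for s in key))
    else:
        raise ValueError(f"unrecognized margin spec: {key!r}")
    if k not in MARGIN_KEYS:
        raise ValueError(f"margin must be one of {MARGIN_KEYS}, got {key!r}")
    return k


@dataclass(frozen=True)
class CellProbs:
    """Outcome probability per (race, BMI-class, GWG-class) cell."""

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float).reshape(2, 2, 2)
        if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
            raise ValueError("cell probabilities must lie in [0, 1]")
        object.__setattr__(self, "p", p)

    def cell(self, x: int, m1: int, m2: int) -> float:
        return float(self.p[x - 1, m1 - 1, m2 - 1])

    @classmethod
    def constant(cls, value: float) -> "CellProbs":
        return cls(np.full((2, 2, 2), float(value)))


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    ``n_per_race`` is either one count (both races) or a mapping
    ``{1: n_non_black, 2: n_black}``. ``cell_probs`` is a single
    :class:`CellProbs` (one outcome, column named ``event``) or a mapping
    from outcome name to :class:`CellProbs`. ``missing_rates`` gives a
    missing-completely-at-random probability per field (anthropometrics
    and/or outcomes); it applies only at record level.
    """

    n_per_race: int | Mapping[int, int]
    prevalence: PrevalenceTable
    cell_probs: CellProbs | Mapping[str, CellProbs]
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    level: str = "record"

    def n_for(self, x: int) -> int:
        if isinstance(self.n_per_race, Mapping):
            return int(self.n_per_race[x])
        return int(self.n_per_race)

    def outcome_probs(self) -> dict[str, CellProbs]:
        if isinstance(self.cell_probs, CellProbs):
            return {"event": self.cell_probs}
        return dict(self.cell_probs)

    def validate(self) -> None:
        errors = []
        if self.level not in ("record", "cell"):
            errors.append(f"level must be 'record' or 'cell', got {self.level!r}")
        for x in (1, 2):
            try:
                if self.n_for(x) < 0:
                    errors.append(f"n_per_race for race {x} must be >= 0")
            except (KeyError, TypeError, ValueError):
                errors.append(f"n_per_race missing a count for race {x}")
        if not isinstance(self.prevalence, PrevalenceTable):
            errors.append("prevalence must be a PrevalenceTable")
        else:
            fr = self.prevalence.fractions()
            if not np.allclose(fr.reshape(2, 4).sum(axis=1), 1.0, atol=1e-9):
                errors.append("each race's prevalence must sum to 100%")
        for name, cp in self.outcome_probs().items():
            if not isinstance(cp, CellProbs):
                errors.append(f"cell_probs for {name!r} must be a CellProbs")
        for fld, rate in self.missing_rates.items():
            if not 0.0 <= float(rate) <= 1.0:
                errors.append(f"missing rate for {fld!r} must be in [0, 1]")
        if errors:
            raise ConfigError("; ".join(errors))


# ---------------------------------------------------------------------------
# Forward contrasts (generating truth)


def true_total_effect(prevalence: PrevalenceTable, probs: CellProbs) -> float:
    """Prevalence-weighted race contrast in outcome probability."""
    fr = prevalence.fractions()
    marg = (fr * probs.p).reshape(2, 4).sum(axis=1)
    return float(marg[1] - marg[0])


def true_cde(prevalence: PrevalenceTable, probs: CellProbs, margin) -> float:
    """True controlled direct effect for a margin, mediators fixed optimal.

    For {M1,M2} this is the (x=2, 1, 1) minus (x=1, 1, 1) cell contrast.
    For a single mediator, the other mediator is marginalized using its
    conditional prevalence at the fixed optimal level, matching what fitting
    the pooled (collapsed) counts converges to.
    """
    margin = normalize_margin(margin)
    fr = prevalence.fractions()
    if margin == "M1M2":
        return probs.cell(2, 1, 1) - probs.cell(1, 1, 1)
    out = []
    for x in (1, 2):
        if margin == "M1":
            w = fr[x - 1, 0, :]
            p = probs.p[x - 1, 0, :]
        else:  # M2
            w = fr[x - 1, :, 0]
            p = probs.p[x - 1, :, 0]
        out.append(float((w * p).sum() / w.sum()))
    return out[1] - out[0]


# ---------------------------------------------------------------------------
# Calibration solver


def _cell_name(x, m1, m2):
    return f"PO[{x},{m1},{m2}]"


def calibrate_cell_probs(
    prevalence: PrevalenceTable,
    te_target: float,
    cde_targets: Mapping | None = None,
    baseline: float = 0.05,
) -> CellProbs:
    """Solve cell probabilities hitting a total effect and optional CDEs.

    Parameters
    ----------
    prevalence
        Joint mediator prevalence per race (the mixing weights of the
        marginal contrasts).
    te_target
        Target total effect on the probability scale (may be negative).
    cde_targets
        Optional mapping from margin ({M1}, {M2} or {M1,M2}) to a target
        controlled direct effect on the probability scale.
    baseline
        Outcome rate shared by every reference-race (x=1) cell.

    Returns
    -------
    CellProbs whose forward-computed contrasts equal the targets; the
    solution is verified by recomputation to 1e-12 before returning.
    """
    if te_target is None:
        raise CalibrationError("te_target is required")
    te_target = float(te_target)
    baseline = float(baseline)
    if not 0.0 <= baseline <= 1.0:
        raise CalibrationError("baseline must be in [0, 1]")
    targets = {normalize_margin(k): float(v) for k, v in (cde_targets or {}).items()}

    fr = prevalence.fractions()
    p = np.full((2, 2, 2), baseline)
    fixed = np.zeros((2, 2), dtype=bool)  # x=2 cells pinned by a CDE constraint

    def _set(m1, m2, value):
        if not 0.0 <= value <= 1.0:
            raise CalibrationError(
                f"infeasible: solved probability {value:.6g} for cell "
                f"{_cell_name(2, m1, m2)} lies outside [0, 1]"
            )
        p[1, m1 - 1, m2 - 1] = value
        fixed[m1 - 1, m2 - 1] = True

    if "M1M2" in targets:
        _set(1, 1, baseline + targets["M1M2"])
    if "M1" in targets:
        # conditional weights over m2 within (x=2, m1=1)
        w = fr[1, 0, :] / fr[1, 0, :].sum()
        level = baseline + targets["M1"]
        if fixed[0, 0]:
            _set(1, 2, (level - w[0] * p[1, 0, 0]) / w[1])
        else:
            _set(1, 1, level)
            _set(1, 2, level)
    if "M2" in targets:
        w = fr[1, :, 0] / fr[1, :, 0].sum()
        level = baseline + targets["M2"]
        if fixed[0, 0]:
            _set(2, 1, (level - w[0] * p[1, 0, 0]) / w[1])
        else:
            _set(1, 1, level)
            _set(2, 1, level)

    # remaining x=2 cells share one rate solved from the total effect
    target_mean = baseline + te_target
    fixed_mass = float((fr[1] * p[1] * fixed).sum())
    free_mass = float((fr[1] * ~fixed).sum())
    if free_mass > 0:
        common = (target_mean - fixed_mass) / free_mass
        for m1 in (1, 2):
            for m2 in (1, 2):
                if not fixed[m1 - 1, m2 - 1]:
                    _set(m1, m2, common)
    else:
        implied = float((fr[1] * p[1]).sum())
        if abs(implied - target_mean) > 1e-12:
            raise CalibrationError(
                "all x=2 cells are pinned by CDE targets and the implied total "
                f"effect {implied - baseline:.6g} conflicts with te_target {te_target:.6g}"
            )

    probs = CellProbs(p)
    # forward verification: recompute every constrained contrast
    achieved_te = true_total_effect(prevalence, probs)
    if abs(achieved_te - te_target) > 1e-12:
        raise CalibrationError(
            f"forward check failed: total effect {achieved_te!r} != {te_target!r}"
        )
    for margin, value in targets.items():
        achieved = true_cde(prevalence, probs, margin)
        if abs(achieved - value) > 1e-12:
            raise CalibrationError(
                f"forward check failed: CDE[{margin}] {achieved!r} != {value!r}"
            )
    return probs


# ---------------------------------------------------------------------------
# Generators


def _sample_in_class(rng, n, optimal_mask, optimal_interval, nonopt_intervals):
    """Uniform within the class interval; non-optimal is a length-weighted
    mixture of its two disjoint sub-intervals."""
    out = np.empty(n)
    n_opt = int(optimal_mask.sum())
    out[optimal_mask] = rng.uniform(*optimal_interval, size=n_opt)
    n_non = n - n_opt
    (lo1, hi1), (lo2, hi2) = nonopt_intervals
    w1 = (hi1 - lo1) / ((hi1 - lo1) + (hi2 - lo2))
    pick_low = rng.random(n_non) < w1
    vals = np.where(
        pick_low,
        rng.uniform(lo1, hi1, size=n_non),
        rng.uniform(lo2, hi2, size=n_non),
    )
    out[~optimal_mask] = vals
    return out


def simulate_records(config: GeneratorConfig) -> pd.DataFrame:
    """Draw record-level births whose derivation recovers the drawn classes.

    For each race, mediator combinations are drawn from the race's joint
    prevalence; BMI and adjusted GWG are sampled uniformly within the drawn
    class's interval; height and gestation length are sampled independently
    and the weight fields back-solved so that BMI/GWG derivation reproduces
    the drawn values. Outcomes are Bernoulli with the record's cell
    probability; missingness is applied per field, MCAR.
    """
    config.validate()
    if config.level != "record":
        raise ConfigError(f"simulate_records requires level='record', got {config.level!r}")
    rng = np.random.default_rng(config.seed)
    combos = np.asarray(MEDIATOR_COMBOS)
    outcome_probs = config.outcome_probs()
    fr = config.prevalence.fractions()

    frames = []
    for x in (1, 2):
        n = config.n_for(x)
        if n == 0:
            continue
        weights = np.array([fr[x - 1, m1 - 1, m2 - 1] for m1, m2 in MEDIATOR_COMBOS])
        combo_idx = rng.choice(4, size=n, p=weights)
        m1 = combos[combo_idx, 0]
        m2 = combos[combo_idx, 1]
        bmi = _sample_in_class(rng, n, m1 == 1, BMI_OPTIMAL_INTERVAL, BMI_NONOPT_INTERVALS)
        gwg = _sample_in_class(rng, n, m2 == 1, GWG_OPTIMAL_INTERVAL, GWG_NONOPT_INTERVALS)
        weeks = rng.uniform(*GESTATION_INTERVAL, size=n)
        height = rng.uniform(*HEIGHT_INTERVAL, size=n)
        prepreg = bmi * (height / 100.0) ** 2
        delivery = prepreg + gwg * weeks / 40.0
        frame = pd.DataFrame(
            {
                "race_class": np.full(n, x, dtype=float),
                "height_cm": height,
                "prepreg_weight_kg": prepreg,
                "delivery_weight_kg": delivery,
                "gestation_weeks": weeks,
            }
        )
        for name, cp in outcome_probs.items():
            cell_p = cp.p[x - 1, m1 - 1, m2 - 1]
            frame[name] = (rng.random(n) < cell_p).astype(float)
        frames.append(frame)

    if not frames:
        cols = ["race_class"] + list(ANTHRO_FIELDS) + list(outcome_probs)
        return pd.DataFrame(columns=cols).astype(float)
    records = pd.concat(frames, ignore_index=True)
    for fld, rate in config.missing_rates.items():
        if fld not in records.columns:
            raise ConfigError(f"missing rate given for unknown field {fld!r}")
        if rate > 0:
            mask = rng.random(len(records)) < float(rate)
            records.loc[mask, fld] = np.nan
    return records


def simulate_cell_counts(config: GeneratorConfig):
    """Draw the eight-cell count table directly.

    Cell denominators are ``round(n_per_race * prevalence fraction)``; case
    counts are Binomial(n, cell probability). Returns one
    :class:`CellCounts` for a single outcome, or a dict keyed by outcome.
    All outcomes share the same denominators (the same simulated cohort).
    """
    config.validate()
    if config.level != "cell":
        raise ConfigError(f"simulate_cell_counts requires level='cell', got {config.level!r}")
    rng = np.random.default_rng(config.seed)
    fr = config.prevalence.fractions()
    n_cells = np.zeros((2, 2, 2), dtype=np.int64)
    for x in (1, 2):
        n_cells[x - 1] = np.rint(config.n_for(x) * fr[x - 1]).astype(np.int64)
    outcome_probs = config.outcome_probs()
    results = {
        name: CellCounts(rng.binomial(n_cells, cp.p), n_cells, outcome=name)
        for name, cp in outcome_probs.items()
    }
    if isinstance(config.cell_probs, CellProbs):
        return results["event"]
    return results
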