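"""Recovery study: simulate cohorts pinned to the published effect sizes
and re-estimate them with the full pipeline.

Each recovery calibrates generating cell probabilities to a published
total effect (and, for percent-attributable recoveries, the one published
CDE implied by that scenario's PA), simulates the eight-cell count table
at study-scale cohort sizes (14M non-Black / 3M Black births), runs the
Bayesian estimation with 10,000 posterior draws, and summarizes.

Delta-method standard errors for the simulated cohort's binomial noise are
provided so checks can be phrased as "within k simulation SEs of the
generating truth".
"""
from __future__ import annotations

import numpy as np

from . import reference as ref
from .mediation_effects import (
    EffectEstimate,
    controlled_direct_effect,
    percent_attributable,
    substream_seed,
    summarize,
    total_effect,
)
from .record_prep import CellCounts, PrevalenceTable, aggregate, filter_records, prevalence_table
from .synthetic_data import (
    CellProbs,
    GeneratorConfig,
    calibrate_cell_probs,
    simulate_records,
)

DRAWS = 10_000


def calibrated_probs(outcome: str, margins=()) -> CellProbs:
    """Generating truth for one recovery: published TE plus the published
    CDEs for the given margins only."""
    targets = {m: ref.cde_target(outcome, m) for m in margins}
    return calibrate_cell_probs(
        ref.study_prevalence(),
        te_target=ref.total_effect_target(outcome),
        cde_targets=targets,
        baseline=ref.BASELINE_RATE[outcome],
    )


def simulate_outcome_counts(
    outcome: str,
    seed: int,
    margins=(),
    n_non_black: int = ref.N_NON_BLACK,
    n_black: int = ref.N_BLACK,
) -> CellCounts:
    """One simulated study-scale cohort for one outcome, as cell counts."""
    probs = calibrated_probs(outcome, margins)
    config = GeneratorConfig(
        n_per_race={1: n_non_black, 2: n_black},
        prevalence=ref.study_prevalence(),
        cell_probs={outcome: probs},
        seed=seed,
        level="cell",
    )
    from .synthetic_data import simulate_cell_counts

    return simulate_cell_counts(config)[outcome]


def recover_total_effect(
    outcome: str, seed: int, S: int = DRAWS, margins=()
) -> EffectEstimate:
    """Recovered posterior total effect on the per-1000 scale."""
    cells = simulate_outcome_counts(outcome, substream_seed(seed, outcome, "sim"), margins)
    draws = total_effect(cells, S=S, seed=seed)
    return summarize(draws, scale="per-1000")


def recover_percent_attributable(
    outcome: str, margin: str, seed: int, S: int = DRAWS
) -> EffectEstimate:
    """Recovered posterior PA (percent) for one optimization scenario,
    computed draw-wise from paired TE and CDE draws."""
    cells = simulate_outcome_counts(
        outcome, substream_seed(seed, outcome, margin, "sim"), margins=(margin,)
    )
    te = total_effect(cells, S=S, seed=seed)
    cde = controlled_direct_effect(cells, margin, S=S, seed=seed)
    return summarize(percent_attributable(te, cde), scale="percent")


def recover_prevalence(seed: int, n_per_race: int = 1_000_000) -> PrevalenceTable:
    """Round-trip mediator prevalence through the record-level pipeline.

    Simulates records (no missingness) from the published joint prevalence,
    derives and classifies the mediators, aggregates, and reads the
    observed prevalence back.
    """
    config = GeneratorConfig(
        n_per_race=n_per_race,
        prevalence=ref.study_prevalence(),
        cell_probs={name: CellProbs.constant(p) for name, p in ref.BASELINE_RATE.items()},
        seed=seed,
        level="record",
    )
    records = simulate_records(config)
    derived, _ = filter_records(records)
    cells = aggregate(derived, "cesarean_delivery")
    return prevalence_table(cells)


# ---------------------------------------------------------------------------
# Simulation (cohort-sampling) standard errors, by the delta method


def _margin_truth_and_var(outcome, margins, spec_margin, n_non_black, n_black):
    """True pooled rate and its sampling variance per race for one PO margin.

    spec_margin: (m1, m2) with None meaning collapsed.
    """
    probs = calibrated_probs(outcome, margins)
    fr = ref.study_prevalence().fractions()
    n_race = {1: n_non_black, 2: n_black}
    out = {}
    for x in (1, 2):
        f = fr[x - 1].copy()
        p = probs.p[x - 1]
        m1, m2 = spec_margin
        mask = np.ones((2, 2), dtype=bool)
        if m1 is not None:
            keep = np.zeros((2, 2), dtype=bool)
            keep[m1 - 1, :] = True
            mask &= keep
        if m2 is not None:
            keep = np.zeros((2, 2), dtype=bool)
            keep[:, m2 - 1] = True
            mask &= keep
        cells_n = n_race[x] * f * mask
        n_pool = cells_n.sum()
        rate = float((cells_n * p).sum() / n_pool)
        var = float((cells_n * p * (1 - p)).sum() / n_pool**2)
        out[x] = (rate, var)
    return out


def total_effect_sim_se(
    outcome: str,
    margins=(),
    n_non_black: int = ref.N_NON_BLACK,
    n_black: int = ref.N_BLACK,
) -> float:
    """SE (probability scale) of the recovered TE across simulated cohorts."""
    stats = _margin_truth_and_var(outcome, margins, (None, None), n_non_black, n_black)
    return float(np.sqrt(stats[1][1] + stats[2][1]))


def percent_attributable_sim_se(
    outcome: str,
    margin: str,
    n_non_black: int = ref.N_NON_BLACK,
    n_black: int = ref.N_BLACK,
) -> float:
    """Delta-method SE (percentage points) of the recovered PA."""
    spec = {"M1": (1, None), "M2": (None, 1), "M1M2": (1, 1)}[margin]
    te = ref.total_effect_target(outcome)
    cde = ref.cde_target(outcome, margin)
    var_te = total_effect_sim_se(outcome, (margin,), n_non_black, n_black) ** 2
    stats = _margin_truth_and_var(outcome, (margin,), spec, n_non_black, n_black)
    var_cde = stats[1][1] + stats[2][1]
    d_te = 100.0 * cde / te**2
    d_cde = -100.0 / te
    return float(np.sqrt(d_te**2 * var_te + d_cde**2 * var_cde))


def prevalence_sim_se(x: int, m1: int, m2: int, n_per_race: int = 1_000_000) -> float:
    """Multinomial SE (percentage points) of one recovered prevalence entry."""
    f = ref.study_prevalence().fractions()[x - 1, m1 - 1, m2 - 1]
    return float(100.0 * np.sqrt(f * (1 - f) / n_per_race))
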