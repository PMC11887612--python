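"""Published reference estimates used to calibrate recovery simulations.

These are the headline quantities from the 2016-2021 US National Vital
Statistics System singleton-birth analysis of Black / non-Black disparity
in five maternal outcomes (17.7M retained records): the joint prevalence of
the optimal/non-optimal BMI x GWG combinations per race, and per outcome
the total effect (cases per 1000 births) with the percent of disparity
eliminated under each optimization scenario. They serve as *inputs*: the
calibration solver pins synthetic cohorts to these effect sizes, and the
recovery study checks that the pipeline estimates them back.
"""
from __future__ import annotations

from .record_prep import OUTCOMES, PrevalenceTable
from .synthetic_data import CellProbs, calibrate_cell_probs, normalize_margin

#: Joint mediator prevalence (percent), display order
#: (opt BMI, opt GWG), (non-opt, opt), (opt, non-opt), (non-opt, non-opt).
#: Printed columns are rounded and need renormalization (Black sums to 99.9).
PREVALENCE_PERCENT = {
    "non_black": (15.1, 14.0, 29.2, 41.7),
    "black": (9.7, 14.7, 24.2, 51.3),
}

#: Total effect x 1000: excess cases among Black women per 1000 births.
TOTAL_EFFECT_PER_1000 = {
    "gestational_hypertension": 10.5,
    "hypertension_eclampsia": 1.1,
    "parturition_induction": -28.1,
    "cesarean_delivery": 40.2,
    "icu_admission": 0.7,
}

TOTAL_EFFECT_CRI = {
    "gestational_hypertension": (10.1, 10.8),
    "hypertension_eclampsia": (1.0, 1.2),
    "parturition_induction": (-28.7, -27.5),
    "cesarean_delivery": (39.6, 40.9),
    "icu_admission": (0.7, 0.8),
}

#: Percent of racial disparity eliminated when the named mediator(s) are
#: fixed at optimal (negative = disparity grows).
PA_PERCENT = {
    "gestational_hypertension": {"M1": -8.7, "M2": -34.3, "M1M2": -19.2},
    "hypertension_eclampsia": {"M1": -1.4, "M2": -10.0, "M1M2": 9.6},
    "parturition_induction": {"M1": 0.1, "M2": 21.0, "M1M2": 16.9},
    "cesarean_delivery": {"M1": 57.6, "M2": -14.2, "M1M2": 49.9},
    "icu_admission": {"M1": 23.8, "M2": 9.9, "M1M2": 36.9},
}

PA_CRI = {
    "gestational_hypertension": {
        "M1": (-15.1, -2.5), "M2": (-42.6, -26.4), "M1M2": (-28.6, -10.2),
    },
    "hypertension_eclampsia": {
        "M1": (-15.0, 10.5), "M2": (-26.1, 4.9), "M1M2": (-9.6, 27.3),
    },
    "parturition_induction": {
        "M1": (-4.1, 4.1), "M2": (16.4, 25.5), "M1M2": (10.2, 23.6),
    },
    "cesarean_delivery": {
        "M1": (55.1, 60.2), "M2": (-17.9, -10.7), "M1M2": (45.3, 54.6),
    },
    "icu_admission": {
        "M1": (8.0, 38.0), "M2": (-8.8, 26.9), "M1M2": (12.7, 59.2),
    },
}

#: Assumed non-Black marginal outcome rates for simulation: every reference
#: cell sits at this baseline. Chosen as plausible US rates (gestational
#: hypertension ~5%, cesarean ~25%, induction ~30%, ICU ~0.2%, composite
#: hypertension-eclampsia ~1%).
BASELINE_RATE = {
    "gestational_hypertension": 0.05,
    "hypertension_eclampsia": 0.01,
    "parturition_induction": 0.30,
    "cesarean_delivery": 0.25,
    "icu_admission": 0.002,
}

#: Race-class cohort sizes approximating the study (non-Black, Black).
N_NON_BLACK = 14_000_000
N_BLACK = 3_000_000


def study_prevalence(normalize: bool = True) -> PrevalenceTable:
    """The published joint mediator prevalence as a PrevalenceTable."""
    return PrevalenceTable.from_percentages(
        PREVALENCE_PERCENT["non_black"], PREVALENCE_PERCENT["black"],
        normalize=normalize,
    )


def total_effect_target(outcome: str) -> float:
    """Target total effect on the probability scale."""
    return TOTAL_EFFECT_PER_1000[outcome] / 1000.0


def cde_target(outcome: str, margin) -> float:
    """CDE target on the probability scale implied by a published PA:
    CDE = TE * (1 - PA / 100)."""
    margin = normalize_margin(margin)
    te = total_effect_target(outcome)
    return te * (1.0 - PA_PERCENT[outcome][margin] / 100.0)


def study_cell_probs(outcome: str, margins=("M1", "M2", "M1M2")) -> CellProbs:
    """Generating-truth cell probabilities calibrated to the published
    total effect and the published PAs for the given margins."""
    if outcome not in OUTCOMES:
        raise KeyError(f"unknown outcome {outcome!r}")
    targets = {m: cde_target(outcome, m) for m in margins}
    return calibrate_cell_probs(
        study_prevalence(),
        te_target=total_effect_target(outcome),
        cde_targets=targets,
        baseline=BASELINE_RATE[outcome],
    )
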