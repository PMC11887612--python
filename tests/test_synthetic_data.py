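"""Calibration solver and the two synthetic generators."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from pomediate.record_prep import MEDIATOR_COMBOS, aggregate, filter_records
from pomediate.synthetic_data import (
    CalibrationError,
    CellProbs,
    ConfigError,
    GeneratorConfig,
    calibrate_cell_probs,
    simulate_cell_counts,
    simulate_records,
    true_cde,
    true_total_effect,
)


class TestCalibration:
    def test_constant_shift_solution(self, uniform_prevalence):
        probs = calibrate_cell_probs(uniform_prevalence, te_target=0.01, baseline=0.05)
        assert np.allclose(probs.p[0], 0.05) and np.allclose(probs.p[1], 0.06)

    def test_null_effect_case(self, uniform_prevalence):
        probs = calibrate_cell_probs(
            uniform_prevalence, te_target=0.0, cde_targets={"M1M2": 0.0}, baseline=0.2
        )
        assert true_total_effect(uniform_prevalence, probs) == pytest.approx(0, abs=1e-15)
        assert true_cde(uniform_prevalence, probs, "M1M2") == pytest.approx(0, abs=1e-15)

    def test_cesarean_row_targets_forward_check(self, study_prevalence):
        te, joint = 0.0402, 0.0402 * (1 - 0.499)
        probs = calibrate_cell_probs(
            study_prevalence, te_target=te, cde_targets={"M1M2": joint}, baseline=0.25
        )
        assert true_total_effect(study_prevalence, probs) == pytest.approx(te, abs=1e-12)
        assert true_cde(study_prevalence, probs, "M1M2") == pytest.approx(
            0.0201402, abs=1e-12
        )

    def test_all_three_margins_simultaneously(self, study_prevalence):
        targets = {"M1": 0.002, "M2": -0.004, "M1M2": 0.006}
        probs = calibrate_cell_probs(
            study_prevalence, te_target=0.01, cde_targets=targets, baseline=0.1
        )
        for margin, target in targets.items():
            assert true_cde(study_prevalence, probs, margin) == pytest.approx(
                target, abs=1e-12
            )
        assert true_total_effect(study_prevalence, probs) == pytest.approx(0.01, abs=1e-12)

    def test_infeasible_target_names_cell(self, uniform_prevalence):
        with pytest.raises(CalibrationError, match=r"PO\[2,1,1\]"):
            calibrate_cell_probs(
                uniform_prevalence, te_target=0.01, cde_targets={"M1M2": 0.5},
                baseline=0.9,
            )

    def test_missing_te_target_errors(self, uniform_prevalence):
        with pytest.raises(CalibrationError, match="te_target"):
            calibrate_cell_probs(uniform_prevalence, te_target=None)

    @given(
        te=st.floats(-0.05, 0.05),
        cde=st.floats(-0.05, 0.05),
        baseline=st.floats(0.1, 0.6),
        margin=st.sampled_from(["M1", "M2", "M1M2"]),
    )
    def test_forward_verification_property(self, study_prevalence, te, cde, baseline, margin):
        try:
            probs = calibrate_cell_probs(
                study_prevalence, te_target=te, cde_targets={margin: cde},
                baseline=baseline,
            )
        except CalibrationError:
            assume(False)
        assert true_total_effect(study_prevalence, probs) == pytest.approx(te, abs=1e-12)
        assert true_cde(study_prevalence, probs, margin) == pytest.approx(cde, abs=1e-12)


def make_config(study_prevalence, **over):
    defaults = dict(
        n_per_race=1000,
        prevalence=study_prevalence,
        cell_probs=CellProbs.constant(0.1),
        seed=11,
        level="record",
    )
    defaults.update(over)
    return GeneratorConfig(**defaults)


class TestSimulateRecords:
    def test_zero_births_empty_frame(self, study_prevalence):
        records = simulate_records(make_config(study_prevalence, n_per_race=0))
        assert len(records) == 0

    def test_level_mismatch_errors(self, study_prevalence):
        with pytest.raises(ConfigError, match="level"):
            simulate_records(make_config(study_prevalence, level="cell"))

    def test_seed_determinism_byte_identical(self, study_prevalence):
        cfg = make_config(study_prevalence, n_per_race=500)
        a = simulate_records(cfg).to_csv()
        b = simulate_records(make_config(study_prevalence, n_per_race=500)).to_csv()
        assert a == b

    def test_round_trip_recovers_prevalence(self, study_prevalence):
        """No missingness: every record is retained and the recovered joint
        prevalence matches the generating one within 3 multinomial SEs."""
        n = 100_000
        records = simulate_records(make_config(study_prevalence, n_per_race=n, seed=2))
        derived, log = filter_records(records, outcomes=["event"])
        assert log.n_retained == log.n_input == 2 * n
        cells = aggregate(derived, "event")
        fr = study_prevalence.fractions()
        for x in (1, 2):
            for m1, m2 in MEDIATOR_COMBOS:
                f = fr[x - 1, m1 - 1, m2 - 1]
                se = np.sqrt(f * (1 - f) / n)
                got = cells.n[x - 1, m1 - 1, m2 - 1] / n
                assert abs(got - f) < 3 * se

    def test_missingness_rates_applied(self, study_prevalence):
        cfg = make_config(
            study_prevalence, n_per_race=20_000,
            missing_rates={"height_cm": 0.1, "event": 0.05},
        )
        records = simulate_records(cfg)
        frac_h = records["height_cm"].isna().mean()
        frac_y = records["event"].isna().mean()
        assert abs(frac_h - 0.1) < 0.01 and abs(frac_y - 0.05) < 0.01

    def test_invalid_config_rejected(self, study_prevalence):
        with pytest.raises(ConfigError):
            make_config(study_prevalence, n_per_race=-5).validate()
        with pytest.raises(ValueError):
            CellProbs.constant(1.5)


class TestSimulateCellCounts:
    def test_degenerate_probabilities(self, study_prevalence):
        zero = simulate_cell_counts(
            make_config(study_prevalence, level="cell",
                        cell_probs=CellProbs.constant(0.0))
        )
        assert zero.r.sum() == 0
        one = simulate_cell_counts(
            make_config(study_prevalence, level="cell",
                        cell_probs=CellProbs.constant(1.0))
        )
        assert np.array_equal(one.r, one.n)

    def test_binomial_moments(self, uniform_prevalence):
        p = np.zeros((2, 2, 2)); p[0, 0, 0] = 0.1
        cells = simulate_cell_counts(
            make_config(uniform_prevalence, level="cell", n_per_race=1_000_000,
                        cell_probs=CellProbs(p), seed=4)
        )
        n = cells.n[0, 0, 0]
        assert n == 250_000
        assert abs(cells.r[0, 0, 0] - 25_000) < 3 * np.sqrt(250_000 * 0.1 * 0.9)

    def test_determinism(self, study_prevalence):
        cfg = dict(level="cell", n_per_race=5000, seed=9)
        a = simulate_cell_counts(make_config(study_prevalence, **cfg))
        b = simulate_cell_counts(make_config(study_prevalence, **cfg))
        assert a == b


def test_record_and_cell_generators_agree(study_prevalence):
    """Aggregated record-level output converges to the generating cell
    probabilities (within 4 binomial SEs per cell at n=1e6 per race)."""
    probs = calibrate_cell_probs(
        study_prevalence, te_target=0.01, cde_targets={"M1M2": 0.005}, baseline=0.05
    )
    cfg = GeneratorConfig(
        n_per_race=1_000_000, prevalence=study_prevalence,
        cell_probs=probs, seed=6, level="record",
    )
    records = simulate_records(cfg)
    derived, _ = filter_records(records, outcomes=["event"])
    cells = aggregate(derived, "event")
    for x in (1, 2):
        for m1 in (1, 2):
            for m2 in (1, 2):
                r, n = cells.cell(x, m1, m2)
                p = probs.cell(x, m1, m2)
                assert abs(r / n - p) < 4 * np.sqrt(p * (1 - p) / n)
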