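"""Total effect, controlled direct effects, percent attributable, summaries."""
import numpy as np
import pytest
from scipy import stats

from pomediate.mediation_effects import (
    EffectEstimate,
    PosteriorDraws,
    controlled_direct_effect,
    percent_attributable,
    run_analysis,
    substream_seed,
    summarize,
    total_effect,
)
from pomediate.po_inference import MarginSpec, posterior_margin
from pomediate.record_prep import CellCounts
from pomediate.synthetic_data import (
    CellProbs,
    GeneratorConfig,
    calibrate_cell_probs,
    simulate_cell_counts,
    true_cde,
    true_total_effect,
)


def constant_draws(value, S=1000, label="c"):
    return PosteriorDraws(np.full(S, float(value)), label=label)


class TestTotalEffect:
    def test_symmetric_counts_non_significant(self):
        n = np.full((2, 2, 2), 1000)
        r = np.full((2, 2, 2), 100)
        cells = CellCounts(r, n)
        est = summarize(total_effect(cells, S=10_000, seed=1))
        assert not est.significant
        assert abs(est.median) < 0.02

    def test_beta_difference_location(self):
        n = np.zeros((2, 2, 2), dtype=int)
        r = np.zeros((2, 2, 2), dtype=int)
        n[0, 0, 0], r[0, 0, 0] = 10**6, 1000
        n[1, 0, 0], r[1, 0, 0] = 10**6, 2000
        cells = CellCounts(r, n)
        draws = total_effect(cells, S=10_000, seed=2)
        mc_se = 1.2533 * draws.values.std() / np.sqrt(draws.S)
        assert np.median(draws.values) == pytest.approx(0.001, abs=3 * mc_se)

    def test_antisymmetry_under_race_swap(self):
        """Swapping the race labels (and, with them, the per-race posterior
        substreams) negates every TE draw exactly."""
        rng = np.random.default_rng(3)
        n = rng.integers(50, 500, size=(2, 2, 2))
        r = rng.binomial(n, 0.2)
        cells = CellCounts(r, n)
        swapped = CellCounts(r[::-1], n[::-1])
        s_hi, s_lo = 101, 202
        te = (
            posterior_margin(cells, MarginSpec(2), S=2000, seed=s_hi).values
            - posterior_margin(cells, MarginSpec(1), S=2000, seed=s_lo).values
        )
        te_swapped = (
            posterior_margin(swapped, MarginSpec(2), S=2000, seed=s_lo).values
            - posterior_margin(swapped, MarginSpec(1), S=2000, seed=s_hi).values
        )
        assert np.array_equal(te_swapped, -te)

    def test_antisymmetry_in_distribution(self):
        rng = np.random.default_rng(4)
        n = rng.integers(500, 5000, size=(2, 2, 2))
        r = rng.binomial(n, 0.1)
        cells = CellCounts(r, n, outcome="a")
        swapped = CellCounts(r[::-1], n[::-1], outcome="a")
        med = np.median(total_effect(cells, S=20_000, seed=5).values)
        med_sw = np.median(total_effect(swapped, S=20_000, seed=5).values)
        sd = total_effect(cells, S=2000, seed=5).values.std()
        assert med_sw == pytest.approx(-med, abs=4 * 1.2533 * sd / np.sqrt(20_000))


class TestControlledDirectEffect:
    def test_identical_rates_all_margins_null(self):
        rng = np.random.default_rng(6)
        n = np.full((2, 2, 2), 50_000)
        r = rng.binomial(n, 0.1)
        cells = CellCounts(r, n)
        for margin in ("M1", "M2", "M1M2"):
            est = summarize(controlled_direct_effect(cells, margin, S=5000, seed=7))
            assert not est.significant

    def test_joint_margin_collapses_to_total_effect_on_optimal_cells(self):
        n = np.zeros((2, 2, 2), dtype=int)
        r = np.zeros((2, 2, 2), dtype=int)
        n[:, 0, 0] = 5000
        r[0, 0, 0], r[1, 0, 0] = 400, 700
        cells = CellCounts(r, n, outcome="x")
        cde = controlled_direct_effect(cells, "M1M2", S=8000, seed=8)
        te = total_effect(cells, S=8000, seed=8)
        # only the (x, 1, 1) cells are populated, so pooling changes nothing:
        # the two contrasts are the same distribution (different substreams)
        assert stats.ks_2samp(cde.values, te.values).pvalue > 0.01

    def test_calibrated_cells_recover_target(self, study_prevalence):
        te_t, cde_t = 0.02, 0.012
        probs = calibrate_cell_probs(
            study_prevalence, te_target=te_t, cde_targets={"M2": cde_t}, baseline=0.2
        )
        cfg = GeneratorConfig(
            n_per_race=2_000_000, prevalence=study_prevalence,
            cell_probs=probs, seed=9, level="cell",
        )
        cells = simulate_cell_counts(cfg)
        te_med = np.median(total_effect(cells, S=10_000, seed=10).values)
        cde_med = np.median(
            controlled_direct_effect(cells, "M2", S=10_000, seed=10).values
        )
        se = np.sqrt(2 * 0.2 * 0.8 / 500_000)  # generous pooled-count bound
        assert te_med == pytest.approx(te_t, abs=4 * se)
        assert cde_med == pytest.approx(cde_t, abs=4 * se)


class TestPercentAttributable:
    def test_equal_draws_give_zero(self):
        te = constant_draws(0.01)
        pa = percent_attributable(te, constant_draws(0.01))
        assert np.all(pa.values == 0.0)

    def test_null_cde_gives_full_elimination(self):
        pa = percent_attributable(constant_draws(0.02), constant_draws(0.0))
        assert np.all(pa.values == 100.0)

    def test_negative_pa_when_cde_exceeds_te(self):
        pa = percent_attributable(constant_draws(0.0105), constant_draws(0.0125))
        assert pa.values[0] == pytest.approx(-19.0476, abs=1e-3)

    def test_zero_te_draws_excluded(self):
        te = PosteriorDraws(np.array([0.0, 0.01, 0.02]))
        cde = PosteriorDraws(np.array([0.005, 0.005, 0.005]))
        pa = percent_attributable(te, cde)
        assert np.isnan(pa.values[0]) and np.isfinite(pa.values[1:]).all()
        est = summarize(pa, scale="percent")
        assert est.n_undefined == 1

    def test_all_zero_te_errors(self):
        with pytest.raises(ValueError, match="all TE draws"):
            percent_attributable(constant_draws(0.0), constant_draws(0.0))

    def test_mismatched_draw_counts_error(self):
        with pytest.raises(ValueError):
            percent_attributable(constant_draws(0.1, S=10), constant_draws(0.1, S=20))

    def test_draw_wise_differs_from_ratio_of_medians(self):
        """PA must be computed per draw: the median of the draw-wise ratio is
        not the ratio of medians for skewed posteriors."""
        rng = np.random.default_rng(11)
        # differences of Beta posteriors with the TE noisy near zero, the
        # regime where the ratio's skew matters
        te = PosteriorDraws(rng.beta(8, 992, 20_000) - rng.beta(4, 996, 20_000))
        cde = PosteriorDraws(rng.beta(10, 990, 20_000) - rng.beta(7, 993, 20_000))
        draw_wise = summarize(percent_attributable(te, cde), scale="percent").median
        of_medians = 100 * (np.median(te.values) - np.median(cde.values)) / np.median(
            te.values
        )
        assert abs(draw_wise - of_medians) > 1.0


class TestSummarize:
    def test_constant_draws(self):
        est = summarize(constant_draws(0.3))
        assert (est.median, est.ci_low, est.ci_high) == (0.3, 0.3, 0.3)
        assert est.significant
        assert not summarize(constant_draws(0.0)).significant

    def test_symmetric_draws_non_significant(self):
        rng = np.random.default_rng(12)
        est = summarize(PosteriorDraws(rng.normal(0, 1, size=10_000)))
        assert not est.significant

    def test_uniform_draws_order_statistics(self):
        rng = np.random.default_rng(13)
        est = summarize(PosteriorDraws(rng.random(10_000)))
        se = lambda q: np.sqrt(q * (1 - q) / 10_000)
        assert est.median == pytest.approx(0.5, abs=3 * se(0.5))
        assert est.ci_low == pytest.approx(0.025, abs=3 * se(0.025))
        assert est.ci_high == pytest.approx(0.975, abs=3 * se(0.975))

    def test_per_1000_scaling(self):
        est = summarize(constant_draws(0.0105), scale="per-1000")
        assert est.median == pytest.approx(10.5)

    def test_estimate_invariant_enforced(self):
        with pytest.raises(ValueError):
            EffectEstimate(median=1.0, ci_low=2.0, ci_high=3.0,
                           significant=True)


class TestRunAnalysis:
    @staticmethod
    def null_cells(outcome="o", seed=14):
        rng = np.random.default_rng(seed)
        n = np.full((2, 2, 2), 2000)
        return CellCounts(rng.binomial(n, 0.1), n, outcome=outcome)

    def test_null_simulation_flags_unstable_pa(self):
        report = run_analysis({"o": self.null_cells()}, S=2000, seed=15)
        te_row = report[report.estimate_type == "TE"].iloc[0]
        assert not te_row.significant
        assert not report[report.estimate_type.str.startswith("PA")].stable.any()

    def test_identical_outcomes_identical_rows(self):
        cells = self.null_cells()
        a = CellCounts(cells.r, cells.n, outcome="same")
        b = CellCounts(cells.r, cells.n, outcome="same")
        ra = run_analysis({"same": a}, S=1000, seed=16)
        rb = run_analysis({"same": b}, S=1000, seed=16)
        assert ra.equals(rb)

    def test_report_shape_and_columns(self):
        report = run_analysis(
            {"a": self.null_cells("a"), "b": self.null_cells("b", seed=17)},
            S=1000, seed=18,
        )
        assert len(report) == 8
        assert set(report.estimate_type) == {"TE", "PA_M1", "PA_M2", "PA_M1M2"}
        assert (report[report.estimate_type == "TE"].scale == "per-1000").all()

    def test_rejects_too_few_draws(self):
        with pytest.raises(ValueError):
            run_analysis({"o": self.null_cells()}, S=10)


def test_substream_seeds_distinct_and_bounded():
    seeds = {substream_seed(1, "a", lab) for lab in ("x", "y", "z")}
    assert len(seeds) == 3
    assert all(0 <= s < 2**31 for s in seeds)
    assert substream_seed(1, "a") != substream_seed(2, "a")


def test_parameter_recovery_on_calibrated_simulation(study_prevalence):
    """TE and each CDE median lie within 4 simulation SEs of the generating
    truth at 1e6 births per race."""
    targets = {"M1": 0.004, "M2": -0.003, "M1M2": 0.008}
    probs = calibrate_cell_probs(
        study_prevalence, te_target=0.012, cde_targets=targets, baseline=0.15
    )
    cells = simulate_cell_counts(
        GeneratorConfig(n_per_race=1_000_000, prevalence=study_prevalence,
                        cell_probs=probs, seed=19, level="cell")
    )
    te_med = np.median(total_effect(cells, S=10_000, seed=20).values)
    se_te = np.sqrt(2 * 0.15 * 0.85 / 1_000_000)
    assert te_med == pytest.approx(0.012, abs=4 * se_te)
    for margin, target in targets.items():
        med = np.median(
            controlled_direct_effect(cells, margin, S=10_000, seed=20).values
        )
        # smallest pooled cell is (x=2, m1=1, m2=1): ~9.7% of 1e6 births
        se = np.sqrt(2 * 0.16 * 0.84 / 97_000)
        assert med == pytest.approx(target, abs=4 * se)
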