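import numpy as np
import pytest

from esrecal import (
    calibration_report,
    expected_deaths,
    hosmer_lemeshow,
    oe_ratio,
    quartile_audit,
    summarize,
)

from conftest import make_cohort


class TestOERatio:
    @pytest.mark.parametrize(
        "observed, predicted, printed",
        [(6.27, 4.82, 1.30), (8.21, 5.06, 1.62), (4.54, 4.61, 0.98)],
    )
    def test_group_level_ratios(self, observed, predicted, printed):
        assert round(oe_ratio(observed, predicted), 2) == printed

    def test_full_precision(self):
        assert oe_ratio(6.27, 4.82) == pytest.approx(1.3008, abs=5e-5)

    def test_perfect_calibration(self):
        assert oe_ratio(3.7, 3.7) == 1.0

    def test_nonpositive_predicted_rejected(self):
        with pytest.raises(ValueError):
            oe_ratio(5.0, 0.0)


class TestExpectedDeaths:
    def test_offpump_count(self):
        cohort = make_cohort(np.full(3042, 4.61), np.zeros(3042))
        e = expected_deaths(cohort)
        assert e == pytest.approx(140.24, abs=0.005)
        assert round(e) == 140

    def test_onpump_count(self):
        cohort = make_cohort(np.full(2729, 5.06), np.zeros(2729))
        assert round(expected_deaths(cohort)) == 138

    def test_certainty_limit(self):
        cohort = make_cohort(np.full(10, 100.0), np.ones(10))
        assert expected_deaths(cohort) == 10.0

    def test_misaligned_vector_rejected(self):
        cohort = make_cohort([1, 2, 3], [0, 0, 1])
        with pytest.raises(ValueError, match="align"):
            expected_deaths(cohort, np.array([1.0, 2.0]))


class TestHosmerLemeshow:
    def _two_group_cohort(self):
        # group A: n=100 predicted 10%, 10 deaths; group B: n=100 predicted 20%, 30 deaths
        scores = np.concatenate([np.full(100, 10.0), np.full(100, 20.0)])
        died = np.concatenate([np.ones(10), np.zeros(90), np.ones(30), np.zeros(70)])
        return make_cohort(scores, died)

    def test_hand_computed_two_cell_statistic(self):
        # A contributes 0; B contributes (30-20)^2 / (20 * 0.8) = 6.25
        hl = hosmer_lemeshow(self._two_group_cohort(), n_groups=2)
        assert hl.statistic == pytest.approx(6.25, abs=1e-12)
        assert hl.df == 2  # validation convention: df = g

    def test_development_df_convention(self):
        hl = hosmer_lemeshow(self._two_group_cohort(), n_groups=2,
                             df_convention="development")
        assert hl.df == 1

    def test_statistic_equals_brute_force_two_cell_chi_square(self):
        rng = np.random.default_rng(8)
        scores = rng.uniform(1, 40, size=600)
        died = (rng.uniform(size=600) < scores / 50).astype(int)
        cohort = make_cohort(scores, died)
        hl = hosmer_lemeshow(cohort, n_groups=10)
        brute = 0.0
        for b in hl.bins:
            exp_dead = b.expected_deaths
            exp_alive = b.n - exp_dead
            obs_dead = b.observed_deaths
            obs_alive = b.n - obs_dead
            brute += (obs_dead - exp_dead) ** 2 / exp_dead
            brute += (obs_alive - exp_alive) ** 2 / exp_alive
        assert hl.statistic == pytest.approx(brute, rel=1e-12)

    def test_perfect_fit_statistic_zero(self):
        hl = hosmer_lemeshow(
            make_cohort(
                np.concatenate([np.full(100, 10.0), np.full(100, 20.0)]),
                np.concatenate([np.ones(10), np.zeros(90), np.ones(20), np.zeros(80)]),
            ),
            n_groups=2,
        )
        assert hl.statistic == pytest.approx(0.0, abs=1e-12)
        assert hl.p_value == pytest.approx(1.0)

    def test_preconditions(self):
        cohort = make_cohort([1, 2, 3], [0, 1, 0])
        with pytest.raises(ValueError):
            hosmer_lemeshow(cohort, n_groups=1)
        with pytest.raises(ValueError):
            hosmer_lemeshow(cohort, n_groups=5)
        with pytest.raises(ValueError):
            hosmer_lemeshow(cohort, df_convention="bogus", n_groups=2)

    def test_tie_heavy_grouping_warns_but_runs(self):
        scores = np.concatenate([np.full(150, 5.0), np.full(150, 9.0)])
        died = np.concatenate([np.ones(8), np.zeros(142), np.ones(14), np.zeros(136)])
        with pytest.warns(UserWarning, match="ties reduced"):
            hl = hosmer_lemeshow(make_cohort(scores, died), n_groups=10)
        assert len(hl.bins) == 2


class TestQuartileAudit:
    def _calibrated_cohort(self, n=40_000, seed=5):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(1, 100, size=n)
        died = (rng.uniform(size=n) < scores / 100).astype(int)
        return make_cohort(scores, died)

    def test_rows_partition_cohort(self, mortality_cohort):
        table = quartile_audit(mortality_cohort)
        assert sum(r.n for r in table.rows) == 2729

    def test_conservation_of_deaths_and_expectation(self):
        cohort = self._calibrated_cohort(n=2000)
        table = quartile_audit(cohort)
        assert sum(r.observed_deaths for r in table.rows) == int(cohort.died.sum())
        assert sum(r.expected_deaths for r in table.rows) == pytest.approx(
            expected_deaths(cohort), rel=1e-12
        )

    def test_calibrated_simulation_oe_near_one(self):
        table = quartile_audit(self._calibrated_cohort())
        for row in table.rows:
            assert row.oe_ratio == pytest.approx(1.0, abs=0.1)

    def test_fixed_published_boundaries(self):
        cohort = self._calibrated_cohort(n=5000, seed=6)
        scores = np.clip(cohort.scores, 0.88, 83.14)
        table = quartile_audit(cohort, predicted=scores,
                               boundaries=(0.88, 1.92, 3.05, 5.14))
        assert len(table.rows) == 4
        assert sum(r.n for r in table.rows) == 5000
        assert table.rows[0].low == 0.88 and table.rows[3].low == 5.14

    def test_unassigned_patient_rejected(self):
        cohort = make_cohort([0.5, 2, 3, 4], [0, 0, 1, 0])
        with pytest.raises(ValueError, match="below the first boundary"):
            quartile_audit(cohort, boundaries=(0.88, 1.92, 3.05, 5.14))

    def test_all_equal_scores_collapse_with_warning(self):
        cohort = make_cohort(np.full(8, 3.0), [0, 1, 0, 0, 0, 1, 0, 0])
        with pytest.warns(UserWarning, match="collapsed"):
            table = quartile_audit(cohort)
        assert len(table.rows) == 1
        assert table.rows[0].n == 8

    def test_dataframe_export_shape(self):
        df = quartile_audit(self._calibrated_cohort(n=400, seed=2)).to_dataframe()
        assert list(df.columns)[0] == "interval"
        assert len(df) == 4


def test_oe_times_expected_equals_observed_deaths():
    """Algebraic identity: O/E * expected deaths = observed deaths, full precision."""
    rng = np.random.default_rng(11)
    scores = rng.uniform(0.9, 60, size=3000)
    died = (rng.uniform(size=3000) < scores / 80).astype(int)
    cohort = make_cohort(scores, died)
    s = summarize(cohort)
    ratio = oe_ratio(s.observed_mortality_pct, s.mean_es2_pct)
    assert ratio * expected_deaths(cohort) == pytest.approx(s.deaths, rel=1e-12)


def test_calibration_report_internal_consistency():
    rng = np.random.default_rng(12)
    scores = rng.uniform(0.9, 60, size=3000)
    died = (rng.uniform(size=3000) < scores / 80).astype(int)
    cohort = make_cohort(scores, died)
    rep = calibration_report(cohort)
    assert rep.oe_ratio == pytest.approx(rep.observed_pct / rep.predicted_pct, rel=1e-12)
    assert rep.expected_deaths == pytest.approx(rep.n * rep.predicted_pct / 100, rel=1e-12)
    assert rep.hl_statistic >= 0
    assert sum(b.n for b in rep.bins) == rep.n
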