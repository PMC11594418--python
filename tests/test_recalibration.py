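import json

import numpy as np
import pytest

from esrecal import (
    CorrectionModel,
    ScoreRecalibration,
    SyntheticConfig,
    apply_correction,
    fit_correction,
    generate_cohort,
    validate_correction,
)

from conftest import make_cohort

PUBLISHED = CorrectionModel(a=1.6545, b=-0.0067)


class TestApplyCorrection:
    def test_zero_fixed_point(self):
        assert apply_correction(PUBLISHED, 0.0) == 0.0

    @pytest.mark.parametrize(
        "x, expected",
        [(5.06, 8.2002), (1.00, 1.6478), (100.0, 98.45)],
    )
    def test_published_coefficient_arithmetic(self, x, expected):
        assert apply_correction(PUBLISHED, x) == pytest.approx(expected, abs=5e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_correction(PUBLISHED, 101.0)
        with pytest.raises(ValueError):
            apply_correction(PUBLISHED, -0.5)

    def test_clamping_warns(self):
        inflating = CorrectionModel(a=3.0, b=0.0)
        with pytest.warns(UserWarning, match="clamped"):
            out = apply_correction(inflating, 50.0)
        assert out == 100.0

    def test_strictly_increasing_on_unit_range(self):
        grid = np.linspace(0, 100, 2001)
        out = apply_correction(PUBLISHED, grid)
        assert np.all(np.diff(out) > 0)
        assert out.max() <= 100.0

    def test_inflates_below_crossing_point(self):
        # x(a + bx) = x at x = (a-1)/(-b) = 97.687...
        crossing = (PUBLISHED.a - 1.0) / (-PUBLISHED.b)
        assert crossing == pytest.approx(97.687, abs=0.01)
        grid = np.linspace(0.5, 97.68, 500)
        assert np.all(apply_correction(PUBLISHED, grid) >= grid)

    def test_json_roundtrip(self, tmp_path):
        path = tmp_path / "model.json"
        PUBLISHED.to_json(path, n_fit=2729)
        again = CorrectionModel.from_json(path)
        assert (again.a, again.b) == (PUBLISHED.a, PUBLISHED.b)
        assert json.loads(path.read_text())["n_fit"] == 2729


class TestFitCorrection:
    def test_no_deaths_gives_zero_correction(self):
        cohort = make_cohort([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        with pytest.warns(UserWarning):
            model = fit_correction(cohort)
        assert model.a == pytest.approx(0.0, abs=1e-12)
        assert model.b == pytest.approx(0.0, abs=1e-12)

    def test_identical_scores_singular(self):
        with pytest.raises(ValueError, match="distinct"):
            ScoreRecalibration(np.full(10, 3.0), np.zeros(10, int))

    def test_parameter_recovery_per_patient(self):
        cohort = generate_cohort(
            SyntheticConfig(n=200_000, seed=17, true_a=1.6545, true_b=-0.0067)
        )
        res = ScoreRecalibration.from_cohort(cohort).fit(method="per_patient")
        assert res.params[0] == pytest.approx(1.6545, abs=0.05)
        assert res.params[1] == pytest.approx(-0.0067, abs=0.005)
        assert res.bse[0] < 0.05 and res.bse[1] < 0.005

    def test_binned_fit_recovers_same_curve(self):
        cohort = generate_cohort(
            SyntheticConfig(n=200_000, seed=17, true_a=1.3, true_b=-0.003)
        )
        res = ScoreRecalibration.from_cohort(cohort).fit(method="binned")
        assert res.params[0] == pytest.approx(1.3, abs=0.1)
        assert res.params[1] == pytest.approx(-0.003, abs=0.005)

    def test_consistency_error_shrinks_with_n(self):
        errs = []
        for n in (1_000, 100_000):
            cohort = generate_cohort(
                SyntheticConfig(n=n, seed=11, true_a=1.6545, true_b=-0.0067)
            )
            res = ScoreRecalibration.from_cohort(cohort).fit()
            errs.append(abs(res.params[0] - 1.6545) + 10 * abs(res.params[1] + 0.0067))
        assert errs[-1] < errs[0]

    def test_constrained_fit_gives_exact_unit_oe(self):
        cohort = generate_cohort(
            SyntheticConfig(n=20_000, seed=3, true_a=1.6545, true_b=-0.0067)
        )
        model = fit_correction(cohort, constrain_oe=True)
        corrected = model.apply(cohort.scores)
        oe = (100.0 * cohort.died.mean()) / corrected.mean()
        assert oe == pytest.approx(1.0, abs=1e-10)
        assert model.fit_method == "constrained"

    def test_constraint_cannot_improve_objective(self):
        cohort = generate_cohort(
            SyntheticConfig(n=20_000, seed=3, true_a=1.6545, true_b=-0.0067)
        )
        recal = ScoreRecalibration.from_cohort(cohort)
        assert recal.fit(constrain_oe=True).ssr >= recal.fit().ssr

    def test_refitting_corrected_scores_is_identity(self):
        cohort = generate_cohort(
            SyntheticConfig(n=100_000, seed=5, true_a=1.6545, true_b=-0.0067)
        )
        model = fit_correction(cohort)
        corrected = make_cohort(model.apply(cohort.scores), cohort.died)
        res = ScoreRecalibration.from_cohort(corrected).fit()
        assert res.params[0] == pytest.approx(1.0, abs=0.05)
        assert res.params[1] == pytest.approx(0.0, abs=0.003)

    def test_summary_smoke(self):
        cohort = generate_cohort(SyntheticConfig(n=2_000, seed=1))
        text = ScoreRecalibration.from_cohort(cohort).fit().summary()
        assert "per_patient" in text and "std err" in text


class TestValidateCorrection:
    def _cohort(self):
        return generate_cohort(
            SyntheticConfig(n=20_000, seed=21, true_a=1.6545, true_b=-0.0067)
        )

    def test_identity_model_matches_uncorrected_report(self):
        from esrecal import calibration_report

        cohort = self._cohort()
        base = calibration_report(cohort)
        rep = validate_correction(cohort, CorrectionModel(1.0, 0.0))
        assert rep.oe_ratio == pytest.approx(base.oe_ratio, rel=1e-12)
        assert rep.hl_statistic == pytest.approx(base.hl_statistic, rel=1e-9)
        assert rep.auc_invariant is True

    def test_constrained_model_validates_to_unit_oe(self):
        cohort = self._cohort()
        model = fit_correction(cohort, constrain_oe=True)
        rep = validate_correction(cohort, model)
        assert rep.oe_ratio == pytest.approx(1.0, abs=1e-10)
        assert rep.auc_invariant is True

    def test_correction_moves_expected_toward_observed(self):
        cohort = self._cohort()
        model = fit_correction(cohort)
        before = validate_correction(cohort, CorrectionModel(1.0, 0.0))
        after = validate_correction(cohort, model)
        assert abs(after.oe_ratio - 1.0) < abs(before.oe_ratio - 1.0)
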