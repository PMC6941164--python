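"""Agreement statistics, MSEP decomposition, cross-validation and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vfamethane import (
    evaluate_pairs,
    external_validate,
    lin_ccc,
    loeo_crossval,
    make_fixture,
    msep_decomposition,
    pearson_r,
    published_equation,
    rank_models,
    rmsep,
    rmsep_from_msep_components,
    variance_component_sds,
)
from vfamethane.evaluation import EvaluationResult


class TestRmsep:
    def test_identity_is_zero(self):
        assert rmsep([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_arithmetic(self):
        assert rmsep([1, 2, 3], [2, 2, 2]) == pytest.approx(0.81650, abs=1e-5)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(5)
        obs = rng.normal(20, 4, 10)
        pred = obs + rng.normal(0, 2, 10)
        total = 0.0
        for o, p in zip(obs, pred):
            total += (o - p) ** 2
        assert rmsep(obs, pred) == pytest.approx(np.sqrt(total / 10), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsep([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            rmsep([], [])


class TestLinCcc:
    def test_identical_series(self):
        assert lin_ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_negative_agreement(self):
        assert lin_ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_arithmetic_with_shift(self):
        # 2*s_xy / (s_x^2 + s_y^2 + bias^2) = 2*(2/3) / (2/3 + 2/3 + 1) = 4/7
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4.0 / 7.0, abs=1e-10)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        obs = rng.normal(20, 4, 100)
        pred = 0.8 * obs + rng.normal(3, 2, 100)
        n = len(obs)
        mx, my = sum(obs) / n, sum(pred) / n
        sxy = sum((a - mx) * (b - my) for a, b in zip(obs, pred)) / n
        sx2 = sum((a - mx) ** 2 for a in obs) / n
        sy2 = sum((b - my) ** 2 for b in pred) / n
        expected = 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)
        assert lin_ccc(obs, pred) == pytest.approx(expected, abs=1e-10)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            lin_ccc([1.0, 1.0], [1.0, 1.0])

    @given(
        arrays(np.float64, 20, elements=st.floats(-50, 50)),
        arrays(np.float64, 20, elements=st.floats(-50, 50)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounded_and_dominated_by_pearson(self, x, y):
        if np.std(x) < 1e-6 or np.std(y) < 1e-6:
            return
        ccc = lin_ccc(x, y)
        r = pearson_r(x, y)
        assert -1.0 - 1e-12 <= ccc <= 1.0 + 1e-12
        assert abs(ccc) <= abs(r) + 1e-9

    def test_equals_pearson_when_moments_match(self):
        rng = np.random.default_rng(23)
        x = rng.normal(0, 1, 500)
        y = rng.normal(0, 1, 500)
        # force exactly equal means and variances
        y = (y - y.mean()) / y.std() * x.std() + x.mean()
        assert lin_ccc(x, y) == pytest.approx(pearson_r(x, y), abs=1e-10)


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(29)
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        assert pearson_r(x, y) == pytest.approx(
            cov / (x.std() * y.std()), abs=1e-12
        )


class TestMsepDecomposition:
    def test_identical_series_all_zero(self):
        assert msep_decomposition([1, 2, 3], [1, 2, 3]) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        ect, er, ed = msep_decomposition([0.0, 2.0], [0.0, 1.0])
        assert (ect, er, ed) == pytest.approx((0.25, 0.25, 0.0))
        assert ect + er + ed == pytest.approx(rmsep([0, 2], [0, 1]) ** 2)

    @given(
        arrays(np.float64, 30, elements=st.floats(-100, 100)),
        arrays(np.float64, 30, elements=st.floats(-100, 100)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_components_sum_to_msep(self, obs, pred):
        if np.std(obs) < 1e-6:
            return
        ect, er, ed = msep_decomposition(obs, pred)
        assert ect >= 0 and er >= 0 and ed >= 0
        assert ect + er + ed == pytest.approx(
            np.mean((obs - pred) ** 2), rel=1e-9, abs=1e-9
        )

    def test_recomposition_helper(self):
        assert rmsep_from_msep_components(3.3, 0.47, 9.3) == pytest.approx(
            np.sqrt(13.07)
        )
        with pytest.raises(ValueError):
            rmsep_from_msep_components(-1.0, 0.0, 0.0)


class TestVarianceComponentSds:
    def test_pooled_lack_of_fit_and_residual(self):
        lof, resid = variance_component_sds((1.7, 1.5, 6.9))
        assert lof == pytest.approx(np.sqrt(3.2))
        assert resid == pytest.approx(np.sqrt(6.9))


class TestEvaluationResult:
    def test_inconsistent_components_rejected(self):
        with pytest.raises(ValueError):
            EvaluationResult(
                n=10, rmsep=2.0, ccc=0.5, msep=4.0, msep_components=(1.0, 1.0, 1.0)
            )

    def test_evaluate_pairs_satisfies_identities(self):
        rng = np.random.default_rng(31)
        obs = rng.normal(20, 4, 50)
        pred = obs + rng.normal(0, 2, 50)
        res = evaluate_pairs(obs, pred)
        assert res.msep == pytest.approx(res.rmsep**2)
        assert sum(res.msep_components) == pytest.approx(res.msep)
        assert res.n == 50


class TestCrossValidation:
    def test_noiseless_two_experiments_perfect_recovery(self, noiseless_m3):
        report = loeo_crossval(noiseless_m3, forms=["M3"])
        res = report.results["M3"]
        assert res.rmsep == pytest.approx(0.0, abs=1e-8)
        assert res.ccc == pytest.approx(1.0, abs=1e-8)
        assert report.ranking["M3"] == 1

    def test_fold_bookkeeping(self, study_scale):
        report = loeo_crossval(study_scale, forms=["M4"])
        assert report.n_folds == study_scale.n_experiments == 7
        preds = report.predictions
        assert len(preds) == len(study_scale)
        assert preds["predicted"].notna().all()
        assert set(preds["fold"]) == set(range(7))

    def test_pooled_predictions_invariant_to_record_order(self, tiny_2exp):
        from vfamethane import Dataset

        shuffled = Dataset(
            records=list(reversed(tiny_2exp.records)),
            provenance=tiny_2exp.provenance,
        )
        a = loeo_crossval(tiny_2exp, forms=["M4"]).predictions
        b = loeo_crossval(shuffled, forms=["M4"]).predictions
        key = ["experiment_id", "treatment_id", "cow_id"]
        merged = a.merge(b, on=key, suffixes=("_a", "_b"))
        assert len(merged) == len(a)
        np.testing.assert_allclose(
            merged["predicted_a"], merged["predicted_b"], rtol=1e-8
        )

    def test_single_experiment_rejected(self, tiny_2exp):
        one = tiny_2exp.subset([tiny_2exp.experiment_ids[0]])
        with pytest.raises(ValueError, match="at least 2 experiments"):
            loeo_crossval(one, forms=["M4"])

    def test_failed_form_does_not_abort_others(self, tiny_2exp):
        # M6 cannot fit: the fixture has no propionate concentrations
        report = loeo_crossval(tiny_2exp, forms=["M4", "M6"])
        assert "M4" in report.results
        assert "M6" in report.failed
        assert "M6" not in report.ranking


class TestRanking:
    def _result(self, rmsep_value, ccc_value):
        return EvaluationResult(
            n=10,
            rmsep=rmsep_value,
            ccc=ccc_value,
            msep=rmsep_value**2,
            msep_components=(0.0, 0.0, rmsep_value**2),
        )

    def test_rounded_ties_share_rank_one(self):
        results = {
            "M3": self._result(3.16, 0.69),
            "M4": self._result(3.18, 0.70),
            "M7": self._result(3.21, 0.703),
        }
        assert rank_models(results) == {"M3": 1, "M4": 1, "M7": 1}

    def test_single_form(self):
        assert rank_models({"M4": self._result(3.2, 0.7)}) == {"M4": 1}

    def test_competition_ranking(self):
        results = {
            "a": self._result(1.0, 0.5),
            "b": self._result(2.0, 0.5),
            "c": self._result(2.0, 0.5),
            "d": self._result(3.0, 0.5),
        }
        assert rank_models(results) == {"a": 1, "b": 2, "c": 2, "d": 4}

    def test_ccc_breaks_rmsep_ties(self):
        results = {"lo": self._result(3.2, 0.50), "hi": self._result(3.2, 0.70)}
        assert rank_models(results) == {"hi": 1, "lo": 2}

    def test_published_table_ranks_reproduced(self):
        """The seven published (RMSEP, CCC) pairs must put the three best
        equations jointly at rank 1 and the concentration model last."""
        results = {
            "M1C": self._result(3.7, 0.52),
            "M2": self._result(3.6, 0.63),
            "M3": self._result(3.2, 0.69),
            "M4": self._result(3.2, 0.70),
            "M5": self._result(3.5, 0.63),
            "M6": self._result(4.2, 0.36),
            "M7": self._result(3.2, 0.70),
        }
        ranking = rank_models(results)
        assert ranking["M3"] == ranking["M4"] == ranking["M7"] == 1
        assert ranking["M6"] == 7


class TestExternalValidation:
    def test_correctly_specified_has_no_bias_terms(self, noiseless_m4):
        res = external_validate(published_equation("M4"), noiseless_m4)
        ect, er, ed = res.msep_components
        assert ect == pytest.approx(0.0, abs=1e-12)
        assert er == pytest.approx(0.0, abs=1e-12)
        assert res.rmsep == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_appears_as_central_tendency_error(self):
        shifted = make_fixture("shifted_bias")
        res = external_validate(published_equation("M4"), shifted)
        ect, er, ed = res.msep_components
        assert ect == pytest.approx(1.0, abs=1e-10)
        assert er == pytest.approx(0.0, abs=1e-10)
        assert ed == pytest.approx(0.0, abs=1e-10)
        assert res.msep == pytest.approx(1.0, abs=1e-10)

    def test_msep_identity_on_noisy_data(self, study_scale):
        res = external_validate(published_equation("M7"), study_scale)
        assert sum(res.msep_components) == pytest.approx(res.msep, rel=1e-9)
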