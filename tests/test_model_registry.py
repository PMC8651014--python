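import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import afscreen as a
from afscreen import model_registry as mr


def _participant(**kw):
    base = dict(
        id="x", age=50.0, sex="male", smoking="never", height=1.75, weight=80.0,
        bmi=26.1, sbp=120.0, heart_rate=65.0,
        hypertension=0.0, antihypertensive_medication=0.0, diabetes=0.0, chd=0.0,
        valvular_disease=0.0, chf=0.0, copd=0.0, pad=0.0, stroke_tia=0.0,
    )
    base.update(kw)
    return pd.DataFrame([base])


class TestLoadDefinitions:
    def test_bundled_models(self, models):
        assert set(models) == {"CHADS2", "CHA2DS2-VASc", "HATCH", "C2HEST", "CHARGE-AF"}
        vasc = models["CHA2DS2-VASc"]
        assert vasc.kind == "score_chart"
        assert len(vasc.terms) == 8  # 7 predictors; age contributes two bands
        assert models["CHARGE-AF"].kind == "cox_linear_predictor"
        for m in models.values():
            assert m.source_citation

    def test_unknown_predictor_rejected(self):
        doc = {
            "name": "bad", "kind": "logistic_equation",
            "terms": [{"predictor": "nt_probnp", "weight": 1.0}],
        }
        with pytest.raises(ValueError, match="nt_probnp"):
            mr.RiskModel.model_validate(doc)

    def test_omitted_terms_may_reference_unknowns(self, models):
        omitted = [t.predictor for t in models["CHARGE-AF"].terms if t.omitted]
        assert omitted == ["ethnicity", "dbp"]

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError):
            mr.RiskModel.model_validate({"name": "e", "kind": "score_chart", "terms": []})

    def test_duplicate_names_rejected(self, tmp_path):
        doc = (
            '{"name": "M", "kind": "score_chart", '
            '"terms": [{"predictor": "diabetes", "points": 1}]}'
        )
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        p1.write_text(doc)
        p2.write_text(doc)
        with pytest.raises(ValueError, match="duplicate"):
            mr.load_model_definitions([p1, p2])

    def test_weight_points_exclusivity(self):
        with pytest.raises(ValueError):
            mr.PredictorTerm(predictor="diabetes", weight=1.0, points=1)


class TestLinearPredictor:
    def test_per_units_arithmetic(self):
        model = mr.RiskModel(
            name="toy", kind="logistic_equation",
            terms=[mr.PredictorTerm(predictor="age", transform=mr.Transform(type="per_units", k=10), weight=0.5)],
        )
        lp = mr.linear_predictor(model, _participant(age=20.0))
        assert lp[0] == pytest.approx(1.0)

    def test_all_reference_levels_give_zero(self, models):
        # youngest never-smoking male with zeroed continuous predictors
        rec = _participant(age=0.0, height=0.0, weight=0.0, sbp=0.0)
        lp = mr.linear_predictor(models["CHARGE-AF"], rec)
        assert lp[0] == 0.0

    def test_charge_af_hand_computed(self, models):
        rec = _participant(
            age=60.0, height=1.70, weight=80.0, sbp=130.0, smoking="current",
            antihypertensive_medication=1.0, diabetes=1.0, chf=0.0, chd=1.0,
        )
        expected = (
            0.508 * 60 / 5 + 0.248 * 170 / 10 + 0.115 * 80 / 15 + 0.197 * 130 / 20
            + 0.359 + 0.349 + 0.237 + 0.496
        )
        lp = mr.linear_predictor(models["CHARGE-AF"], rec)
        assert lp[0] == pytest.approx(expected, rel=1e-12)

    def test_missing_predictor_signals_pre_imputation_use(self, models):
        rec = _participant(sbp=np.nan)
        with pytest.raises(ValueError, match="sbp"):
            mr.linear_predictor(models["CHARGE-AF"], rec)

    def test_score_chart_rejected(self, models):
        with pytest.raises(ValueError, match="score_chart"):
            mr.linear_predictor(models["CHADS2"], _participant())


class TestSumScore:
    @pytest.mark.parametrize(
        "model_name,record_kw,expected",
        [
            ("CHA2DS2-VASc", dict(age=75.0, sex="female", hypertension=1.0, diabetes=1.0), 5),
            ("CHA2DS2-VASc", dict(age=50.0, sex="male"), 0),
            ("CHA2DS2-VASc", dict(age=70.0, sex="female", pad=1.0), 3),
            ("CHADS2", dict(age=80.0, stroke_tia=1.0), 3),
            ("CHADS2", dict(age=74.0, chf=1.0, hypertension=1.0, diabetes=1.0), 3),
            ("HATCH", dict(age=80.0, copd=1.0, chf=1.0), 4),
            ("C2HEST", dict(age=76.0, chd=1.0, copd=1.0, hypertension=1.0), 5),
        ],
    )
    def test_published_chart_examples(self, models, model_name, record_kw, expected):
        score = mr.sum_score(models[model_name], _participant(**record_kw))
        assert score[0] == expected

    def test_term_order_permutation_invariant(self, models):
        m = models["CHA2DS2-VASc"]
        reordered = m.model_copy(update={"terms": list(reversed(m.terms))})
        rec = _participant(age=78.0, sex="female", chf=1.0, stroke_tia=1.0)
        assert mr.sum_score(m, rec)[0] == mr.sum_score(reordered, rec)[0]


class TestRecalibration:
    def test_constant_lp_closed_form(self):
        lp = np.full(1000, 2.0)
        y = np.r_[np.ones(10), np.zeros(990)]
        alpha = mr.recalibrate_intercept(lp, y)
        assert alpha == pytest.approx(np.log(0.01 / 0.99) - 2.0, abs=1e-8)

    def test_two_point_zero(self):
        assert mr.recalibrate_intercept([0.0, 0.0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-10)

    def test_mean_predicted_equals_prevalence(self):
        rng = np.random.default_rng(0)
        lp = rng.normal(size=5000)
        y = (rng.random(5000) < 0.01).astype(float)
        alpha = mr.recalibrate_intercept(lp, y)
        assert abs(mr.predicted_probability(alpha, lp).mean() - y.mean()) < 1e-10

    def test_recovers_generating_intercept(self):
        """Simulation recovery of a known calibration intercept over seeds."""
        true_alpha = -5.49
        failures = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            lp = rng.normal(size=20_000)
            y = (rng.random(20_000) < expit(true_alpha + lp)).astype(float)
            alpha = mr.recalibrate_intercept(lp, y)
            p = mr.predicted_probability(alpha, lp)
            se = 1.0 / np.sqrt(np.sum(p * (1 - p)))
            if abs(alpha - true_alpha) > 3 * se:
                failures += 1
        assert failures <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mr.recalibrate_intercept([0.1, 0.2], [1.0, 1.0])

    def test_omitting_constant_term_preserves_ranking(self, models, small_cohort):
        model = models["CHARGE-AF"]
        # force the diabetes column constant so its term only shifts the LP
        cohort = small_cohort.assign(diabetes=1.0)
        lp_full = mr.linear_predictor(model, cohort)
        dropped = model.model_copy(
            update={"terms": [
                t if t.predictor != "diabetes" else t.model_copy(update={"omitted": True})
                for t in model.terms
            ]}
        )
        lp_drop = mr.linear_predictor(dropped, cohort)
        np.testing.assert_allclose(lp_full - lp_drop, 0.237, rtol=1e-12)
        assert (np.argsort(lp_full, kind="stable") == np.argsort(lp_drop, kind="stable")).all()


class TestPredictedProbability:
    def test_values(self):
        assert mr.predicted_probability(0.0, 0.0) == pytest.approx(0.5)
        assert mr.predicted_probability(np.log(0.0041 / 0.9959), 0.0) == pytest.approx(0.0041)
        assert mr.predicted_probability(-5.0, 2.0) == pytest.approx(1 / (1 + np.e**3), rel=1e-6)

    def test_monotone(self):
        p = mr.predicted_probability(0.0, np.linspace(-5, 5, 11))
        assert (np.diff(p) > 0).all()
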