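"""Cox partial-likelihood loss and the risk predictor network."""

import numpy as np
import pytest

from cinerisk.fingerprint import Fingerprint
from cinerisk.io import CohortTable, SurvivalRecord
from cinerisk.risk import (
    PredictorConfig,
    cox_loss_and_gradient,
    cox_partial_log_likelihood,
    combine_fold_predictions,
    predict_risk,
    train_risk_predictor,
    RiskResult,
)
from cinerisk.stats import concordance_index


class TestPartialLikelihood:
    def test_two_subject_symmetric_risk_set(self):
        val = cox_partial_log_likelihood(
            np.array([0.3, 0.3]), np.array([1.0, 2.0]), np.array([1, 0])
        )
        assert val == pytest.approx(np.log(0.5), abs=1e-10)

    def test_three_subject_hand_computed(self):
        # events at t=1 (risk set all three) and t=2 (risk set subjects 2,3)
        eta = np.array([np.log(2), 0.0, 0.0])
        val = cox_partial_log_likelihood(eta, np.array([1.0, 2.0, 2.5]), np.array([1, 1, 0]))
        assert val == pytest.approx(-2 * np.log(2), abs=1e-10)

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        eta = rng.normal(size=10)
        t = rng.exponential(size=10)
        e = (rng.uniform(size=10) < 0.6).astype(int)
        e[0] = 1
        a = cox_partial_log_likelihood(eta, t, e)
        b = cox_partial_log_likelihood(eta + 17.3, t, e)
        assert a == pytest.approx(b, abs=1e-9)

    def test_breslow_ties_share_risk_set(self):
        # two events tied at t=1, risk set = all three for both
        eta = np.array([0.0, 0.0, 0.0])
        val = cox_partial_log_likelihood(eta, np.array([1.0, 1.0, 2.0]), np.array([1, 1, 0]))
        assert val == pytest.approx(2 * np.log(1 / 3), abs=1e-12)

    def test_zero_events_raises(self):
        with pytest.raises(ValueError, match="zero events"):
            cox_partial_log_likelihood(np.zeros(3), np.arange(1.0, 4.0), np.zeros(3, int))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 13))
            eta = rng.normal(size=n)
            t = np.round(rng.exponential(size=n), 1) + 0.1  # induces ties
            e = (rng.uniform(size=n) < 0.7).astype(int)
            if e.sum() == 0:
                e[int(rng.integers(n))] = 1
            _, grad = cox_loss_and_gradient(eta, t, e)
            h = 1e-6
            for j in range(n):
                ep = eta.copy(); ep[j] += h
                em = eta.copy(); em[j] -= h
                fd = (
                    cox_loss_and_gradient(ep, t, e)[0] - cox_loss_and_gradient(em, t, e)[0]
                ) / (2 * h)
                assert grad[j] == pytest.approx(fd, abs=1e-5)


def _synthetic_fingerprints(n, d=6, seed=0, beta=1.5, censor=8.0):
    """Latent fingerprints whose first coordinate drives an exponential hazard."""
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, d))
    lam = 0.1 * np.exp(beta * Z[:, 0])
    t_event = rng.exponential(1 / lam)
    times = np.minimum(t_event, censor)
    events = (t_event <= censor).astype(int)
    fps = [Fingerprint(mean=Z[i], log_variance=np.zeros(d), subject_id=f"s{i:03d}")
           for i in range(n)]
    recs = [
        SurvivalRecord(f"s{i:03d}", max(times[i], 1e-6), int(events[i]))
        for i in range(n)
    ]
    return fps, CohortTable(records=recs, outcome_label="VA"), Z


class TestTrainRiskPredictor:
    def test_loss_decreases_over_early_epochs(self):
        fps, cohort, _ = _synthetic_fingerprints(80, seed=1)
        model = train_risk_predictor(fps, cohort, [f.subject_id for f in fps],
                                     PredictorConfig(epochs=60, seed=0))
        smoothed = np.convolve(model.history, np.ones(5) / 5, mode="valid")
        assert smoothed[-1] < smoothed[0]

    def test_competing_deaths_are_censoring_for_primary(self):
        # all non-censored outcomes are competing deaths -> zero usable events
        recs = [SurvivalRecord(f"s{i}", 1.0 + i, 2 if i < 5 else 0) for i in range(10)]
        cohort = CohortTable(records=recs, outcome_label="VA")
        fps = [Fingerprint(mean=np.zeros(3), log_variance=np.zeros(3), subject_id=f"s{i}")
               for i in range(10)]
        with pytest.raises(ValueError, match="events"):
            train_risk_predictor(fps, cohort, [f.subject_id for f in fps])

    def test_true_labels_beat_permuted_labels_out_of_sample(self):
        fps, cohort, Z = _synthetic_fingerprints(240, seed=3)
        ids = [f.subject_id for f in fps]
        train, test = ids[:180], ids[180:]
        sub = cohort.subset(test)
        t_test, e_test = sub.times(), sub.event_flags()
        model = train_risk_predictor(fps, cohort, train, PredictorConfig(seed=0))
        eta_true = np.array(
            [predict_risk(model, f).linear_predictor for f in fps[180:]]
        )
        c_true = concordance_index(eta_true, t_test, e_test)[0]

        rng = np.random.default_rng(5)
        perm = rng.permutation(180)
        recs = cohort.records
        perm_recs = [
            SurvivalRecord(recs[i].subject_id, recs[perm[i]].time, recs[perm[i]].event_code)
            for i in range(180)
        ] + recs[180:]
        perm_cohort = CohortTable(records=perm_recs, outcome_label="VA")
        model_p = train_risk_predictor(fps, perm_cohort, train, PredictorConfig(seed=0))
        eta_perm = np.array(
            [predict_risk(model_p, f).linear_predictor for f in fps[180:]]
        )
        c_perm = concordance_index(eta_perm, t_test, e_test)[0]
        assert c_true > c_perm

    def test_deterministic_given_seed(self):
        fps, cohort, _ = _synthetic_fingerprints(60, seed=7)
        ids = [f.subject_id for f in fps]
        m1 = train_risk_predictor(fps, cohort, ids, PredictorConfig(seed=4))
        m2 = train_risk_predictor(fps, cohort, ids, PredictorConfig(seed=4))
        assert m1.history[-1] == m2.history[-1]
        f = fps[0]
        assert predict_risk(m1, f).linear_predictor == predict_risk(m2, f).linear_predictor


class TestPredictRisk:
    def test_score_is_logistic_of_eta(self):
        fps, cohort, _ = _synthetic_fingerprints(60, seed=9)
        model = train_risk_predictor(fps, cohort, [f.subject_id for f in fps])
        r = predict_risk(model, fps[0])
        assert r.cine_risk_score == pytest.approx(1 / (1 + np.exp(-r.linear_predictor)))
        assert 0.0 < r.cine_risk_score < 1.0

    def test_score_strictly_increasing_in_eta(self):
        fps, cohort, _ = _synthetic_fingerprints(60, seed=9)
        model = train_risk_predictor(fps, cohort, [f.subject_id for f in fps])
        rs = [predict_risk(model, f) for f in fps]
        etas = np.array([r.linear_predictor for r in rs])
        scores = np.array([r.cine_risk_score for r in rs])
        order = np.argsort(etas)
        assert np.all(np.diff(scores[order]) >= 0)

    def test_identical_fingerprint_identical_result(self):
        fps, cohort, _ = _synthetic_fingerprints(60, seed=11)
        model = train_risk_predictor(fps, cohort, [f.subject_id for f in fps])
        a, b = predict_risk(model, fps[3]), predict_risk(model, fps[3])
        assert (a.linear_predictor, a.cine_risk_score) == (b.linear_predictor, b.cine_risk_score)

    def test_dimension_mismatch_raises(self):
        fps, cohort, _ = _synthetic_fingerprints(60, seed=11)
        model = train_risk_predictor(fps, cohort, [f.subject_id for f in fps])
        bad = Fingerprint(mean=np.zeros(2), log_variance=np.zeros(2), subject_id="zz")
        with pytest.raises(ValueError, match="dimension"):
            predict_risk(model, bad)


class TestCombineFolds:
    @staticmethod
    def _result(sid, fold):
        return RiskResult(sid, "VA", 0.0, 0.5, fold)

    def test_six_folds_of_two(self):
        folds = [[self._result(f"s{f}{i}", f) for i in range(2)] for f in range(6)]
        assert len(combine_fold_predictions(folds)) == 12

    def test_duplicate_subject_raises(self):
        folds = [[self._result("a", 0)], [self._result("a", 1)]]
        with pytest.raises(ValueError, match="more than one"):
            combine_fold_predictions(folds)

    def test_gap_raises_when_expected_ids_given(self):
        folds = [[self._result("a", 0)]]
        with pytest.raises(ValueError, match="missing"):
            combine_fold_predictions(folds, expected_ids={"a", "b"})

    def test_study_sized_partition_combines_to_350(self):
        sizes = [59, 59, 58, 58, 58, 58]
        folds, k = [], 0
        for f, size in enumerate(sizes):
            folds.append([self._result(f"s{k + i}", f) for i in range(size)])
            k += size
        assert len(combine_fold_predictions(folds)) == 350
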