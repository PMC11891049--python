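"""Site-adjusted logistic regression, DeLong AUC machinery, LOU-CV."""
import itertools

import numpy as np
import pandas as pd
import pytest

from ivimrad.diagnostics import (LogisticModelFit, auc_delong,
                                 delong_paired_test, diagnostic_study,
                                 fit_site_adjusted_logistic, lou_cv_auc,
                                 predict_prob)
from ivimrad.radiomics import METRICS


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestLogistic:
    def test_separation_flagged_ranks_preserved(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        fit = fit_site_adjusted_logistic(x, ["S"] * 20, y)
        assert fit.separation_flag
        p = predict_prob(fit, x, ["S"] * 20)
        assert p[10:].min() > p[:10].max()

    def test_null_slope_within_wald_interval(self, rng):
        n = 2000
        x = rng.normal(0, 1, n)
        y = rng.integers(0, 2, n)
        fit = fit_site_adjusted_logistic(x, ["S"] * n, y)
        assert not fit.separation_flag
        se = np.sqrt(fit.cov[1, 1])
        assert abs(fit.beta["S"]) < 3 * se

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 300
        x = rng.normal(0, 1, n)
        sites = np.repeat(["A", "B", "C"], n // 3)
        eta = 0.5 + 1.2 * x
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_site_adjusted_logistic(x, sites, y)
        z = (x - fit.x_mean) / fit.x_sd
        onehot = pd.get_dummies(sites).to_numpy(dtype=float)
        X = np.column_stack([onehot, onehot * z[:, None]])
        ref = sm.Logit(y, X).fit(disp=0)
        got = [fit.alpha[s] for s in fit.sites] + [fit.beta[s] for s in fit.sites]
        np.testing.assert_allclose(got, ref.params, atol=1e-5)

    def test_opposite_site_slopes_recovered(self, rng):
        n = 1000
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(0, 1, n)])
        sites = np.array(["A"] * n + ["B"] * n)
        eta = np.where(sites == "A", 1.5 * x, -1.5 * x)
        y = (rng.uniform(size=2 * n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_site_adjusted_logistic(x, sites, y)
        assert fit.beta["A"] > 0 > fit.beta["B"]

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            fit_site_adjusted_logistic([1, 2, 3], ["S"] * 3, [1, 1, 1])


class TestPredictProb:
    def _model(self, alpha=0.0, beta=1.0):
        return LogisticModelFit(["S"], {"S": alpha}, {"S": beta}, 0.0, 1.0,
                                False, True, False)

    def test_flat_model_gives_half(self):
        p = predict_prob(self._model(beta=0.0), [0.3, -2.0], ["S", "S"])
        np.testing.assert_allclose(p, 0.5)

    def test_inverse_logit_hand_values(self):
        p = predict_prob(self._model(), [0.0, np.log(3)], ["S", "S"])
        np.testing.assert_allclose(p, [0.5, 0.75], atol=1e-12)

    def test_monotone_within_site(self, rng):
        x = np.sort(rng.normal(0, 1, 30))
        p = predict_prob(self._model(), x, ["S"] * 30)
        assert np.all(np.diff(p) > 0)

    def test_unseen_site_rejected(self):
        with pytest.raises(ValueError, match="unseen"):
            predict_prob(self._model(), [0.1], ["T"])


class TestDelong:
    def test_hand_examples(self):
        r = auc_delong([0.3, 0.5, 0.2, 0.4], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.25)
        r = auc_delong([1, 3, 2, 4], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)
        assert r.se == pytest.approx(np.sqrt(0.125), abs=1e-6)
        r = auc_delong([0, 0, 1, 1], [0, 0, 1, 1])
        assert r.auc == 1.0 and r.se == 0.0

    def test_equals_brute_force_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 8, n).astype(float)  # many ties
            labels = np.r_[np.zeros(n // 2), np.ones(n - n // 2)].astype(int)
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            assert auc_delong(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_antisymmetry(self, rng):
        scores = rng.normal(0, 1, 40)  # tie-free
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a1 = auc_delong(scores, labels).auc
        a2 = auc_delong(-scores, labels).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            auc_delong([1, 2], [1, 1])


class TestPairedDelong:
    def test_identical_scores(self, rng):
        s = rng.normal(0, 1, 30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        z, p = delong_paired_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_rank_invariance(self, rng):
        s = rng.normal(0, 1, 30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        _, p = delong_paired_test(s, 2 * s + 7, y)
        assert p == 1.0


class TestLou:
    def test_large_effect_stability(self, rng):
        n = 60
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        x = rng.normal(y * 3.0, 1.0)
        sites = np.tile(["A", "B"], n // 2)
        lou = lou_cv_auc(x, sites, y)
        app = auc_delong(x, y)
        assert abs(lou.auc - app.auc) < 0.05

    def test_permuted_labels_pessimistic_not_optimistic(self, rng):
        # LOU-CV never looks better than the apparent fit on null data;
        # with fixed class totals it is in fact systematically pessimistic.
        n = 300
        sites = np.repeat(["A", "B", "C"], n // 3)
        gaps, lous = [], []
        for _ in range(10):
            x = rng.normal(0, 1, n)
            y = rng.permutation(
                np.r_[np.zeros(n // 2), np.ones(n // 2)]).astype(int)
            fit = fit_site_adjusted_logistic(x, sites, y)
            apparent = auc_delong(predict_prob(fit, x, sites), y).auc
            lou = lou_cv_auc(x, sites, y).auc
            gaps.append(lou - apparent)
            lous.append(lou)
        assert np.mean(gaps) <= 0.02    # optimism direction
        assert 0.35 < np.mean(lous) < 0.55

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError, match="at least 10"):
            lou_cv_auc([1] * 5, ["S"] * 5, [0, 1, 0, 1, 0])


def _feature_table(rng, identical=True):
    rows = []
    for site in "ABC":
        for i in range(14):
            label = "malignant" if i % 2 else "benign"
            shift = 0.8 if label == "malignant" else 0.0
            base = rng.normal(shift, 1.0, len(METRICS))
            for m in ("seg_a", "seg_b", "bayes"):
                vals = base if identical else base + rng.normal(0, 0.2, len(METRICS))
                for k, metric in enumerate(METRICS):
                    rows.append(dict(patient_id=f"{site}{i}", site_tag=site,
                                     label=label, method_tag=m,
                                     metric_name=metric, value=vals[k]))
    return pd.DataFrame(rows)


class TestDiagnosticStudy:
    def test_identical_methods_degenerate(self, rng):
        summaries = diagnostic_study(_feature_table(rng, identical=True))
        assert sorted(s.metric_name for s in summaries) == sorted(METRICS)
        for s in summaries:
            assert s.cv_auc_pct == pytest.approx(0.0, abs=1e-9)
            assert all(p == pytest.approx(1.0) for p in s.delong_p.values())

    def test_mean_and_cv_of_auc_triple(self):
        from ivimrad.agreement import average_and_cv
        mean, cv = average_and_cv([0.8, 0.8, 0.9])
        assert (mean, round(cv, 3)) == (pytest.approx(0.83333, abs=1e-4), 6.928)
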