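"""Pearson/ICC/Bland-Altman agreement machinery."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ivimrad.agreement import (agreement_study, average_and_cv, bland_altman,
                               icc_absolute_agreement, pearson_r)
from ivimrad.radiomics import METRICS


class TestPearson:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3], [1, 3, 2], 0.5),
    ])
    def test_hand_values(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected)

    def test_zero_variance_flagged(self):
        assert np.isnan(pearson_r([1, 1, 1], [1, 2, 3]))

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.2, -0.7, 2.2, 0.0])
        y = np.array([1.0, 0.4, -1.1, 1.9, 0.3])
        assert pearson_r(a * x + b, y) == pytest.approx(pearson_r(x, y), abs=1e-9)


class TestAverageAndCv:
    def test_hand_value(self):
        mean, cv = average_and_cv([0.8, 0.8, 0.9])
        assert mean == pytest.approx(0.83333, abs=1e-4)
        assert cv == pytest.approx(6.928, abs=0.01)

    def test_constant_values(self):
        assert average_and_cv([0.5, 0.5, 0.5])[1] == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            average_and_cv([0.5])

    def test_nan_cells_excluded(self):
        mean, _ = average_and_cv([0.8, np.nan, 0.9])
        assert mean == pytest.approx(0.85)


class TestIcc:
    def test_perfect_agreement(self, rng):
        col = rng.normal(0, 1, 50)
        assert icc_absolute_agreement(np.column_stack([col] * 3)) == pytest.approx(1.0)

    def test_variance_ratio_model(self, rng):
        # y_ij = p_i + e_ij with var(p)=9, var(e)=1 -> ICC = 0.9
        n = 2000
        p = rng.normal(0, 3, n)
        m = p[:, None] + rng.normal(0, 1, (n, 3))
        assert icc_absolute_agreement(m) == pytest.approx(0.9, abs=0.02)

    def test_offset_penalized(self, rng):
        p = rng.normal(0, 1, 200)
        m = p[:, None] + rng.normal(0, 0.1, (200, 3))
        m_off = m.copy()
        m_off[:, 2] += 1.0
        assert icc_absolute_agreement(m_off) < icc_absolute_agreement(m)

    def test_pure_noise_icc_near_zero(self, rng):
        m = rng.normal(0, 1, (500, 3))
        assert abs(icc_absolute_agreement(m)) < 0.1

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        m = rng.normal(0, 1, (30, 3)) + rng.normal(0, 1, 30)[:, None]
        df = pd.DataFrame(m, columns=list("abc")).reset_index().melt(
            id_vars="index", var_name="rater", value_name="y")
        ref = pingouin.intraclass_corr(df, targets="index", raters="rater",
                                       ratings="y")
        # two-way random absolute-agreement single-rater coefficient
        icc2 = ref.loc[ref.Type.isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert icc_absolute_agreement(m) == pytest.approx(icc2, abs=1e-6)


class TestBlandAltman:
    def test_identity(self):
        ba = bland_altman([1, 2, 3], [1, 2, 3])
        assert ba["mean_abs_diff"] == 0 and ba["sd_abs_diff"] == 0
        assert ba["cv_pct"] == 0

    def test_hand_values(self):
        ba = bland_altman([1, 2, 3], [2, 2, 2])
        assert ba["mean_abs_diff"] == pytest.approx(2 / 3)
        assert ba["sd_abs_diff"] == pytest.approx(np.sqrt(1 / 3), abs=1e-6)

    def test_bias_antisymmetry(self, rng):
        x, y = rng.normal(1, 0.2, 20), rng.normal(1, 0.2, 20)
        assert bland_altman(x, y)["bias"] == pytest.approx(
            -bland_altman(y, x)["bias"], abs=1e-14)


def _table(rng, methods=("seg_a", "seg_b", "bayes"), n_per_site=12, noise=0.0):
    rows = []
    for site in "ABC":
        for i in range(n_per_site):
            base = {m: rng.normal(1.0, 0.3, len(METRICS)) for m in ["seg_a"]}
            vals = {"seg_a": base["seg_a"],
                    "seg_b": base["seg_a"],
                    "bayes": base["seg_a"] + rng.normal(0, noise or 1e-9, len(METRICS))}
            for m in methods:
                for k, metric in enumerate(METRICS):
                    rows.append(dict(patient_id=f"{site}{i}", site_tag=site,
                                     label="benign" if i % 2 else "malignant",
                                     method_tag=m, metric_name=metric,
                                     value=vals[m][k]))
    return pd.DataFrame(rows)


class TestAgreementStudy:
    def test_identical_methods_give_unit_correlation(self, rng):
        summaries, records = agreement_study(_table(rng, noise=0.3))
        ab = [p.r for p in records if p.method_pair == ("seg_a", "seg_b")]
        assert all(r == pytest.approx(1.0) for r in ab)
        # pairs involving the noisy method correlate less
        ac = [p.r for p in records if p.method_pair == ("seg_a", "bayes")]
        assert np.mean(ac) < 1.0

    def test_ranking_is_permutation_of_all_metrics(self, rng):
        summaries, _ = agreement_study(_table(rng, noise=0.2))
        assert sorted(s.metric_name for s in summaries) == sorted(METRICS)
        assert sorted(s.rank for s in summaries) == list(range(1, 17))

    def test_missing_method_detected(self, rng):
        t = _table(rng)
        with pytest.raises(ValueError, match="lacks"):
            agreement_study(t[t.method_tag != "bayes"])
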