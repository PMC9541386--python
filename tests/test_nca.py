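import numpy as np
import pandas as pd
import pytest

from mphpk.io_datasets import BLQ, MISSING, OBSERVED
from mphpk.nca import (
    auc_extrapolate,
    auc_linear_trapezoid,
    compute_cmax_tmax,
    estimate_lambda_z,
    preprocess_blq,
    subject_nca,
    summarize_cohort,
)


def series(times, values):
    """Build (times, conc, status) arrays from numbers and marker strings."""
    conc, status = [], []
    for v in values:
        if v == "BLQ":
            conc.append(np.nan)
            status.append(BLQ)
        elif v is None:
            conc.append(np.nan)
            status.append(MISSING)
        else:
            conc.append(float(v))
            status.append(OBSERVED)
    return np.array(times, float), np.array(conc), np.array(status, object)


class TestPreprocessBlq:
    def test_blq_positions_recoded_around_first_quantifiable(self):
        t, c, s = series([0, 2, 4, 6], ["BLQ", "BLQ", 0.5, "BLQ"])
        clean = preprocess_blq(t, c, s)
        np.testing.assert_array_equal(clean.conc[:3], [0.0, 0.0, 0.5])
        assert np.isnan(clean.conc[3])
        assert clean.evaluable

    def test_all_quantifiable_unchanged(self):
        t, c, s = series([0, 2, 4], [0.1, 1.0, 2.0])
        clean = preprocess_blq(t, c, s)
        np.testing.assert_array_equal(clean.conc, c)

    def test_missing_predose_zeroed_missing_postdose_excluded(self):
        t, c, s = series([0, 2, 4, 6], [None, 1.0, None, 2.0])
        clean = preprocess_blq(t, c, s)
        assert clean.conc[0] == 0.0
        assert clean.conc[1] == 1.0
        assert np.isnan(clean.conc[2])
        assert clean.conc[3] == 2.0

    def test_no_quantifiable_flags_non_evaluable(self):
        t, c, s = series([0, 2, 4], ["BLQ", "BLQ", "BLQ"])
        clean = preprocess_blq(t, c, s)
        assert not clean.evaluable
        np.testing.assert_array_equal(clean.conc, [0.0, 0.0, 0.0])

    def test_record_count_preserved(self):
        t, c, s = series([0, 2, 4, 6, 8], ["BLQ", 1.0, "BLQ", None, 3.0])
        clean = preprocess_blq(t, c, s)
        assert clean.conc.size == 5
        # quantifiable post-first values untouched
        assert clean.conc[1] == 1.0 and clean.conc[4] == 3.0


class TestCmaxTmax:
    @pytest.mark.parametrize(
        "times,conc,expected",
        [
            ([0, 2, 4, 6], [0, 5, 10, 7], (10.0, 4.0)),
            ([0, 2, 4], [0, 10, 10], (10.0, 2.0)),  # earliest-tie rule
            ([0, 2, 4], [0, 0, 3], (3.0, 4.0)),
        ],
    )
    def test_values(self, times, conc, expected):
        assert compute_cmax_tmax(np.array(times, float), np.array(conc, float)) == expected

    def test_non_evaluable_raises_with_subject(self):
        with pytest.raises(ValueError, match="S07"):
            compute_cmax_tmax(np.array([0.0, 2.0]), np.array([0.0, 0.0]), subject="S07")


class TestAuc:
    @pytest.mark.parametrize(
        "times,conc,expected",
        [
            ([0, 1, 2], [0, 2, 4], 4.0),
            (np.linspace(0, 10, 11), [5.0] * 11, 50.0),
        ],
    )
    def test_trapezoid(self, times, conc, expected):
        assert auc_linear_trapezoid(np.array(times, float), np.array(conc, float)) == (
            pytest.approx(expected)
        )

    def test_exponential_closed_form(self):
        t = np.arange(0, 40.0001, 0.1)
        c = 10 * np.exp(-0.2 * t)
        # ∫₀^∞ = 10/0.2 = 50; truncation at 40 h leaves < 0.04%
        assert auc_linear_trapezoid(t, c) == pytest.approx(50.0, rel=1e-3)

    def test_missing_bridged_and_collinear_invariance(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        c = np.array([0.0, 2.0, np.nan, 6.0])  # bridge 1→3 linearly
        assert auc_linear_trapezoid(t, c) == pytest.approx(
            auc_linear_trapezoid(np.array([0.0, 1.0, 3.0]), np.array([0.0, 2.0, 6.0]))
        )
        # inserting a collinear midpoint leaves the AUC unchanged
        assert auc_linear_trapezoid(
            np.array([0.0, 1.0, 2.0, 3.0]), np.array([0.0, 2.0, 4.0, 6.0])
        ) == pytest.approx(auc_linear_trapezoid(np.array([0.0, 3.0]), np.array([0.0, 6.0])))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            auc_linear_trapezoid(np.array([0.0]), np.array([1.0]))


class TestLambdaZ:
    def test_exact_single_exponential(self):
        t = np.array([6, 8, 10, 12, 24, 36, 48], float)
        c = 10 * np.exp(-0.2 * t)
        lam, n, quality = estimate_lambda_z(t, c, tmax=0.0)
        assert lam == pytest.approx(0.2, rel=1e-12)
        assert np.log(2) / lam == pytest.approx(3.4657, abs=5e-5)
        assert n == 7
        assert quality == pytest.approx(1.0, abs=1e-12)

    def test_biexponential_selects_terminal_phase(self):
        t = np.concatenate([np.arange(2, 25, 2.0), [26, 30, 36, 42, 48]])
        c = 50 * np.exp(-0.5 * t) + 5 * np.exp(-0.1 * t)
        lam, n, _ = estimate_lambda_z(t, c, tmax=2.0)
        assert lam == pytest.approx(0.1, rel=0.02)

    def test_insufficient_points(self):
        assert estimate_lambda_z(np.array([1.0, 2.0]), np.array([2.0, 1.0]), 0.0) is None

    def test_rising_tail_not_estimable(self):
        t = np.array([2, 4, 6, 8.0])
        c = np.array([1.0, 2.0, 3.0, 4.0])
        assert estimate_lambda_z(t, c, tmax=0.0) is None


class TestExtrapolation:
    def test_direct_formula(self):
        assert auc_extrapolate(100.0, 1.0, 0.2) == pytest.approx(105.0)

    def test_zero_tail(self):
        assert auc_extrapolate(100.0, 0.0, 0.2) == 100.0

    def test_missing_lambda(self):
        assert auc_extrapolate(100.0, 1.0, None) is None


class TestSubjectNca:
    def test_noiseless_exponential_chain(self):
        """Full chain recovers closed forms on 10·e^(−0.2t) decay data."""
        t = np.arange(0.0, 48.001, 0.25)
        c = 10 * np.exp(-0.2 * t)
        s = np.array([OBSERVED] * t.size, object)
        res = subject_nca(t, c, s)
        assert res.lambda_z == pytest.approx(0.2, rel=1e-3)
        assert res.t_half == pytest.approx(np.log(2) / 0.2, rel=1e-3)
        assert res.auc_0_inf == pytest.approx(50.0, rel=1e-3)
        assert res.evaluable


class TestSummaries:
    def make_results(self, rows):
        base = {
            "auc_0_t": 100.0,
            "auc_0_inf": 110.0,
            "lambda_z": 0.2,
            "t_half": 3.5,
            "n_lambda_points": 4,
            "lambda_fit_quality": 0.99,
            "evaluable": True,
        }
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_mean_and_cv(self):
        res = self.make_results(
            [
                {"subject_id": "a", "formulation": "SI", "cmax": 10.0, "tmax": 11.0},
                {"subject_id": "b", "formulation": "SI", "cmax": 20.0, "tmax": 14.0},
                {"subject_id": "c", "formulation": "SI", "cmax": 15.0, "tmax": 17.0},
            ]
        )
        out = summarize_cohort(res).iloc[0]
        assert out["cmax_mean"] == pytest.approx(15.0)
        assert out["tmax_median"] == 14.0
        assert (out["tmax_min"], out["tmax_max"]) == (11.0, 17.0)
        # CV of (10, 20): SD 7.0711, 100·7.0711/15 = 47.14
        two = self.make_results(
            [
                {"subject_id": "a", "formulation": "SI", "cmax": 10.0, "tmax": 1.0},
                {"subject_id": "b", "formulation": "SI", "cmax": 20.0, "tmax": 2.0},
            ]
        )
        assert summarize_cohort(two).iloc[0]["cmax_cv_pct"] == pytest.approx(47.14, abs=0.01)

    def test_identical_values_zero_cv(self):
        res = self.make_results(
            [
                {"subject_id": s, "formulation": "SI", "cmax": 12.0, "tmax": 10.0}
                for s in "abc"
            ]
        )
        assert summarize_cohort(res).iloc[0]["cmax_cv_pct"] == 0.0

    def test_small_group_excluded_with_warning(self, caplog):
        res = self.make_results(
            [{"subject_id": "a", "formulation": "DC", "cmax": 10.0, "tmax": 1.0}]
        )
        with caplog.at_level("WARNING", logger="mphpk.nca"):
            out = summarize_cohort(res)
        assert out.empty
        assert any("evaluable" in r.message for r in caplog.records)
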