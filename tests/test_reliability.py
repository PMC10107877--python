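"""Reliability battery: ICC(3,1), typical error, CV%, MDC95, SWC, banding."""

import math

import numpy as np
import pandas as pd
import pytest

from tmsemg.reliability import (DegenerateVarianceError, ReliabilityError,
                                classify_icc, cv_percent, icc_3_1, mdc95,
                                reliability_table, round_half_up, summarize,
                                swc, typical_error)


def brute_force_icc31(m):
    """Independent two-way ANOVA oracle, written from the definition."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    ss_between_subjects = sum(k * (row.mean() - grand) ** 2 for row in m)
    ss_between_sessions = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = sum((v - grand) ** 2 for v in m.ravel())
    ms_subj = ss_between_subjects / (n - 1)
    ms_err = (ss_total - ss_between_subjects - ss_between_sessions) / ((n - 1) * (k - 1))
    return (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)


class TestIcc31:
    def test_identical_columns_give_one(self):
        m = [[1, 1], [2, 2], [3, 3], [4, 4]]
        assert icc_3_1(m) == pytest.approx(1.0)

    def test_consistency_form_is_shift_invariant(self):
        m = np.array([[1.0, 1.3], [2.0, 2.3], [3.5, 3.8], [4.0, 4.3]])
        assert icc_3_1(m) == pytest.approx(1.0)

    def test_matches_anova_oracle_on_fixed_matrix(self):
        m = [[1, 2], [2, 3], [3, 5], [4, 6]]
        assert icc_3_1(m) == pytest.approx(brute_force_icc31(m), abs=1e-12)

    def test_matches_pingouin_on_random_matrices(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        for _ in range(5):
            m = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1)) * 1.5
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(8), 2),
                "session": np.tile([1, 2], 8),
                "score": m.ravel(),
            })
            ref = pingouin.intraclass_corr(long, targets="subject",
                                           raters="session", ratings="score")
            icc3 = float(ref.loc[ref.Type == "ICC(C,1)", "ICC"].iloc[0])
            assert icc_3_1(m) == pytest.approx(icc3, abs=1e-8)

    def test_degenerate_variance_flagged(self):
        with pytest.raises(DegenerateVarianceError):
            icc_3_1([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ReliabilityError):
            icc_3_1([[1, 2], [2, 3]])


class TestTypicalError:
    def test_identical_sessions_give_zero(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert typical_error(a, a) == 0.0

    def test_hand_calculation(self):
        """Differences {0.2,-0.2,0.2,-0.2}: SD 0.2309, TE 0.1633."""
        a = np.zeros(4)
        b = np.array([0.2, -0.2, 0.2, -0.2])
        assert typical_error(a, b) == pytest.approx(0.16330, abs=1e-4)

    def test_identity_with_difference_variance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=50), rng.normal(size=50)
        te = typical_error(a, b)
        assert 2 * te**2 == pytest.approx(np.var(b - a, ddof=1), rel=1e-12)

    def test_estimator_consistency(self):
        """Large-sample TE approaches the generating within-subject SD."""
        rng = np.random.default_rng(2)
        sigma_w = 0.3
        mu = rng.normal(10, 2, size=500)
        a = mu + rng.normal(0, sigma_w, size=500)
        b = mu + rng.normal(0, sigma_w, size=500)
        assert typical_error(a, b) == pytest.approx(sigma_w, rel=0.10)

    def test_single_pair_rejected(self):
        with pytest.raises(ReliabilityError):
            typical_error([1.0], [2.0])


class TestCvPercent:
    def test_identical_sessions_give_zero(self):
        a = [1.0, 2.0, 3.0]
        assert cv_percent(a, a) == 0.0

    def test_closed_form_backtransform(self):
        """Log-scale TE of 0.1 corresponds to CV% = 10.517."""
        c = 0.1 * math.sqrt(2.0) / math.sqrt(4.0 / 3.0)
        a = np.ones(4)
        b = np.exp(np.array([c, -c, c, -c]))
        assert cv_percent(a, b) == pytest.approx(100 * (math.e**0.1 - 1), rel=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(0, 0.3, size=20)
        b = rng.lognormal(0, 0.3, size=20)
        assert cv_percent(5 * a, 5 * b) == pytest.approx(cv_percent(a, b), rel=1e-12)

    def test_nonpositive_values_dropped_with_warning(self):
        a = [1.0, 2.0, -1.0, 3.0]
        b = [1.1, 2.1, 1.0, 3.3]
        with pytest.warns(UserWarning, match="non-positive"):
            cv_percent(a, b)


class TestMdc95:
    @pytest.mark.parametrize("te, expected", [(0.43, 1.19), (0.0, 0.0),
                                              (18.4, 51.00)])
    def test_known_values_at_table_precision(self, te, expected):
        assert round_half_up(mdc95(te), 2) == pytest.approx(expected)

    def test_negative_te_rejected(self):
        with pytest.raises(ReliabilityError):
            mdc95(-0.1)


class TestSwc:
    def test_definition(self):
        # subject means with SD exactly 1.0
        m = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]) + 5.0
        value, pct = swc(m)
        assert value == pytest.approx(0.2)
        assert pct == pytest.approx(100 * 0.2 / 6.0)

    def test_identical_subjects_give_zero(self):
        value, pct = swc(np.full((4, 3), 2.0))
        assert value == 0.0 and pct == 0.0

    def test_estimator_consistency(self):
        rng = np.random.default_rng(4)
        sigma_b = 0.8
        mu = rng.normal(10, sigma_b, size=500)
        m = mu[:, None] + rng.normal(0, 0.01, size=(500, 3))
        value, _ = swc(m)
        assert value == pytest.approx(0.2 * sigma_b, rel=0.10)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ReliabilityError):
            swc(np.ones((2, 3)))


class TestClassifyIcc:
    @pytest.mark.parametrize("icc, band", [
        (0.51, "fair"), (0.75, "excellent"), (0.39, "poor"),
        (0.40, "fair"), (0.59, "fair"), (0.60, "good"), (0.74, "good"),
        (0.92, "excellent"), (0.71, "good"), (-0.2, "poor"),
    ])
    def test_band_cuts(self, icc, band):
        assert classify_icc(icc) == band

    def test_nonfinite_rejected(self):
        with pytest.raises(ReliabilityError):
            classify_icc(float("nan"))


def _tidy(values_by_subject):
    rows = []
    for sid, vals in values_by_subject.items():
        for s, v in enumerate(vals, start=1):
            if v is not None:
                rows.append({"subject_id": sid, "session": s,
                             "mode": "isometric", "outcome": "AMT120",
                             "value": v})
    return pd.DataFrame(rows)


class TestSummarize:
    def test_identical_sessions_perfectly_reliable(self):
        table = _tidy({"S01": [1.0, 1.0, 1.0], "S02": [2.0, 2.0, 2.0],
                       "S03": [3.0, 3.0, 3.0], "S04": [1.5, 1.5, 1.5]})
        r = summarize(table, "AMT120", "isometric")
        assert r.icc_mean == pytest.approx(1.0)
        assert r.te_mean == 0.0
        assert r.mdc95 == 0.0
        assert r.cv_pct_mean == 0.0
        assert r.band == "excellent"
        assert r.sensitive  # zero noise is below any positive SWC

    def test_subject_missing_third_session_drops_from_second_pair_only(self):
        table = _tidy({"S01": [1.0, 1.1, 1.2], "S02": [2.0, 2.2, 2.1],
                       "S03": [3.0, 2.9, 3.2], "S04": [1.5, 1.4, None]})
        r = summarize(table, "AMT120", "isometric")
        n = {p.session_pair: p.n_subjects_used for p in r.pairs}
        assert n[(1, 2)] == 4
        assert n[(2, 3)] == 3

    def test_too_few_complete_cases_rejected(self):
        table = _tidy({"S01": [1.0, 1.1, None], "S02": [2.0, 2.2, None],
                       "S03": [3.0, 2.9, 3.2], "S04": [1.5, 1.4, 1.3]})
        with pytest.raises(ReliabilityError):
            summarize(table, "AMT120", "isometric")

    def test_reliability_table_covers_outcomes(self):
        table = pd.concat([
            _tidy({"S01": [1.0, 1.1, 1.2], "S02": [2.0, 2.2, 2.1],
                   "S03": [3.0, 2.9, 3.2], "S04": [1.5, 1.4, 1.6]}),
        ])
        rep = reliability_table(table)
        assert set(rep.columns) >= {"outcome", "mode", "icc_mean", "te_mean",
                                    "cv_pct_mean", "mdc95", "pct_swc", "band",
                                    "sensitive"}
        assert len(rep) == 1


def test_round_half_up_matches_table_formatting():
    assert round_half_up(1.005, 2) == 1.01
    assert round_half_up(0.944, 2) == 0.94
    assert round_half_up(51.0019, 2) == 51.00
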