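"""Convergence criteria and reliability statistics."""

import math

import numpy as np
import pytest

from pestmle import (
    accuracy_flags,
    bland_altman,
    convergence_trial,
    criterion_trial_at_95,
    icc_2_1,
    limits_of_agreement,
    per_trial_reliability,
    precision_flags,
    reference_value,
    reproducibility_coefficient,
    standard_error_of_measurement,
    within_subject_sd,
)

from conftest import make_log


def icc_2_1_bruteforce(m):
    """Independent oracle: two-way ANOVA sums of squares by explicit loops."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = sum(m[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(m[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum(
        (m[i][j] - row[i] - col[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestPrecision:
    def test_fig_example_window(self):
        # running estimates ending 55, 54, 53 span 2 -> precise at that trial
        flags = precision_flags([50, 52, 55, 55, 55, 55, 55, 55, 54, 53])
        assert flags[-1]

    @pytest.mark.parametrize(
        "window, expected",
        [((55, 54, 53), True), ((55, 52, 53), False), ((50, 50, 50), True)],
    )
    def test_three_trial_span(self, window, expected):
        assert precision_flags(list(window))[2] == expected

    def test_undefined_before_trial_three(self):
        flags = precision_flags([50, 50, 50, 50])
        assert not flags[0] and not flags[1]
        assert flags[2] and flags[3]


class TestReference:
    def test_constant_tail(self):
        intensities = [40] * 24 + [54] * 6
        assert reference_value(intensities) == 54.0

    def test_mixed_tail(self):
        intensities = [40] * 24 + [55, 55, 54, 55, 54, 55]
        assert reference_value(intensities) == pytest.approx(54.667, abs=1e-3)

    def test_short_log_rejected(self):
        with pytest.raises(ValueError):
            reference_value([50] * 29)

    def test_from_session_log_uses_tested_intensities(self):
        log = make_log([50.0] * 30, intensities=[40] * 24 + [54.6] * 6)
        assert reference_value(log) == pytest.approx(54.6)
        assert reference_value(log, use_estimates=True) == 50.0


class TestAccuracy:
    @pytest.mark.parametrize(
        "reference, estimate, expected",
        [(54.6, 55.0, True), (54.6, 58.0, False), (40.0, 42.0, True)],  # 2.0 <= 2.0
    )
    def test_relative_band(self, reference, estimate, expected):
        assert accuracy_flags([estimate], reference)[0] == expected

    def test_absolute_band_option(self):
        assert accuracy_flags([58.0], 54.6, tol=5.0, relative=False)[0]

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            accuracy_flags([50.0], 0.0)


class TestConvergenceTrial:
    def test_final_trailing_run(self):
        # met at 4, lost at 5, maintained from 6 -> convergence at 6
        flags = [False, False, False, True, False] + [True] * 5
        assert convergence_trial(flags) == 6

    def test_all_true(self):
        assert convergence_trial([True] * 8) == 1

    def test_last_false_means_none(self):
        assert convergence_trial([True] * 7 + [False]) is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            convergence_trial([])


class TestCriterionAt95:
    def test_all_converged_at_one(self):
        k, curve = criterion_trial_at_95([1] * 10, n_trials=30)
        assert k == 1
        assert curve[0] == 1.0

    def test_95_of_100_by_trial_7(self):
        trials = [7] * 95 + [20] * 5
        k, _ = criterion_trial_at_95(trials, n_trials=30)
        assert k == 7

    def test_never_converged_sessions_count_against(self):
        k, curve = criterion_trial_at_95([1] * 90 + [None] * 10, n_trials=30)
        assert k is None
        assert np.all(np.diff(curve) >= 0)

    def test_curve_non_decreasing(self, rng):
        trials = [int(t) if t < 28 else None for t in rng.integers(1, 31, 50)]
        _, curve = criterion_trial_at_95(trials, n_trials=30)
        assert np.all(np.diff(curve) >= 0)


class TestIcc:
    def test_perfect_agreement(self):
        m = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        assert icc_2_1(m) == pytest.approx(1.0)

    def test_constant_offset_matrix(self):
        # rows (1,2),(3,4),(5,6): perfect consistency, systematic +1 offset
        m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert icc_2_1(m) == pytest.approx(icc_2_1_bruteforce(m), abs=1e-12)
        assert icc_2_1(m) == pytest.approx(8.0 / 9.0)

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 20))
            m = rng.normal(50, 8, size=(n, 2)) + rng.normal(0, 3, size=(n, 1))
            assert icc_2_1(m) == pytest.approx(icc_2_1_bruteforce(m), abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        m = rng.normal(50, 8, size=(10, 2))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 2),
                "rater": np.tile(["a", "b"], 10),
                "score": m.ravel(),
            }
        )
        res = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        # ICC(A,1): two-way, absolute agreement, single rater == ICC(2,1)
        expected = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_2_1(m) == pytest.approx(expected, abs=1e-9)

    def test_subject_permutation_invariant(self, rng):
        m = rng.normal(50, 8, size=(12, 2))
        perm = rng.permutation(12)
        assert icc_2_1(m) == pytest.approx(icc_2_1(m[perm]), abs=1e-12)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError, match="zero total variance"):
            icc_2_1(np.full((5, 2), 3.0))

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            icc_2_1(np.array([[1.0, 2.0], [3.0, 4.0]]))


class TestAgreementFormulas:
    def test_sw_identical_sessions(self):
        assert within_subject_sd([3, 4, 5], [3, 4, 5]) == 0.0

    def test_sw_direct_formula(self):
        # d = (2, -2), n = 2 -> sqrt(8 / 4)
        assert within_subject_sd([3, 1], [1, 3]) == pytest.approx(math.sqrt(2), abs=1e-5)

    def test_sw_homogeneous(self, rng):
        a, b = rng.normal(50, 5, 10), rng.normal(50, 5, 10)
        assert within_subject_sd(3 * a, 3 * b) == pytest.approx(
            3 * within_subject_sd(a, b)
        )

    def test_rc_values(self):
        assert reproducibility_coefficient(0.0) == 0.0
        assert reproducibility_coefficient(1.0) == pytest.approx(2.77186, abs=1e-5)
        # RC(sqrt(2)) = 1.96 * sqrt(2) * sqrt(2) = 3.92 exactly
        assert reproducibility_coefficient(math.sqrt(2)) == pytest.approx(3.92, abs=1e-9)

    def test_sem_values(self):
        assert standard_error_of_measurement(4.0, 1.0) == 0.0
        assert standard_error_of_measurement(4.0, 0.0) == 4.0
        assert standard_error_of_measurement(4.0, 0.84) == pytest.approx(1.6)
        with pytest.raises(ValueError):
            standard_error_of_measurement(4.0, 1.1)


class TestBlandAltman:
    def test_identical_pairs(self):
        ba = bland_altman([50, 55, 60], [50, 55, 60])
        assert ba.mean_diff == ba.sd_diff == 0.0
        assert ba.loa_lower == ba.loa_upper == 0.0

    def test_limits_bracket_mean(self, rng):
        a, b = rng.normal(50, 5, 20), rng.normal(50, 5, 20)
        ba = bland_altman(a, b)
        assert ba.loa_lower <= ba.mean_diff <= ba.loa_upper

    def test_noise_widens_limits(self, rng):
        a = rng.normal(50, 5, 200)
        narrow = bland_altman(a, a + rng.normal(0, 1, 200))
        wide = bland_altman(a, a + rng.normal(0, 5, 200))
        assert wide.loa_upper - wide.loa_lower > narrow.loa_upper - narrow.loa_lower

    def test_sample_sd_uses_n_minus_1(self):
        ba = bland_altman([52.0, 50.0], [50.0, 50.0])
        assert ba.mean_diff == pytest.approx(1.0)
        assert ba.sd_diff == pytest.approx(np.std([2.0, 0.0], ddof=1))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])

    def test_limits_of_agreement_formula(self):
        lo, hi = limits_of_agreement(2.0, 1.0)
        assert lo == pytest.approx(2.0 - 1.96)
        assert hi == pytest.approx(2.0 + 1.96)


class TestPerTrialReliability:
    def _paired_logs(self, rng, n_subjects=8, noise=0.5):
        logs1, logs2 = [], []
        for _ in range(n_subjects):
            base = rng.uniform(40, 60)
            e1 = base + rng.normal(0, noise, 30)
            e2 = base + rng.normal(0, noise, 30)
            logs1.append(make_log(e1))
            logs2.append(make_log(e2))
        return logs1, logs2

    def test_identical_collections_perfect_icc(self, rng):
        logs1, _ = self._paired_logs(rng)
        report = per_trial_reliability(logs1, logs1)
        assert np.allclose(report.table["icc"], 1.0)
        assert report.icc_convergence_trial == 1
        assert np.allclose(report.table["sw"], 0.0)

    def test_deterministic_across_reruns(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        r1 = per_trial_reliability(*self._paired_logs(rng1))
        r2 = per_trial_reliability(*self._paired_logs(rng2))
        assert r1.table.equals(r2.table)

    def test_row_invariants(self, rng):
        logs1, logs2 = self._paired_logs(rng)
        t = per_trial_reliability(logs1, logs2).table
        assert (t["rc"] >= 0).all() and (t["sw"] >= 0).all()
        assert (t["loa_lower"] <= t["loa_upper"]).all()
        assert t["pearson_r"].between(-1, 1).all()
        assert (t["n_pairs"] == 8).all()

    def test_drift_lowers_between_day_icc(self, rng):
        # adding a per-subject day shift to session B lowers ICC at trial 30
        logs1, logs2 = self._paired_logs(rng, n_subjects=12, noise=0.3)
        shifted = [
            make_log(np.asarray(lg.estimates) + rng.normal(0, 6.0)) for lg in logs2
        ]
        within = per_trial_reliability(logs1, logs2).table["icc"].iloc[-1]
        between = per_trial_reliability(logs1, shifted).table["icc"].iloc[-1]
        assert between < within

    def test_too_few_pairs_rejected(self, rng):
        logs1, logs2 = self._paired_logs(rng, n_subjects=2)
        with pytest.raises(ValueError):
            per_trial_reliability(logs1, logs2)
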