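"""Five-parameter logistic regression, correlation statistics, residual
F-tests and significance matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctfriqa.iqa_eval import (
    InsufficientDataError,
    UndefinedCorrelationError,
    evaluate,
    fit_5pl,
    logistic5,
    plcc,
    residual_f_test,
    rmse,
    significance_matrix,
    srocc,
    srocc_d2,
)


class TestFit5PL:
    def test_recovers_noiseless_curve(self):
        rng = np.random.default_rng(0)
        y = np.sort(rng.uniform(0, 10, 80))
        x = logistic5(y, 40.0, 1.2, 5.0, 2.0, 10.0)
        fit = fit_5pl(y, x)
        assert fit.converged
        assert np.sqrt(fit.sse / len(y)) < 1e-6

    def test_beta2_zero_reduces_to_linear_regression(self):
        # with a vanishing logistic term the family is affine; on affine data
        # the fit must match ordinary least squares exactly
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 50, 40)
        x = 1.7 * y - 3.0
        fit = fit_5pl(y, x)
        assert np.abs(fit.residuals).max() < 1e-8
        b1, b2, b3, b4, b5 = fit.beta
        np.testing.assert_allclose(logistic5(y, b1, 0.0, b3, 1.7, -3.0), x, atol=1e-12)

    def test_plcc_never_below_raw_correlation(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            y = rng.uniform(0, 1, 60)
            x = 80 * y**2 + rng.normal(0, 5, 60)
            fit = fit_5pl(y, x)
            assert plcc(x, fit.y_l) >= abs(plcc(x, y)) - 1e-9

    def test_sse_matches_residuals(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0, 10, 30)
        x = rng.uniform(0, 100, 30)
        fit = fit_5pl(y, x)
        assert fit.sse == pytest.approx(float(fit.residuals @ fit.residuals), rel=1e-12)
        assert rmse(x, fit.y_l) ** 2 * len(x) == pytest.approx(fit.sse, rel=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_5pl(np.arange(5.0), np.arange(5.0))

    def test_constant_y_flagged_degenerate(self):
        fit = fit_5pl(np.full(20, 3.0), np.arange(20.0))
        assert not fit.converged


class TestCorrelations:
    def test_affine_relation_gives_one(self):
        x = np.arange(10.0)
        assert plcc(x, 2 * x + 1) == pytest.approx(1.0)
        assert plcc(x, -x) == pytest.approx(-1.0)

    def test_plcc_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        x = rng.normal(50, 20, 50)
        y = rng.normal(0, 1, 50)
        direct = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert plcc(x, y) == pytest.approx(direct, abs=1e-12)

    def test_srocc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        assert srocc(x, np.exp(x)) == pytest.approx(1.0)
        assert srocc(x, x[::-1] * 0 - stats.rankdata(x)) == pytest.approx(-1.0)

    def test_rank_difference_closed_form_on_tie_free_data(self):
        rng = np.random.default_rng(6)
        x = rng.permutation(60).astype(float)
        y = x + rng.normal(0, 5, 60)
        while len(np.unique(y)) < 60:  # pragma: no cover - vanishing probability
            y = x + rng.normal(0, 5, 60)
        assert srocc(x, y) == pytest.approx(srocc_d2(x, y), abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            plcc(np.ones(10), np.arange(10.0))
        with pytest.raises(UndefinedCorrelationError):
            srocc(np.arange(10.0), np.ones(10))

    def test_rmse_hand_example(self):
        assert rmse(np.zeros(2), np.array([3.0, 4.0])) == pytest.approx(np.sqrt(12.5))
        assert rmse(np.arange(5.0), np.arange(5.0)) == 0.0


class TestResidualFTest:
    def test_identical_residuals_indistinguishable(self):
        r = np.random.default_rng(7).normal(0, 3, 50)
        assert residual_f_test(r, r.copy()) == "-"

    def test_large_variance_ratio_detected(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 210)
        b = rng.normal(0, 10, 210)
        assert residual_f_test(a, b) == "1"
        assert residual_f_test(b, a) == "0"

    def test_decision_matches_f_quantile(self):
        # borderline ratio straddling the 5% one-tailed critical value
        n = 210
        crit = stats.f.ppf(0.05, n - 1, n - 1)
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, n)
        base = (base - base.mean()) / base.std(ddof=1)
        just_better = base * np.sqrt(crit * 0.95)
        not_better = base * np.sqrt(crit * 1.05)
        assert residual_f_test(just_better, base) == "1"
        assert residual_f_test(not_better, base) == "-"

    def test_zero_variance_both_rejected(self):
        with pytest.raises(ValueError):
            residual_f_test(np.zeros(20), np.zeros(20))


class TestSignificanceMatrix:
    def test_single_method_diagonal(self):
        r = {"A": {"noise": np.random.default_rng(0).normal(0, 1, 30)}}
        mat = significance_matrix(r, ("noise",))
        assert mat.cells[("A", "A")] == "-"

    def test_diagonal_and_antisymmetry(self):
        rng = np.random.default_rng(10)
        res = {
            m: {g: rng.normal(0, sd, 40) for g, sd in (("noise", sd1), ("blur", sd2))}
            for m, sd1, sd2 in (("A", 1, 5), ("B", 5, 1), ("C", 2, 2))
        }
        mat = significance_matrix(res, ("noise", "blur"))
        flip = {"1": "0", "0": "1", "-": "-"}
        for a in "ABC":
            assert mat.cells[(a, a)] == "- -"
            for b in "ABC":
                if a == b:
                    continue
                fwd = mat.cells[(a, b)].split()
                rev = mat.cells[(b, a)].split()
                assert [flip[s] for s in fwd] == rev

    def test_tied_methods_all_dashes(self):
        r = np.random.default_rng(11).normal(0, 2, 30)
        res = {"A": {"all": r}, "B": {"all": r.copy()}}
        mat = significance_matrix(res, ("all",))
        assert mat.cells[("A", "B")] == "-"
        assert mat.to_frame().loc["A", "B"] == "-"


@pytest.fixture(scope="module")
def records():
    rng = np.random.default_rng(12)
    rows = []
    for site in ("head", "chest", "abdomen"):
        for ref in range(2):
            for sn in (0.0, 6.0, 14.0, 30.0):
                for sb in (0.0, 0.9, 2.1):
                    if sn == 0 and sb == 0:
                        continue
                    q = 30 + 70 * np.exp(-(sn / 12 + sb / 1.2))
                    rows.append(
                        {
                            "site": site,
                            "sigma_noise": sn,
                            "sigma_blur": sb,
                            "X": q + rng.normal(0, 2),
                            "good": q / 10 + rng.normal(0, 0.3),
                            "bad": q / 10 + rng.normal(0, 3.0),
                        }
                    )
    return pd.DataFrame(rows)


class TestEvaluate:
    def test_summary_complete_over_groups_and_methods(self, records):
        summary, matrices = evaluate(records, ("good", "bad"))
        assert set(summary["group"]) == {"all", "noise", "blur", "head", "chest", "abdomen"}
        assert len(summary) == 6 * 2
        assert (summary["status"] == "ok").all()
        assert matrices["site"].subgroup_order == ("head", "chest", "abdomen")

    def test_better_method_wins_f_test(self, records):
        _, matrices = evaluate(records, ("good", "bad"))
        assert matrices["all"].cells[("good", "bad")] == "1"
        assert matrices["all"].cells[("bad", "good")] == "0"

    def test_subgroup_sizes_follow_grid_arithmetic(self, records):
        summary, _ = evaluate(records, ("good",))
        noise_n = summary.loc[summary.group == "noise", "n"].iloc[0]
        assert noise_n == 6 * 3  # refs x nonzero noise grades

    def test_small_subgroup_skipped(self, records):
        few = records.head(6)
        summary, _ = evaluate(few, ("good",), groups=("all",))
        assert (summary["status"] == "skipped").all()
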