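"""Logistic preference model: VIF screen, KS statistic, IRLS fit, Wald reporting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ethnosurvey.exceptions import DomainError, SeparationError, SingularMatrixError
from ethnosurvey.preference import (
    PreferenceRecord,
    fit_logit,
    ks_statistic,
    log1p_transform,
    odds_ratio,
    significance_stars,
    vif_screen,
    vif_values,
    wald_z,
)


class TestVIF:
    def test_orthogonal_covariates_vif_one(self):
        n = 64
        a = np.repeat([1.0, -1.0], n // 2)
        b = np.tile([1.0, -1.0], n // 2)
        c = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        frame = pd.DataFrame({"a": a, "b": b, "c": c})
        vifs = vif_values(frame)
        for name in ("a", "b", "c"):
            assert vifs[name] == pytest.approx(1.0, abs=1e-9)
        kept, excluded = vif_screen(frame)
        assert kept == ["a", "b", "c"] and excluded == {}

    def test_duplicated_column_infinite_vif_one_copy_excluded(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        frame = pd.DataFrame({"x": x, "x_copy": x, "z": rng.normal(size=50)})
        vifs = vif_values(frame)
        assert math.isinf(vifs["x"]) and math.isinf(vifs["x_copy"])
        kept, excluded = vif_screen(frame)
        assert len(kept) == 2 and "z" in kept
        assert len(excluded) == 1 and math.isinf(next(iter(excluded.values())))

    def test_correlated_pair_closed_form(self):
        # Construct two columns with sample correlation exactly 0.9:
        # VIF = 1/(1-0.81) = 5.2631...
        n = 200
        rng = np.random.default_rng(2)
        u = rng.normal(size=n)
        v = rng.normal(size=n)
        # orthonormalize, then mix to the target correlation
        u = (u - u.mean()) / u.std()
        v = v - v.mean() - u * (u @ (v - v.mean())) / (u @ u)
        v = v / v.std()
        rho = 0.9
        w = rho * u + math.sqrt(1 - rho**2) * v
        frame = pd.DataFrame({"a": u, "b": w})
        vifs = vif_values(frame)
        assert vifs["a"] == pytest.approx(1 / (1 - 0.81), rel=1e-9)
        assert vifs["b"] == pytest.approx(1 / (1 - 0.81), rel=1e-9)
        kept, excluded = vif_screen(frame, threshold=5.0)
        assert len(kept) == 1 and len(excluded) == 1

    def test_too_few_records(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
        with pytest.raises(DomainError):
            vif_screen(frame)


class TestKS:
    def test_single_observation_at_median(self):
        assert ks_statistic([0.0], stats.norm(0, 1)) == pytest.approx(0.5)

    def test_two_point_uniform_enumeration(self):
        assert ks_statistic([0.25, 0.75], stats.uniform(0, 1)) == pytest.approx(0.25)

    def test_quantile_sample_converges(self):
        n = 2000
        sample = stats.norm.ppf((np.arange(1, n + 1)) / (n + 1))
        assert ks_statistic(sample, stats.norm(0, 1).cdf) < 0.01

    def test_empty_sample(self):
        with pytest.raises(DomainError):
            ks_statistic([], stats.norm(0, 1))


def saturated_2x2_records(n00=10, n01=10, n10=5, n11=15):
    """x=0: n01 successes / n00 failures; x=1: n11 successes / n10 failures."""
    records = []
    rows = (
        [(0.0, 0)] * n00 + [(0.0, 1)] * n01 + [(1.0, 0)] * n10 + [(1.0, 1)] * n11
    )
    for i, (x, y) in enumerate(rows):
        records.append(PreferenceRecord(f"R{i}", y, {"x": x}))
    return records


class TestLogitFit:
    def test_saturated_2x2_closed_form(self):
        # log odds at x=0: log(10/10)=0; slope: log cross-ratio = log 3
        fit = fit_logit(saturated_2x2_records())
        assert fit.converged
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-6)
        assert fit.params["x"] == pytest.approx(math.log(3.0), abs=1e-6)

    def test_intercept_only_even_split(self):
        records = [
            PreferenceRecord(f"R{i}", i % 2, {"noise": 0.0}) for i in range(20)
        ]
        frame = pd.DataFrame({"y": [r.outcome for r in records]})
        fit = fit_logit(frame, outcome="y")
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-8)

    def test_single_class_raises_separation(self):
        records = [PreferenceRecord(f"R{i}", 1, {"x": float(i)}) for i in range(10)]
        with pytest.raises(SeparationError):
            fit_logit(records)

    def test_perfectly_separating_covariate_raises(self):
        records = [
            PreferenceRecord(f"R{i}", int(i >= 10), {"x": float(i)}) for i in range(20)
        ]
        with pytest.raises(SeparationError):
            fit_logit(records)

    def test_duplicate_covariate_singular_information(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        frame = pd.DataFrame({"x": x, "x_dup": x, "y": y})
        with pytest.raises(SingularMatrixError, match="x"):
            fit_logit(frame, outcome="y")

    def test_loglikelihood_nondecreasing(self):
        rng = np.random.default_rng(4)
        n = 300
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x)))
        y = (rng.random(n) < p).astype(int)
        fit = fit_logit(pd.DataFrame({"x": x, "y": y}), outcome="y")
        diffs = np.diff(fit.llf_path)
        assert (diffs >= -1e-9).all()

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 500
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.4).astype(float)
        eta = -0.3 + 0.8 * x1 - 1.1 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        frame = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        fit = fit_logit(frame, outcome="y")
        reference = sm.Logit(y, sm.add_constant(frame[["x1", "x2"]])).fit(disp=0)
        assert fit.params["intercept"] == pytest.approx(reference.params["const"], abs=1e-6)
        assert fit.params["x1"] == pytest.approx(reference.params["x1"], abs=1e-6)
        assert fit.params["x2"] == pytest.approx(reference.params["x2"], abs=1e-6)
        assert fit.bse["x1"] == pytest.approx(reference.bse["x1"], rel=1e-4)
        assert fit.llf == pytest.approx(reference.llf, abs=1e-6)

    def test_report_columns_are_pure_functions_of_estimates(self):
        fit = fit_logit(saturated_2x2_records(8, 12, 6, 14))
        for name in fit.params:
            assert fit.odds_ratios[name] == pytest.approx(math.exp(fit.params[name]))
            assert fit.zvalues[name] == pytest.approx(fit.params[name] / fit.bse[name])
            assert fit.pvalues[name] == pytest.approx(
                2 * stats.norm.sf(abs(fit.zvalues[name]))
            )

    def test_summary_frame_layout(self):
        frame = fit_logit(saturated_2x2_records()).summary_frame()
        assert list(frame.columns) == [
            "term", "estimate", "std_error", "z_value", "p_value", "signif", "odds_ratio",
        ]
        assert list(frame["term"])[0] == "intercept"


class TestWaldReporting:
    def test_wald_z(self):
        assert wald_z(1.0, 0.5) == pytest.approx(2.0)
        assert wald_z(0.0, 0.3) == 0.0

    def test_wald_z_requires_positive_se(self):
        with pytest.raises(DomainError):
            wald_z(1.0, 0.0)

    def test_odds_ratio(self):
        assert odds_ratio(0.0) == 1.0
        assert odds_ratio(math.log(2)) == pytest.approx(2.0)
        with pytest.raises(DomainError):
            odds_ratio(float("inf"))

    @pytest.mark.parametrize(
        ("p", "stars"),
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.08, "."), (0.2, "")],
    )
    def test_significance_stars(self, p, stars):
        assert significance_stars(p) == stars


def test_log1p_transform_rejects_negative():
    frame = pd.DataFrame({"income": [1.0, -2.0]})
    with pytest.raises(DomainError):
        log1p_transform(frame, ["income"])
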