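"""Lack-of-fit test, fit-quality indices and case classification."""

import numpy as np
import pytest
from scipy import stats

from hormfit import (
    NaturalParams,
    classify_case,
    compare_models,
    fit_model,
    lack_of_fit_test,
    pseudo_r2,
    relative_bias,
)
from hormfit.compare import FitDiagnostics, diagnostics
from hormfit.data import DoseResponseData
from hormfit.errors import ValidationError
from hormfit.fitting import FitResult


def synthetic_fit(ss_res=25.0, ss_corrected=100.0, df_res=20):
    return FitResult(model="loglogistic4", estimates={"e": 1.0},
                     covariance=np.eye(1), ss_res=ss_res, df_res=df_res,
                     ss_corrected=ss_corrected, converged=True, n_iter=1)


def test_pseudo_r2_formula():
    assert pseudo_r2(synthetic_fit(25.0, 100.0)) == pytest.approx(0.75)
    assert pseudo_r2(synthetic_fit(0.0, 100.0)) == 1.0
    assert pseudo_r2(synthetic_fit(100.0, 100.0)) == 0.0
    with pytest.raises(ValidationError):
        pseudo_r2(synthetic_fit(1.0, 0.0))


@pytest.mark.parametrize("better,other,expected", [
    (10.0, 10.0, 0.0),
    (10.0, 12.0, 20.0),
    (10.0, 7.4, -26.0),
])
def test_relative_bias_formula(better, other, expected):
    assert relative_bias(better, other) == pytest.approx(expected)


def test_relative_bias_zero_denominator():
    with pytest.raises(ValidationError):
        relative_bias(0.0, 5.0)


def hand_anova_data():
    """Small replicated table with a hand-computable decomposition."""
    dose = np.repeat([0.0, 1, 2, 4, 8], 2)
    resp = np.array([100.0, 104, 88, 92, 76, 80, 58, 62, 30, 34])
    return DoseResponseData(dose=dose, response=resp)


def test_lack_of_fit_hand_anova():
    """Weighted (here unit-weight) decomposition against an
    independently computed ANOVA: SS_pure from replicate deviations,
    SS_lof from mean deviations around the fitted curve."""
    data = hand_anova_data()
    fit = fit_model(data, "loglogistic4")
    F, p, (df_lof, df_pure) = lack_of_fit_test(data, fit)
    # oracle: each dose has 2 replicates at mean +/- 2 -> SS_pure = 5*2*(2^2)
    ss_pure = 40.0
    pred = fit.predict(data.dose_levels)
    ss_lof = float(np.sum(2 * (data.per_dose_mean - pred) ** 2))
    df_lof_expect, df_pure_expect = 5 - 4, 10 - 5
    assert (df_lof, df_pure) == (df_lof_expect, df_pure_expect)
    F_expect = (ss_lof / df_lof_expect) / (ss_pure / df_pure_expect)
    assert F == pytest.approx(F_expect, rel=1e-8)
    assert p == pytest.approx(stats.f.sf(F_expect, df_lof, df_pure), rel=1e-10)


def test_lack_of_fit_zero_when_curve_interpolates_means():
    """If the fitted curve passes exactly through every per-dose mean,
    SS_lof = 0, F = 0 and p = 1."""
    from hormfit import eval_loglogistic4
    p4 = NaturalParams(c=0, d=100, b=2, e=3)
    dose = np.repeat([0.0, 1, 2, 4, 8], 2)
    mean = eval_loglogistic4(p4, dose)
    # symmetric +/-1.5 noise leaves every per-dose mean exactly on the
    # generating curve, which the 4-parameter fit then reproduces
    resp = mean + np.where(np.arange(10) % 2 == 0, -1.5, 1.5)
    data = DoseResponseData(dose=dose, response=resp)
    fit = fit_model(data, "loglogistic4")
    F, p, _ = lack_of_fit_test(data, fit)
    assert F == pytest.approx(0.0, abs=1e-8)
    assert p == pytest.approx(1.0, abs=1e-6)


def test_lack_of_fit_requires_replication():
    dose = np.array([0.0, 1, 2, 4, 8, 16], float)
    resp = np.array([100.0, 90, 75, 50, 25, 10])
    data = DoseResponseData(dose=dose, response=resp)
    fit = fit_model(data, "loglogistic4")
    with pytest.raises(ValidationError, match="replication"):
        lack_of_fit_test(data, fit)


def test_ss_decomposition_identity(default_data, crs_fit, bc_data, bc_fit):
    """SS_lof + SS_pure = SS_res to 1e-10 relative on every fit."""
    for data, fit in ((default_data, crs_fit), (bc_data, bc_fit)):
        w, y, x = data.weight, data.response, data.dose
        ss_res = float(np.sum(w * (y - fit.predict(x)) ** 2))
        means = {lv: np.mean(y[x == lv]) for lv in data.dose_levels}
        ybar = np.array([means[v] for v in x])
        ss_pure = float(np.sum(w * (y - ybar) ** 2))
        F, _, (df_lof, df_pure) = lack_of_fit_test(data, fit)
        ss_lof = F * (ss_pure / df_pure) * df_lof
        assert ss_lof + ss_pure == pytest.approx(ss_res, rel=1e-10)


class FakeTest:
    def __init__(self, significant):
        self.significant = significant
        self.f_estimate = 1.0 if significant else 0.0


def diag(s2=1.0, r2=0.95, runs_p=0.5):
    return FitDiagnostics(ss_res_over_df=s2, pseudo_r2=r2, lof_F=None,
                          lof_p=None, lof_df=None, runs_p=runs_p)


@pytest.mark.parametrize("sig_bc,sig_crs,d_bc,d_crs,expected", [
    # only BC significant -> case2 even when CRS fits better
    (True, False, diag(s2=1.2, r2=0.90), diag(s2=1.0, r2=0.94),
     "case2_bc_better"),
    # only CRS significant -> case3
    (False, True, diag(), diag(), "case3_crs_better"),
    # both significant, diagnostics within margins -> case4
    (True, True, diag(s2=1.0, r2=0.950), diag(s2=1.02, r2=0.952),
     "case4_equal"),
    # both significant, CRS clearly better -> case3
    (True, True, diag(s2=2.0, r2=0.90), diag(s2=1.0, r2=0.95),
     "case3_crs_better"),
    # neither significant, both fail the residual screen -> case1
    (False, False, diag(runs_p=0.001), diag(runs_p=0.002), "case1_neither"),
])
def test_classify_case_rules(sig_bc, sig_crs, d_bc, d_crs, expected):
    case, trace, _ = classify_case(FakeTest(sig_bc), FakeTest(sig_crs),
                                   d_bc, d_crs)
    assert case == expected
    assert trace  # rationale records triggered rules


def test_classify_case_deterministic():
    args = (FakeTest(True), FakeTest(True), diag(), diag(s2=1.01))
    assert classify_case(*args) == classify_case(*args)


def test_compare_models_full_report(default_data, crs_fit, bc_fit):
    from hormfit import LDS, M, build_reparam_model, ed, fit_reparam
    tables = {}
    for fam, pilot in (("brain_cousens", bc_fit), ("cedergreen", crs_fit)):
        tables[fam] = {
            t.name: fit_reparam(default_data, build_reparam_model(fam, t),
                                pilot=pilot)
            for t in (ed(50), LDS, M)
        }
    rep = compare_models(default_data, bc_fit, crs_fit, dose_tables=tables)
    assert rep.case in ("case1_neither", "case2_bc_better",
                        "case3_crs_better", "case4_equal")
    assert len(rep.bias_table) == 3
    assert set(rep.bias_table["quantity"]) == {"ED50", "LDS", "M"}
    # bias computed against the better-fitting model's estimates
    row = rep.bias_table.set_index("quantity").loc["ED50"]
    cols = [c for c in rep.bias_table.columns if c.startswith("estimate_")]
    e1, e2 = row[cols[0]], row[cols[1]]
    assert row["rel_bias_pct"] == pytest.approx(100 * (e2 - e1) / e1)
    js = rep.to_json_dict()
    assert js["case"] == rep.case
    assert "diagnostics" in js


def test_runs_screen_detects_systematic_misfit():
    """A monotone fit to strongly hormetic data leaves sign-patterned
    residuals that the runs test flags."""
    from hormfit import SimulationConfig, generate_dataset
    cfg = SimulationConfig(seed=42, noise_cv=0.02)
    data = generate_dataset(cfg).with_weights("inverse_sd")
    mono = fit_model(data, "loglogistic4")
    good = fit_model(data, "cedergreen")
    d_mono = diagnostics(data, mono)
    d_good = diagnostics(data, good)
    assert d_mono.runs_p < 0.05
    assert d_good.runs_p > 0.05
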