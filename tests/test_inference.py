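"""Wald/t intervals, hormesis test, delta-method prediction and
pre-hormetic drop quantification."""

import numpy as np
import pytest
from scipy import stats

from hormfit import (
    NaturalParams,
    SimulationConfig,
    estimate_y_max,
    fit_model,
    generate_dataset,
    pre_hormetic_quantities,
    predict_response,
    wald_ci,
)
from hormfit import test_hormesis as hormesis_test  # avoid pytest collection
from hormfit.errors import NotEstimatedError
from hormfit.fitting import FitResult


def synthetic_fit(est, se, df=20, model="brain_cousens"):
    """Hand-built FitResult with a given estimate/SE structure."""
    names = list(est)
    cov = np.diag([s**2 for s in se.values()])
    return FitResult(model=model, estimates=dict(est), covariance=cov,
                     ss_res=float(df), df_res=df, ss_corrected=100.0,
                     converged=True, n_iter=1)


def test_wald_ci_halfwidth_t20():
    fit = synthetic_fit({"e": 2.0}, {"e": 0.5}, df=20)
    ci = wald_ci(fit, "e")
    # 0.5 * t_{0.975,20} = 0.5 * 2.0860 = 1.0430
    assert ci.upper - ci.estimate == pytest.approx(1.043, abs=1e-3)
    assert ci.lower == pytest.approx(2.0 - 1.043, abs=1e-3)


def test_wald_ci_normal_limit_and_degenerate():
    fit = synthetic_fit({"e": 2.0}, {"e": 0.5}, df=10**6)
    ci = wald_ci(fit, "e")
    assert (ci.upper - 2.0) / 0.5 == pytest.approx(1.96, abs=1e-3)
    fit0 = synthetic_fit({"e": 2.0}, {"e": 0.0}, df=20)
    ci0 = wald_ci(fit0, "e")
    assert ci0.lower == ci0.upper == 2.0


def test_wald_ci_fixed_parameter_rejected():
    fit = synthetic_fit({"e": 2.0}, {"e": 0.5})
    fit.fixed = {"a": 1.0}
    with pytest.raises(NotEstimatedError):
        wald_ci(fit, "a")


@pytest.mark.parametrize("f,se,expect_sig", [
    (2.0, 0.5, True),    # CI (0.957, 3.043) excludes 0
    (0.5, 1.0, False),   # CI covers 0
    (0.0, 0.5, False),
    (-2.0, 0.5, False),  # two-sided exclusion but f < 0: not hormesis
])
def test_hormesis_ci_excludes_zero_rule(f, se, expect_sig):
    fit = synthetic_fit({"f": f}, {"f": se}, df=20)
    ht = hormesis_test(fit)
    assert ht.significant is expect_sig
    if f == -2.0:
        assert ht.excludes_zero


def test_hormesis_requires_free_f():
    fit = synthetic_fit({"e": 1.0}, {"e": 0.1}, model="loglogistic4")
    with pytest.raises(NotEstimatedError):
        hormesis_test(fit)
    fit2 = synthetic_fit({"e": 1.0}, {"e": 0.1})
    fit2.fixed = {"f": 0.0}
    with pytest.raises(NotEstimatedError):
        hormesis_test(fit2)


def test_hormesis_same_on_natural_and_edk_fit(default_data, crs_fit):
    from hormfit import build_reparam_model, ed, fit_reparam
    rfit = fit_reparam(default_data, build_reparam_model("cedergreen", ed(50)),
                       pilot=crs_fit)
    h_nat = hormesis_test(crs_fit)
    h_rep = hormesis_test(rfit)
    assert h_nat.significant == h_rep.significant
    assert h_rep.f_estimate == pytest.approx(h_nat.f_estimate, rel=1e-4)
    assert h_rep.ci.se == pytest.approx(h_nat.ci.se, rel=1e-2)


def test_predict_at_dose_zero_is_d(crs_fit):
    est, ci = predict_response(crs_fit, 0.0)
    assert est == pytest.approx(crs_fit.estimates["d"], rel=1e-12)
    assert ci.se == pytest.approx(crs_fit.se("d"), rel=1e-4)


def test_predict_zero_covariance_zero_width(crs_fit):
    import copy
    fit = copy.copy(crs_fit)
    fit.covariance = np.zeros_like(crs_fit.covariance)
    est, ci = predict_response(fit, 3.0)
    assert ci.lower == ci.upper == est


def test_ymax_uses_prediction_code_path(default_data, crs_fit):
    from hormfit import M, build_reparam_model, fit_reparam
    mfit = fit_reparam(default_data, build_reparam_model("cedergreen", M),
                       pilot=crs_fit)
    ym = estimate_y_max(mfit)
    est, ci = predict_response(mfit, mfit.estimates["M"])
    assert ym["y_max"] == est
    assert ym["y_max_ci"] == ci
    assert ym["y_max"] >= mfit.natural_params().d


DIP_TRUTH = NaturalParams(c=0, d=100, b=0.7, e=10, f=80, a=2.0)
DIP_DOSES = (0, 0.003, 0.01, 0.03, 0.1, 0.3, 1, 3, 10, 30, 100)


@pytest.fixture(scope="module")
def dip_fit():
    cfg = SimulationConfig(truth_params=DIP_TRUTH, doses=DIP_DOSES,
                           replicates=5, seed=3)
    data = generate_dataset(cfg).with_weights("inverse_sd")
    return fit_model(data, "cedergreen")


def test_pre_hormetic_ordering_and_cis(dip_fit):
    """A Cedergreen curve dipping below control yields
    0 < M_min < LDS_min < M with CIs from the multi-root refits."""
    from hormfit import functionals_from_natural
    phq = pre_hormetic_quantities(dip_fit)
    assert phq.has_drop
    m = functionals_from_natural("cedergreen", dip_fit.natural_params(),
                                 quantities=("M",))["M"]
    assert 0 < phq.m_min < phq.lds_min < m
    assert phq.m_min_ci is not None and phq.lds_min_ci is not None
    assert phq.m_min_source in ("multiroot_refit", "delta_from_fit")
    # y_min below control, reported relative to d
    assert phq.y_min < dip_fit.natural_params().d
    assert phq.y_min_relative < 100.0
    assert phq.significant_drop == (phq.y_min_relative_ci.upper < 100.0)


def test_pre_hormetic_drop_defining_properties(dip_fit):
    """M_min is a stationary point and the curve recrosses d at
    LDS_min."""
    from hormfit import curve_dose_derivative, eval_family
    phq = pre_hormetic_quantities(dip_fit)
    nat = dip_fit.natural_params()
    assert abs(curve_dose_derivative("cedergreen", nat, phq.m_min)) \
        < 1e-6 * nat.d / nat.e
    assert eval_family("cedergreen", nat, phq.lds_min) \
        == pytest.approx(nat.d, rel=1e-6)


def test_no_dip_flagged_not_error(default_data, crs_fit):
    phq = pre_hormetic_quantities(crs_fit)
    assert phq.has_drop is False
    assert phq.m_min is None


def test_delta_se_close_to_bootstrap_for_ed50(default_data, crs_fit):
    """Delta-from-natural CI for ED50 agrees with the direct
    reparameterized CI on a well-conditioned fit (within 5% in
    half-width)."""
    from hormfit import build_reparam_model, ed, fit_reparam
    from hormfit.inference import delta_method_ci
    from hormfit import functionals_from_natural

    names = crs_fit.free_names

    def ed50_of(vec):
        p = NaturalParams(**dict(zip(names, vec)))
        return functionals_from_natural("cedergreen", p,
                                        K_list=(50.0,))["ED50"]

    val, ci_delta = delta_method_ci(crs_fit, ed50_of)
    rfit = fit_reparam(default_data, build_reparam_model("cedergreen", ed(50)),
                       pilot=crs_fit)
    ci_direct = wald_ci(rfit, "ED50")
    assert val == pytest.approx(rfit.estimates["ED50"], rel=1e-4)
    assert ci_delta.se == pytest.approx(ci_direct.se, rel=0.05)
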