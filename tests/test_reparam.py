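"""Defining relationships, substitution identities and the numeric
oracle for effective dosages."""

import numpy as np
import pytest
from scipy import optimize

from hormfit import (
    LDS,
    M,
    NaturalParams,
    build_reparam_model,
    curve_dose_derivative,
    ed,
    eval_family,
    functionals_from_natural,
    solve_d_for_edk,
    solve_f_for_m,
)
from hormfit.errors import (
    NoHormesisError,
    StationarityDegenerateError,
    ValidationError,
)
from hormfit.reparam import TargetQuantity

CRS = NaturalParams(c=0, d=100, b=2, e=10, f=50, a=1)
BC = NaturalParams(c=0, d=100, b=2, e=10, f=5)


# --- closed forms ----------------------------------------------------

@pytest.mark.parametrize("family,params", [
    ("cedergreen", CRS),
    ("cedergreen", NaturalParams(c=4, d=90, b=1.2, e=5, f=30, a=0.5)),
    ("brain_cousens", BC),
    ("brain_cousens", NaturalParams(c=10, d=120, b=3, e=2, f=40)),
])
@pytest.mark.parametrize("K", [0.0, 10.0, 50.0, 90.0])
@pytest.mark.parametrize("convention",
                         ["relative_to_control", "relative_to_range"])
def test_solve_d_satisfies_defining_relationship(family, params, K, convention):
    """The recovered d makes the curve pass through the target level
    at the given ED_K dose (K = 0 is the LDS case)."""
    edk = 1.7 * params.e  # any dose on the inhibitory side
    d = solve_d_for_edk(family, c=params.c, b=params.b, e=params.e,
                        f=params.f, ed_k=edk, K=K, a=params.a,
                        convention=convention)
    p = params.replace(d=d)
    level = ((1 - K / 100) * d if convention == "relative_to_control"
             else params.c + (1 - K / 100) * (d - params.c))
    assert eval_family(family, p, edk) == pytest.approx(level, rel=1e-12)


def test_solve_d_conventions_coincide_at_K0_and_c0():
    for conv in ("relative_to_control", "relative_to_range"):
        d = solve_d_for_edk("cedergreen", c=0, b=2, e=10, f=50,
                            ed_k=6.0, K=0, a=1, convention=conv)
        p = CRS.replace(d=d)
        assert eval_family("cedergreen", p, 6.0) == pytest.approx(d, rel=1e-12)


def test_solve_d_K_domain():
    with pytest.raises(ValidationError):
        solve_d_for_edk("cedergreen", c=0, b=2, e=10, f=50, ed_k=5.0,
                        K=100, a=1)
    with pytest.raises(ValidationError):
        TargetQuantity(kind="ED_K", K=150)


@pytest.mark.parametrize("family,params", [
    ("cedergreen", CRS),
    ("cedergreen", NaturalParams(c=4, d=90, b=0.9, e=5, f=30, a=0.5)),
    ("brain_cousens", BC),
])
def test_solve_f_zeroes_derivative_at_m(family, params):
    m = 0.3 * params.e
    f = solve_f_for_m(family, c=params.c, d=params.d, b=params.b,
                      e=params.e, m=m, a=params.a)
    p = params.replace(f=f)
    slope = curve_dose_derivative(family, p, m)
    assert abs(slope) < 1e-8 * params.d / params.e


def test_solve_f_recovers_truth_from_golden_section_argmax():
    """Golden-section search on the natural curve locates M; plugging
    that M into the closed form recovers the generating f."""
    res = optimize.minimize_scalar(
        lambda x: -eval_family("cedergreen", CRS, x),
        bounds=(1e-6, 100.0), method="bounded",
        options={"xatol": 1e-12})
    m = float(res.x)
    f = solve_f_for_m("cedergreen", c=0, d=100, b=2, e=10, m=m, a=1)
    assert f == pytest.approx(50.0, rel=1e-6)


def test_solve_f_degenerate_b_zero():
    with pytest.raises(StationarityDegenerateError):
        solve_f_for_m("cedergreen", c=0, d=100, b=0.0, e=10, m=2.0, a=1)


# --- reparameterized model specs -------------------------------------

@pytest.mark.parametrize("family,params", [
    ("cedergreen", CRS), ("brain_cousens", BC),
])
@pytest.mark.parametrize("target", [ed(50), ed(10), LDS, M])
def test_substitution_identity_on_grid(family, params, target):
    """Evaluating the reparameterized mean function equals evaluating
    the natural model with the implied parameter."""
    fn = functionals_from_natural(family, params, K_list=(10.0, 50.0))
    tval = fn[target.name]
    spec = build_reparam_model(family, target)
    assert spec.free_names[-1] == target.name
    theta = spec.theta_from_natural(params, tval)
    grid = np.concatenate([[0.0], np.geomspace(0.01, 1e3, 60)])
    np.testing.assert_allclose(spec.mean(theta, grid),
                               eval_family(family, params, grid),
                               rtol=1e-9, atol=1e-9)


def test_reparam_defining_properties():
    fn = functionals_from_natural("cedergreen", CRS, K_list=(50.0,))
    # derivative vanishes at M
    spec_m = build_reparam_model("cedergreen", M)
    p = spec_m.implied_params(spec_m.theta_from_natural(CRS, fn["M"]))
    assert abs(curve_dose_derivative("cedergreen", p, fn["M"])) \
        < 1e-8 * CRS.d / CRS.e
    # curve passes through d at LDS
    spec_l = build_reparam_model("cedergreen", LDS)
    p = spec_l.implied_params(spec_l.theta_from_natural(CRS, fn["LDS"]))
    assert eval_family("cedergreen", p, fn["LDS"]) == pytest.approx(
        p.d, rel=1e-9)


def test_spec_serialization_round_trip():
    spec = build_reparam_model("cedergreen", ed(25))
    js = spec.to_json_dict()
    assert js["eliminated_parameter"] == "d"
    assert js["free_parameters"][-1] == "ED25"
    assert build_reparam_model(js["family"],
                               ed(js["K"], js["convention"])) == spec


# --- numeric oracle ---------------------------------------------------

def test_oracle_symmetric_loglogistic_ed50_is_e():
    p = NaturalParams(c=0, d=100, b=2, e=10, f=0.0)
    fn = functionals_from_natural("brain_cousens", p, K_list=(50.0,),
                                  quantities=("ED",))
    assert fn["ED50"] == pytest.approx(10.0, rel=1e-10)


def test_oracle_no_hormesis_errors():
    p = NaturalParams(c=0, d=100, b=2, e=10, f=0.0)
    with pytest.raises(NoHormesisError):
        functionals_from_natural("brain_cousens", p, quantities=("M",))
    with pytest.raises(NoHormesisError):
        functionals_from_natural("brain_cousens", p, quantities=("LDS",))


@pytest.mark.parametrize("family,params", [
    ("cedergreen", CRS),
    ("cedergreen", NaturalParams(c=0, d=100, b=1, e=30, f=60, a=0.25)),
    ("brain_cousens", BC),
])
def test_ordering_and_monotonicity_of_effective_doses(family, params):
    """0 < M < LDS < ED_K with ED_K strictly increasing in K, and
    y_max >= d."""
    fn = functionals_from_natural(family, params,
                                  K_list=(10.0, 50.0, 90.0))
    assert 0 < fn["M"] < fn["LDS"] < fn["ED10"] < fn["ED50"] < fn["ED90"]
    assert fn["y_max"] >= params.d


def test_ymax_tends_to_d_as_f_vanishes():
    # f must stay large enough for the stimulation to beat the
    # logistic decline somewhere (the Cedergreen stimulation term
    # vanishes faster than any power of x at 0)
    prev = np.inf
    for f in (50.0, 20.0, 10.0, 5.0):
        fn = functionals_from_natural("cedergreen", CRS.replace(f=f),
                                      quantities=("M",))
        excess = fn["y_max"] - CRS.d
        assert 0 < excess < prev
        prev = excess
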