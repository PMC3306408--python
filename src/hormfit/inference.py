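"""Wald/t inference: confidence intervals, the hormesis significance
test, delta-method prediction (y_max) and pre-hormetic drop
quantification.

Intervals are t-based with df = residual degrees of freedom, matching
the nonlinear-regression defaults of the mainstream statistical
packages used in bioassay practice. The hormesis test follows the
CI-excludes-zero rule: a hormetic effect is significant at level
alpha = 1 - level if the two-sided CI for the stimulation parameter f
does not cover zero (with f-hat > 0); it works identically on natural
and ED_K-parameterized fits since both carry a free f.

Curves of the Cedergreen family can dip below the control level before
the hormetic rise ("pre-hormetic drop"). Because the dosage-defining
relationships then have more than one solution, the drop is quantified
by refitting the M- and LDS-parameterized models started at the
pre-hormetic solutions (M_min, LDS_min), with a delta-method fallback
when the refit wanders off; y_min significance compares the CI of
100*y_min/d against 100 (exploratory).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (
    HormfitError,
    NotEstimatedError,
    NumericDomainError,
    ValidationError,
)
from .fitting import FitResult, _mean_function, fit_model
from .models import curve_dose_derivative, eval_family
from .reparam import ReparamSpec, TargetQuantity


@dataclass(frozen=True)
class ConfidenceInterval:
    level: float
    lower: float
    upper: float
    se: float
    df: int

    def __post_init__(self):
        if not 0 < self.level < 1:
            raise ValidationError("level must be in (0, 1)")

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def estimate(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class HormesisTest:
    """CI-excludes-zero test for the stimulation parameter f."""

    f_estimate: float
    ci: ConfidenceInterval
    significant: bool       # f-hat > 0 and CI entirely above 0
    excludes_zero: bool     # two-sided exclusion regardless of sign
    alpha: float


@dataclass(frozen=True)
class EffectiveDoseEstimate:
    quantity: TargetQuantity
    estimate: float
    ci: ConfidenceInterval
    source: str  # 'direct_reparam_fit' or 'delta_from_natural'


@dataclass
class PreHormeticQuantities:
    """Quantification of a dip below the control level before the rise.

    m_min: dose of maximal drop; y_min: response there (absolute, plus
    relative to d in percent); lds_min: dose where the drop disappears.
    significant_drop: CI of 100*y_min/d excludes 100 (exploratory).
    """

    has_drop: bool
    m_min: float | None = None
    m_min_ci: ConfidenceInterval | None = None
    y_min: float | None = None
    y_min_ci: ConfidenceInterval | None = None
    y_min_relative: float | None = None
    y_min_relative_ci: ConfidenceInterval | None = None
    lds_min: float | None = None
    lds_min_ci: ConfidenceInterval | None = None
    significant_drop: bool | None = None
    m_min_source: str | None = None
    lds_min_source: str | None = None


def _tq(level: float, df: int) -> float:
    return float(stats.t.ppf(0.5 * (1 + level), df))


def wald_ci(fit: FitResult, parameter: str, level: float = 0.95) -> ConfidenceInterval:
    """t-based Wald interval: estimate +/- t(df, (1+level)/2) * SE."""
    if parameter in fit.fixed:
        raise NotEstimatedError(f"{parameter!r} was fixed, not estimated")
    if parameter not in fit.estimates:
        raise NotEstimatedError(f"{parameter!r} is not a parameter of this fit")
    est = fit.estimates[parameter]
    se = fit.se(parameter)
    half = _tq(level, fit.df_res) * se
    return ConfidenceInterval(level=level, lower=est - half, upper=est + half,
                              se=se, df=fit.df_res)


def test_hormesis(fit: FitResult, level: float = 0.95) -> HormesisTest:
    """Significance of hormesis via the CI for f.

    Hormesis is declared significant when the two-sided CI for f does
    not cover zero and f-hat > 0.
    """
    if "f" in fit.fixed:
        raise NotEstimatedError("f is fixed; hormesis not testable")
    if "f" not in fit.estimates:
        raise NotEstimatedError("model has no hormesis parameter f")
    ci = wald_ci(fit, "f", level=level)
    f_hat = fit.estimates["f"]
    excludes = ci.lower > 0 or ci.upper < 0
    return HormesisTest(
        f_estimate=f_hat, ci=ci,
        significant=bool(f_hat > 0 and ci.lower > 0),
        excludes_zero=bool(excludes),
        alpha=1 - level,
    )


def _gradient(func, theta: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function of the free
    parameter vector."""
    g = np.empty_like(theta)
    for i, t in enumerate(theta):
        h = rel_step * max(abs(t), 1e-8)
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        try:
            fp, fm = func(tp), func(tm)
        except HormfitError:
            # one-sided step if the central one leaves the domain
            fp, fm = func(tp), func(theta)
            h = 0.5 * h
            g[i] = (fp - fm) / (2 * h)
            continue
        g[i] = (fp - fm) / (2 * h)
    return g


def delta_method_ci(fit: FitResult, func, level: float = 0.95) -> tuple[float, ConfidenceInterval]:
    """First-order (delta-method) CI for a scalar function of the free
    parameters. ``func`` maps a parameter vector (fit order) to a
    number."""
    theta = np.array([fit.estimates[n] for n in fit.free_names])
    val = float(func(theta))
    g = _gradient(func, theta)
    var = float(g @ fit.covariance @ g)
    if not np.isfinite(var) or var < 0:
        raise NumericDomainError("non-finite delta-method variance")
    se = np.sqrt(var)
    half = _tq(level, fit.df_res) * se
    return val, ConfidenceInterval(level=level, lower=val - half,
                                   upper=val + half, se=se, df=fit.df_res)


def predict_response(fit: FitResult, dose: float, level: float = 0.95,
                     relative_to_d: bool = False) -> tuple[float, ConfidenceInterval]:
    """Fitted mean response at a dose with a delta-method t CI.

    With ``relative_to_d`` the response is expressed as a percentage
    of the control mean d (full covariance propagation through the
    ratio) — the form used for y_max and y_min reporting.
    """
    if dose < 0:
        raise NumericDomainError("dose must be >= 0")
    mu = _mean_function(fit.model, fit.fixed)

    if relative_to_d:
        names = fit.free_names

        def func(vec):
            theta = dict(zip(names, vec))
            theta.update(fit.fixed)
            if "d" in theta:
                d = theta["d"]
            else:  # d eliminated (ED_K-parameterized fit)
                d = fit.model.implied_params(theta).d
            return 100.0 * mu(vec, dose) / d
    else:
        def func(vec):
            return mu(vec, dose)

    return delta_method_ci(fit, func, level=level)


def estimate_y_max(fit: FitResult, level: float = 0.95) -> dict:
    """y_max = fitted response at M-hat, absolute and relative to d.

    For an M-parameterized fit, M-hat is the direct estimate;
    otherwise the numeric argmax of the fitted curve is used. Because
    M-hat is a stationary point, the gradient of y(M(theta); theta)
    reduces to the partial gradient at fixed dose, so the same
    prediction code path serves y_max exactly.
    """
    from .reparam import functionals_from_natural
    if isinstance(fit.model, ReparamSpec) and fit.model.target.kind == "M":
        m = fit.estimates["M"]
    else:
        m = functionals_from_natural(fit.family, fit.natural_params(),
                                     quantities=("M",))["M"]
    y_abs, ci_abs = predict_response(fit, m, level=level)
    y_rel, ci_rel = predict_response(fit, m, level=level, relative_to_d=True)
    return {"M": m, "y_max": y_abs, "y_max_ci": ci_abs,
            "y_max_relative": y_rel, "y_max_relative_ci": ci_rel}


# ---------------------------------------------------------------------
# pre-hormetic drop
# ---------------------------------------------------------------------

def _refit_multiroot(fit: FitResult, target: TargetQuantity, start_value: float,
                     expected: float, level: float):
    """Refit the target-parameterized model started at a pre-hormetic
    solution; accept only if it lands on that solution with the same
    curve (equal ss_res)."""
    spec = ReparamSpec(fit.family, target)
    nat = fit.natural_params()
    start = spec.theta_from_natural(nat, start_value)
    for k in fit.fixed:
        start.pop(k, None)
    refit = fit_model(fit.data, spec, start=start, fixed=fit.fixed)
    est = refit.estimates[target.name]
    same_root = abs(est - expected) <= 0.05 * abs(expected)
    same_curve = abs(refit.ss_res - fit.ss_res) <= 1e-6 * max(fit.ss_res, 1e-300)
    if not (same_root and same_curve):
        raise HormfitError("multi-root refit wandered off the pre-hormetic root")
    return est, wald_ci(refit, target.name, level=level)


def _delta_ci_for_dose(fit: FitResult, solve, level: float):
    """Delta-method CI for an implicitly defined dose functional.

    ``solve`` maps a free-parameter vector to the dose (re-solving the
    defining equation at perturbed parameters)."""
    return delta_method_ci(fit, solve, level=level)


def pre_hormetic_quantities(fit: FitResult, level: float = 0.95,
                            min_depth_rel: float = 1e-3) -> PreHormeticQuantities:
    """Quantify a dip of the fitted Cedergreen curve below the control
    mean before the hormetic rise.

    Returns a no-drop result (not an error) when the fitted curve does
    not dip. CIs for M_min and LDS_min come from multi-root refits of
    the M- and LDS-parameterized models (delta-method fallback,
    recorded in the ``*_source`` fields); y_min uses the delta-method
    prediction at M_min.
    """
    if fit.family != "cedergreen":
        raise ValidationError("pre-hormetic drop applies to the Cedergreen family")
    nat = fit.natural_params()
    if (nat.f or 0) <= 0:
        return PreHormeticQuantities(has_drop=False)
    from .reparam import functionals_from_natural
    fn = functionals_from_natural(fit.family, nat, quantities=("M",))
    m, d = fn["M"], nat.d

    def curve(x):
        return eval_family(fit.family, nat, x)

    # the Cedergreen stimulation term vanishes faster than any power of
    # x at 0, so every fitted curve dips below d infinitesimally near
    # zero; only a dip deeper than min_depth_rel * d counts as a drop
    grid = np.geomspace(m * 1e-8, m, 400)
    vals = curve(grid)
    i = int(np.argmin(vals))
    if vals[i] >= d * (1 - min_depth_rel) or i in (0, len(grid) - 1):
        return PreHormeticQuantities(has_drop=False)
    res = optimize.minimize_scalar(curve, bounds=(grid[i - 1], grid[i + 1]),
                                   method="bounded",
                                   options={"xatol": 1e-13 * m})
    m_min = float(res.x)
    # polish on the analytic slope
    try:
        lo, hi = m_min * (1 - 1e-3), m_min * (1 + 1e-3)
        if np.sign(curve_dose_derivative(fit.family, nat, lo)) != \
                np.sign(curve_dose_derivative(fit.family, nat, hi)):
            m_min = float(optimize.brentq(
                lambda x: curve_dose_derivative(fit.family, nat, x),
                lo, hi, rtol=8.9e-16))
    except Exception:  # pragma: no cover
        pass
    lds_min = float(optimize.brentq(lambda x: curve(x) - d, m_min, m,
                                    rtol=8.9e-16))

    from .reparam import M as M_TARGET, TargetQuantity as TQ
    out = PreHormeticQuantities(has_drop=True, m_min=m_min, lds_min=lds_min)

    # y_min at the stationary dose: prediction gradient is exact there
    y_min, y_ci = predict_response(fit, m_min, level=level)
    y_rel, y_rel_ci = predict_response(fit, m_min, level=level,
                                       relative_to_d=True)
    out.y_min, out.y_min_ci = y_min, y_ci
    out.y_min_relative, out.y_min_relative_ci = y_rel, y_rel_ci
    out.significant_drop = not y_rel_ci.covers(100.0)

    # M_min CI: multi-root refit of the M-parameterized model (the
    # point estimate stays the numeric stationary dose of the fitted
    # curve; the refit supplies its standard error)
    try:
        _, ci = _refit_multiroot(fit, M_TARGET, m_min, m_min, level)
        out.m_min_ci, out.m_min_source = ci, "multiroot_refit"
    except Exception:  # noqa: BLE001 - delta fallback per protocol
        names = fit.free_names

        def solve_mmin(vec):
            theta = dict(zip(names, vec))
            theta.update(fit.fixed)
            p = (fit.model.implied_params(theta)
                 if isinstance(fit.model, ReparamSpec) else
                 fit.natural_params().replace(**theta))
            return float(optimize.brentq(
                lambda x: curve_dose_derivative(fit.family, p, x),
                m_min * 0.2, lds_min, rtol=1e-13))

        _, ci = _delta_ci_for_dose(fit, solve_mmin, level)
        out.m_min_ci, out.m_min_source = ci, "delta_from_fit"

    # LDS_min CI: multi-root refit of the LDS-parameterized model
    try:
        lds_target = TQ(kind="LDS")
        _, ci = _refit_multiroot(fit, lds_target, lds_min, lds_min, level)
        out.lds_min_ci = ci
        out.lds_min_source = "multiroot_refit"
    except Exception:  # noqa: BLE001
        names = fit.free_names

        def solve_ldsmin(vec):
            theta = dict(zip(names, vec))
            theta.update(fit.fixed)
            p = (fit.model.implied_params(theta)
                 if isinstance(fit.model, ReparamSpec) else
                 fit.natural_params().replace(**theta))
            return float(optimize.brentq(
                lambda x: eval_family(fit.family, p, x) - p.d,
                m_min, m, rtol=1e-13))

        _, ci = _delta_ci_for_dose(fit, solve_ldsmin, level)
        out.lds_min_ci, out.lds_min_source = ci, "delta_from_fit"

    return out


def effective_dose_table(fits: dict, level: float = 0.95):
    """Tidy effective-dose table from target-parameterized fits.

    ``fits`` maps quantity names (e.g. 'ED50', 'LDS', 'M') to their
    reparameterized :class:`FitResult`. Columns: quantity, K,
    estimate, se, lower, upper, source, convention.
    """
    import pandas as pd
    rows = []
    for name, fit in fits.items():
        target = fit.model.target
        ci = wald_ci(fit, name, level=level)
        rows.append({
            "quantity": name,
            "K": target.effective_K if target.kind != "M" else np.nan,
            "estimate": fit.estimates[name],
            "se": ci.se,
            "lower": ci.lower,
            "upper": ci.upper,
            "source": "direct_reparam_fit",
            "convention": target.convention,
        })
    return pd.DataFrame(rows)
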