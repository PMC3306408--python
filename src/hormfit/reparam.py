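"""Reparameterized hormetic models with directly estimable dosages.

The natural parameters of the Brain-Cousens and Cedergreen families do
not include the dosages practitioners report: ED_K (the dose giving K%
inhibition relative to the untreated control), LDS (the limited dose
for stimulation, where the hormetic rise re-crosses the control level;
the K = 0 special case of ED_K) and M (the dose of maximal
stimulation, a stationary point of the mean curve). This module builds
model variants in which one natural parameter is solved out of a
defining relationship and replaced by the target dosage, so a single
nonlinear fit returns the dosage with its standard error and Wald/t
confidence interval.

Defining relationships (x is the target dosage, y(x) the mean curve):

* ED_K  — ``y(ED_K)`` equals the target response level; linear in
  ``d``, so ``d`` is eliminated in closed form.
* LDS   — ED_K at K = 0 (``y(LDS) = d``).
* M     — ``dy/dx = 0`` at ``x = M``; linear in ``f``, so ``f`` is
  eliminated in closed form.

Two response-level conventions exist for ED_K: ``relative_to_control``
(level = (1 - K/100) * d, the convention used throughout when the
lower asymptote is constrained to c = 0) and ``relative_to_range``
(level = c + (1 - K/100) * (d - c)). They coincide when c = 0.

A numeric oracle (:func:`functionals_from_natural`) extracts the same
functionals from a natural-parameter fit by bounded golden-section
maximization and bracketed root finding; it backs the equivalence tests
between natural and reparameterized fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import (
    CapabilityError,
    NoHormesisError,
    NumericDomainError,
    ReparamInfeasibleError,
    RootNotFoundError,
    StationarityDegenerateError,
    ValidationError,
)
from .models import (
    NaturalParams,
    _logistic_term,
    _stimulation_term,
    curve_dose_derivative,
    eval_family,
    param_names,
)

CONVENTIONS = ("relative_to_control", "relative_to_range")

#: denominator magnitude below which a closed form is declared degenerate
_DEGENERATE_TOL = 1e-12

#: bracket-expansion limit for root finding, in units of e
_BRACKET_LIMIT = 1e6


@dataclass(frozen=True)
class TargetQuantity:
    """An effective dosage to be estimated directly.

    kind: 'ED_K', 'LDS' or 'M'; K: percent inhibition in (0, 100) for
    ED_K (LDS fixes K = 0, M has no K); convention: response-level
    convention for ED_K/LDS.
    """

    kind: str
    K: float | None = None
    convention: str = "relative_to_control"

    def __post_init__(self):
        if self.kind not in ("ED_K", "LDS", "M"):
            raise ValidationError(f"unknown target kind {self.kind!r}")
        if self.convention not in CONVENTIONS:
            raise ValidationError(f"unknown convention {self.convention!r}")
        if self.kind == "ED_K":
            if self.K is None or not 0 < self.K < 100:
                raise ValidationError("ED_K requires 0 < K < 100")
        if self.kind == "LDS" and self.K not in (None, 0):
            raise ValidationError("LDS fixes K = 0")

    @property
    def effective_K(self) -> float:
        return 0.0 if self.kind in ("LDS", "M") else float(self.K)

    @property
    def name(self) -> str:
        """Parameter name used in fits: 'ED50', 'LDS' or 'M'."""
        if self.kind == "ED_K":
            return f"ED{self.K:g}"
        return self.kind


def ed(K: float, convention: str = "relative_to_control") -> TargetQuantity:
    """Convenience constructor for an ED_K target."""
    return TargetQuantity(kind="ED_K", K=K, convention=convention)


LDS = TargetQuantity(kind="LDS")
M = TargetQuantity(kind="M")


def _stim_at(family: str, x: float, f: float, a: float | None) -> float:
    """Numerator stimulation term s(x): f*x (BC) or f*exp(-x^-a) (CRS)."""
    if family == "brain_cousens":
        return f * x
    return f * float(_stimulation_term(np.asarray(x, float), a))


def solve_d_for_edk(family: str, c: float, b: float, e: float, f: float,
                    ed_k: float, K: float,
                    a: float | None = None,
                    convention: str = "relative_to_control") -> float:
    """Closed-form control mean d implied by a given ED_K dose.

    Solves the (linear-in-d) defining relationship
    ``y(ED_K) = level(K)`` for d. K = 0 gives the LDS case, where both
    conventions coincide (``y(LDS) = d``).
    """
    if not 0 <= K < 100:
        raise ValidationError("K must satisfy 0 <= K < 100 (K=0 is LDS)")
    if family not in ("brain_cousens", "cedergreen"):
        raise CapabilityError(f"no ED_K reparameterization for {family!r}")
    if ed_k <= 0:
        raise NumericDomainError("ED_K must be > 0")
    p = 1.0 - K / 100.0
    D = 1.0 + float(_logistic_term(np.asarray(ed_k, float), b, e))
    s = _stim_at(family, ed_k, f, a)
    if convention == "relative_to_control":
        denom = 1.0 - p * D
        if abs(denom) < _DEGENERATE_TOL * max(1.0, abs(p * D)):
            raise ReparamInfeasibleError(
                "target level unreachable: 1 - (1-K/100)*(1+(ED/e)^b) ~ 0"
            )
        return (c * (1.0 - D) - s) / denom
    if convention == "relative_to_range":
        denom = 1.0 - p * D
        if abs(denom) < _DEGENERATE_TOL * max(1.0, abs(p * D)):
            raise ReparamInfeasibleError("degenerate range-convention coefficient")
        return c - s / denom
    raise ValidationError(f"unknown convention {convention!r}")


def solve_f_for_m(family: str, c: float, d: float, b: float, e: float,
                  m: float, a: float | None = None) -> float:
    """Closed-form hormesis parameter f implied by a stationary dose M.

    Isolates f in ``dy/dx(M) = 0``. The returned f may be negative,
    which signals that the requested M is not a genuine maximum for
    these parameters (callers flag this).
    """
    if family not in ("brain_cousens", "cedergreen"):
        raise CapabilityError(f"no M reparameterization for {family!r}")
    if m <= 0:
        raise NumericDomainError("M must be > 0")
    if b == 0:
        raise StationarityDegenerateError(
            "b = 0: flat logistic term, stationarity cannot determine f"
        )
    L = float(_logistic_term(np.asarray(m, float), b, e))
    if family == "brain_cousens":
        denom = m * (1.0 + L - b * L)
        if abs(denom) < _DEGENERATE_TOL * max(1.0, m * (1.0 + L)):
            raise StationarityDegenerateError(
                "degenerate stationarity denominator for Brain-Cousens at M"
            )
        return (d - c) * b * L / denom
    if a is None or a <= 0:
        raise NumericDomainError("Cedergreen family requires a > 0")
    g = float(_stimulation_term(np.asarray(m, float), a))
    # m * g'(m) = a * m^(-a) * g
    mgp = a * m ** (-a) * g
    denom = mgp * (1.0 + L) - g * b * L
    if g == 0 or abs(denom) < _DEGENERATE_TOL * max(1.0, abs(g) * (1.0 + L)):
        raise StationarityDegenerateError(
            "degenerate stationarity denominator for Cedergreen at M"
        )
    return (d - c) * b * L / denom


@dataclass(frozen=True)
class ReparamSpec:
    """A model family with one natural parameter replaced by a dosage.

    ``free_names`` lists the fit parameters in order, the target dosage
    last. Evaluating the reparameterized mean function equals
    evaluating the natural model with the implied eliminated parameter
    (curve-set equivalence).
    """

    family: str
    target: TargetQuantity

    def __post_init__(self):
        if self.family not in ("brain_cousens", "cedergreen"):
            raise CapabilityError(
                f"reparameterization supports brain_cousens/cedergreen, "
                f"got {self.family!r}"
            )

    @property
    def eliminated_parameter(self) -> str:
        return "d" if self.target.kind in ("ED_K", "LDS") else "f"

    @property
    def free_names(self) -> tuple[str, ...]:
        base = [n for n in param_names(self.family)
                if n != self.eliminated_parameter]
        return tuple(base) + (self.target.name,)

    def implied_params(self, theta: dict) -> NaturalParams:
        """Natural parameters implied by a reparameterized vector."""
        t = dict(theta)
        target_val = t.pop(self.target.name)
        a = t.get("a")
        if self.eliminated_parameter == "d":
            d = solve_d_for_edk(
                self.family, c=t["c"], b=t["b"], e=t["e"], f=t["f"],
                ed_k=target_val, K=self.target.effective_K, a=a,
                convention=self.target.convention,
            )
            return NaturalParams(c=t["c"], d=d, b=t["b"], e=t["e"],
                                 f=t["f"], a=a)
        f = solve_f_for_m(self.family, c=t["c"], d=t["d"], b=t["b"],
                          e=t["e"], m=target_val, a=a)
        return NaturalParams(c=t["c"], d=t["d"], b=t["b"], e=t["e"],
                             f=f, a=a)

    def mean(self, theta: dict, dose):
        """Mean response of the reparameterized model."""
        return eval_family(self.family, self.implied_params(theta), dose)

    def theta_from_natural(self, params: NaturalParams,
                           target_value: float) -> dict:
        """Reparameterized vector matching a natural curve + target."""
        theta = {n: getattr(params, n) for n in self.free_names
                 if n != self.target.name}
        theta[self.target.name] = target_value
        return theta

    def to_json_dict(self) -> dict:
        return {
            "family": self.family,
            "target_kind": self.target.kind,
            "K": self.target.K,
            "convention": self.target.convention,
            "eliminated_parameter": self.eliminated_parameter,
            "free_parameters": list(self.free_names),
        }


def build_reparam_model(family: str, target: TargetQuantity) -> ReparamSpec:
    """Construct the reparameterized variant of a hormetic family."""
    return ReparamSpec(family=family, target=target)


# ---------------------------------------------------------------------
# numeric oracle
# ---------------------------------------------------------------------

def _response_level(K: float, c: float, d: float, convention: str) -> float:
    p = 1.0 - K / 100.0
    if convention == "relative_to_control":
        return p * d
    return c + p * (d - c)


def _find_max(family: str, params: NaturalParams) -> float:
    """Argmax of the mean curve by grid bracketing + golden/Brent."""
    e = params.e
    grid = np.geomspace(e * 1e-8, e * 1e4, 600)
    vals = eval_family(family, params, grid)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda x: -eval_family(family, params, x),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-13 * e},
    )
    m = float(res.x)
    # polish to machine precision on the analytic slope when it
    # brackets a sign change around the golden-section estimate
    try:
        dlo, dhi = m * (1 - 1e-3), m * (1 + 1e-3)
        slo = curve_dose_derivative(family, params, dlo)
        shi = curve_dose_derivative(family, params, dhi)
        if np.sign(slo) != np.sign(shi):
            m = float(optimize.brentq(
                lambda x: curve_dose_derivative(family, params, x),
                dlo, dhi, rtol=8.9e-16,
            ))
    except Exception:  # pragma: no cover - polish is best-effort
        pass
    return m


def _bracketed_root(func, lo: float, hi0: float, limit: float) -> float:
    """Root of func on (lo, +inf): expand [lo, hi] geometrically x10
    until a sign change appears, then bisect with brentq."""
    flo = func(lo)
    hi = hi0
    while hi <= limit:
        fhi = func(hi)
        if np.sign(fhi) != np.sign(flo):
            return float(optimize.brentq(func, lo, hi, xtol=1e-300,
                                         rtol=8.9e-16, maxiter=200))
        hi *= 10.0
    raise RootNotFoundError(
        f"no sign change on ({lo:g}, {limit:g}); curve never reaches the "
        "target level"
    )


def functionals_from_natural(family: str, params: NaturalParams,
                             K_list=(50.0,),
                             convention: str = "relative_to_control",
                             quantities=("M", "LDS", "ED")) -> dict:
    """Extract M, y_max, LDS and ED_K doses from a natural-parameter
    curve by bounded maximization and bracketed root finding.

    This is the independent numeric route against which the direct
    reparameterized fits are checked. ED_K and LDS are always taken on
    the inhibitory branch (right of M); pre-hormetic roots are handled
    by :func:`hormfit.inference.pre_hormetic_quantities`.
    """
    if family == "loglogistic4":
        f = 0.0
    else:
        f = params.f if params.f is not None else 0.0
    hormetic = f > 0
    want_m = "M" in quantities
    want_lds = "LDS" in quantities
    want_ed = "ED" in quantities
    if (want_m or want_lds) and not hormetic:
        raise NoHormesisError("M/LDS require a hormetic curve (f > 0)")

    out: dict[str, float] = {}
    e = params.e
    c, d = params.c, params.d
    limit = _BRACKET_LIMIT * e

    if hormetic and (want_m or want_lds or want_ed):
        m = _find_max(family, params)
        # f > 0 is necessary but not sufficient: the stimulation must
        # actually lift the curve above the control mean somewhere
        if eval_family(family, params, m) <= d * (1 + 1e-12):
            if want_m or want_lds:
                raise NoHormesisError(
                    "f > 0 but the stimulation never exceeds the control "
                    "mean: no hormetic maximum"
                )
            hormetic = False
            m = None
        if want_m:
            out["M"] = m
            out["y_max"] = float(eval_family(family, params, m))
        start = m if m is not None else e * 1e-10
    else:
        start = e * 1e-10

    def curve(x):
        return eval_family(family, params, x)

    if want_lds:
        out["LDS"] = _bracketed_root(
            lambda x: curve(x) - d, start * (1 + 1e-12), max(10 * e, start * 1.01),
            limit,
        )
    if want_ed:
        for K in K_list:
            level = _response_level(K, c, d, convention)
            lo = out.get("LDS", start) * (1 + 1e-12) if hormetic else start
            out[f"ED{K:g}"] = _bracketed_root(
                lambda x: curve(x) - level, lo, max(10 * e, lo * 1.01), limit,
            )
    return out


def check_stationarity(family: str, params: NaturalParams, m: float,
                       tol_scale: float = 1e-8) -> bool:
    """True if |dy/dx| at m is below tol_scale * d / e (defining
    property of a fitted M)."""
    slope = curve_dose_derivative(family, params, m)
    return abs(slope) < tol_scale * abs(params.d) / params.e
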