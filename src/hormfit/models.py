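"""Mean functions and dose-derivatives for hormetic log-logistic families.

Three nested families are provided:

* ``loglogistic4`` — the monotone four-parameter log-logistic,
  ``y = c + (d - c) / (1 + (x/e)^b)``.
* ``brain_cousens`` — the Brain-Cousens hormetic extension, which adds a
  linear low-dose stimulation term ``f*x`` to the numerator:
  ``y = c + (d - c + f*x) / (1 + (x/e)^b)``. ``f`` is the rate of
  stimulation at doses near zero; ``f > 0`` is necessary for hormesis.
* ``cedergreen`` — the Cedergreen-Ritz-Streibig extension, which uses a
  saturating stimulation term ``f*exp(-x^(-a))``:
  ``y = c + (d - c + f*exp(-x^(-a))) / (1 + (x/e)^b)``. Here ``f`` is
  an upper-bound-type hormesis parameter (response units) and ``a > 0``
  shapes how quickly the stimulation sets in at low doses.

Both hormetic families reduce exactly to ``loglogistic4`` at ``f = 0``.
Parameters: ``c`` lower asymptote (response at infinite dose), ``d``
control mean (response at dose 0 for ``b > 0``), ``b`` slope-type,
``e`` dose-scale (> 0), and the hormetic ``f`` (plus ``a`` for the
Cedergreen family).

Evaluation at dose 0 is defined by the analytic limit (returns ``d``
for ``b > 0``); the logistic exponent is clamped at +/-700 before
exponentiation so extreme ``b``/dose combinations stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import NumericDomainError

FAMILIES = ("brain_cousens", "cedergreen", "loglogistic4")

#: clamp for exponents before np.exp to avoid overflow
_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class NaturalParams:
    """Natural-parameter vector (c, d, b, e, f[, a]) of a model family."""

    c: float
    d: float
    b: float
    e: float
    f: float | None = None
    a: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    def replace(self, **kw) -> "NaturalParams":
        d = asdict(self)
        d.update(kw)
        return NaturalParams(**d)


def param_names(family: str) -> tuple[str, ...]:
    """Free natural parameters of a family, in canonical order."""
    if family == "loglogistic4":
        return ("c", "d", "b", "e")
    if family == "brain_cousens":
        return ("c", "d", "b", "e", "f")
    if family == "cedergreen":
        return ("c", "d", "b", "e", "f", "a")
    raise NumericDomainError(f"unknown model family {family!r}")


def _check(params: NaturalParams, family: str) -> None:
    for name in param_names(family):
        v = getattr(params, name)
        if v is None or not np.isfinite(v):
            raise NumericDomainError(f"parameter {name} is missing or non-finite")
    if params.e <= 0:
        raise NumericDomainError(f"e must be > 0, got {params.e}")
    if family == "cedergreen" and params.a <= 0:
        raise NumericDomainError(f"a must be > 0, got {params.a}")


def _logistic_term(x: np.ndarray, b: float, e: float) -> np.ndarray:
    """(x/e)^b computed as exp(b*(ln x - ln e)) with exponent clamping.

    Defined for x > 0; the x = 0 limit is handled by the callers.
    """
    with np.errstate(divide="ignore"):
        expo = b * (np.log(x) - np.log(e))
    return np.exp(np.clip(expo, -_EXP_CLAMP, _EXP_CLAMP))


def _stimulation_term(x: np.ndarray, a: float) -> np.ndarray:
    """exp(-x^(-a)) for x > 0 (0 at x = 0 by limit), overflow-safe."""
    with np.errstate(divide="ignore"):
        t = -a * np.log(x)  # ln(x^-a)
    return np.exp(-np.exp(np.clip(t, -_EXP_CLAMP, _EXP_CLAMP)))


def _limit_at_zero(c: float, d: float, b: float) -> float:
    # logistic term -> 0 for b > 0 (response d), -> inf for b < 0
    # (response c); b = 0 gives the midpoint
    if b > 0:
        return d
    if b < 0:
        return c
    return c + (d - c) / 2.0


def _eval(family: str, params: NaturalParams, dose) -> np.ndarray | float:
    _check(params, family)
    x = np.asarray(dose, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0):
        raise NumericDomainError("dose must be non-negative")
    c, d, b, e = params.c, params.d, params.b, params.e
    out = np.empty_like(x)
    zero = x == 0
    pos = ~zero
    xp = x[pos]
    L = _logistic_term(xp, b, e)
    if family == "loglogistic4":
        num = d - c
    elif family == "brain_cousens":
        num = d - c + params.f * xp
    else:
        num = d - c + params.f * _stimulation_term(xp, params.a)
    out[pos] = c + num / (1.0 + L)
    out[zero] = _limit_at_zero(c, d, b)
    return float(out[0]) if scalar else out


def eval_loglogistic4(params: NaturalParams, dose):
    """Monotone 4-parameter log-logistic mean response at ``dose``."""
    return _eval("loglogistic4", params, dose)


def eval_brain_cousens(params: NaturalParams, dose):
    """Brain-Cousens hormetic mean response at ``dose``."""
    return _eval("brain_cousens", params, dose)


def eval_cedergreen(params: NaturalParams, dose):
    """Cedergreen hormetic mean response at ``dose``."""
    return _eval("cedergreen", params, dose)


_EVALS = {
    "loglogistic4": eval_loglogistic4,
    "brain_cousens": eval_brain_cousens,
    "cedergreen": eval_cedergreen,
}


def eval_family(family: str, params: NaturalParams, dose):
    """Dispatch mean-function evaluation by family name."""
    try:
        fn = _EVALS[family]
    except KeyError:
        raise NumericDomainError(f"unknown model family {family!r}") from None
    return fn(params, dose)


def curve_dose_derivative(family: str, params: NaturalParams, dose):
    """Analytic first derivative of the mean response w.r.t. dose.

    Defined for dose > 0 only (at 0 the derivative exists only as a
    one-sided limit). Vectorized over doses.
    """
    _check(params, family)
    x = np.asarray(dose, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x <= 0):
        raise NumericDomainError("derivative defined for dose > 0 only")
    c, d, b, e = params.c, params.d, params.b, params.e
    L = _logistic_term(x, b, e)
    D = 1.0 + L
    dL = b * L / x
    if family == "loglogistic4":
        num, dnum = d - c, np.zeros_like(x)
    elif family == "brain_cousens":
        num, dnum = d - c + params.f * x, np.full_like(x, params.f)
    else:
        a = params.a
        g = _stimulation_term(x, a)
        # g' = a * x^(-a-1) * g
        dg = a * np.exp(np.clip((-a - 1.0) * np.log(x), -_EXP_CLAMP, _EXP_CLAMP)) * g
        num, dnum = d - c + params.f * g, params.f * dg
    out = (dnum * D - num * dL) / D**2
    return float(out[0]) if scalar else out
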