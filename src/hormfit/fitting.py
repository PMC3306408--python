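"""Weighted nonlinear least-squares engine for hormetic models.

The objective is ``sum_i w_i * (y_i - mu(x_i; theta))**2`` with
per-observation weights from the data container (inverse replicate SD
by default). Minimization uses a damped least-squares trust-region
iteration (scipy's reflective variant) that honors the box constraints
c >= 0, e > 0, a > 0 and target dosages > 0 natively.

Starting values follow the bioassay protocol: d from the control mean,
c = 0, e slightly below the dose whose mean is nearest 50% of control,
and a ladder of presets for f (scaled by the observed maximum
stimulation above control), a and b that is walked deterministically
until a fit converges. Reparameterized fits are seeded from a pilot
natural fit, with the target dosage seeded by the numeric oracle.

When the Cedergreen shape parameter ``a`` cannot be freely estimated,
:func:`fix_a_profile` refits over a fixed grid a in [0.07, 1.75]
(step 0.02) and keeps the fit with the smallest residual sum of
squares; a fixed ``a`` is not counted as an estimated parameter in the
degrees of freedom.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .data import DoseResponseData
from .errors import (
    HormfitError,
    NonConvergenceError,
    RankDeficiencyError,
    StartValueError,
    ValidationError,
)
from .models import NaturalParams, eval_family, param_names
from .reparam import ReparamSpec, functionals_from_natural

logger = logging.getLogger(__name__)

#: default bounds per parameter name (target dosages handled separately)
_BOUNDS = {
    "c": (0.0, np.inf),
    "d": (-np.inf, np.inf),
    "b": (-np.inf, np.inf),
    "e": (1e-12, np.inf),
    "f": (-np.inf, np.inf),
    "a": (1e-8, np.inf),
}

#: grid for fixing the Cedergreen shape parameter a: [0.07, 1.75] step 0.02
A_GRID = np.round(np.arange(0.07, 1.75 + 1e-9, 0.02), 10)

#: relative-SS-reduction convergence tolerance
FTOL = 1e-12


def _free_names(model, fixed: dict) -> tuple[str, ...]:
    if isinstance(model, ReparamSpec):
        names = model.free_names
    else:
        names = param_names(model)
    return tuple(n for n in names if n not in fixed)


def _mean_function(model, fixed: dict):
    """Return mu(theta_vector, doses) over the free parameters."""
    if isinstance(model, ReparamSpec):
        names = _free_names(model, fixed)

        def mu(vec, x):
            theta = dict(zip(names, vec))
            theta.update(fixed)
            return model.mean(theta, x)
    else:
        names = _free_names(model, fixed)

        def mu(vec, x):
            theta = dict(zip(names, vec))
            theta.update(fixed)
            return eval_family(model, NaturalParams(**theta), x)
    return mu


def _bounds_for(name: str) -> tuple[float, float]:
    if name in _BOUNDS:
        return _BOUNDS[name]
    # target dosages (ED*, LDS, M) are strictly positive
    return (1e-12, np.inf)


@dataclass
class FitResult:
    """Result of a weighted nonlinear least-squares fit.

    estimates/covariance are over the free parameters only; ``fixed``
    records parameters held constant (e.g. a preset Cedergreen a),
    which are excluded from the degrees-of-freedom accounting.
    """

    model: object  # family name or ReparamSpec
    estimates: dict
    covariance: np.ndarray
    ss_res: float
    df_res: int
    ss_corrected: float
    converged: bool
    n_iter: int
    fixed: dict = field(default_factory=dict)
    start_used: dict = field(default_factory=dict)
    seed_trace: list = field(default_factory=list)
    data: DoseResponseData | None = None

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(self.estimates.keys())

    @property
    def family(self) -> str:
        return self.model.family if isinstance(self.model, ReparamSpec) else self.model

    @property
    def n_free(self) -> int:
        return len(self.estimates)

    def all_params(self) -> dict:
        return {**self.estimates, **self.fixed}

    def natural_params(self) -> NaturalParams:
        """Natural parameters of the fitted curve (implied for
        reparameterized fits)."""
        theta = self.all_params()
        if isinstance(self.model, ReparamSpec):
            return self.model.implied_params(theta)
        return NaturalParams(**theta)

    def predict(self, dose):
        """Fitted mean response at ``dose``."""
        return eval_family(self.family, self.natural_params(), dose)

    def se(self, name: str) -> float:
        if name not in self.estimates:
            from .errors import NotEstimatedError
            raise NotEstimatedError(f"{name!r} is not a free parameter")
        i = list(self.estimates).index(name)
        return float(np.sqrt(self.covariance[i, i]))

    @property
    def s2(self) -> float:
        """Residual variance estimate ss_res / df_res."""
        return self.ss_res / self.df_res

    @property
    def pseudo_r2(self) -> float:
        return 1.0 - self.ss_res / self.ss_corrected

    def weighted_residuals(self) -> np.ndarray:
        w = self.data.weight
        return np.sqrt(w) * (self.data.response - self.predict(self.data.dose))

    def to_json_dict(self) -> dict:
        model = (self.model.to_json_dict() if isinstance(self.model, ReparamSpec)
                 else self.model)
        return {
            "model": model,
            "estimates": self.estimates,
            "se": {n: self.se(n) for n in self.estimates},
            "covariance": self.covariance.tolist(),
            "ss_res": self.ss_res,
            "df_res": self.df_res,
            "ss_corrected": self.ss_corrected,
            "pseudo_r2": self.pseudo_r2,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "fixed": self.fixed,
            "start_used": self.start_used,
        }

    def report(self, level: float = 0.95) -> str:
        """Human-readable fit report (estimates +/- SE with t CIs)."""
        from .inference import wald_ci
        name = (f"{self.model.family}[{self.model.target.name}]"
                if isinstance(self.model, ReparamSpec) else str(self.model))
        lines = [f"Model: {name}",
                 f"ss_res = {self.ss_res:.6g} on {self.df_res} df "
                 f"(ss_res/df = {self.s2:.6g}), Pseudo-R2 = {self.pseudo_r2:.4f}"]
        for n in self.estimates:
            ci = wald_ci(self, n, level=level)
            lines.append(f"  {n:>6s} = {self.estimates[n]:12.6g} "
                         f"+/- {ci.se:.4g}  CI{level * 100:.0f}% "
                         f"[{ci.lower:.6g}, {ci.upper:.6g}]")
        for n, v in self.fixed.items():
            lines.append(f"  {n:>6s} = {v:12.6g}  (fixed)")
        return "\n".join(lines)


# ---------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------

def initial_values(data: DoseResponseData, model) -> dict:
    """First (best-guess) starting values for a natural-family fit."""
    return next(iter(start_candidates(data, model)))


def start_candidates(data: DoseResponseData, model):
    """Deterministic ladder of starting-value dicts for a family.

    d = control mean; c = 0; e = 0.8 x the dose whose per-dose mean is
    nearest 50% of control; f presets {0, 1, 10, 100} scaled by the
    observed maximum stimulation above control (outermost), then
    a presets {0.1, 0.5, 1}, then b presets {1, 2, 3}.
    """
    family = model.family if isinstance(model, ReparamSpec) else model
    levels = data.dose_levels
    if 0.0 not in levels:
        raise StartValueError("no untreated control (dose 0): cannot seed d")
    means = data.per_dose_mean
    d0 = data.control_mean
    pos = levels > 0
    if not np.any(pos):
        raise StartValueError("no positive doses")
    near50 = levels[pos][np.argmin(np.abs(means[pos] - 0.5 * d0))]
    e0 = 0.8 * near50
    stim = float(means.max() - d0)
    if family == "loglogistic4":
        f_menu = [None]
    else:
        # scale the preset menu by the apparent stimulation size
        if stim <= 0:
            f_menu = [0.0, 1.0, 10.0, 100.0]
        elif family == "brain_cousens":
            s = stim / (10.0 * e0)  # f has response-per-dose units
            f_menu = [0.0, s, 10 * s, 100 * s]
        else:
            s = stim / 10.0  # f has response units
            f_menu = [0.0, s, 10 * s, 100 * s]
    a_menu = [0.1, 0.5, 1.0] if family == "cedergreen" else [None]
    b_menu = [1.0, 2.0, 3.0]
    for f0, a0, b0 in itertools.product(f_menu, a_menu, b_menu):
        cand = {"c": 0.0, "d": d0, "b": b0, "e": e0}
        if f0 is not None:
            cand["f"] = f0
        if a0 is not None:
            cand["a"] = a0
        yield cand


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------

def _fit_once(data: DoseResponseData, model, start: dict, fixed: dict,
              bounds: dict | None, max_iter: int) -> FitResult:
    names = _free_names(model, fixed)
    if len(names) < 1:
        raise ValidationError("no free parameters")
    n = data.n_obs
    df_res = n - len(names)
    if df_res < 1:
        raise ValidationError(
            f"df_res = {df_res} < 1 ({n} observations, {len(names)} parameters)"
        )
    missing = [k for k in names if k not in start]
    if missing:
        raise StartValueError(f"start lacks values for {missing}")
    lb = np.array([(bounds or {}).get(k, _bounds_for(k))[0] for k in names])
    ub = np.array([(bounds or {}).get(k, _bounds_for(k))[1] for k in names])
    x0 = np.array([float(start[k]) for k in names])
    if np.any(x0 < lb) or np.any(x0 > ub):
        bad = [k for k, v, l, u in zip(names, x0, lb, ub) if v < l or v > u]
        raise ValidationError(f"starting values out of bounds for {bad}")
    w = data.weight
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    sw = np.sqrt(w)
    x, y = data.dose, data.response
    mu = _mean_function(model, fixed)

    def resid(vec):
        r = sw * (y - mu(vec, x))
        return np.where(np.isfinite(r), r, 1e150)

    res = least_squares(
        resid, x0, bounds=(lb, ub), method="trf",
        ftol=FTOL, xtol=FTOL, gtol=1e-14,
        max_nfev=max_iter * max(len(names), 1),
    )
    ss_res = float(np.sum(res.fun**2))
    if not np.isfinite(ss_res):
        raise NonConvergenceError("non-finite residual sum of squares")
    converged = res.status > 0
    if not converged:
        raise NonConvergenceError(
            f"optimizer stopped without convergence (status {res.status})"
        )
    # covariance s^2 * (J'WJ)^-1 via SVD of the weighted Jacobian
    J = res.jac
    U, s, Vt = np.linalg.svd(J, full_matrices=False)
    if s[0] == 0 or s[-1] < 1e-10 * s[0]:
        direction = names[int(np.argmax(np.abs(Vt[-1])))]
        raise RankDeficiencyError(
            f"J'WJ singular at the optimum; weakest direction ~ {direction!r}",
            direction=direction,
        )
    s2 = ss_res / df_res
    cov = (Vt.T / s**2) @ Vt * s2
    cov = 0.5 * (cov + cov.T)
    ybar_w = float(np.sum(w * y) / np.sum(w))
    ss_corrected = float(np.sum(w * (y - ybar_w) ** 2))
    result = FitResult(
        model=model,
        estimates=dict(zip(names, map(float, res.x))),
        covariance=cov,
        ss_res=ss_res,
        df_res=df_res,
        ss_corrected=ss_corrected,
        converged=converged,
        n_iter=int(res.nfev),
        fixed=dict(fixed),
        start_used={k: float(start[k]) for k in names},
        data=data,
    )
    # interpretability warnings, not errors
    try:
        nat = result.natural_params()
        if nat.c > nat.d:
            logger.warning("fitted c (%.4g) exceeds d (%.4g): fit is "
                           "numerically valid but hard to interpret",
                           nat.c, nat.d)
        if (result.family == "brain_cousens" and nat.f is not None
                and nat.f > 0 and nat.b <= 1):
            logger.warning("Brain-Cousens fit has b = %.4g <= 1 with f > 0; "
                           "the low-slope regime is known to be fragile for "
                           "this family", nat.b)
    except HormfitError:
        pass
    return result


def fit_model(data: DoseResponseData, model, start: dict | None = None,
              fixed: dict | None = None, bounds: dict | None = None,
              max_iter: int = 1000) -> FitResult:
    """Fit a natural family or a :class:`ReparamSpec` to the data.

    With an explicit ``start`` a single attempt is made; without one
    the starting-value ladder is walked until a fit converges, and a
    :class:`NonConvergenceError` carrying the attempt trace is raised
    if every rung fails. Reparameterized models without an explicit
    start are seeded from a pilot natural fit (see
    :func:`fit_reparam`).
    """
    fixed = dict(fixed or {})
    if start is not None:
        return _fit_once(data, model, start, fixed, bounds, max_iter)
    if isinstance(model, ReparamSpec):
        return fit_reparam(data, model, fixed=fixed, bounds=bounds,
                           max_iter=max_iter)
    trace = []
    for i, cand in enumerate(start_candidates(data, model)):
        try:
            fit = _fit_once(data, model, cand, fixed, bounds, max_iter)
        except Exception as exc:  # noqa: BLE001 - ladder records and retries
            trace.append({"step": i, "start": cand, "error": str(exc)})
            continue
        fit.seed_trace = trace + [{"step": i, "start": cand, "error": None}]
        return fit
    raise NonConvergenceError(
        f"all {len(trace)} starting-value ladder steps failed", trace=trace
    )


def fit_reparam(data: DoseResponseData, spec: ReparamSpec,
                pilot: FitResult | None = None, fixed: dict | None = None,
                bounds: dict | None = None, max_iter: int = 1000) -> FitResult:
    """Fit a reparameterized model, seeded from a pilot natural fit.

    The pilot's final estimates seed the shared parameters and the
    numeric oracle seeds the target dosage — the protocol of refitting
    each target from the converged natural fit.
    """
    fixed = dict(fixed or {})
    if pilot is None:
        pilot = fit_model(data, spec.family, fixed=fixed, bounds=bounds,
                          max_iter=max_iter)
    nat = pilot.natural_params()
    target = spec.target
    if target.kind == "M":
        fn = functionals_from_natural(spec.family, nat, quantities=("M",))
        tval = fn["M"]
    elif target.kind == "LDS":
        fn = functionals_from_natural(spec.family, nat, quantities=("M", "LDS"),
                                      convention=target.convention)
        tval = fn["LDS"]
    else:
        from .errors import NoHormesisError
        try:
            fn = functionals_from_natural(
                spec.family, nat, K_list=(target.K,),
                convention=target.convention,
                quantities=("M", "LDS", "ED") if (nat.f or 0) > 0 else ("ED",),
            )
        except NoHormesisError:
            # f-hat > 0 but no actual hump: ED_K is still well defined
            fn = functionals_from_natural(
                spec.family, nat, K_list=(target.K,),
                convention=target.convention, quantities=("ED",),
            )
        tval = fn[target.name]
    start = spec.theta_from_natural(nat, tval)
    for k in fixed:
        start.pop(k, None)
    fit = _fit_once(data, spec, start, fixed, bounds, max_iter)
    fit.seed_trace = [{"step": 0, "start": start, "error": None,
                       "pilot": pilot.estimates}]
    return fit


def fix_a_profile(data: DoseResponseData, model, grid=None,
                  force_grid: bool = False, **kw) -> FitResult:
    """Cedergreen fitting protocol for the shape parameter a.

    First attempts free estimation of a; if that fails (non-convergence,
    rank deficiency, or a non-estimable f) the model is refit with a
    fixed at each grid value in [0.07, 1.75] and the smallest-ss_res
    fit is returned, with a recorded in ``fixed`` (not counted in the
    degrees of freedom).
    """
    family = model.family if isinstance(model, ReparamSpec) else model
    if family != "cedergreen":
        raise ValidationError("fix_a_profile applies to the Cedergreen family")
    if grid is None:
        grid = A_GRID
    if not force_grid:
        try:
            fit = fit_model(data, model, **kw)
            if np.all(np.isfinite(np.diag(fit.covariance))):
                return fit
        except Exception as exc:  # noqa: BLE001 - fall back to the grid
            logger.info("free-a fit failed (%s); profiling fixed a", exc)
    best, trace = None, []
    for a0 in grid:
        try:
            fit = fit_model(data, model, fixed={"a": float(a0)}, **kw)
        except Exception as exc:  # noqa: BLE001
            trace.append({"a": float(a0), "error": str(exc)})
            continue
        if best is None or fit.ss_res < best.ss_res:
            best = fit
    if best is None:
        raise NonConvergenceError("all fixed-a grid fits failed", trace=trace)
    return best


def save_fit(fit: FitResult, path) -> None:
    """Serialize a fit to JSON."""
    with open(path, "w") as fh:
        json.dump(fit.to_json_dict(), fh, indent=2)
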