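"""Synthetic dose-response data and Monte-Carlo validation harnesses.

The generator emulates replicated germination-bioassay designs: a
geometric dose series including an untreated control (dose 0), a
hormetic mean curve from either model family, and heteroscedastic
Gaussian noise with a per-dose SD. The default scenario is a
Cedergreen truth (c=0, d=100, b=2, e=10, f=50, a=1) on doses
{0, 0.1, 0.3, 1, 3, 10, 30, 100} with 5 replicates and SD proportional
to the mean (5% of control at the control, floored at 1% of control),
which exercises the inverse-SD weighting meaningfully.

Monte-Carlo harnesses cover CI coverage of effective dosages, type-I
error of the hormesis test, and the bias incurred by fitting the wrong
family (misspecification).
"""

from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DoseResponseData
from .errors import ConfigError, ExperimentInvalidError, NoHormesisError
from .fitting import fit_model, fit_reparam
from .inference import test_hormesis, wald_ci
from .models import NaturalParams, eval_family
from .reparam import ReparamSpec, TargetQuantity, functionals_from_natural

DEFAULT_DOSES = (0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)
DEFAULT_TRUTH = NaturalParams(c=0.0, d=100.0, b=2.0, e=10.0, f=50.0, a=1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Truth model, dose design, replication and noise for a scenario.

    noise_cv: per-dose SD as a fraction of the local true mean;
    noise_floor: lower bound on the SD as a fraction of the control
    mean d. ``noise_sd`` overrides both with explicit per-dose SDs.
    """

    truth_family: str = "cedergreen"
    truth_params: NaturalParams = DEFAULT_TRUTH
    doses: tuple = DEFAULT_DOSES
    replicates: int = 5
    noise_cv: float = 0.05
    noise_floor: float = 0.01
    noise_sd: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if len(self.doses) < 5 or 0.0 not in self.doses:
            raise ConfigError("dose design needs >= 5 levels including 0")
        if self.replicates < 2:
            raise ConfigError("need >= 2 replicates per dose for weighting")
        if self.noise_sd is not None and len(self.noise_sd) != len(self.doses):
            raise ConfigError("noise_sd must match the dose design length")

    def per_dose_sd(self) -> np.ndarray:
        doses = np.asarray(self.doses, float)
        if self.noise_sd is not None:
            sd = np.asarray(self.noise_sd, float)
        else:
            mean = eval_family(self.truth_family, self.truth_params, doses)
            d = self.truth_params.d
            sd = np.maximum(self.noise_cv * mean, self.noise_floor * d)
        if np.any(sd <= 0):
            raise ConfigError("all per-dose SDs must be > 0")
        return sd


def generate_dataset(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> DoseResponseData:
    """Draw one replicated dataset from the configured truth.

    Responses are truth mean + Gaussian noise with the per-dose SD;
    negative draws are truncated at 0 (measurement floor) and counted
    on the returned container as ``n_truncated``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    doses = np.asarray(config.doses, float)
    mean = eval_family(config.truth_family, config.truth_params, doses)
    sd = config.per_dose_sd()
    r = config.replicates
    dose_col = np.repeat(doses, r)
    resp = rng.normal(np.repeat(mean, r), np.repeat(sd, r))
    n_trunc = int(np.sum(resp < 0))
    resp = np.maximum(resp, 0.0)
    if n_trunc > 0.01 * resp.size:
        logging.getLogger(__name__).warning(
            "%d of %d responses truncated at 0 (> 1%%): noise may be too "
            "large for this truth curve", n_trunc, resp.size)
    data = DoseResponseData(
        dose=dose_col, response=resp,
        replicate=np.tile(np.arange(1, r + 1), len(doses)),
    )
    data.n_truncated = n_trunc
    return data


def _sim_rng(config: SimulationConfig, i: int) -> np.random.Generator:
    """Per-simulation generator: seed sequence (config.seed, i)."""
    return np.random.default_rng(np.random.SeedSequence((config.seed, i)))



def coverage_experiment(config: SimulationConfig, quantity: TargetQuantity,
                        n_sims: int = 300, level: float = 0.95,
                        a_handling: str = "free",
                        max_failure_rate: float = 0.2) -> dict:
    """Empirical CI coverage and bias for one effective dosage.

    Per simulation: generate, weight (inverse SD), fit the
    reparameterized model, record whether the t CI covers the truth
    functional and the relative estimation error. Returns coverage
    with a binomial normal-approximation CI and a bias summary.
    """
    truth = functionals_from_natural(
        config.truth_family, config.truth_params,
        K_list=(quantity.effective_K,) if quantity.kind == "ED_K" else (50.0,),
        convention=quantity.convention,
    )
    if quantity.name not in truth:
        raise NoHormesisError(f"truth has no {quantity.name}")
    true_val = truth[quantity.name]
    spec = ReparamSpec(config.truth_family, quantity)
    fixed = ({"a": config.truth_params.a}
             if (config.truth_family == "cedergreen" and a_handling != "free")
             else {})
    rows, failures = [], []
    for i in range(n_sims):
        data = generate_dataset(config, rng=_sim_rng(config, i))
        try:
            wdata = data.with_weights("inverse_sd")
            pilot = fit_model(wdata, spec.family, fixed=fixed)
            fit = fit_reparam(wdata, spec, pilot=pilot, fixed=fixed)
            ci = wald_ci(fit, quantity.name, level=level)
            est = fit.estimates[quantity.name]
        except Exception as exc:  # noqa: BLE001 - counted, bounded below
            failures.append({"sim": i, "error": str(exc)})
            continue
        rows.append({
            "sim": i, "estimate": est,
            "lower": ci.lower, "upper": ci.upper,
            "covers": ci.lower <= true_val <= ci.upper,
            "rel_error_pct": 100.0 * (est - true_val) / true_val,
        })
    if n_sims and len(failures) > max_failure_rate * n_sims:
        raise ExperimentInvalidError(
            f"{len(failures)}/{n_sims} fits failed", trace=failures)
    table = pd.DataFrame(rows)
    n_ok = len(table)
    cov = float(table["covers"].mean()) if n_ok else float("nan")
    half = 1.96 * np.sqrt(cov * (1 - cov) / n_ok) if n_ok else float("nan")
    bias = table["rel_error_pct"] if n_ok else pd.Series(dtype=float)
    return {
        "quantity": quantity.name,
        "truth": true_val,
        "n_sims": n_sims,
        "n_ok": n_ok,
        "n_failed": len(failures),
        "coverage": cov,
        "coverage_ci": (cov - half, cov + half),
        "median_rel_bias_pct": float(bias.median()) if n_ok else float("nan"),
        "median_abs_rel_bias_pct": float(bias.abs().median()) if n_ok else float("nan"),
        "table": table,
    }


def type1_experiment(config: SimulationConfig, fit_family: str = "brain_cousens",
                     n_sims: int = 500, level: float = 0.95,
                     max_failure_rate: float = 0.2) -> dict:
    """Rejection rate of the hormesis test under a non-hormetic truth.

    The truth should have f = 0 (or be a plain log-logistic); each
    simulated dataset is fit with a hormetic family and the
    CI-excludes-zero rule for f is applied.
    """
    rows, failures = [], []
    for i in range(n_sims):
        data = generate_dataset(config, rng=_sim_rng(config, i))
        try:
            fit = fit_model(data.with_weights("inverse_sd"), fit_family)
            ht = test_hormesis(fit, level=level)
        except Exception as exc:  # noqa: BLE001
            failures.append({"sim": i, "error": str(exc)})
            continue
        rows.append({"sim": i, "f": ht.f_estimate, "significant": ht.significant})
    if n_sims and len(failures) > max_failure_rate * n_sims:
        raise ExperimentInvalidError(
            f"{len(failures)}/{n_sims} fits failed", trace=failures)
    table = pd.DataFrame(rows)
    rate = float(table["significant"].mean()) if len(table) else float("nan")
    return {"n_sims": n_sims, "n_ok": len(table), "n_failed": len(failures),
            "rejection_rate": rate, "table": table}


def misspecification_experiment(config: SimulationConfig, fit_family: str,
                                n_sims: int = 100,
                                quantities=("ED50", "LDS", "M", "y_max"),
                                a_handling: str = "fixed_truth",
                                max_failure_rate: float = 0.2) -> pd.DataFrame:
    """Relative bias of effective dosages when fitting the wrong family.

    Data are drawn from ``config.truth_family`` and fit with
    ``fit_family``; per simulation the fitted curve's functionals are
    compared with the truth functionals. Returns a tidy table (one row
    per simulation x quantity) with a ``rel_bias_pct`` column.
    """
    truth = functionals_from_natural(config.truth_family, config.truth_params,
                                     K_list=(50.0,))
    rows, failures = [], []
    for i in range(n_sims):
        data = generate_dataset(config, rng=_sim_rng(config, i))
        try:
            fixed = {}
            if fit_family == "cedergreen" and a_handling == "fixed_truth" \
                    and config.truth_family == "cedergreen":
                fixed = {"a": config.truth_params.a}
            fit = fit_model(data.with_weights("inverse_sd"), fit_family,
                            fixed=fixed)
            est = functionals_from_natural(fit_family, fit.natural_params(),
                                           K_list=(50.0,))
        except Exception as exc:  # noqa: BLE001
            failures.append({"sim": i, "error": str(exc)})
            continue
        for q in quantities:
            if q in truth and q in est:
                rows.append({
                    "sim": i, "quantity": q, "truth": truth[q],
                    "estimate": est[q],
                    "rel_bias_pct": 100.0 * (est[q] - truth[q]) / truth[q],
                })
    if n_sims and len(failures) > max_failure_rate * n_sims:
        raise ExperimentInvalidError(
            f"{len(failures)}/{n_sims} fits failed", trace=failures)
    cols = ["sim", "quantity", "truth", "estimate", "rel_bias_pct"]
    return pd.DataFrame(rows, columns=cols)


def mixed_truth_scenarios(seed0: int = 100) -> list[SimulationConfig]:
    """Twenty hormetic scenarios (ten per family) spanning slopes,
    dose scales, stimulation sizes and Cedergreen shapes; used by the
    equivalence validation battery."""
    crs = [
        NaturalParams(c=0, d=100, b=2.0, e=10, f=50, a=1.0),
        NaturalParams(c=0, d=100, b=1.5, e=5, f=40, a=0.5),
        NaturalParams(c=0, d=100, b=3.0, e=20, f=60, a=1.0),
        NaturalParams(c=0, d=100, b=2.0, e=10, f=30, a=0.8),
        NaturalParams(c=0, d=100, b=1.0, e=30, f=60, a=0.25),
        NaturalParams(c=5, d=100, b=2.5, e=15, f=80, a=1.5),
        NaturalParams(c=0, d=120, b=2.0, e=8, f=70, a=1.2),
        NaturalParams(c=0, d=100, b=1.2, e=12, f=45, a=0.4),
        NaturalParams(c=0, d=80, b=2.2, e=25, f=35, a=0.9),
        NaturalParams(c=0, d=100, b=2.8, e=6, f=90, a=1.0),
    ]
    bc = [
        NaturalParams(c=0, d=100, b=2.0, e=10, f=5.0),
        NaturalParams(c=0, d=100, b=3.0, e=20, f=2.0),
        NaturalParams(c=0, d=100, b=1.5, e=5, f=8.0),
        NaturalParams(c=5, d=100, b=2.5, e=15, f=4.0),
        NaturalParams(c=0, d=120, b=2.0, e=8, f=6.0),
        NaturalParams(c=0, d=100, b=2.0, e=12, f=6.0),
        NaturalParams(c=0, d=80, b=2.5, e=12, f=3.0),
        NaturalParams(c=0, d=100, b=1.8, e=10, f=10.0),
        NaturalParams(c=0, d=100, b=2.2, e=18, f=2.5),
        NaturalParams(c=0, d=110, b=2.7, e=7, f=7.0),
    ]
    out = []
    for i, p in enumerate(crs):
        out.append(SimulationConfig(truth_family="cedergreen",
                                    truth_params=p, seed=seed0 + i))
    for i, p in enumerate(bc):
        out.append(SimulationConfig(truth_family="brain_cousens",
                                    truth_params=p, seed=seed0 + i))
    return out


def broad_hormesis_config(seed: int = 0) -> SimulationConfig:
    """A flat, broad-hormesis Cedergreen truth (small a, wide M-LDS
    span) — the shape the Brain-Cousens model handles worst."""
    return SimulationConfig(
        truth_family="cedergreen",
        truth_params=NaturalParams(c=0.0, d=100.0, b=1.0, e=30.0, f=60.0, a=0.25),
        doses=(0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0),
        replicates=5,
        seed=seed,
    )
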