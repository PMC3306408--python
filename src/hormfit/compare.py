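"""Goodness-of-fit diagnostics and two-model comparison.

Implements the lack-of-fit F test against pure error from replicates
(on the weighted scale used by the fit), the descriptive Pseudo-R²
(1 - SS_res/SS_corrected; a supplemental criterion only), the signed
relative bias between the two families' effective-dose estimates
(baseline = the better-fitting model), a CI-overlap screen (an
indication, not a test — the rule does not hold a 5% type-I error
rate), and a four-way case classification:

* case1_neither — no significant hormesis from either family and both
  fail a residual-pattern screen;
* case2_bc_better — Brain-Cousens preferred (only BC finds significant
  f, or both do and BC fits better);
* case3_crs_better — symmetric for the Cedergreen family;
* case4_equal — both significant with diagnostics within margins.

Since a human graphical-agreement judgment cannot be automated, the
residual-pattern screen is a Wald-Wolfowitz runs test on the signs of
dose-ordered residuals — a reproducible surrogate, labeled as such in
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import DoseResponseData
from .errors import ValidationError
from .fitting import FitResult
from .inference import test_hormesis, wald_ci

CASES = ("case1_neither", "case2_bc_better", "case3_crs_better", "case4_equal")


@dataclass(frozen=True)
class FitDiagnostics:
    ss_res_over_df: float
    pseudo_r2: float
    lof_F: float | None
    lof_p: float | None
    lof_df: tuple | None
    runs_p: float | None = None


def lack_of_fit_test(data: DoseResponseData, fit: FitResult):
    """Weighted lack-of-fit F test against pure error from replicates.

    Decomposes SS_res about the per-dose means:
    SS_res = SS_lof + SS_pure, F = (SS_lof/df_lof)/(SS_pure/df_pure)
    with df_pure = n - #doses and df_lof = #doses - #free parameters.
    """
    levels = data.dose_levels
    n = data.n_obs
    df_pure = n - len(levels)
    if df_pure < 1:
        raise ValidationError("no replication: pure-error df < 1")
    df_lof = len(levels) - fit.n_free
    if df_lof < 1:
        raise ValidationError("lack-of-fit df < 1")
    w, y, x = data.weight, data.response, data.dose
    pred = fit.predict(x)
    ss_res = float(np.sum(w * (y - pred) ** 2))
    means = {lv: np.mean(y[x == lv]) for lv in levels}
    ybar = np.array([means[v] for v in x])
    ss_pure = float(np.sum(w * (y - ybar) ** 2))
    ss_lof = ss_res - ss_pure
    F = (ss_lof / df_lof) / (ss_pure / df_pure)
    p = float(stats.f.sf(max(F, 0.0), df_lof, df_pure))
    return F, p, (df_lof, df_pure)


def pseudo_r2(fit: FitResult) -> float:
    """1 - SS_res/SS_corrected (weighted); descriptive only."""
    if fit.ss_corrected <= 0:
        raise ValidationError("constant response data: SS_corrected = 0")
    return 1.0 - fit.ss_res / fit.ss_corrected


def relative_bias(estimate_better: float, estimate_other: float) -> float:
    """Signed percent deviation of the other model from the better one:
    100 * (estimate_other - estimate_better) / estimate_better."""
    if estimate_better == 0:
        raise ValidationError("zero baseline estimate: relative bias undefined")
    return 100.0 * (estimate_other - estimate_better) / estimate_better


def runs_test_residuals(data: DoseResponseData, fit: FitResult) -> float:
    """Two-sided Wald-Wolfowitz runs test p-value on the signs of
    dose-ordered residuals (normal approximation). Small p indicates
    systematic misfit."""
    order = np.argsort(data.dose, kind="stable")
    r = (data.response - fit.predict(data.dose))[order]
    signs = np.sign(r)
    signs = signs[signs != 0]
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def diagnostics(data: DoseResponseData, fit: FitResult) -> FitDiagnostics:
    try:
        F, p, dfs = lack_of_fit_test(data, fit)
    except ValidationError:
        F = p = dfs = None
    return FitDiagnostics(
        ss_res_over_df=fit.s2,
        pseudo_r2=pseudo_r2(fit),
        lof_F=F, lof_p=p, lof_df=dfs,
        runs_p=runs_test_residuals(data, fit),
    )


@dataclass
class ComparisonReport:
    """Paired-model diagnostics, effective-dose bias and case label."""

    diagnostics_bc: FitDiagnostics
    diagnostics_crs: FitDiagnostics
    hormesis_bc: object
    hormesis_crs: object
    case: str
    rationale: list = field(default_factory=list)
    bias_table: pd.DataFrame | None = None
    better: str | None = None

    def to_json_dict(self) -> dict:
        return {
            "case": self.case,
            "better": self.better,
            "rationale": self.rationale,
            "diagnostics": {
                "brain_cousens": vars(self.diagnostics_bc),
                "cedergreen": vars(self.diagnostics_crs),
            },
            "hormesis": {
                "brain_cousens": {
                    "f": self.hormesis_bc.f_estimate,
                    "significant": self.hormesis_bc.significant,
                },
                "cedergreen": {
                    "f": self.hormesis_crs.f_estimate,
                    "significant": self.hormesis_crs.significant,
                },
            },
            "bias_table": (self.bias_table.to_dict("records")
                           if self.bias_table is not None else None),
        }

    def text(self) -> str:
        lines = [f"Case: {self.case}"
                 + (f" (better fit: {self.better})" if self.better else "")]
        lines += [f"  - {r}" for r in self.rationale]
        if self.bias_table is not None and len(self.bias_table):
            lines.append(self.bias_table.to_string(index=False))
        return "\n".join(lines)


def classify_case(hormesis_bc, hormesis_crs, diag_bc: FitDiagnostics,
                  diag_crs: FitDiagnostics,
                  r2_margin: float = 0.01,
                  s2_ratio_band: tuple = (0.9, 1.1),
                  runs_alpha: float = 0.05) -> tuple[str, list, str | None]:
    """Four-way suitability classification of the two families.

    Returns (case, rationale trace, better-fitting family or None).
    Deterministic given the fits and margins.
    """
    trace = []
    sig_bc, sig_crs = hormesis_bc.significant, hormesis_crs.significant
    s2_ratio = diag_bc.ss_res_over_df / diag_crs.ss_res_over_df
    within = (abs(diag_bc.pseudo_r2 - diag_crs.pseudo_r2) < r2_margin
              and s2_ratio_band[0] <= s2_ratio <= s2_ratio_band[1])
    trace.append(f"hormesis significant: BC={sig_bc}, CRS={sig_crs}")
    trace.append(f"ss_res/df: BC={diag_bc.ss_res_over_df:.6g}, "
                 f"CRS={diag_crs.ss_res_over_df:.6g} (ratio {s2_ratio:.3f})")
    trace.append(f"Pseudo-R2: BC={diag_bc.pseudo_r2:.4f}, "
                 f"CRS={diag_crs.pseudo_r2:.4f}")
    if not sig_bc and not sig_crs:
        bad_bc = diag_bc.runs_p is not None and diag_bc.runs_p < runs_alpha
        bad_crs = diag_crs.runs_p is not None and diag_crs.runs_p < runs_alpha
        trace.append(f"residual-pattern screen (runs test surrogate for "
                     f"graphical agreement): BC fails={bad_bc}, CRS fails={bad_crs}")
        if bad_bc and bad_crs:
            trace.append("neither model significant and both fail the screen")
            return "case1_neither", trace, None
        better = "brain_cousens" if s2_ratio <= 1 else "cedergreen"
        trace.append("neither significant but at least one screen passes; "
                     "classified by fit quality")
        return ("case2_bc_better" if better == "brain_cousens"
                else "case3_crs_better"), trace, better
    if sig_bc and not sig_crs:
        trace.append("only Brain-Cousens detects significant hormesis")
        return "case2_bc_better", trace, "brain_cousens"
    if sig_crs and not sig_bc:
        trace.append("only Cedergreen detects significant hormesis")
        return "case3_crs_better", trace, "cedergreen"
    if within:
        trace.append("both significant; diagnostics within margins")
        return "case4_equal", trace, None
    better = "brain_cousens" if s2_ratio < 1 else "cedergreen"
    trace.append(f"both significant; {better} fits better beyond margins")
    return ("case2_bc_better" if better == "brain_cousens"
            else "case3_crs_better"), trace, better


def compare_models(data: DoseResponseData, fit_bc: FitResult,
                   fit_crs: FitResult, dose_tables: dict | None = None,
                   level: float = 0.95, **margins) -> ComparisonReport:
    """Full two-model comparison report.

    ``dose_tables`` optionally maps family name -> {quantity name ->
    reparameterized FitResult} to populate the per-quantity relative
    bias and CI-overlap table.
    """
    diag_bc = diagnostics(data, fit_bc)
    diag_crs = diagnostics(data, fit_crs)
    h_bc = test_hormesis(fit_bc, level=level)
    h_crs = test_hormesis(fit_crs, level=level)
    case, trace, better = classify_case(h_bc, h_crs, diag_bc, diag_crs,
                                        **margins)
    report = ComparisonReport(
        diagnostics_bc=diag_bc, diagnostics_crs=diag_crs,
        hormesis_bc=h_bc, hormesis_crs=h_crs,
        case=case, rationale=trace, better=better,
    )
    if dose_tables:
        base_family = better or ("brain_cousens"
                                 if diag_bc.ss_res_over_df
                                 <= diag_crs.ss_res_over_df
                                 else "cedergreen")
        other_family = ("cedergreen" if base_family == "brain_cousens"
                        else "brain_cousens")
        rows = []
        base = dose_tables.get(base_family, {})
        other = dose_tables.get(other_family, {})
        for q in base:
            if q not in other:
                continue
            e1, e2 = base[q].estimates[q], other[q].estimates[q]
            ci1 = wald_ci(base[q], q, level=level)
            ci2 = wald_ci(other[q], q, level=level)
            rows.append({
                "quantity": q,
                "estimate_" + base_family: e1,
                "estimate_" + other_family: e2,
                "rel_bias_pct": relative_bias(e1, e2),
                "abs_rel_bias_pct": abs(relative_bias(e1, e2)),
                "ci_overlap": bool(ci1.covers(e2) or ci2.covers(e1)),
            })
        report.bias_table = pd.DataFrame(rows)
        report.rationale.append(
            f"relative-bias baseline: {base_family} (better fit)")
    return report
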