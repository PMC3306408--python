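"""Dose-response data container, CSV I/O and replicate-based weighting.

The container holds one row per experimental unit (dose, response,
optional replicate label) together with per-dose summaries (n, mean, SD)
and a per-observation weight used by the weighted least-squares
objective ``sum(w_i * r_i**2)``.

Weighting follows the variance-stabilizing convention common in
herbicide bioassay work: the inverse replicate standard deviation at
each dose multiplies the squared residual (``inverse_sd``); inverse
variance and unweighted schemes are also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateVarianceError,
    DesignError,
    InsufficientReplicationError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: relative tolerance for merging dose levels that differ only by
#: floating-point noise
DOSE_MERGE_RTOL = 1e-9

WEIGHT_SCHEMES = ("inverse_sd", "inverse_variance", "none")


def _merge_close_doses(dose: np.ndarray) -> np.ndarray:
    """Snap doses that agree within DOSE_MERGE_RTOL onto one level."""
    out = dose.copy()
    levels = np.unique(dose)
    if len(levels) < 2:
        return out
    ref = levels[0]
    for lv in levels[1:]:
        scale = max(abs(ref), abs(lv))
        if scale > 0 and abs(lv - ref) <= DOSE_MERGE_RTOL * scale:
            out[out == lv] = ref
        else:
            ref = lv
    return out


@dataclass
class DoseResponseData:
    """Replicated dose-response observations with per-dose summaries.

    Parameters
    ----------
    dose, response : arrays of equal length
        Non-negative dose (concentration units) and response (e.g. root
        length) per experimental unit. Row order is preserved for
        residual reporting.
    replicate : optional array of labels per observation.
    weight : per-observation weights (default 1); constant within a
        dose level by construction of :meth:`with_weights`.
    """

    dose: np.ndarray
    response: np.ndarray
    replicate: np.ndarray | None = None
    weight: np.ndarray = field(default=None)  # type: ignore[assignment]
    weight_scheme: str = "none"
    require_control: bool = True

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.dose.shape != self.response.shape or self.dose.ndim != 1:
            raise ValidationError("dose and response must be equal-length 1-d arrays")
        if not np.all(np.isfinite(self.response)):
            bad = int(np.flatnonzero(~np.isfinite(self.response))[0])
            raise ValidationError(f"non-finite response at row {bad}")
        if not np.all(np.isfinite(self.dose)):
            bad = int(np.flatnonzero(~np.isfinite(self.dose))[0])
            raise ValidationError(f"non-finite dose at row {bad}")
        if np.any(self.dose < 0):
            bad = int(np.flatnonzero(self.dose < 0)[0])
            raise ValidationError(f"negative dose at row {bad}")
        self.dose = _merge_close_doses(self.dose)
        levels = np.unique(self.dose)
        if len(levels) < 5:
            raise DesignError(
                f"need at least 5 distinct dose levels, found {len(levels)}"
            )
        if self.require_control and 0.0 not in levels:
            raise DesignError("untreated control (dose 0) is required")
        if self.weight is None:
            self.weight = np.ones_like(self.response)
        else:
            self.weight = np.asarray(self.weight, dtype=float)
            if np.any(self.weight <= 0):
                raise ValidationError("weights must be positive")

    # -- per-dose summaries --------------------------------------------

    @property
    def dose_levels(self) -> np.ndarray:
        """Sorted unique doses (strictly increasing)."""
        return np.unique(self.dose)

    @property
    def n_obs(self) -> int:
        return len(self.dose)

    def _group(self, values: np.ndarray, func) -> np.ndarray:
        return np.array(
            [func(values[self.dose == lv]) for lv in self.dose_levels]
        )

    @property
    def per_dose_n(self) -> np.ndarray:
        return self._group(self.response, len).astype(int)

    @property
    def per_dose_mean(self) -> np.ndarray:
        return self._group(self.response, np.mean)

    @property
    def per_dose_sd(self) -> np.ndarray:
        """Replicate SD per dose (ddof=1; 0 where n == 1)."""
        return self._group(
            self.response, lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0
        )

    @property
    def control_mean(self) -> float:
        """Mean response of the untreated control (dose 0)."""
        if 0.0 not in self.dose_levels:
            raise DesignError("no untreated control (dose 0) present")
        return float(np.mean(self.response[self.dose == 0.0]))

    # -- weighting ------------------------------------------------------

    def with_weights(self, scheme: str = "inverse_sd",
                     zero_sd_fallback: bool = True) -> "DoseResponseData":
        """Return a copy with weights set by the given scheme.

        ``inverse_sd`` sets weight = 1/SD of replicates at the
        observation's dose; ``inverse_variance`` uses 1/SD**2; ``none``
        sets 1. A dose with SD 0 gets the smallest positive per-dose SD
        substituted when ``zero_sd_fallback`` is enabled (logged),
        otherwise a :class:`DegenerateVarianceError` is raised.
        """
        if scheme not in WEIGHT_SCHEMES:
            raise ValidationError(
                f"unknown weight scheme {scheme!r}; choose from {WEIGHT_SCHEMES}"
            )
        if scheme == "none":
            w = np.ones_like(self.response)
        else:
            levels = self.dose_levels
            ns = self.per_dose_n
            if np.any(ns < 2):
                bad = levels[ns < 2][0]
                raise InsufficientReplicationError(
                    f"dose {bad:g} has a single replicate; scheme {scheme!r} "
                    "needs n >= 2 at every dose"
                )
            sds = self.per_dose_sd
            if np.any(sds == 0):
                if not zero_sd_fallback or not np.any(sds > 0):
                    bad = levels[sds == 0][0]
                    raise DegenerateVarianceError(
                        f"zero replicate SD at dose {bad:g}"
                    )
                fallback = sds[sds > 0].min()
                for lv in levels[sds == 0]:
                    logger.info(
                        "dose %g has zero replicate SD; substituting the "
                        "smallest positive per-dose SD %g", lv, fallback
                    )
                sds = np.where(sds == 0, fallback, sds)
            per_level = 1.0 / sds if scheme == "inverse_sd" else 1.0 / sds**2
            lookup = dict(zip(levels, per_level))
            w = np.array([lookup[d] for d in self.dose])
        return DoseResponseData(
            dose=self.dose, response=self.response, replicate=self.replicate,
            weight=w, weight_scheme=scheme, require_control=self.require_control,
        )

    # -- I/O -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"dose": self.dose, "response": self.response})
        if self.replicate is not None:
            df["replicate"] = self.replicate
        return df

    def to_csv(self, path) -> None:
        # 17 significant digits round-trip doubles bit-exactly
        self.to_frame().to_csv(path, index=False,
                               float_format=lambda v: format(v, ".17g"))

    def summary_frame(self) -> pd.DataFrame:
        """Tidy per-dose summary (dose, n, mean, sd, weight)."""
        levels = self.dose_levels
        lookup = {lv: self.weight[self.dose == lv][0] for lv in levels}
        return pd.DataFrame({
            "dose": levels,
            "n": self.per_dose_n,
            "mean": self.per_dose_mean,
            "sd": self.per_dose_sd,
            "weight": [lookup[lv] for lv in levels],
        })


def compute_weights(data: DoseResponseData, scheme: str = "inverse_sd",
                    zero_sd_fallback: bool = True) -> DoseResponseData:
    """Functional alias for :meth:`DoseResponseData.with_weights`."""
    return data.with_weights(scheme=scheme, zero_sd_fallback=zero_sd_fallback)


def read_dose_response(path, column_map: dict | None = None,
                       require_control: bool = True) -> DoseResponseData:
    """Read a dose-response CSV into a validated container.

    Parameters
    ----------
    path : file path to a UTF-8 CSV with a header row.
    column_map : optional mapping from the container's field names
        (``dose``, ``response``, ``replicate``) to the file's column
        names; defaults to identical names.
    """
    cmap = {"dose": "dose", "response": "response", "replicate": "replicate"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("dose", "response"):
        if cmap[key] not in df.columns:
            raise SchemaError(
                f"required column {cmap[key]!r} (for {key}) not found in {path}"
            )
    dose = pd.to_numeric(df[cmap["dose"]], errors="coerce").to_numpy(float)
    resp = pd.to_numeric(df[cmap["response"]], errors="coerce").to_numpy(float)
    if np.any(np.isnan(dose)):
        bad = int(np.flatnonzero(np.isnan(dose))[0])
        raise ValidationError(f"unparseable dose at row {bad}")
    if np.any(np.isnan(resp)):
        bad = int(np.flatnonzero(np.isnan(resp))[0])
        raise ValidationError(f"unparseable response at row {bad}")
    rep = None
    if cmap["replicate"] in df.columns:
        rep = df[cmap["replicate"]].to_numpy()
    return DoseResponseData(dose=dose, response=resp, replicate=rep,
                            require_control=require_control)
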