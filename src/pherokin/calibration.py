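"""EAG dose–response calibration, inverse prediction, and release accounting.

The calibration line regresses blank-corrected EAG response (%) on the flow
rate (µL·min⁻¹) of a reference pheromone solution.  Inverse prediction maps a
corrected response back to a concentration through mass-flux equivalence: the
antenna is assumed to respond to the delivered mass flux (concentration ×
flow), so a response matching the line at equivalent flow x_eq delivered at
``source_flow`` implies concentration = reference × x_eq / source_flow.  That
assumption is this module's explicit convention — it is dimensionally
consistent and reproduces a halving of apparent concentration at double the
flow — not a claim about the underlying electrophysiology.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import DomainError, ExtrapolationError, InsufficientDataError

__all__ = [
    "CalibrationLine",
    "InversionResult",
    "ReleaseRecord",
    "fit_calibration_line",
    "invert_calibration",
    "release_accounting",
]

#: Recovery fraction above which a release record is flagged implausible.
RECOVERY_IMPLAUSIBLE = 1.0
#: Benchmark recovery fraction for the evaporator.
RECOVERY_BENCHMARK = 0.8


@dataclass
class CalibrationLine:
    """OLS dose–response line: corrected response % = slope·flow + intercept."""

    slope: float
    intercept: float
    r_squared: float
    flow_range: tuple[float, float] = (0.01, 2.0)
    reference_concentration_ng_ul: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1:
            raise DomainError(f"r_squared must be in [0, 1], got {self.r_squared}")
        if self.flow_range[0] >= self.flow_range[1]:
            raise DomainError("flow_range must be (min, max) with min < max")
        if not self.reference_concentration_ng_ul > 0:
            raise DomainError("reference_concentration_ng_ul must be positive")

    @property
    def usable(self) -> bool:
        return self.slope > 0

    def predict(self, flow_ul_min: float) -> float:
        return self.slope * flow_ul_min + self.intercept

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "r_squared": self.r_squared,
                    "flow_range": list(self.flow_range),
                    "reference_concentration_ng_ul": self.reference_concentration_ng_ul,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CalibrationLine":
        with open(path) as fh:
            obj = json.load(fh)
        obj["flow_range"] = tuple(obj["flow_range"])
        return cls(**obj)


@dataclass
class InversionResult:
    """Inverse prediction outcome; below-detection is a result, not an error."""

    concentration_ng_ul: float
    equivalent_flow_ul_min: float
    below_detection: bool
    extrapolated: bool


@dataclass
class ReleaseRecord:
    """Evaporator release/recovery bookkeeping for one run."""

    solution_concentration_ng_ul: float
    flow_rate_ul_min: float
    duration_min: float
    theoretical_mass_ng: float | None = None
    recovered_mass_ng: float | None = None
    recovery_fraction: float | None = None
    below_benchmark: bool | None = None
    implausible: bool | None = None

    def __post_init__(self) -> None:
        for name in ("solution_concentration_ng_ul", "flow_rate_ul_min", "duration_min"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.recovered_mass_ng is not None and self.recovered_mass_ng < 0:
            raise DomainError("recovered_mass_ng must be non-negative")


def fit_calibration_line(
    flows_ul_min,
    corrected_responses_pct,
    *,
    reference_concentration_ng_ul: float = 10.0,
) -> CalibrationLine:
    """OLS fit of corrected response (%) vs flow; at least 3 distinct flows."""
    flows = np.asarray(flows_ul_min, dtype=float)
    responses = np.asarray(corrected_responses_pct, dtype=float)
    if flows.shape != responses.shape or flows.ndim != 1:
        raise DomainError("flows and responses must be 1-D arrays of equal length")
    if len(np.unique(flows)) < 3:
        raise InsufficientDataError("fit_calibration_line requires >= 3 distinct flows")
    res = stats.linregress(flows, responses)
    r_squared = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    if res.slope <= 0:
        warnings.warn(
            f"fit_calibration_line: non-positive slope ({res.slope:.3g}); "
            "calibration flagged unusable",
            stacklevel=2,
        )
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r_squared,
        flow_range=(float(flows.min()), float(flows.max())),
        reference_concentration_ng_ul=reference_concentration_ng_ul,
    )


def invert_calibration(
    line: CalibrationLine,
    corrected_response_pct: float,
    source_flow_ul_min: float,
    *,
    allow_extrapolation: bool = False,
) -> InversionResult:
    """Estimate the source concentration behind a corrected EAG response.

    x_eq = (response − intercept)/slope is the calibration flow that would
    evoke the same response from the reference solution; by mass-flux
    equivalence the source concentration is reference × x_eq / source_flow.
    A response at or below the intercept yields a below-detection result.
    x_eq outside the calibrated flow range raises
    :class:`ExtrapolationError` unless ``allow_extrapolation`` (then the
    result is flagged).
    """
    if not line.usable:
        raise DomainError("calibration line is unusable (non-positive slope)")
    if not source_flow_ul_min > 0:
        raise DomainError(f"source_flow_ul_min must be positive, got {source_flow_ul_min}")
    if corrected_response_pct <= line.intercept:
        return InversionResult(0.0, 0.0, below_detection=True, extrapolated=False)
    x_eq = (corrected_response_pct - line.intercept) / line.slope
    lo, hi = line.flow_range
    # round-off tolerance so responses at the exact range edges stay in range
    tol = 1e-9 * max(abs(lo), abs(hi))
    extrapolated = not (lo - tol <= x_eq <= hi + tol)
    if extrapolated and not allow_extrapolation:
        raise ExtrapolationError(
            f"equivalent flow {x_eq:.4g} outside calibrated range {line.flow_range}; "
            "EAG dose-response saturates, refusing to extrapolate"
        )
    if extrapolated:
        warnings.warn(
            f"invert_calibration: extrapolating outside {line.flow_range}", stacklevel=2
        )
    concentration = line.reference_concentration_ng_ul * x_eq / source_flow_ul_min
    return InversionResult(
        concentration_ng_ul=float(concentration),
        equivalent_flow_ul_min=float(x_eq),
        below_detection=False,
        extrapolated=extrapolated,
    )


def release_accounting(record: ReleaseRecord) -> ReleaseRecord:
    """Fill theoretical mass and, when measured, the recovery fraction.

    theoretical = concentration × flow × duration; recovery below the 0.8
    benchmark or above 1 is flagged (flags, not errors).
    """
    theoretical = (
        record.solution_concentration_ng_ul * record.flow_rate_ul_min * record.duration_min
    )
    updates: dict = {"theoretical_mass_ng": theoretical}
    if record.recovered_mass_ng is not None:
        fraction = record.recovered_mass_ng / theoretical
        updates["recovery_fraction"] = fraction
        updates["below_benchmark"] = fraction < RECOVERY_BENCHMARK
        updates["implausible"] = fraction > RECOVERY_IMPLAUSIBLE
        if fraction > RECOVERY_IMPLAUSIBLE:
            warnings.warn(
                f"release_accounting: recovery fraction {fraction:.3g} > 1 is implausible",
                stacklevel=2,
            )
    return replace(record, **updates)
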