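"""Michaelis–Menten rate law and Hanes–Woolf estimation of apparent constants.

The acetyl-transferase batch assay follows the single-substrate Michaelis–Menten
law v = Vmax·S/(Km+S) (acetyl-CoA held saturating, so it does not enter the rate
law).  Apparent Km and Vmax are estimated from (S, v) pairs through the
Hanes–Woolf linearization, S/v = S/Vmax + Km/Vmax, fitted by ordinary least
squares: slope = 1/Vmax, intercept = Km/Vmax.  A direct nonlinear fit is
provided as a cross-check only; Hanes–Woolf is the reference estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DomainError, InsufficientDataError

__all__ = [
    "KineticParameters",
    "VelocityDataset",
    "HanesWoolfResult",
    "michaelis_menten_rate",
    "hanes_woolf_fit",
    "fit_michaelis_menten_nls",
]

#: Relative tolerance for the Km = (k_b + k_r)/k_f consistency check.
KM_CONSISTENCY_RTOL = 1e-9


@dataclass
class KineticParameters:
    """Rate constants and derived apparent constants of the enzymatic reaction.

    Parameters
    ----------
    k_f : float, optional
        Complex-formation (second-order) rate constant, µM⁻¹·s⁻¹.
    k_b : float, optional
        Complex-dissociation rate constant, s⁻¹.
    k_r : float, optional
        Product-formation (catalytic) rate constant, s⁻¹.
    km : float, optional
        Apparent Michaelis constant, µM.  Derived as (k_b + k_r)/k_f when all
        three rate constants are given and km is not.
    vmax : float, optional
        Apparent maximal velocity.  Unit is carried by ``vmax_unit``; pKat
        values convert to the canonical µM·s⁻¹ through a reference volume
        (see :mod:`pherokin.units`).
    vmax_unit : str
        Either ``"uM_per_s"`` or ``"pKat"``.
    """

    k_f: float | None = None
    k_b: float | None = None
    k_r: float | None = None
    km: float | None = None
    vmax: float | None = None
    vmax_unit: str = "uM_per_s"

    def __post_init__(self) -> None:
        for name in ("k_f", "k_b", "k_r", "km", "vmax"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise DomainError(f"{name} must be strictly positive when set, got {value}")
        if self.vmax_unit not in ("uM_per_s", "pKat"):
            raise DomainError(f"vmax_unit must be 'uM_per_s' or 'pKat', got {self.vmax_unit!r}")
        if self.k_f is not None and self.k_b is not None and self.k_r is not None:
            km_derived = (self.k_b + self.k_r) / self.k_f
            if self.km is None:
                self.km = km_derived
            elif not math.isclose(self.km, km_derived, rel_tol=KM_CONSISTENCY_RTOL):
                raise DomainError(
                    f"km={self.km} inconsistent with (k_b + k_r)/k_f = {km_derived}"
                )


@dataclass
class VelocityDataset:
    """Substrate-concentration / initial-velocity pairs from a batch assay."""

    substrate_um: np.ndarray
    velocity: np.ndarray
    velocity_unit: str = "uM_per_s"
    enzyme_amount_ug: float | None = None

    def __post_init__(self) -> None:
        self.substrate_um = np.asarray(self.substrate_um, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.substrate_um.shape != self.velocity.shape:
            raise DomainError("substrate_um and velocity must have the same length")
        if np.any(self.substrate_um <= 0):
            raise DomainError("substrate_um values must be strictly positive")
        if len(np.unique(self.substrate_um)) != len(self.substrate_um):
            raise DomainError("substrate_um values must be distinct")
        if np.any(self.velocity < 0):
            raise DomainError("velocity values must be non-negative")

    def __len__(self) -> int:
        return len(self.substrate_um)

    @classmethod
    def from_csv(cls, path) -> "VelocityDataset":
        """Read the ``substrate_uM, velocity, velocity_unit`` CSV schema."""
        df = pd.read_csv(path)
        units = df["velocity_unit"].unique()
        if len(units) != 1:
            raise DomainError(f"mixed velocity units in {path}: {list(units)}")
        return cls(df["substrate_uM"].to_numpy(), df["velocity"].to_numpy(), str(units[0]))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "substrate_uM": self.substrate_um,
                "velocity": self.velocity,
                "velocity_unit": self.velocity_unit,
            }
        ).to_csv(path, index=False)


@dataclass
class HanesWoolfResult:
    """Outcome of a Hanes–Woolf fit.

    ``valid`` is False (never an exception) when the transformed regression
    yields a non-positive slope or intercept, in which case ``params`` is None
    and ``message`` carries the diagnostics.
    """

    params: KineticParameters | None
    r_squared: float
    valid: bool
    n_used: int
    slope: float
    intercept: float
    message: str = ""
    excluded: int = 0
    diagnostics: dict = field(default_factory=dict)


def michaelis_menten_rate(substrate_um: float, params: KineticParameters):
    """Michaelis–Menten velocity v = Vmax·S/(Km+S).

    Returns the velocity in the unit of ``params.vmax``; 0 at S = 0, strictly
    increasing in S and bounded above by Vmax.  Accepts scalar or array S.
    """
    s = np.asarray(substrate_um, dtype=float)
    if np.any(s < 0):
        raise DomainError("substrate_um must be non-negative")
    if params.km is None or not params.km > 0:
        raise DomainError(f"params.km must be positive, got {params.km}")
    if params.vmax is None or not params.vmax > 0:
        raise DomainError(f"params.vmax must be positive, got {params.vmax}")
    rate = params.vmax * s / (params.km + s)
    return float(rate) if np.isscalar(substrate_um) else rate


def hanes_woolf_fit(data: VelocityDataset) -> HanesWoolfResult:
    """Estimate apparent (Km, Vmax) by OLS on the Hanes–Woolf transform.

    Points with v ≤ 0 are excluded with a warning before the transform (noisy
    data can produce them); fewer than 3 usable points raises
    :class:`InsufficientDataError`.  The reported r² is that of the transformed
    regression of S/v on S.
    """
    mask = data.velocity > 0
    excluded = int(np.sum(~mask))
    if excluded:
        warnings.warn(
            f"hanes_woolf_fit: excluded {excluded} point(s) with non-positive velocity",
            stacklevel=2,
        )
    s = data.substrate_um[mask]
    v = data.velocity[mask]
    if len(s) < 3:
        raise InsufficientDataError(
            f"hanes_woolf_fit requires at least 3 usable points, got {len(s)}"
        )
    res = stats.linregress(s, s / v)
    r_squared = float(res.rvalue**2)
    if res.slope <= 0 or res.intercept <= 0:
        return HanesWoolfResult(
            params=None,
            r_squared=r_squared,
            valid=False,
            n_used=len(s),
            slope=float(res.slope),
            intercept=float(res.intercept),
            message=(
                "non-positive slope or intercept in Hanes-Woolf regression; "
                "Km/Vmax undefined"
            ),
            excluded=excluded,
            diagnostics={"stderr": float(res.stderr)},
        )
    vmax = 1.0 / res.slope
    km = res.intercept / res.slope
    params = KineticParameters(km=km, vmax=vmax, vmax_unit=data.velocity_unit)
    return HanesWoolfResult(
        params=params,
        r_squared=r_squared,
        valid=True,
        n_used=len(s),
        slope=float(res.slope),
        intercept=float(res.intercept),
        excluded=excluded,
        diagnostics={"stderr": float(res.stderr)},
    )


def fit_michaelis_menten_nls(data: VelocityDataset) -> KineticParameters:
    """Direct nonlinear least-squares MM fit (cross-check, not the reference)."""
    mask = data.velocity > 0
    s, v = data.substrate_um[mask], data.velocity[mask]
    if len(s) < 3:
        raise InsufficientDataError("nonlinear MM fit requires at least 3 usable points")
    p0 = (np.median(s), float(np.max(v)))
    popt, _ = optimize.curve_fit(
        lambda x, km, vmax: vmax * x / (km + x), s, v, p0=p0, maxfev=10000
    )
    return KineticParameters(km=float(popt[0]), vmax=float(popt[1]), vmax_unit=data.velocity_unit)
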