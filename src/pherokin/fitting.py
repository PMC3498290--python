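"""Estimation of measured and free model constants.

Three estimators, mirroring how each constant was obtained experimentally:

* ``fit_deactivation`` — first-order deactivation constant K_D (h⁻¹) from a
  long-term batch activity time course, by ordinary least squares of
  log(mean activity ratio) against incubation time (K_D = −slope).
* ``estimate_adsorption_factor`` — F_AD = 1 − S_recovered/S_initial from the
  enzyme-free bead control.
* ``fit_free_parameters`` — the free rate constants (k_f, k_b, k_r) by bounded
  derivative-free least squares of the RK4 forward model against measured
  (τ, S, P) rows, multi-started from a seeded Latin hypercube.  Only the
  compound quantities Vmax = k_r·E_active and Km = (k_b + k_r)/k_f are
  identifiable; individual k_f and k_b lie along sloppy directions and are
  reported without any recovery claim.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from ._fastsim import integrate_reactor
from .errors import DomainError, InsufficientDataError, NormalizationError
from .kinetics import KineticParameters
from .reactor import ImmobilizationParameters, enzyme_activity
from .units import um_per_s_to_pkat

__all__ = [
    "DeactivationAssay",
    "DeactivationFit",
    "AdsorptionControl",
    "ConversionDataset",
    "FitResult",
    "fit_deactivation",
    "estimate_adsorption_factor",
    "fit_free_parameters",
]

#: Search bounds for each rate constant, log10 of lumped units.
LOG10_BOUNDS = (-6.0, 6.0)
#: Latin-hypercube start box, log10 (narrower than the bounds: extreme corners
#: are numerically infeasible and only waste starts).
LOG10_START_BOX = (-3.0, 3.0)
#: Step budget per objective evaluation of the fast integrator.
MAX_STEPS_PER_EVAL = 50_000
_PENALTY = 1e12


@dataclass
class DeactivationAssay:
    """Long-term batch activity observations (activity proxy vs time)."""

    time_h: np.ndarray
    replicate: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.replicate = np.asarray(self.replicate)
        self.activity = np.asarray(self.activity, dtype=float)
        if not (len(self.time_h) == len(self.replicate) == len(self.activity)):
            raise DomainError("time_h, replicate and activity must have equal length")
        if len(np.unique(self.time_h)) < 2:
            raise DomainError("at least 2 distinct time points are required")
        if np.any(self.activity < 0):
            raise DomainError("activities must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "DeactivationAssay":
        df = pd.read_csv(path)
        return cls(df["time_h"].to_numpy(), df["replicate"].to_numpy(), df["activity"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_h": self.time_h, "replicate": self.replicate, "activity": self.activity}
        ).to_csv(path, index=False)


@dataclass
class DeactivationFit:
    k_d: float
    stderr: float
    negative_estimate: bool
    n_times: int


@dataclass
class AdsorptionControl:
    """Substrate before/after incubation with enzyme-free carrier beads."""

    s_initial_um: float
    s_recovered_um: float

    def __post_init__(self) -> None:
        if not self.s_initial_um > 0:
            raise DomainError(f"s_initial_um must be positive, got {self.s_initial_um}")
        if self.s_recovered_um < 0:
            raise DomainError("s_recovered_um must be non-negative")
        if self.s_recovered_um > self.s_initial_um:
            raise DomainError(
                f"s_recovered_um ({self.s_recovered_um}) exceeds s_initial_um "
                f"({self.s_initial_um})"
            )

    @classmethod
    def from_json(cls, path) -> "AdsorptionControl":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(obj["s_initial_um"], obj["s_recovered_um"])


@dataclass
class ConversionDataset:
    """Measured (τ, S, P) rows pooled over reactors; τ stored in seconds."""

    tau_s: np.ndarray
    s_um: np.ndarray
    p_um: np.ndarray
    reactor_id: np.ndarray
    s0: float | None = None
    enzyme_amount_ug: float | None = None

    def __post_init__(self) -> None:
        self.tau_s = np.asarray(self.tau_s, dtype=float)
        self.s_um = np.asarray(self.s_um, dtype=float)
        self.p_um = np.asarray(self.p_um, dtype=float)
        self.reactor_id = np.asarray(self.reactor_id)
        n = len(self.tau_s)
        if not (len(self.s_um) == len(self.p_um) == len(self.reactor_id) == n):
            raise DomainError("all ConversionDataset columns must have equal length")
        if np.any(self.tau_s <= 0):
            raise DomainError("residence times must be strictly positive")
        if np.any(self.s_um < 0) or np.any(self.p_um < 0):
            raise DomainError("concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.tau_s)

    @classmethod
    def from_csv(cls, path, s0: float | None = None) -> "ConversionDataset":
        """Read the ``reactor_id, tau_min, S_uM, P_uM`` schema (τ in minutes)."""
        df = pd.read_csv(path)
        return cls(
            tau_s=df["tau_min"].to_numpy() * 60.0,
            s_um=df["S_uM"].to_numpy(),
            p_um=df["P_uM"].to_numpy(),
            reactor_id=df["reactor_id"].to_numpy(),
            s0=s0,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "reactor_id": self.reactor_id,
                "tau_min": self.tau_s / 60.0,
                "S_uM": self.s_um,
                "P_uM": self.p_um,
            }
        ).to_csv(path, index=False)


@dataclass
class FitResult:
    """Best converged multi-start result with derived reactor Vmax."""

    params: KineticParameters | None
    vmax_um_s: float | None
    vmax_pkat: float | None
    rss: float
    converged: bool
    n_starts: int
    start_objectives: list = field(default_factory=list)
    best_start: int | None = None
    at_boundary: bool = False
    seed: int = 0
    message: str = ""


def fit_deactivation(assay: DeactivationAssay) -> DeactivationFit:
    """K_D (h⁻¹) from OLS of log activity ratio vs time; K_D = −slope.

    Replicates are averaged within each time point before the log transform;
    the ratio is relative to the t = 0 mean (zero there is a normalization
    error).  A negative estimate is returned with a warning flag rather than
    raised.
    """
    times = np.unique(assay.time_h)
    means = np.array([assay.activity[assay.time_h == t].mean() for t in times])
    if 0.0 not in times:
        raise NormalizationError("deactivation assay must include a t = 0 observation")
    a0 = means[times == 0.0][0]
    if not a0 > 0:
        raise NormalizationError("mean activity at t = 0 is zero; cannot normalize")
    usable = means > 0
    if np.sum(usable) < 2:
        raise InsufficientDataError("fewer than 2 time points with positive mean activity")
    if not np.all(usable):
        warnings.warn(
            "fit_deactivation: dropping time point(s) with non-positive mean activity",
            stacklevel=2,
        )
    res = stats.linregress(times[usable], np.log(means[usable] / a0))
    k_d = -float(res.slope)
    negative = k_d < 0
    if negative:
        warnings.warn(f"fit_deactivation: negative K_D estimate ({k_d:.3g} 1/h)", stacklevel=2)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else float("nan")
    return DeactivationFit(k_d=k_d, stderr=stderr, negative_estimate=negative, n_times=int(np.sum(usable)))


def estimate_adsorption_factor(control: AdsorptionControl) -> float:
    """F_AD = 1 − S_recovered/S_initial, clipped to [0, 1)."""
    f_ad = 1.0 - control.s_recovered_um / control.s_initial_um
    if f_ad >= 1.0:  # S_recovered == 0 after validation
        warnings.warn(
            "estimate_adsorption_factor: no substrate recovered; capping F_AD below 1",
            stacklevel=2,
        )
        return 1.0 - 1e-9
    return max(f_ad, 0.0)


def fit_free_parameters(
    data: ConversionDataset,
    fixed: ImmobilizationParameters,
    s0: float,
    *,
    seed: int = 0,
    n_starts: int = 8,
    weight: str = "both",
    enzyme_age_h: float = 0.0,
    p0: float = 0.0,
    reference_volume_ul: float | None = None,
    h_max: float | None = None,
) -> FitResult:
    """Least-squares fit of (k_f, k_b, k_r) against measured conversion rows.

    The objective is the sum of squared residuals of the RK4 forward model at
    the observed residence times, over substrate and product rows equally
    weighted in µM (``weight``: "both" | "substrate" | "product").  The search
    runs in log10 space within [1e−6, 1e6], Nelder–Mead from ``n_starts``
    seeded Latin-hypercube starts plus a polish from the best start.  The
    derived reactor Vmax is k_r × active enzyme at ``enzyme_age_h`` (reported
    additionally in pKat when ``reference_volume_ul`` is given).

    A failed fit returns a :class:`FitResult` with ``converged=False`` and
    diagnostics — never a silent exception.
    """
    if len(data) < 3:
        raise InsufficientDataError("fit_free_parameters requires at least 3 rows")
    if weight not in ("both", "substrate", "product"):
        raise DomainError(f"weight must be 'both', 'substrate' or 'product', got {weight!r}")
    if not s0 > 0:
        raise DomainError(f"s0 must be strictly positive, got {s0}")

    order = np.argsort(data.tau_s, kind="stable")
    taus = np.ascontiguousarray(data.tau_s[order])
    s_obs = data.s_um[order]
    p_obs = data.p_um[order]
    tau_max = float(taus[-1])
    if h_max is None:
        h_max = tau_max / 2000.0
    e_active = enzyme_activity(enzyme_age_h, fixed)
    use_s = weight in ("both", "substrate")
    use_p = weight in ("both", "product")

    def objective(x: np.ndarray) -> float:
        k_f, k_b, k_r = 10.0**x
        s_mod, p_mod, status = integrate_reactor(
            k_f, k_b, k_r, fixed.f_ad, e_active, s0, p0, taus, h_max, MAX_STEPS_PER_EVAL
        )
        if status != 0:
            return _PENALTY
        rss = 0.0
        if use_s:
            rss += float(np.sum((s_mod - s_obs) ** 2))
        if use_p:
            rss += float(np.sum((p_mod - p_obs) ** 2))
        return rss

    sampler = qmc.LatinHypercube(d=3, seed=seed)
    lo, hi = LOG10_START_BOX
    starts = lo + (hi - lo) * sampler.random(n_starts)
    bounds = [LOG10_BOUNDS] * 3

    best = None
    start_objectives = []
    best_start = None
    for i, x0 in enumerate(starts):
        f0 = objective(x0)
        start_objectives.append(f0)
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-8, "fatol": 1e-12, "maxfev": 3000},
        )
        if best is None or res.fun < best.fun:
            best = res
            best_start = i
    # polish from the incumbent
    best = min(
        best,
        optimize.minimize(
            objective,
            best.x,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-10, "fatol": 1e-14, "maxfev": 3000},
        ),
        key=lambda r: r.fun,
    )

    converged = bool(best.fun < _PENALTY)
    if not converged:
        return FitResult(
            params=None,
            vmax_um_s=None,
            vmax_pkat=None,
            rss=float(best.fun),
            converged=False,
            n_starts=n_starts,
            start_objectives=start_objectives,
            best_start=best_start,
            seed=seed,
            message="no start produced a feasible objective value",
        )

    k_f, k_b, k_r = 10.0**best.x
    at_boundary = bool(
        np.any(np.abs(best.x - LOG10_BOUNDS[0]) < 1e-6)
        or np.any(np.abs(best.x - LOG10_BOUNDS[1]) < 1e-6)
    )
    vmax_um_s = k_r * e_active
    vmax_pkat = (
        um_per_s_to_pkat(vmax_um_s, reference_volume_ul)
        if reference_volume_ul is not None
        else None
    )
    params = KineticParameters(k_f=float(k_f), k_b=float(k_b), k_r=float(k_r))
    return FitResult(
        params=params,
        vmax_um_s=float(vmax_um_s),
        vmax_pkat=vmax_pkat,
        rss=float(best.fun),
        converged=True,
        n_starts=n_starts,
        start_objectives=start_objectives,
        best_start=best_start,
        at_boundary=at_boundary,
        seed=seed,
        message="at-boundary estimate" if at_boundary else "",
    )
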