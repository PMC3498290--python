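"""Seeded generators emulating every dataset the pipeline consumes.

Each generator is a pure function of its arguments including the
:class:`SyntheticConfig` seed, so identical configs give bit-identical output.
Substreams are derived from the master seed with
``np.random.SeedSequence(entropy=seed, spawn_key=(stream_id,))`` where
``stream_id`` is a fixed per-generator constant — adding a generator never
perturbs the existing streams.

Defaults are the study's stated conditions: ten substrate levels log-spaced on
1.25–1300 µM with batch constants Km = 1.63 µM and Vmax = 5.5 pKat; a
deactivation course at 0/19/32 h in duplicate with K_D = 1.4 h⁻¹; reactor runs
from S0 = 119 µM with F_AD = 0.34 and a generating reactor Vmax of 19.4 pKat
(through the 250-µm channel's 0.1225 µL geometric volume); the EAG calibration
line y = 1.0658·x + 3.3392 over flows 0.01–2 µL·min⁻¹; wind-tunnel counts with
N = 20; EAG records on 10 antennae × 4 replicates.  The default noise level
for reactor scatter (10% multiplicative) is a stand-in: the study reports
large scatter without a variance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import BEHAVIOR_STEPS, BehaviorTable, EAGRecordSet
from .errors import DomainError
from .fitting import ConversionDataset, DeactivationAssay
from .kinetics import KineticParameters, VelocityDataset, michaelis_menten_rate
from .reactor import ImmobilizationParameters, ReactorGeometry, rk4_integrate

__all__ = [
    "SyntheticConfig",
    "BATCH_KM_UM",
    "BATCH_VMAX_PKAT",
    "REACTOR_VMAX_PKAT",
    "REFERENCE_KINETICS",
    "REFERENCE_IMMOBILIZATION",
    "REFERENCE_GEOMETRY",
    "S0_UM",
    "CALIBRATION_SLOPE",
    "CALIBRATION_INTERCEPT",
    "gen_batch_velocities",
    "gen_deactivation_course",
    "gen_microreactor_runs",
    "gen_eag_calibration",
    "gen_wind_tunnel_counts",
    "gen_eag_records",
]

# ---- stated experimental world -------------------------------------------------
BATCH_KM_UM = 1.63
BATCH_VMAX_PKAT = 5.5
REACTOR_VMAX_PKAT = 19.4
K_D_PER_H = 1.4
F_AD = 0.34
S0_UM = 119.0
P0_UM = 0.0
CALIBRATION_SLOPE = 1.0658
CALIBRATION_INTERCEPT = 3.3392
CALIBRATION_FLOWS = (0.01, 0.05, 0.1, 0.5, 1.0, 2.0)
WIND_TUNNEL_N = 20

#: 250-µm meandering channel (the 300-µm variant gives 0.147 µL).
REFERENCE_GEOMETRY = ReactorGeometry(
    channel_length_mm=9.8, channel_width_um=250.0, channel_height_um=50.0
)

#: Generating rate-constant split: Km = (k_b + k_r)/k_f = 1.63 µM (batch value,
#: the study prints no separate reactor Km) in a non-stiff, identifiable regime.
REFERENCE_KINETICS = KineticParameters(k_f=2.0, k_b=0.76, k_r=2.5)

#: Lumped enzyme load chosen so that k_r·E0 equals the printed reactor Vmax
#: through the geometric volume: E0 = 19.4 pKat / (k_r · 0.1225 µL) in µM.
REFERENCE_REACTOR_E0_UM = REACTOR_VMAX_PKAT / (
    REFERENCE_KINETICS.k_r * REFERENCE_GEOMETRY.volume_ul
)

REFERENCE_IMMOBILIZATION = ImmobilizationParameters(
    f_ad=F_AD, k_d=K_D_PER_H, e0=REFERENCE_REACTOR_E0_UM
)

#: Default synthetic residence times (s).  With the stated Vmax and volume the
#: model saturates on the seconds scale, so the grid spans partial to
#: near-complete conversion.
DEFAULT_TAU_LEVELS = tuple(np.geomspace(0.05, 1.5, 8))

#: Wind-tunnel marginal response probabilities per treatment (printed values
#: where available; the females' source-contact probability is a stand-in).
DEFAULT_BEHAVIOR_PROBS = {
    "evaporator_pheromone": (0.97, 0.90, 0.73, 0.0),
    "virgin_females": (1.00, 0.85, 0.85, 0.70),
    "blank": (0.20, 0.0, 0.0, 0.0),
}

DEFAULT_EAG_MEAN_PCT = {"pheromone": 40.0, "blank": 5.0}
DEFAULT_EAG_SD_PCT = {"pheromone": 5.0, "blank": 2.0}

# fixed substream ids (never renumber; append only)
_STREAM_BATCH = 1
_STREAM_DEACTIVATION = 2
_STREAM_REACTOR = 3
_STREAM_CALIBRATION = 4
_STREAM_WIND_TUNNEL = 5
_STREAM_EAG = 6

NOISE_MODELS = ("none", "gaussian-multiplicative", "gaussian-additive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Seed and noise model shared by all generators."""

    seed: int = 0
    noise: str = "none"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.noise not in NOISE_MODELS:
            raise DomainError(f"noise must be one of {NOISE_MODELS}, got {self.noise!r}")
        if self.sigma < 0:
            raise DomainError(f"sigma must be non-negative, got {self.sigma}")


def _rng(config: SyntheticConfig, stream_id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream_id,))
    )


def _apply_noise(values: np.ndarray, config: SyntheticConfig, rng) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if config.noise == "none" or config.sigma == 0.0:
        return values.copy()
    z = rng.standard_normal(values.shape)
    if config.noise == "gaussian-multiplicative":
        return values * (1.0 + config.sigma * z)
    return values + config.sigma * z


def default_substrate_levels(n: int = 10) -> np.ndarray:
    """Ten log-spaced substrate concentrations on 1.25–1300 µM."""
    return np.geomspace(1.25, 1300.0, n)


def gen_batch_velocities(
    km: float = BATCH_KM_UM,
    vmax: float = BATCH_VMAX_PKAT,
    substrate_levels=None,
    config: SyntheticConfig = SyntheticConfig(),
) -> VelocityDataset:
    """Michaelis–Menten batch velocities (pKat) at the assay substrate levels."""
    levels = (
        default_substrate_levels()
        if substrate_levels is None
        else np.asarray(substrate_levels, dtype=float)
    )
    if np.any(levels <= 0):
        raise DomainError("substrate levels must be strictly positive")
    params = KineticParameters(km=km, vmax=vmax, vmax_unit="pKat")
    v = michaelis_menten_rate(levels, params)
    v = np.clip(_apply_noise(v, config, _rng(config, _STREAM_BATCH)), 0.0, None)
    return VelocityDataset(levels, v, velocity_unit="pKat")


def gen_deactivation_course(
    e0: float = 1.0,
    k_d: float = K_D_PER_H,
    times=(0.0, 19.0, 32.0),
    replicates: int = 2,
    config: SyntheticConfig = SyntheticConfig(),
) -> DeactivationAssay:
    """Exponential activity decay sampled in replicate at the assay times."""
    times = np.asarray(times, dtype=float)
    rng = _rng(config, _STREAM_DEACTIVATION)
    t_col = np.repeat(times, replicates)
    rep_col = np.tile(np.arange(1, replicates + 1), len(times))
    activity = e0 * np.exp(-k_d * t_col)
    activity = np.clip(_apply_noise(activity, config, rng), 0.0, None)
    return DeactivationAssay(t_col, rep_col, activity)


def gen_microreactor_runs(
    params: KineticParameters = REFERENCE_KINETICS,
    immo: ImmobilizationParameters = REFERENCE_IMMOBILIZATION,
    s0: float = S0_UM,
    tau_levels=None,
    config: SyntheticConfig = SyntheticConfig(),
    n_reactors: int = 2,
    enzyme_age_h: float = 0.0,
    p0: float = P0_UM,
) -> ConversionDataset:
    """(τ, S, P) rows from the RK4 forward model, one block per reactor.

    All reactors share the model (equal enzyme loads); noise is drawn
    independently per reactor block.
    """
    taus = np.sort(
        np.asarray(DEFAULT_TAU_LEVELS if tau_levels is None else tau_levels, dtype=float)
    )
    if np.any(taus <= 0):
        raise DomainError("tau levels must be strictly positive")
    from .reactor import enzyme_activity  # local import avoids cycle at module load

    e_active = enzyme_activity(enzyme_age_h, immo)

    def f(_tau, y):
        s, es, _p = y
        e_free = max(e_active - es, 0.0)
        binding = params.k_f * e_free * s
        return (
            -binding + params.k_b * es,
            binding - (params.k_b + params.k_r) * es,
            (1.0 - immo.f_ad) * params.k_r * es,
        )

    grid = np.concatenate([[0.0], taus])
    ys = rk4_integrate(f, (s0, 0.0, p0), grid, max_dtau=taus[-1] / 2000.0)
    s_true, p_true = ys[1:, 0], ys[1:, 2]

    rng = _rng(config, _STREAM_REACTOR)
    tau_col, s_col, p_col, id_col = [], [], [], []
    for r in range(1, n_reactors + 1):
        tau_col.append(taus)
        s_col.append(np.clip(_apply_noise(s_true, config, rng), 0.0, None))
        p_col.append(np.clip(_apply_noise(p_true, config, rng), 0.0, None))
        id_col.append(np.full(len(taus), r))
    return ConversionDataset(
        tau_s=np.concatenate(tau_col),
        s_um=np.concatenate(s_col),
        p_um=np.concatenate(p_col),
        reactor_id=np.concatenate(id_col),
        s0=s0,
    )


def gen_eag_calibration(
    slope: float = CALIBRATION_SLOPE,
    intercept: float = CALIBRATION_INTERCEPT,
    flows=CALIBRATION_FLOWS,
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected EAG responses on the calibration line (+ optional noise)."""
    flows = np.asarray(flows, dtype=float)
    responses = slope * flows + intercept
    responses = _apply_noise(responses, config, _rng(config, _STREAM_CALIBRATION))
    return flows, responses


def gen_wind_tunnel_counts(
    probabilities: dict[str, tuple] | None = None,
    n: int = WIND_TUNNEL_N,
    config: SyntheticConfig = SyntheticConfig(),
) -> BehaviorTable:
    """Binomial behavioral counts with the nested-step structure enforced.

    Marginal probabilities (non-increasing along the behavior sequence) are
    converted to conditional continuation probabilities and each insect is
    simulated as a Markov chain, so a responder at step k responded at every
    earlier step by construction.
    """
    probs = DEFAULT_BEHAVIOR_PROBS if probabilities is None else probabilities
    if n <= 0:
        raise DomainError("n must be positive")
    rng = _rng(config, _STREAM_WIND_TUNNEL)
    treatments = list(probs)
    counts = np.zeros((len(treatments), len(BEHAVIOR_STEPS)), dtype=int)
    for i, t in enumerate(treatments):
        p = np.asarray(probs[t], dtype=float)
        if len(p) != len(BEHAVIOR_STEPS):
            raise DomainError(f"{t!r}: need {len(BEHAVIOR_STEPS)} step probabilities")
        if np.any(p < 0) or np.any(p > 1) or np.any(np.diff(p) > 0):
            raise DomainError(f"{t!r}: probabilities must be in [0,1] and non-increasing")
        alive = n
        prev = 1.0
        for j, pj in enumerate(p):
            cond = pj / prev if prev > 0 else 0.0
            alive = rng.binomial(alive, min(cond, 1.0))
            counts[i, j] = alive
            prev = pj
            if alive == 0:
                break
    return BehaviorTable(treatments, list(BEHAVIOR_STEPS), counts, np.full(len(treatments), n))


def gen_eag_records(
    mean_pct: dict[str, float] | None = None,
    sd_pct: dict[str, float] | None = None,
    n_antennae: int = 10,
    n_replicates: int = 4,
    config: SyntheticConfig = SyntheticConfig(),
    standard_mv: float = 1.0,
) -> EAGRecordSet:
    """EAG records with per-antenna random effects.

    Each antenna draws a session standard response (~N(standard_mv, 5%²),
    positive) and, per treatment, an antenna-level normalized mean
    ~N(mean, (0.8·sd)²); replicates add within-antenna noise with sd 1.2·sd,
    so antenna-level replicate means have sd ≈ the requested value (for 4
    replicates).  Raw depolarizations are standard × pct/100, floored at 0.
    """
    means = DEFAULT_EAG_MEAN_PCT if mean_pct is None else mean_pct
    sds = DEFAULT_EAG_SD_PCT if sd_pct is None else sd_pct
    if set(means) != set(sds):
        raise DomainError("mean_pct and sd_pct must cover the same treatments")
    if n_replicates > 4:
        raise DomainError("at most 4 replicates per antenna")
    rng = _rng(config, _STREAM_EAG)
    import pandas as pd

    rows = []
    for antenna in range(1, n_antennae + 1):
        std = abs(rng.normal(standard_mv, 0.05 * standard_mv)) or standard_mv
        for treatment, mu in means.items():
            sd = sds[treatment]
            antenna_mean = rng.normal(mu, 0.8 * sd)
            for rep in range(1, n_replicates + 1):
                pct = antenna_mean + rng.normal(0.0, 1.2 * sd)
                raw = max(std * pct / 100.0, 0.0)
                rows.append((antenna, rep, treatment, raw, std))
    df = pd.DataFrame(
        rows, columns=["antenna", "replicate", "treatment", "raw_mv", "standard_mv"]
    )
    return EAGRecordSet(df)
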