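"""Synthetic cohorts with the statistical structure the analysis assumes.

Each simulated participant is a hyperbolic discounter: the subjective value
of a delayed outcome is V = A / (1 + k D) with rate k (1/h).  Sexual
discounting rates are log-normal per scenario x partner condition; a
fraction of agents are extreme responders who answer the visual analog
scale at 0 (always immediate unprotected sex) or 100 (always wait for the
condom) at every delay, producing the point masses at both ends of the AUC
distribution that real cohorts show.  Questionnaire totals, image counts
and the monetary discounting rate are tied to the sexual-discounting
propensity through a Gaussian copula whose implied Spearman correlations
match configurable targets.

Extreme-responder status is assigned by thresholding the latent propensity
at its upper p_floor / lower p_ceiling tails.  Marginally this is a plain
mixture with those weights, but the coupling keeps AUC monotone in the
latent, so the rank correlations with the other measures survive the
mixture instead of being diluted by an independent coin flip.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .cohort import (
    DELAYED_AMOUNT,
    SCENARIOS,
    CohortTable,
    all_columns,
    ddt_columns,
    sdt_columns,
)
from .curves import (
    DDT_SCHEDULE,
    SDT_SCHEDULE,
    SEXUAL_CONDITIONS,
    DelaySchedule,
    IndifferenceCurve,
    hyperbolic_value,
)

__all__ = [
    "TRAITS",
    "TitrationConfig",
    "DemographicsConfig",
    "SimulationConfig",
    "Agent",
    "default_config",
    "null_config",
    "sample_agent",
    "simulate_sdt_response",
    "simulate_ddt_titration",
    "generate_cohort",
    "spearman_to_pearson",
    "pearson_to_spearman",
]

# Traits coupled to the sexual-discounting propensity.  "monetary" is the
# latent behind the monetary discounting rate; the rest map to instrument
# totals / the image count through their range quantile functions.
TRAITS = ("monetary", "hrbs", "ztpi", "sss", "cfc", "image_count")


def spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation of a bivariate normal with Spearman rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def pearson_to_spearman(rho_p: float) -> float:
    return (6.0 / math.pi) * math.asin(rho_p / 2.0)


@dataclass(frozen=True)
class TitrationConfig:
    """Adjusting-amount ladder for the monetary task.

    The immediate offer starts at half the delayed amount; the adjustment
    halves after every choice.  ``temperature`` > 0 adds logistic choice
    noise on the dollar scale (0 = deterministic value comparison).
    """

    n_trials: int = 8
    start_offer: float = 500.0
    start_step: float = 250.0
    temperature: float = 0.0

    @property
    def final_step(self) -> float:
        return self.start_step / 2 ** (self.n_trials - 1)


@dataclass(frozen=True)
class DemographicsConfig:
    """Marginal distributions for the demographic columns.

    Ages, incomes and days-since-last-encounter are log-normal,
    parameterized by their median and log-scale sigma so that printed
    medians/IQRs are easy to match; household size is 1 + Poisson.
    """

    p_female: float = 0.44
    age_median: float = 30.0
    age_sigma: float = 0.29
    age_min: int = 18
    age_max: int = 80
    days_since_median: float = 6.0
    days_since_sigma: float = 1.80
    household_poisson_mean: float = 1.6
    income_median: float = 37_000.0
    income_sigma: float = 0.77
    p_employed: float = 0.75
    p_some_college: float = 0.90
    p_single: float = 0.43
    p_married: float = 0.35


# Scenario effects on log k (sexual conditions).  Lower log k = shallower
# discounting = higher AUC.  The shipped preset mirrors the qualitative
# pattern the task is sensitive to: the regret scenario lowers discounting
# most in the most-attractive and least-STI partner conditions; both
# negative scenarios lower discounting in the least-attractive and most-STI
# conditions; the monetary task is unaffected by scenario.
DEFAULT_SCENARIO_SHIFTS: dict[str, dict[str, float]] = {
    "positive": {c: 0.0 for c in SEXUAL_CONDITIONS},
    "negative": {
        "least_attractive": -1.0,
        "most_attractive": -0.5,
        "least_sti": -0.5,
        "most_sti": -0.85,
    },
    "negative_regret": {
        "least_attractive": -1.15,
        "most_attractive": -1.35,
        "least_sti": -1.15,
        "most_sti": -0.9,
    },
}

BASE_MU_LOG_K = -5.0  # log(1/h); median half-value delay ~ 6 days
BASE_MU_LOG_K_MONEY = -9.5  # money is discounted far more shallowly

DEFAULT_COPULA_TARGETS: dict[str, float] = {
    "monetary": 0.04,
    "hrbs": -0.15,
    "ztpi": 0.08,
    "sss": -0.14,
    "cfc": -0.20,
    "image_count": -0.20,
}


@dataclass
class SimulationConfig:
    """All generator parameters; fully determines a cohort given the seed."""

    n_per_scenario: dict[str, int] = field(
        default_factory=lambda: {"positive": 136, "negative": 137, "negative_regret": 135}
    )
    mu_log_k: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            s: {c: BASE_MU_LOG_K + DEFAULT_SCENARIO_SHIFTS[s][c] for c in SEXUAL_CONDITIONS}
            for s in SCENARIOS
        }
    )
    sigma_log_k: float = 2.0
    sigma_log_k_cond: float = 0.3  # condition-specific jitter on log k
    p_floor: float = 0.20
    p_ceiling: float = 0.15
    sigma_vas: float = 4.0  # VAS noise, 0-100 scale
    mu_log_k_money: dict[str, float] = field(
        default_factory=lambda: {s: BASE_MU_LOG_K_MONEY for s in SCENARIOS}
    )
    sigma_log_k_money: float = 1.2
    male_log_k_shift: float = 0.8  # males discount sex more steeply
    copula_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COPULA_TARGETS)
    )
    demographics: DemographicsConfig = field(default_factory=DemographicsConfig)
    titration: TitrationConfig = field(default_factory=TitrationConfig)
    discount_model: str = "hyperbolic"
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_per_scenario) != set(SCENARIOS):
            raise ValueError(f"n_per_scenario must cover {SCENARIOS}")
        if self.p_floor < 0 or self.p_ceiling < 0 or self.p_floor + self.p_ceiling > 1:
            raise ValueError("mixture weights must be >= 0 with p_floor + p_ceiling <= 1")
        if self.discount_model not in ("hyperbolic", "exponential"):
            raise ValueError(f"unknown discount model {self.discount_model!r}")
        unknown = set(self.copula_targets) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown copula targets: {sorted(unknown)}")
        bad = {t: v for t, v in self.copula_targets.items() if not -1 < v < 1}
        if bad:
            raise ValueError(f"copula targets must lie in (-1, 1): {bad}")
        _latent_correlations(self.copula_targets)  # raises if not positive definite

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "demographics" in d and isinstance(d["demographics"], dict):
            d["demographics"] = DemographicsConfig(**d["demographics"])
        if "titration" in d and isinstance(d["titration"], dict):
            d["titration"] = TitrationConfig(**d["titration"])
        return cls(**d)


def default_config(seed: int = 0, n_per_scenario: int | dict[str, int] | None = None) -> SimulationConfig:
    """The shipped effect-size preset (scenario + gender effects active)."""
    cfg = SimulationConfig(seed=seed)
    if n_per_scenario is not None:
        if isinstance(n_per_scenario, int):
            n_per_scenario = {s: n_per_scenario for s in SCENARIOS}
        cfg = replace(cfg, n_per_scenario=dict(n_per_scenario))
    return cfg


def null_config(seed: int = 0, n_per_scenario: int | dict[str, int] | None = None) -> SimulationConfig:
    """Same marginals, but no scenario effect anywhere (for calibration runs)."""
    cfg = default_config(seed=seed, n_per_scenario=n_per_scenario)
    flat = {s: {c: BASE_MU_LOG_K for c in SEXUAL_CONDITIONS} for s in SCENARIOS}
    return replace(cfg, mu_log_k=flat)


def _trait_spearman_with_propensity(targets: dict[str, float]) -> dict[str, float]:
    """Desired Spearman between each trait latent and the propensity z.

    Sexual AUC is a decreasing function of the propensity, so a target
    correlation between AUC and an increasing trait flips sign on the
    latent scale.  Monetary AUC is itself decreasing in its latent, so the
    two flips cancel.
    """
    out = {}
    for trait, target in targets.items():
        out[trait] = target if trait == "monetary" else -target
    return out


def _latent_correlations(targets: dict[str, float]) -> dict[str, float]:
    """Latent Pearson loadings of each trait on the propensity factor.

    Traits are conditionally independent given the propensity (one-factor
    structure), so the implied full correlation matrix is positive
    semi-definite whenever every loading is inside (-1, 1); the check is
    still performed explicitly and names offenders.
    """
    spearman_targets = _trait_spearman_with_propensity(targets)
    loadings = {t: spearman_to_pearson(r) for t, r in spearman_targets.items()}
    traits = list(loadings)
    r = np.array([loadings[t] for t in traits])
    corr = np.outer(r, r)
    np.fill_diagonal(corr, 1.0)
    full = np.block([[np.ones((1, 1)), r[None, :]], [r[:, None], corr]])
    eigvals = np.linalg.eigvalsh(full)
    if eigvals.min() < -1e-10:
        offenders = [t for t in traits if abs(loadings[t]) >= 1]
        raise ValueError(
            "copula targets imply a non-positive-definite correlation matrix; "
            f"offending targets: {offenders or traits}"
        )
    return loadings


@dataclass(frozen=True)
class Agent:
    """One simulated participant's latent state."""

    participant_id: str
    scenario: str
    gender: str
    age: int
    k_sex: dict[str, float]  # per sexual condition, 1/h
    k_money: float  # 1/h
    latent_traits: dict[str, float]
    is_floor: bool = False  # always-immediate responder (sexual AUC = 0)
    is_ceiling: bool = False  # always-delayed responder (sexual AUC = 1)

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.k_sex.values()) or self.k_money <= 0:
            raise ValueError("discount rates must be > 0")


def _delayed_value(amount: float, k, delays, model: str) -> np.ndarray:
    if model == "exponential":
        k = np.asarray(k, dtype=float)
        return amount * np.exp(-k * np.asarray(delays, dtype=float))
    return hyperbolic_value(amount, k, delays)


def _sample_latents(n: int, targets: dict[str, float], rng: np.random.Generator):
    """Propensity z plus one-factor-coupled trait latents, all standard normal."""
    loadings = _latent_correlations(targets)
    z = rng.standard_normal((n, 1 + len(TRAITS)))
    z_sex = z[:, 0]
    traits = {}
    for i, trait in enumerate(TRAITS):
        r = loadings.get(trait, 0.0)
        traits[trait] = r * z_sex + math.sqrt(1.0 - r * r) * z[:, i + 1]
    return z_sex, traits


def _titrate(k_money: np.ndarray, cfg: TitrationConfig, rng: np.random.Generator,
             model: str = "hyperbolic") -> np.ndarray:
    """Vectorized adjusting-amount ladder; returns final offers (n, 6) in dollars."""
    delays = np.asarray(DDT_SCHEDULE.durations)
    value = _delayed_value(DELAYED_AMOUNT, k_money[:, None], delays[None, :], model)
    offer = np.full_like(value, cfg.start_offer)
    step = cfg.start_step
    for _ in range(cfg.n_trials):
        if cfg.temperature > 0:
            p_imm = expit((offer - value) / cfg.temperature)
            immediate = rng.random(offer.shape) < p_imm
        else:
            immediate = offer > value
        offer = np.where(immediate, offer - step, offer + step)
        step /= 2.0
    return offer


def _quantile_scores(u: np.ndarray, n_levels: int, low: float, step: float) -> np.ndarray:
    """Map uniforms to n_levels equally likely ordered levels from low."""
    idx = np.minimum((u * n_levels).astype(int), n_levels - 1)
    return low + idx * step


def _sample_block(config: SimulationConfig, scenario: str, n: int,
                  rng: np.random.Generator, id_start: int) -> pd.DataFrame:
    demo = config.demographics
    z_sex, traits = _sample_latents(n, config.copula_targets, rng)
    u_sex = ndtr(z_sex)
    is_floor = u_sex >= 1.0 - config.p_floor  # steepest-discounting tail
    is_ceiling = u_sex < config.p_ceiling

    female = rng.random(n) < demo.p_female
    male_shift = np.where(female, 0.0, config.male_log_k_shift)

    data: dict[str, np.ndarray | list] = {}
    data["participant_id"] = [f"P{id_start + i:04d}" for i in range(n)]
    data["scenario"] = [scenario] * n
    data["gender"] = np.where(female, "female", "male")

    sdt_delays = np.asarray(SDT_SCHEDULE.durations)
    for cond in SEXUAL_CONDITIONS:
        log_k = (
            config.mu_log_k[scenario][cond]
            + config.sigma_log_k * z_sex
            + male_shift
            + config.sigma_log_k_cond * rng.standard_normal(n)
        )
        k = np.exp(log_k)
        vas = _delayed_value(100.0, k[:, None], sdt_delays[None, :], config.discount_model)
        vas = vas + rng.normal(0.0, config.sigma_vas, size=vas.shape) if config.sigma_vas > 0 else vas
        vas = np.clip(vas, 0.0, 100.0)
        vas[is_floor] = 0.0
        vas[is_ceiling] = 100.0
        for j, col in enumerate(sdt_columns(cond)):
            data[col] = vas[:, j]

    k_money = np.exp(
        config.mu_log_k_money[scenario] + config.sigma_log_k_money * traits["monetary"]
    )
    offers = _titrate(k_money, config.titration, rng, config.discount_model)
    for j, col in enumerate(ddt_columns()):
        data[col] = offers[:, j]

    u = {t: ndtr(traits[t]) for t in TRAITS}
    data["hrbs_score"] = _quantile_scores(u["hrbs"], 56, 0.0, 1.0)
    data["ztpi_score"] = 1.0 + np.round(u["ztpi"] * 48.0) / 12.0
    data["sss_score"] = _quantile_scores(u["sss"], 85, 21.0, 1.0)
    data["cfc_score"] = 1.0 + np.round(u["cfc"] * 48.0) / 12.0
    data["image_count"] = _quantile_scores(u["image_count"], 19, 2.0, 1.0).astype(int)

    age = np.round(demo.age_median * np.exp(demo.age_sigma * rng.standard_normal(n)))
    data["age"] = np.clip(age, demo.age_min, demo.age_max).astype(int)
    days = np.round(demo.days_since_median * np.exp(demo.days_since_sigma * rng.standard_normal(n)))
    data["days_since_last_encounter"] = np.clip(days, 0, 3650).astype(int)
    data["household_size"] = 1 + np.minimum(rng.poisson(demo.household_poisson_mean, n), 11)
    income = np.round(demo.income_median * np.exp(demo.income_sigma * rng.standard_normal(n)))
    data["income_usd"] = income.astype(int)
    data["education"] = np.where(
        rng.random(n) < demo.p_some_college, "some_college_or_more", "high_school_or_less"
    )
    marital_u = rng.random(n)
    marital = np.where(
        marital_u < demo.p_single,
        "single",
        np.where(marital_u < demo.p_single + demo.p_married, "married", "other"),
    )
    data["marital_status"] = marital
    data["employed"] = rng.random(n) < demo.p_employed

    return pd.DataFrame(data)[all_columns()]


def generate_cohort(
    config: SimulationConfig,
    out_csv=None,
    sidecar_json=None,
) -> CohortTable:
    """Generate a full cohort; byte-identical output for identical config+seed.

    Optionally writes the canonical cohort CSV and a JSON sidecar holding
    the complete configuration (including the seed).
    """
    rng = np.random.default_rng(config.seed)
    blocks = []
    id_start = 0
    for scenario in SCENARIOS:
        n = config.n_per_scenario[scenario]
        blocks.append(_sample_block(config, scenario, n, rng, id_start))
        id_start += n
    df = pd.concat(blocks, ignore_index=True)
    cohort = CohortTable(df)
    if out_csv is not None:
        cohort.write_csv(out_csv)
    if sidecar_json is not None:
        with open(sidecar_json, "w", encoding="utf-8") as fh:
            json.dump(config.to_dict(), fh, indent=2, default=str)
    return cohort


# ---------------------------------------------------------------------------
# per-agent operations (single-participant views of the same model)


def sample_agent(config: SimulationConfig, scenario: str, rng: np.random.Generator) -> Agent:
    """Draw a single agent's latent state for one scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    demo = config.demographics
    z_sex, traits = _sample_latents(1, config.copula_targets, rng)
    z_sex = float(z_sex[0])
    u_sex = float(ndtr(z_sex))
    female = rng.random() < demo.p_female
    male_shift = 0.0 if female else config.male_log_k_shift
    k_sex = {}
    for cond in SEXUAL_CONDITIONS:
        log_k = (
            config.mu_log_k[scenario][cond]
            + config.sigma_log_k * z_sex
            + male_shift
            + config.sigma_log_k_cond * float(rng.standard_normal())
        )
        k_sex[cond] = float(np.exp(log_k))
    k_money = float(
        np.exp(config.mu_log_k_money[scenario] + config.sigma_log_k_money * traits["monetary"][0])
    )
    age = int(np.clip(round(demo.age_median * math.exp(demo.age_sigma * float(rng.standard_normal()))),
                      demo.age_min, demo.age_max))
    return Agent(
        participant_id="A0000",
        scenario=scenario,
        gender="female" if female else "male",
        age=age,
        k_sex=k_sex,
        k_money=k_money,
        latent_traits={t: float(traits[t][0]) for t in TRAITS},
        is_floor=u_sex >= 1.0 - config.p_floor,
        is_ceiling=u_sex < config.p_ceiling,
    )


def simulate_sdt_response(
    agent: Agent,
    condition: str,
    schedule: DelaySchedule = SDT_SCHEDULE,
    rng: np.random.Generator | None = None,
    sigma_vas: float = 0.0,
    model: str = "hyperbolic",
) -> IndifferenceCurve:
    """One agent's VAS curve for one partner condition, as proportions."""
    if condition not in SEXUAL_CONDITIONS:
        raise ValueError(f"unknown sexual condition {condition!r}")
    delays = np.asarray(schedule.durations)
    if agent.is_floor:
        vas = np.zeros(len(delays))
    elif agent.is_ceiling:
        vas = np.full(len(delays), 100.0)
    else:
        vas = _delayed_value(100.0, agent.k_sex[condition], delays, model)
        if sigma_vas > 0:
            if rng is None:
                raise ValueError("rng required when sigma_vas > 0")
            vas = vas + rng.normal(0.0, sigma_vas, size=vas.shape)
        vas = np.clip(vas, 0.0, 100.0)
    return IndifferenceCurve(
        agent.participant_id, "sexual", condition, schedule, tuple(vas / 100.0)
    )


def simulate_ddt_titration(
    agent: Agent,
    delay_hours: float,
    titration: TitrationConfig = TitrationConfig(),
    rng: np.random.Generator | None = None,
    model: str = "hyperbolic",
) -> float:
    """Run the adjusting-amount ladder at one delay; returns offer / $1000."""
    if titration.temperature > 0 and rng is None:
        raise ValueError("rng required when temperature > 0")
    value = float(_delayed_value(DELAYED_AMOUNT, agent.k_money, delay_hours, model))
    offer = titration.start_offer
    step = titration.start_step
    for _ in range(titration.n_trials):
        if titration.temperature > 0:
            immediate = rng.random() < expit((offer - value) / titration.temperature)
        else:
            immediate = offer > value
        offer = offer - step if immediate else offer + step
        step /= 2.0
    return offer / DELAYED_AMOUNT
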