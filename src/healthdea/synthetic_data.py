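"""Seeded synthetic panels with a known production frontier and ground truth.

No machine-readable source exists for the provincial yearbook panel the
analysis was designed around, so every pipeline stage is exercised on
generated data whose truth is known.  The generator emulates that panel's
structure: 19 DMUs (cities) observed over 9 consecutive years, three
strictly positive inputs (health technicians, beds, total expenditure), two
outputs (total visits, discharges) and five covariates (per-capita GDP,
average annual income, urbanization rate, population density, education),
with heavy right skew across DMUs and steady year-on-year growth.

The world model:

* city sizes are log-normal (one common size factor per DMU plus small
  per-input jitter), giving the right-skewed cross-sections seen in real
  provincial data;
* the frontier is Cobb-Douglas, y_c = w_c * A_t * prod_a x_a^{alpha_a},
  split across outputs by fixed share weights; with sum(alpha)=1 the
  frontier surface is a convex cone, so DMUs placed on it are SBM-efficient
  under both CRS and VRS;
* technology is Hicks-neutral, A_t = A_0 * g^t, so the Malmquist TECHCH of
  every DMU recovers g exactly when relative positions are static;
* inefficiency is u = softplus(gamma . z + offset + noise) >= 0 for
  non-frontier DMUs (u = 0 on the frontier), and realized outputs are
  frontier * exp(-u), linking covariates to measured efficiency;
* an optional one-period shock multiplies the first output by
  shock_factor^{e_i} with per-DMU exposures e_i ~ U(0, 2).  The exposure
  heterogeneity is deliberate: a uniform rescaling of one output column is a
  unit change that per-period efficiency scores are invariant to, whereas a
  disaster hits cities unevenly and visibly depresses the period's mean
  score.

One root seed drives everything through named substreams spawned in a fixed
documented order (sizes, input jitter, covariates, inefficiency noise, shock
exposure), so adding a component never silently shifts existing draws and
identical seeds give byte-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel_io import PanelDataset, PanelSchema

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "TobitGroundTruth",
    "generate_panel",
    "generate_tobit_data",
    "default_schema",
]

_INPUT_NAMES = ("health_technicians", "beds", "total_expenditure")
_OUTPUT_NAMES = ("total_visits", "discharges")
_COVARIATE_NAMES = (
    "pgdp",
    "avg_annual_income",
    "urbanization_rate",
    "population_density",
    "education",
)

# cross-DMU location/scale used to place covariates on plausible raw scales
_COV_LOC = np.array([35000.0, 28000.0, 45.0, 250.0, 9000.0])
_COV_SCALE = np.array([12000.0, 6000.0, 10.0, 150.0, 4000.0])


def default_schema() -> PanelSchema:
    return PanelSchema(
        input_names=_INPUT_NAMES,
        output_names=_OUTPUT_NAMES,
        covariate_names=_COVARIATE_NAMES,
        dmu_column="city",
        period_column="year",
        units={
            "health_technicians": "person",
            "beds": "bed",
            "total_expenditure": "10k yuan",
            "total_visits": "person-time",
            "discharges": "person",
            "pgdp": "yuan",
            "avg_annual_income": "yuan",
            "urbanization_rate": "%",
            "population_density": "person/sq.km",
            "education": "person",
        },
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of the synthetic frontier world.

    Defaults emulate the 19-city x 2010-2018 provincial panel: input base
    levels and per-input growth follow that panel's first-year means and
    observed 8-year growth, cross-DMU dispersion is log-normal with sd 0.9
    (coefficient of variation just above 1, matching the printed descriptive
    statistics), and roughly 45% of cities sit on the frontier, as in the
    printed score table's first year.
    """

    n_dmus: int = 19
    periods: int = 9
    start_period: int = 2010
    m: int = 3
    s: int = 2
    frontier_exponents: tuple[float, ...] = (0.40, 0.35, 0.25)  # sum 1 => CRS cone
    output_shares: tuple[float, ...] = (0.97, 0.03)
    base_tech_level: float = 560.0
    tech_growth: float = 0.95  # Hicks-neutral frontier factor per period
    input_base_scales: tuple[float, ...] = (16157.0, 15093.0, 303932.0)
    input_scale_logsd: float = 0.9
    input_growth: tuple[float, ...] | float = (1.071, 1.089, 1.171)
    covariate_growth: float = 1.05
    covariate_correlation: float = 0.4
    inefficiency_coefs: tuple[float, ...] = (0.0, -0.15, 0.0, -0.20, -0.15)
    inefficiency_offset: float = -1.0
    inefficiency_noise_sd: float = 0.3
    frontier_fraction: float = 0.45
    shock_period: int | None = None
    shock_factor: float = 0.6
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_dmus < 1 or self.periods < 1:
            raise ValueError("n_dmus and periods must be positive")
        if len(self.frontier_exponents) != self.m or any(a <= 0 for a in self.frontier_exponents):
            raise ValueError("frontier_exponents must be m strictly positive reals")
        if len(self.output_shares) != self.s or any(w <= 0 for w in self.output_shares):
            raise ValueError("output_shares must be s strictly positive reals")
        if self.input_scale_logsd <= 0 or self.inefficiency_noise_sd < 0:
            raise ValueError("scale/sd parameters must be positive")
        if not 0.0 <= self.frontier_fraction <= 1.0:
            raise ValueError("frontier_fraction must lie in [0, 1]")
        if not 0.0 < self.shock_factor <= 1.0:
            raise ValueError("shock_factor must lie in (0, 1]")
        if len(self.input_base_scales) != self.m:
            raise ValueError("input_base_scales must have one entry per input")
        growth = self.input_growth
        if np.ndim(growth) and len(np.atleast_1d(growth)) != self.m:
            raise ValueError("input_growth must be a scalar or one factor per input")

    @property
    def rts_sum(self) -> float:
        return float(sum(self.frontier_exponents))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows that the estimators must recover."""

    inefficiency: np.ndarray  # (n, T) true u >= 0
    frontier: np.ndarray  # (n,) bool, u == 0 in every period
    gamma: np.ndarray  # (p,) covariate -> inefficiency coefficients
    tech_level: np.ndarray  # (T,) A_t
    shock_exposure: np.ndarray | None  # (n,) e_i if a shock was applied


def _softplus(v: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, v)


def generate_panel(config: GeneratorConfig = GeneratorConfig()) -> tuple[PanelDataset, GroundTruth]:
    """Generate one balanced panel plus its ground truth."""
    cfg = config
    n, T, m, s = cfg.n_dmus, cfg.periods, cfg.m, cfg.s
    p = len(cfg.inefficiency_coefs)

    # fixed substream order: sizes, input jitter, covariates, noise, shock
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_size = np.random.default_rng(streams[0])
    rng_jit = np.random.default_rng(streams[1])
    rng_cov = np.random.default_rng(streams[2])
    rng_noise = np.random.default_rng(streams[3])
    rng_shock = np.random.default_rng(streams[4])

    alpha = np.asarray(cfg.frontier_exponents)
    shares = np.asarray(cfg.output_shares)
    base = np.asarray(cfg.input_base_scales, dtype=float)
    growth = np.broadcast_to(np.asarray(cfg.input_growth, dtype=float), (m,))

    # inputs: common log-normal size factor per DMU + small per-input jitter;
    # the log-normal mean correction makes base scales cross-DMU *means*
    sd_s, sd_j = cfg.input_scale_logsd, cfg.input_scale_logsd / 4.0
    size = rng_size.normal(0.0, sd_s, size=n)
    jitter = rng_jit.normal(0.0, sd_j, size=(n, m))
    mean_corr = np.exp(-(sd_s**2 + sd_j**2) / 2.0)
    t_idx = np.arange(T)
    X = (
        base[None, None, :]
        * mean_corr
        * np.exp(size[:, None, None] + jitter[:, None, :])
        * (growth[None, None, :] ** t_idx[None, :, None])
    )

    # covariates: correlated standard scores, slow multiplicative drift
    corr = np.full((p, p), cfg.covariate_correlation)
    np.fill_diagonal(corr, 1.0)
    L = np.linalg.cholesky(corr)
    z = rng_cov.normal(size=(n, p)) @ L.T  # (n, p), static relative positions
    drift = cfg.covariate_growth ** t_idx
    Z = (_COV_LOC[None, None, :] + _COV_SCALE[None, None, :] * z[:, None, :]) * drift[
        None, :, None
    ]

    # inefficiency: zero for frontier DMUs, softplus link otherwise
    n_frontier = int(round(cfg.frontier_fraction * n))
    frontier = np.zeros(n, dtype=bool)
    frontier[:n_frontier] = True  # DMU order is itself a random draw of sizes
    gamma = np.asarray(cfg.inefficiency_coefs)
    noise = rng_noise.normal(0.0, cfg.inefficiency_noise_sd, size=(n, T))
    latent = z @ gamma  # (n,), static covariate mix
    u = _softplus(latent[:, None] + cfg.inefficiency_offset + noise)
    u[frontier] = 0.0

    # frontier outputs and realized outputs
    A = cfg.base_tech_level * cfg.tech_growth ** t_idx  # (T,)
    frontier_total = A[None, :] * np.prod(X ** alpha[None, None, :], axis=2)  # (n, T)
    Y = shares[None, None, :] * frontier_total[:, :, None] * np.exp(-u)[:, :, None]

    exposure = None
    if cfg.shock_period is not None:
        periods = [cfg.start_period + t for t in range(T)]
        if cfg.shock_period not in periods:
            raise ValueError(f"shock_period {cfg.shock_period} outside panel periods")
        tt = periods.index(cfg.shock_period)
        exposure = rng_shock.uniform(0.0, 2.0, size=n)
        Y[:, tt, 0] *= cfg.shock_factor ** exposure

    dmus = tuple(f"city{i + 1:02d}" for i in range(n))
    periods = tuple(cfg.start_period + t for t in range(T))
    schema = default_schema()
    if (m, s, p) != (len(schema.input_names), len(schema.output_names), len(schema.covariate_names)):
        schema = PanelSchema(
            input_names=tuple(f"input{a + 1}" for a in range(m)),
            output_names=tuple(f"output{c + 1}" for c in range(s)),
            covariate_names=tuple(f"cov{j + 1}" for j in range(p)),
            dmu_column="city",
            period_column="year",
        )
    panel = PanelDataset(dmus=dmus, periods=periods, X=X, Y=Y, Z=Z, schema=schema)
    truth = GroundTruth(
        inefficiency=u,
        frontier=frontier,
        gamma=gamma,
        tech_level=A,
        shock_exposure=exposure,
    )
    return panel, truth


@dataclass(frozen=True)
class TobitGroundTruth:
    y_star: np.ndarray
    beta: np.ndarray
    sigma: float
    censored_low: np.ndarray
    censored_high: np.ndarray

    @property
    def censored_fraction(self) -> float:
        return float(np.mean(self.censored_low | self.censored_high))


def generate_tobit_data(
    n: int,
    true_beta,
    sigma: float,
    censor_limits: tuple[float | None, float | None] = (0.0, None),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, TobitGroundTruth]:
    """Latent-Gaussian regression data clipped at the censoring limits.

    Design matrix: intercept column followed by len(beta)-1 standard-normal
    covariates.  Used for exact parameter-recovery tests of the Tobit fitter
    (the panel generator's softplus link is deliberately not the Tobit data
    model, so recovery there is approximate by design).
    """
    beta = np.asarray(true_beta, dtype=float)
    if n <= len(beta) + 2:
        raise ValueError("need n > len(beta) + 2")
    rng = np.random.default_rng(seed)
    X = np.c_[np.ones(n), rng.normal(size=(n, len(beta) - 1))]
    y_star = X @ beta + rng.normal(0.0, sigma, size=n)
    y = y_star.copy()
    lo, hi = censor_limits
    low_mask = np.zeros(n, dtype=bool)
    high_mask = np.zeros(n, dtype=bool)
    if lo is not None:
        low_mask = y_star <= lo
        y[low_mask] = lo
    if hi is not None:
        high_mask = y_star >= hi
        y[high_mask] = hi
    truth = TobitGroundTruth(
        y_star=y_star, beta=beta, sigma=float(sigma), censored_low=low_mask, censored_high=high_mask
    )
    return X, y, truth
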