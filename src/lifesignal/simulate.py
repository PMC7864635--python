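"""Synthetic aging cohorts with lifespan-coupled reporter expression.

The generator emulates the data structure of a longitudinal single-animal
culture experiment: isogenic individuals imaged every few hours from hatch
to death, in several biological replicates, each animal contributing one
expression trajectory per fluorescent reporter plus manually annotated
life-stage times.

Generative model
----------------
Each animal *i* carries a vector of latent "physiological state" variables
``z_i ~ N(0, I)``, one per lifespan-determining process.  Lifespan is a
baseline law (log-normal or Gompertz, parameterized by median and
coefficient of variation) modulated multiplicatively by the latent state::

    T_i = T0_i * exp(sum_p c_p * z_ip)

so the latent coupling is additive on the log-lifespan scale and lifespans
stay positive.  The baseline CV is shrunk so the *total* CV matches the
configured value (inbred C. elegans cohorts show lifespan CV of roughly
0.19-0.23; the default is 0.21).

Reporter expression follows a deterministic age template (declining, peaked
or increasing) plus a latent-coupled deviation that switches on at a
configurable age::

    x_i(t) = template(t) + ramp(t) * g_i * (level_loading + slope_loading*t)
             + batch_offset + death_signal(t) + noise

with ``g_i = sum_p w_p z_ip`` the reporter's read-out of the latent state.
``ramp`` rises linearly from 0 to 1 over ``coupling_ramp_h`` hours starting
at ``coupling_onset_age_h`` (default 120 h, i.e. 5 days post-hatch),
reproducing the observation that expression variability exists early in
life but only becomes informative about lifespan from mid-adulthood on.

Because lifespan and the windowed (mean, slope) features are jointly a
linear-Gaussian function of the latent state (exactly so for the features,
log-linearly for lifespan), the *population* coefficient of determination
of any feature set against lifespan has a closed form, implemented in
:func:`population_r2`.  Recovery tests compare the regression engine's
estimates against this analytic ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import Dataset

__all__ = [
    "TemplateSpec",
    "ReporterSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_lifespans",
    "simulate_trajectory",
    "simulate_cohort",
    "population_r2",
    "population_joint_r2",
    "population_pair_semipartials",
    "calibrate_coupling",
    "hierarchy_config",
    "death_probability_by",
]


class ConfigurationError(ValueError):
    """The simulation configuration is internally inconsistent."""


# -- templates -----------------------------------------------------------


@dataclass(frozen=True)
class TemplateSpec:
    """Deterministic age profile of a reporter's population-mean expression.

    Kinds
    -----
    ``declining`` : ``level0 - rate * age`` — linear loss of expression.
    ``increasing`` : ``level0 + rate * age`` — e.g. age-pigment behaviour.
    ``peaked`` : ``baseline + amplitude * (age/t_peak) * exp(1 - age/t_peak)``
        — rises to a young-adult peak at ``t_peak`` then declines.
    ``constant`` : ``level0`` — degenerate profile, used in tests.
    """

    kind: str = "declining"
    level0: float = 1.0
    rate: float = 0.002
    amplitude: float = 1.0
    t_peak: float = 96.0
    baseline: float = 0.2

    def __call__(self, age_h: np.ndarray) -> np.ndarray:
        age_h = np.asarray(age_h, dtype=float)
        if self.kind == "declining":
            return self.level0 - self.rate * age_h
        if self.kind == "increasing":
            return self.level0 + self.rate * age_h
        if self.kind == "peaked":
            ratio = age_h / self.t_peak
            return self.baseline + self.amplitude * ratio * np.exp(1.0 - ratio)
        if self.kind == "constant":
            return np.full_like(age_h, self.level0)
        raise ConfigurationError(f"unknown template kind {self.kind!r}")


@dataclass(frozen=True)
class ReporterSpec:
    """One reporter's template and its read-out of the latent processes.

    ``loadings`` maps process name -> weight; the reporter's latent signal is
    ``g_i = sum_p loadings[p] * z_ip``.  ``level_loading`` (expression units
    per latent unit) and ``slope_loading`` (expression units per hour per
    latent unit) convert the signal into a level and a trend deviation.
    """

    template: TemplateSpec = field(default_factory=TemplateSpec)
    loadings: tuple[tuple[str, float], ...] = (("X", 1.0),)
    level_loading: float = 0.25
    slope_loading: float = 0.002
    noise_sd: float = 0.15

    def loading_vector(self, processes: list[str]) -> np.ndarray:
        d = dict(self.loadings)
        return np.array([d.get(p, 0.0) for p in processes], dtype=float)


# -- configuration -------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario definition for a synthetic cohort.

    Parameters
    ----------
    n_individuals : animals per biological replicate.
    n_replicates : number of biological replicates (batches).
    sampling_interval_h : hours between imaging timepoints (default 4).
    median_lifespan_h : target median lifespan (default 240 h = 10 days).
    lifespan_cv : target total coefficient of variation of lifespan.
    lifespan_family : ``lognormal`` or ``gompertz`` baseline law.
    lifespan_coupling : process -> coefficient on log-lifespan.  The summed
        squared coefficients must leave room inside the total lifespan
        variance implied by ``lifespan_cv``.
    reporters : name -> :class:`ReporterSpec`.
    coupling_onset_age_h, coupling_ramp_h : where the latent state begins to
        influence expression (linear 0->1 ramp).
    coupling_offset_age_h : optional age at which the coupling ramps back
        down to 0, for planting a bounded informative window.
    death_signal_amp, death_signal_lookback_h : optional moribundity term
        ``amp * max(0, 1 - (T_i - t)/lookback)`` added to expression, which
        couples expression to lifespan only through imminent death.
    batch_sd : SD of the per-replicate additive expression offset.
    batch_lifespan_sd : SD (log scale) of the per-replicate multiplicative
        lifespan factor (default 0.05, i.e. about +/-5%).
        Batch effects are deviations between replicates; a single-replicate
        cohort has none.
    seed : mandatory integer; fully determines all outputs.
    """

    n_individuals: int = 100
    n_replicates: int = 1
    sampling_interval_h: float = 4.0
    median_lifespan_h: float = 240.0
    lifespan_cv: float = 0.21
    lifespan_family: str = "lognormal"
    lifespan_coupling: tuple[tuple[str, float], ...] = (("X", 0.125),)
    reporters: tuple[tuple[str, ReporterSpec], ...] = (("gfp", ReporterSpec()),)
    coupling_onset_age_h: float = 120.0
    coupling_ramp_h: float = 24.0
    coupling_offset_age_h: float | None = None
    death_signal_amp: float = 0.0
    death_signal_lookback_h: float = 48.0
    batch_sd: float = 0.0
    batch_lifespan_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.sampling_interval_h <= 0:
            raise ConfigurationError("sampling_interval_h must be > 0")
        if self.median_lifespan_h <= 0:
            raise ConfigurationError("median_lifespan_h must be > 0")
        if self.lifespan_cv <= 0:
            raise ConfigurationError("lifespan_cv must be > 0")
        if self.lifespan_family not in ("lognormal", "gompertz"):
            raise ConfigurationError(f"unknown lifespan_family {self.lifespan_family!r}")
        # total log-variance implied by the CV must accommodate the coupling
        if self.coupling_variance() >= self.total_log_variance() + 1e-12:
            raise ConfigurationError(
                "lifespan_coupling variance exceeds the total lifespan "
                "variance implied by lifespan_cv"
            )

    # -- derived quantities ------------------------------------------

    @property
    def processes(self) -> list[str]:
        names: list[str] = []
        for p, _ in self.lifespan_coupling:
            if p not in names:
                names.append(p)
        for _, spec in self.reporters:
            for p, _ in spec.loadings:
                if p not in names:
                    names.append(p)
        return names

    def coupling_vector(self) -> np.ndarray:
        d = dict(self.lifespan_coupling)
        return np.array([d.get(p, 0.0) for p in self.processes], dtype=float)

    def coupling_variance(self) -> float:
        return float(np.sum(self.coupling_vector() ** 2))

    def total_log_variance(self) -> float:
        """Log-scale variance a pure log-normal with this CV would have."""
        return math.log1p(self.lifespan_cv**2)

    def base_cv(self) -> float:
        """Baseline-law CV after removing the latent-coupling variance.

        Solved from ``(1 + cv_total^2) = (1 + cv_base^2) * exp(V_coupling)``,
        which holds exactly for independent multiplicative modulation.
        """
        ratio = (1.0 + self.lifespan_cv**2) / math.exp(self.coupling_variance())
        if ratio <= 1.0:
            raise ConfigurationError("coupling leaves no room for baseline variation")
        return math.sqrt(ratio - 1.0)

    def reporter(self, name: str) -> ReporterSpec:
        d = dict(self.reporters)
        if name not in d:
            raise ConfigurationError(f"unknown reporter {name!r}")
        return d[name]

    def ramp(self, age_h: np.ndarray) -> np.ndarray:
        """Coupling activation in [0, 1] as a function of age."""
        age_h = np.asarray(age_h, dtype=float)
        up = np.clip((age_h - self.coupling_onset_age_h) / self.coupling_ramp_h, 0.0, 1.0)
        if self.coupling_offset_age_h is not None:
            down = np.clip(
                (age_h - self.coupling_offset_age_h) / self.coupling_ramp_h, 0.0, 1.0
            )
            up = up * (1.0 - down)
        return up


# -- lifespan law --------------------------------------------------------


def _gompertz_shape_for_cv(cv: float) -> float:
    """Solve the Gompertz shape parameter giving the requested CV.

    Uses the scipy ``gompertz`` parameterization ``S(x) = exp(-c (e^x - 1))``
    on dimensionless ``x``; CV is scale-free so depends on ``c`` only.  The
    CV decreases in ``c`` (more rectangular survival curves).
    """

    def cv_of(log_c: float) -> float:
        c = math.exp(log_c)
        m, v = stats.gompertz.stats(c, moments="mv")
        return math.sqrt(v) / m - cv

    try:
        log_c = optimize.brentq(cv_of, math.log(1e-8), math.log(1e4), xtol=1e-12)
    except ValueError as exc:  # pragma: no cover - pathological CV
        raise ConfigurationError(f"no Gompertz shape achieves CV={cv}") from exc
    return math.exp(log_c)


def _baseline_lifespans(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw baseline lifespans with the configured median and residual CV."""
    cv0 = config.base_cv()
    med = config.median_lifespan_h
    if config.lifespan_family == "lognormal":
        sigma = math.sqrt(math.log1p(cv0**2))
        return med * np.exp(sigma * rng.standard_normal(n))
    c = _gompertz_shape_for_cv(cv0)
    scale = med / stats.gompertz.ppf(0.5, c)
    return stats.gompertz.rvs(c, scale=scale, size=n, random_state=rng)


def simulate_lifespans(
    config: SimulationConfig, latent: np.ndarray, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Lifespans (hours) for animals with latent state ``latent`` (n x P).

    The baseline draw is modulated by ``exp(c . z)`` so lifespan is a
    strictly increasing function of the summed loaded latent values given
    the baseline noise, and stays positive.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    latent = np.atleast_2d(np.asarray(latent, dtype=float))
    c = config.coupling_vector()
    if latent.shape[1] != c.size:
        raise ConfigurationError(
            f"latent has {latent.shape[1]} processes, config defines {c.size}"
        )
    base = _baseline_lifespans(config, latent.shape[0], rng)
    return base * np.exp(latent @ c)


# -- trajectories --------------------------------------------------------


def _expression_matrix(
    config: SimulationConfig,
    spec: ReporterSpec,
    ages: np.ndarray,
    g: np.ndarray,
    lifespans: np.ndarray,
    batch_offsets: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dense (n_animals x n_ages) expression values before death masking."""
    ramp = config.ramp(ages)  # (K,)
    base = spec.template(ages)[None, :]
    latent_term = ramp[None, :] * g[:, None] * (
        spec.level_loading + spec.slope_loading * ages[None, :]
    )
    values = base + latent_term
    if config.death_signal_amp != 0.0:
        prox = 1.0 - (lifespans[:, None] - ages[None, :]) / config.death_signal_lookback_h
        values = values + config.death_signal_amp * np.clip(prox, 0.0, 1.0)
    values = values + batch_offsets[:, None]
    if spec.noise_sd > 0:
        values = values + spec.noise_sd * rng.standard_normal(values.shape)
    return values


def simulate_trajectory(
    config: SimulationConfig,
    lifespan_h: float,
    latent: np.ndarray,
    reporter: str = "gfp",
    batch_offset: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """One animal's (age_h, value) series for one reporter.

    Observations are placed on the sampling lattice ``0, dt, 2dt, ...`` up
    to and including the last timepoint at or before death.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    spec = config.reporter(reporter)
    dt = config.sampling_interval_h
    ages = np.arange(0.0, math.floor(lifespan_h / dt) * dt + dt / 2, dt)
    w = spec.loading_vector(config.processes)
    g = np.atleast_1d(np.asarray(latent, dtype=float) @ w)
    values = _expression_matrix(
        config, spec, ages, g, np.array([lifespan_h]), np.array([batch_offset]), rng
    )[0]
    return pd.DataFrame({"age_h": ages, "value": values})


# -- cohort --------------------------------------------------------------


@dataclass
class SimulatedCohort:
    """A generated cohort plus its ground truth."""

    dataset: Dataset
    latent: pd.DataFrame  # animal_id x process, the planted state
    config: SimulationConfig

    @property
    def lifespans(self) -> pd.Series:
        return self.dataset.animals.set_index("animal_id")["lifespan_h"]


def simulate_cohort(config: SimulationConfig, statistic: str = "mean") -> SimulatedCohort:
    """Generate a full cohort dataset (all replicates, all reporters).

    The result passes :meth:`lifesignal.io.Dataset.validate`.  All series
    carry the same nominal summary ``statistic`` label (the simulator models
    the already-summarized per-timepoint measurement, not pixel images).

    Randomness is fully determined by ``config.seed``: identical configs
    give bit-identical cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    ss_latent, ss_life, ss_batch, ss_noise = root.spawn(4)
    rng_latent = np.random.default_rng(ss_latent)
    rng_life = np.random.default_rng(ss_life)
    rng_batch = np.random.default_rng(ss_batch)
    noise_seqs = ss_noise.spawn(len(config.reporters))

    processes = config.processes
    n_rep = config.n_replicates
    n_per = config.n_individuals
    n = n_rep * n_per

    z = rng_latent.standard_normal((n, len(processes)))
    lifespans = simulate_lifespans(config, z, rng_life)

    rep_ids = np.repeat(np.arange(1, n_rep + 1), n_per)
    if n_rep > 1:
        expr_off = rng_batch.normal(0.0, config.batch_sd, n_rep)
        life_fac = np.exp(rng_batch.normal(0.0, config.batch_lifespan_sd, n_rep))
    else:
        expr_off = np.zeros(1)
        life_fac = np.ones(1)
    lifespans = lifespans * life_fac[rep_ids - 1]
    batch_offsets = expr_off[rep_ids - 1]

    animal_ids = np.array([f"r{r}_a{i:05d}" for i, r in enumerate(rep_ids)])
    animals = pd.DataFrame(
        {
            "animal_id": animal_ids,
            "replicate_id": rep_ids,
            "hatch_age_h": 0.0,
            "first_egg_age_h": np.nan,
            "death_age_h": lifespans,
            "excluded": False,
            "exclusion_reason": "none",
        }
    )

    dt = config.sampling_interval_h
    k_max = int(math.floor(lifespans.max() / dt))
    ages = np.arange(k_max + 1) * dt
    alive = ages[None, :] <= lifespans[:, None]  # (n, K)

    frames = []
    for (name, spec), seq in zip(config.reporters, noise_seqs):
        rng_noise = np.random.default_rng(seq)
        w = spec.loading_vector(processes)
        g = z @ w
        values = _expression_matrix(
            config, spec, ages, g, lifespans, batch_offsets, rng_noise
        )
        rows, cols = np.nonzero(alive)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": animal_ids[rows],
                    "replicate_id": rep_ids[rows],
                    "reporter": name,
                    "statistic": statistic,
                    "age_h": ages[cols],
                    "value": values[rows, cols],
                }
            )
        )
    measurements = pd.concat(frames, ignore_index=True)
    dataset = Dataset(animals, measurements, provenance=f"simulated cohort (seed={config.seed})")
    latent = pd.DataFrame(z, columns=processes, index=pd.Index(animal_ids, name="animal_id"))
    return SimulatedCohort(dataset, latent, config)


# -- closed-form population quantities -----------------------------------


def _baseline_moments(config: SimulationConfig) -> tuple[float, float]:
    """First two raw moments of the baseline lifespan law."""
    cv0 = config.base_cv()
    med = config.median_lifespan_h
    if config.lifespan_family == "lognormal":
        s2 = math.log1p(cv0**2)
        m1 = med * math.exp(s2 / 2)
        m2 = med**2 * math.exp(2 * s2)
        return m1, m2
    c = _gompertz_shape_for_cv(cv0)
    scale = med / stats.gompertz.ppf(0.5, c)
    m1 = stats.gompertz.moment(1, c, scale=scale)
    m2 = stats.gompertz.moment(2, c, scale=scale)
    return m1, m2


def _window_lattice(config: SimulationConfig, window: tuple[float, float]) -> np.ndarray:
    dt = config.sampling_interval_h
    start, end = window
    k0 = math.ceil(start / dt - 1e-9)
    k1 = math.floor(end / dt + 1e-9)
    return np.arange(k0, k1 + 1) * dt


def _feature_model(
    config: SimulationConfig, reporter: str, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Loadings and noise variances of the windowed (mean, slope) features.

    Returns ``A`` (2 x P), the coefficients of the features on the latent
    processes, and the 2-vector of independent feature noise variances.
    Valid only where the coupling ramp is saturated at 1 across the window
    and no moribundity term is active.
    """
    spec = config.reporter(reporter)
    t = _window_lattice(config, window)
    if t.size < 2:
        raise ConfigurationError("window holds fewer than 2 sampling timepoints")
    if config.ramp(t).min() < 1.0 - 1e-12:
        raise ConfigurationError(
            "closed-form features require the coupling ramp to be 1 over the window"
        )
    if config.death_signal_amp != 0.0:
        raise ConfigurationError("closed form not available with a death signal")
    w = spec.loading_vector(config.processes)
    tbar = t.mean()
    sst = float(np.sum((t - tbar) ** 2))
    a_mean = w * (spec.level_loading + spec.slope_loading * tbar)
    a_slope = w * spec.slope_loading
    noise = np.array([spec.noise_sd**2 / t.size, spec.noise_sd**2 / sst])
    return np.vstack([a_mean, a_slope]), noise


def _truncated_log_terms(v: float, s0: float) -> dict[str, float]:
    """Moments of S ~ N(0, v) conditioned on S > s0.

    Returns the conditional mean and variance of S and the exponential
    moments E[e^S], E[e^2S] and Cov(S, e^S), all in closed form via the
    standard normal pdf/sf.  With s0 = -inf these reduce to the familiar
    log-normal moments.
    """
    sd = math.sqrt(v)
    w0 = s0 / sd if math.isfinite(s0) else -math.inf
    surv = stats.norm.sf(w0)
    e_s = sd * stats.norm.pdf(w0) / surv
    e_s2 = v * (1.0 + (w0 * stats.norm.pdf(w0) / surv if math.isfinite(w0) else 0.0))
    e_exp = math.exp(v / 2) * stats.norm.sf(w0 - sd) / surv
    e_exp2 = math.exp(2 * v) * stats.norm.sf(w0 - 2 * sd) / surv
    e_s_exp = (
        sd
        * math.exp(v / 2)
        * (sd * stats.norm.sf(w0 - sd) + stats.norm.pdf(w0 - sd))
        / surv
    )
    return {
        "mean_s": e_s,
        "var_s": e_s2 - e_s**2,
        "e_exp": e_exp,
        "var_exp": e_exp2 - e_exp**2,
        "cov_s_exp": e_s_exp - e_s * e_exp,
    }


def population_r2(
    config: SimulationConfig,
    window: tuple[float, float],
    reporters: list[str],
    account_censoring: bool = True,
) -> float:
    """Population R^2 of lifespan on the stacked (mean, slope) features.

    Exact under the generative model for a single replicate (batch effects
    confound the closed form) and a window inside the saturated coupling
    regime.  By default the value is computed *conditional on surviving the
    window* (``lifespan > window end``), matching the censoring the
    regression engine applies; survivorship truncates the short-lived tail
    and genuinely lowers the explainable variance, so the censored and
    uncensored values can differ materially.  The censoring-aware form is
    available for the log-normal lifespan family.
    """
    if config.n_replicates > 1 and (config.batch_sd or config.batch_lifespan_sd):
        raise ConfigurationError("closed form requires a batch-effect-free cohort")
    blocks, noises = zip(*(_feature_model(config, r, window) for r in reporters))
    A = np.vstack(blocks)  # (2R, P)
    D = np.concatenate(noises)
    c = config.coupling_vector()
    v_c = float(c @ c)

    if account_censoring:
        if config.lifespan_family != "lognormal":
            raise NotImplementedError(
                "censoring-aware closed form implemented for lognormal only"
            )
        # total log-lifespan deviation S = c.z + sigma_eps*eps ~ N(0, v);
        # conditioning on S > s0 keeps (z, S) jointly tractable because
        # z = (c/v) S + u with u independent of S.
        v = config.total_log_variance()
        s0 = math.log(window[1] / config.median_lifespan_h)
        t = _truncated_log_terms(v, s0)
        med = config.median_lifespan_h
        a_c = A @ c
        var_t = med**2 * t["var_exp"]
        cov_tf = med * (a_c / v) * t["cov_s_exp"]
        cov_u = np.eye(c.size) - np.outer(c, c) / v
        sigma_f = (
            np.outer(a_c, a_c) * t["var_s"] / v**2 + A @ cov_u @ A.T + np.diag(D)
        )
    else:
        m1, m2 = _baseline_moments(config)
        var_t = m2 * math.exp(2 * v_c) - m1**2 * math.exp(v_c)
        cov_tf = m1 * math.exp(v_c / 2) * (A @ c)
        sigma_f = A @ A.T + np.diag(D)
    beta = np.linalg.solve(sigma_f, cov_tf)
    return float(cov_tf @ beta / var_t)


def population_joint_r2(
    config: SimulationConfig,
    window: tuple[float, float],
    reporter: str = "gfp",
    account_censoring: bool = True,
) -> float:
    """Single-reporter population joint R^2 of (mean, slope) vs lifespan."""
    return population_r2(config, window, [reporter], account_censoring)


def population_pair_semipartials(
    config: SimulationConfig,
    window: tuple[float, float],
    reporter_a: str,
    reporter_b: str,
    account_censoring: bool = True,
) -> dict[str, float]:
    """Closed-form single, pair, and semipartial R^2 for a reporter pair."""
    r2_a = population_r2(config, window, [reporter_a], account_censoring)
    r2_b = population_r2(config, window, [reporter_b], account_censoring)
    r2_pair = population_r2(config, window, [reporter_a, reporter_b], account_censoring)
    return {
        "r2_a": r2_a,
        "r2_b": r2_b,
        "r2_pair": r2_pair,
        "sp_a_given_b": r2_pair - r2_b,
        "sp_b_given_a": r2_pair - r2_a,
    }


def calibrate_coupling(
    config: SimulationConfig,
    window: tuple[float, float],
    target_r2: float,
    reporter: str = "gfp",
) -> SimulationConfig:
    """Rescale the lifespan coupling so the population joint R^2 hits a target.

    Solves for a scalar multiplier on all coupling coefficients by bisection
    against :func:`population_joint_r2`.  The achievable ceiling is bounded
    by the feature noise and by the share of lifespan variance the coupling
    can claim; a target beyond it raises :class:`ConfigurationError`.
    """
    if not 0 < target_r2 < 1:
        raise ConfigurationError("target_r2 must be in (0, 1)")
    base = dict(config.lifespan_coupling)
    names = list(base)
    vec = np.array([base[p] for p in names], dtype=float)
    norm = float(np.linalg.norm(vec))
    if norm == 0:
        raise ConfigurationError("cannot calibrate a zero coupling vector")
    unit = vec / norm
    sigma_tot = math.sqrt(config.total_log_variance())
    hi = 0.999 * sigma_tot  # keep baseline variance positive

    def with_scale(s: float) -> SimulationConfig:
        coupling = tuple((p, float(u * s)) for p, u in zip(names, unit))
        return replace(config, lifespan_coupling=coupling)

    def gap(s: float) -> float:
        return population_joint_r2(with_scale(s), window, reporter) - target_r2

    if gap(hi) < 0:
        raise ConfigurationError(
            f"target R^2={target_r2} unreachable; maximum is {gap(hi) + target_r2:.4f}"
        )
    s_star = optimize.brentq(gap, 1e-9, hi, xtol=1e-12)
    return with_scale(s_star)


def death_probability_by(config: SimulationConfig, age_h: float) -> float:
    """P(lifespan <= age) under the generative model (log-normal family).

    Used to verify that a chosen analysis window censors a negligible part
    of the population, so the closed-form R^2 (which ignores censoring)
    applies.
    """
    if config.lifespan_family != "lognormal":
        raise NotImplementedError("exact death probability implemented for lognormal only")
    sigma = math.sqrt(config.total_log_variance())
    return float(stats.norm.cdf(math.log(age_h / config.median_lifespan_h) / sigma))


# -- canned scenarios ----------------------------------------------------


def hierarchy_config(
    n_individuals: int = 400, seed: int = 0, noise_sd: float = 0.15
) -> SimulationConfig:
    """Three reporters reading nested subsets of three lifespan processes.

    Reporter ``A`` reads processes X, Y and Z; ``B`` reads X and Y; ``C``
    reads X only.  Lifespan loads equally on all three processes, so A
    carries strictly more lifespan information than B, and B more than C —
    the planted informational hierarchy A >= B >= C.  The coupling strength
    puts the trio's single-reporter joint R^2 near 0.36/0.22/0.10,
    the magnitude range reported for strong dual-reporter strains.
    """
    c = 0.085  # per-process log-lifespan coefficient; total variance 3c^2
    spec = lambda procs: ReporterSpec(  # noqa: E731 - local shorthand
        template=TemplateSpec("declining"),
        loadings=tuple((p, 1.0) for p in procs),
        noise_sd=noise_sd,
    )
    return SimulationConfig(
        n_individuals=n_individuals,
        n_replicates=1,
        lifespan_coupling=(("X", c), ("Y", c), ("Z", c)),
        reporters=(
            ("A", spec("XYZ")),
            ("B", spec("XY")),
            ("C", spec("X")),
        ),
        seed=seed,
    )
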