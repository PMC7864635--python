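"""Resampling inference and design calculations.

Confidence intervals for correlation coefficients are percentile bootstrap
intervals: the analysis population is resampled with replacement at the
level of whole animals (a statistic like R-squared is cross-sectional over
animals, so resampling anything finer would break the longitudinal
structure), the statistic is recomputed on each resample, and the 2.5th and
97.5th percentiles of the resampled values form the 95% interval.

Power calculations address the design question "how many animals are
needed to detect a biomarker explaining a given fraction of lifespan
variance?".  The default convention treats the biomarker-lifespan
association as a single correlation of magnitude ``r = sqrt(R^2)`` and uses
the Fisher z-transform normal approximation; at R^2 = 0.15 and alpha = 0.05
this yields 95% power at n = 80.  The noncentral-F convention for the
two-predictor joint test is also provided (it is slightly more
conservative, about 92% at the same settings), as is a direct Monte-Carlo
check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BootstrapSpec",
    "BootstrapResult",
    "bootstrap_ci",
    "power_correlation",
    "minimum_n_for_power",
]


@dataclass(frozen=True)
class BootstrapSpec:
    """Percentile-bootstrap settings (unit of resampling: the animal)."""

    n_boot: int = 1000
    lower_pct: float = 2.5
    upper_pct: float = 97.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100 for CI reporting")
        if not 0 < self.lower_pct < self.upper_pct < 100:
            raise ValueError("percentiles must satisfy 0 < lower < upper < 100")


@dataclass
class BootstrapResult:
    low: float
    high: float
    samples: np.ndarray
    n_failed: int

    @property
    def ci(self) -> tuple[float, float]:
        return (self.low, self.high)


def bootstrap_ci(n_units: int, statistic, spec: BootstrapSpec) -> BootstrapResult:
    """Percentile bootstrap CI of ``statistic`` over ``n_units`` animals.

    ``statistic`` is a closure mapping an integer index array (a resample,
    with replacement, of ``range(n_units)``) to a scalar; it re-runs the
    full analysis on the resampled animals, re-applying any censoring.
    Resamples on which the closure raises or returns a non-finite value are
    dropped and counted; more than 5% failures is an error.

    The CI endpoints are order statistics (linear-interpolated percentiles)
    of the resampled values — no smoothing or bias correction.  The draw is
    fully determined by ``spec.seed`` and independent of animal input order.
    """
    rng = np.random.default_rng(spec.seed)
    values = []
    n_failed = 0
    for _ in range(spec.n_boot):
        idx = rng.integers(0, n_units, n_units)
        try:
            v = float(statistic(idx))
        except Exception:
            v = math.nan
        if math.isfinite(v):
            values.append(v)
        else:
            n_failed += 1
    if n_failed > 0.05 * spec.n_boot:
        raise RuntimeError(
            f"bootstrap closure failed on {n_failed}/{spec.n_boot} resamples"
        )
    samples = np.asarray(values)
    low, high = np.percentile(samples, [spec.lower_pct, spec.upper_pct])
    return BootstrapResult(float(low), float(high), samples, n_failed)


# -- power ---------------------------------------------------------------


def power_correlation(
    n: int,
    true_r2: float,
    alpha: float = 0.05,
    method: str = "fisher_z",
    n_sims: int = 20000,
    seed: int = 0,
) -> float:
    """Power of the two-sided level-alpha test of zero association.

    Methods
    -------
    ``fisher_z`` : normal approximation for a single correlation of
        magnitude ``sqrt(true_r2)`` via the Fisher z-transform (default).
    ``joint_f`` : exact noncentral-F power for the 2-predictor joint
        regression test of R^2 = 0.
    ``monte_carlo`` : empirical rejection rate of the correlation t-test
        over ``n_sims`` simulated bivariate-normal samples.
    """
    if not 0 <= true_r2 < 1:
        raise ValueError("true_r2 must be in [0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    r = math.sqrt(true_r2)
    if method == "fisher_z":
        if n < 4:
            raise ValueError("fisher_z power needs n >= 4")
        z_crit = sps.norm.ppf(1 - alpha / 2)
        delta = math.atanh(r) * math.sqrt(n - 3)
        return float(sps.norm.cdf(delta - z_crit) + sps.norm.cdf(-delta - z_crit))
    if method == "joint_f":
        k = 2
        df2 = n - k - 1
        if df2 < 1:
            raise ValueError("joint_f power needs n >= 4")
        f_crit = sps.f.ppf(1 - alpha, k, df2)
        nc = n * true_r2 / (1 - true_r2)
        return float(sps.ncf.sf(f_crit, k, df2, nc))
    if method == "monte_carlo":
        if n < 3:
            raise ValueError("monte_carlo power needs n >= 3")
        rng = np.random.default_rng(seed)
        rejections = 0
        chunk = max(1, min(n_sims, int(4e6 // n)))
        done = 0
        t_crit = sps.t.ppf(1 - alpha / 2, n - 2)
        while done < n_sims:
            b = min(chunk, n_sims - done)
            x = rng.standard_normal((b, n))
            e = rng.standard_normal((b, n))
            y = r * x + math.sqrt(1 - r * r) * e
            xc = x - x.mean(axis=1, keepdims=True)
            yc = y - y.mean(axis=1, keepdims=True)
            rr = (xc * yc).sum(axis=1) / np.sqrt(
                (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
            )
            t = rr * np.sqrt((n - 2) / (1 - rr**2))
            rejections += int(np.count_nonzero(np.abs(t) > t_crit))
            done += b
        return rejections / n_sims
    raise ValueError(f"unknown method {method!r}")


def minimum_n_for_power(
    true_r2: float,
    alpha: float = 0.05,
    target_power: float = 0.95,
    method: str = "fisher_z",
) -> int:
    """Smallest sample size reaching the target power (analytic methods).

    Power is monotone increasing in n, so a bracketing doubling search
    followed by bisection finds the exact threshold.  A floor of n = 4 is
    enforced (below it the tests are undefined).
    """
    if not alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    if true_r2 <= 0:
        raise ValueError("true_r2 must be positive")
    lo, hi = 4, 8
    while power_correlation(hi, true_r2, alpha, method) < target_power:
        lo, hi = hi, hi * 2
        if hi > 10**7:
            raise RuntimeError("required n exceeds 1e7")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_correlation(mid, true_r2, alpha, method) >= target_power:
            hi = mid
        else:
            lo = mid
    if power_correlation(lo, true_r2, alpha, method) >= target_power:
        return lo
    return hi
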