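"""Poisson and Poisson-lognormal count machinery.

The number of microplastic particles counted in an analytical portion is a
Poisson variate.  Because the Poisson mean ``lambda`` is itself uncertain, it
is modelled as a lognormal random variable moment-matched to an expected value
``E(lambda)`` and variance ``Var(lambda)``; compounding the two gives the
Poisson-lognormal count law used throughout the uncertainty budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "PoissonLognormalSpec",
    "LogScaleParams",
    "lognormal_logparams",
    "poisson_pmf",
    "sample_lambda",
    "sample_poisson_lognormal",
    "poislog_pmf_oracle",
]


@dataclass(frozen=True)
class PoissonLognormalSpec:
    """Mean/variance pair (E(lambda), Var(lambda)) of the count mean.

    ``expected_value == 0`` is legal only as the degenerate point mass at
    zero counts (``variance`` must then also be zero): zero observed counts
    do occur in monitoring data.
    """

    expected_value: float
    variance: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.expected_value) or self.expected_value < 0:
            raise ValueError(f"expected_value must be finite and >= 0, got {self.expected_value}")
        if not np.isfinite(self.variance) or self.variance < 0:
            raise ValueError(f"variance must be finite and >= 0, got {self.variance}")
        if self.expected_value == 0 and self.variance > 0:
            raise ValueError("variance > 0 requires expected_value > 0 (log-scale conversion undefined at E = 0)")

    @property
    def is_degenerate_zero(self) -> bool:
        return self.expected_value == 0


@dataclass(frozen=True)
class LogScaleParams:
    """Natural-log-scale parameters of the lognormal mean: mu = E(ln lambda), sigma2 = Var(ln lambda)."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not np.isfinite(self.sigma2) or self.sigma2 < 0:
            raise ValueError(f"sigma2 must be finite and >= 0, got {self.sigma2}")


def lognormal_logparams(spec: PoissonLognormalSpec) -> LogScaleParams:
    """Convert (E, Var) of lambda to the log-scale (mu, sigma2) of its lognormal.

    sigma2 = ln(1 + Var/E^2) and mu = ln(E) - sigma2/2, so that
    exp(mu + sigma2/2) = E and (exp(sigma2) - 1) exp(2 mu + sigma2) = Var.

    Raises
    ------
    ValueError
        If ``spec.expected_value <= 0``: the conversion is undefined and the
        caller must handle the zero-count degeneracy explicitly.
    """
    e, v = spec.expected_value, spec.variance
    if e <= 0:
        raise ValueError("log-scale conversion undefined for expected_value <= 0; handle the zero-count degeneracy upstream")
    sigma2 = float(np.log1p(v / (e * e)))
    mu = float(np.log(e) - sigma2 / 2.0)
    return LogScaleParams(mu=mu, sigma2=sigma2)


def poisson_pmf(c, lam: float):
    """Poisson probability mass e^{-lam} lam^c / c! for natural-number counts.

    ``c`` may be a scalar or array; every element must be a nonnegative
    integer (integer-valued floats are accepted).
    """
    c_arr = np.asarray(c)
    if not np.all(np.isfinite(c_arr)) or np.any(c_arr < 0) or np.any(c_arr != np.floor(c_arr)):
        raise ValueError(f"counts must be nonnegative integers, got {c!r}")
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be a positive real, got {lam}")
    out = stats.poisson.pmf(c_arr.astype(np.int64), lam)
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def sample_lambda(params: LogScaleParams, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Draw lambda values: exp(z) with z ~ Normal(mu, sigma2).

    With sigma2 = 0 every draw equals exp(mu) (a Normal draw is still
    consumed, keeping the stream layout independent of the parameters).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    z = rng.normal(params.mu, np.sqrt(params.sigma2), size=n_draws)
    return np.exp(z)


def sample_poisson_lognormal(spec: PoissonLognormalSpec, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Draw Poisson-lognormal counts: C_i ~ Poisson(lambda_i), lambda_i lognormal.

    Draw order (fixed for reproducibility): first the ``n_draws`` Normal
    variates behind the lambdas, then the ``n_draws`` Poisson variates.
    The degenerate spec (E = 0, Var = 0) yields all-zero counts and consumes
    no draws.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if spec.is_degenerate_zero:
        return np.zeros(n_draws, dtype=np.int64)
    lam = sample_lambda(lognormal_logparams(spec), n_draws, rng)
    return rng.poisson(lam).astype(np.int64)


def poislog_pmf_oracle(c, spec: PoissonLognormalSpec) -> float:
    """Numerical Poisson-lognormal pmf, for testing the sampler.

    Integrates the Poisson pmf against the lognormal density of lambda by
    adaptive quadrature over z = ln(lambda) on mu +/- 10 sigma (tail mass
    below 1e-12 outside).  Not vectorized; intended as an oracle only.
    """
    c = int(c)
    if c < 0:
        raise ValueError("count must be a nonnegative integer")
    if spec.is_degenerate_zero:
        return 1.0 if c == 0 else 0.0
    p = lognormal_logparams(spec)
    if p.sigma2 == 0:
        return poisson_pmf(c, np.exp(p.mu))
    sigma = np.sqrt(p.sigma2)

    def integrand(z: float) -> float:
        lam = np.exp(z)
        return stats.poisson.pmf(c, lam) * stats.norm.pdf(z, p.mu, sigma)

    lo, hi = p.mu - 10.0 * sigma, p.mu + 10.0 * sigma
    val, _ = integrate.quad(integrand, lo, hi, limit=200, epsabs=1e-12, epsrel=1e-10)
    return float(val)
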