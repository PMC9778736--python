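"""Monte Carlo combination of counting and weighing uncertainty.

Per simulation draw i the contamination of one sample is

    omega_i = (C_r[i] + Delta[i]) / (m W_d)[i] * 1000      [kg^-1]

where C_r ~ Poisson-lognormal(E = C, Var = Var(lambda_r)) carries the random
counting error centred on the observed count C, Delta ~ Poisson-lognormal
(E = C F, Var from the spike experiment) is the integer loss-correction term,
and (m W_d) is the simulated dry analytical-portion mass in grams.  The
simulated distribution is summarised by its histogram mode (best estimate)
and the P0.5/P99.5 percentiles (99 % confidence interval); two samples are
metrologically equivalent when zero lies inside the percentile interval of
their simulated difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .effects import RandomEffects, SystematicEffects, systematic_lambda_spec
from .gravimetry import BalanceSpec, DryWeightRecord, PortionMass, dry_weight_fraction, simulate_dry_portion_mass
from .poislog import PoissonLognormalSpec, sample_poisson_lognormal

__all__ = [
    "SampleRecord",
    "MCSettings",
    "ContaminationResult",
    "ComparisonOutcome",
    "simulate_contamination",
    "summarize",
    "compare",
    "campaign_mean",
    "point_estimate",
]

G_PER_KG = 1000.0


@dataclass(frozen=True)
class SampleRecord:
    """One sediment sample: observed count and gravimetric readings."""

    sample_id: str
    campaign: str
    parameter: str
    count: int
    portion: PortionMass
    dry_record: DryWeightRecord

    def __post_init__(self) -> None:
        if int(self.count) < 0 or self.count != int(self.count):
            raise ValueError(f"count must be a natural number, got {self.count}")


@dataclass(frozen=True)
class MCSettings:
    """Monte Carlo settings: draw count, seed, interval percentiles, mode binning."""

    n_draws: int = 49_999
    seed: int = 0
    lower_percentile: float = 0.5
    upper_percentile: float = 99.5
    mode_bins: int = 200

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not (0.0 < self.lower_percentile < self.upper_percentile < 100.0):
            raise ValueError("need 0 < lower_percentile < upper_percentile < 100")
        if self.mode_bins < 1:
            raise ValueError("mode_bins must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ContaminationResult:
    """Simulated contamination draws (kg^-1) with mode and percentile summary."""

    draws: np.ndarray
    mode: float
    p_lower: float
    p_upper: float
    sample_id: str = ""
    parameter: str = ""

    def format(self, decimals: int = 0) -> str:
        """Render as ``mode; [P_lower; P_upper]`` (integers by default)."""
        if decimals == 0:
            return f"{self.mode:.0f}; [{self.p_lower:.0f}; {self.p_upper:.0f}]"
        return (
            f"{self.mode:.{decimals}f}; "
            f"[{self.p_lower:.{decimals}f}; {self.p_upper:.{decimals}f}]"
        )


@dataclass(frozen=True)
class ComparisonOutcome:
    """Verdict of a metrological comparison of two simulated results."""

    verdict: str  # "equivalent" | "first_greater" | "first_less"
    diff_p_lower: float
    diff_p_upper: float
    confidence_level: float


def summarize(draws: np.ndarray, settings: MCSettings) -> tuple[float, float, float]:
    """(mode, p_lower, p_upper) of a draw vector.

    Percentiles interpolate linearly between order statistics.  The mode is
    the midpoint of the most populated of ``mode_bins`` equal-width bins over
    [min, max] (lowest bin wins ties); when a single exact value holds at
    least half of that bin's draws -- a point mass, e.g. the zeros of an
    uncontaminated sample -- that value is reported instead of the midpoint.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("at least 2 draws are required for a summary")
    lo, hi = float(np.min(draws)), float(np.max(draws))
    p_lower, p_upper = (float(v) for v in np.percentile(
        draws, [settings.lower_percentile, settings.upper_percentile]))
    if lo == hi:
        return lo, p_lower, p_upper
    counts, edges = np.histogram(draws, bins=settings.mode_bins, range=(lo, hi))
    k = int(np.argmax(counts))
    upper_ok = draws <= edges[k + 1] if k == settings.mode_bins - 1 else draws < edges[k + 1]
    in_bin = draws[(draws >= edges[k]) & upper_ok]
    mode = float(0.5 * (edges[k] + edges[k + 1]))
    if in_bin.size:
        values, freqs = np.unique(in_bin, return_counts=True)
        j = int(np.argmax(freqs))
        if freqs[j] * 2 >= counts[k]:
            mode = float(values[j])
    return mode, p_lower, p_upper


def _count_draws(count: int, re: RandomEffects, se: SystematicEffects,
                 n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """C_r + Delta draws.  A zero observed count degenerates both terms to zero."""
    if count == 0:
        return np.zeros(n_draws, dtype=np.int64)
    random_spec = PoissonLognormalSpec(float(count), re.var_lambda_r)
    c_r = sample_poisson_lognormal(random_spec, n_draws, rng)
    delta = sample_poisson_lognormal(systematic_lambda_spec(count, se), n_draws, rng)
    return c_r + delta


def simulate_contamination(
    sample: SampleRecord,
    re: RandomEffects,
    se: SystematicEffects,
    balance: BalanceSpec,
    settings: MCSettings,
    rng: np.random.Generator | None = None,
) -> ContaminationResult:
    """Simulate the contamination omega of one sample, in kg^-1.

    Draw order per run: random-count term, systematic-count term, then the
    three gravimetric components.  Pass ``rng`` to share one stream across
    several samples; otherwise a fresh stream is created from
    ``settings.seed``.
    """
    if rng is None:
        rng = settings.rng()
    n = settings.n_draws
    counts = _count_draws(sample.count, re, se, n, rng)
    dry_mass_g = simulate_dry_portion_mass(sample.portion, sample.dry_record, balance, n, rng)
    omega = counts / (dry_mass_g / G_PER_KG)
    mode, p_lo, p_hi = summarize(omega, settings)
    return ContaminationResult(
        draws=omega, mode=mode, p_lower=p_lo, p_upper=p_hi,
        sample_id=sample.sample_id, parameter=sample.parameter,
    )


def point_estimate(sample: SampleRecord, se: SystematicEffects) -> float:
    """Deterministic corrected contamination C (1 + F) / (m W_d), in kg^-1."""
    dry_mass_kg = sample.portion.nominal_mass * dry_weight_fraction(sample.dry_record) / G_PER_KG
    return sample.count * (1.0 + se.correction_factor) / dry_mass_kg


def compare(a: ContaminationResult, b: ContaminationResult, settings: MCSettings) -> ComparisonOutcome:
    """Metrological comparison via the percentiles of the simulated difference a - b.

    Verdicts: ``equivalent`` when P_lower <= 0 <= P_upper of the difference,
    ``first_greater`` when P_lower > 0, ``first_less`` when P_upper < 0.
    The two results must carry independently drawn vectors of equal length.
    """
    if a.draws.size != b.draws.size:
        raise ValueError(f"draw counts differ ({a.draws.size} vs {b.draws.size}); refusing to truncate")
    d = a.draws - b.draws
    p_lo, p_hi = (float(v) for v in np.percentile(
        d, [settings.lower_percentile, settings.upper_percentile]))
    if p_lo > 0:
        verdict = "first_greater"
    elif p_hi < 0:
        verdict = "first_less"
    else:
        verdict = "equivalent"
    return ComparisonOutcome(
        verdict=verdict, diff_p_lower=p_lo, diff_p_upper=p_hi,
        confidence_level=settings.upper_percentile - settings.lower_percentile,
    )


def campaign_mean(results: Sequence[ContaminationResult], settings: MCSettings) -> ContaminationResult:
    """Per-draw mean contamination over the samples of one campaign."""
    if not results:
        raise ValueError("campaign_mean requires at least one result")
    sizes = {r.draws.size for r in results}
    if len(sizes) != 1:
        raise ValueError("all results must carry the same number of draws")
    mean_draws = np.mean(np.stack([r.draws for r in results]), axis=0)
    mode, p_lo, p_hi = summarize(mean_draws, settings)
    params = {r.parameter for r in results}
    return ContaminationResult(
        draws=mean_draws, mode=mode, p_lower=p_lo, p_upper=p_hi,
        sample_id="mean(" + ",".join(r.sample_id for r in results) + ")",
        parameter=params.pop() if len(params) == 1 else "mixed",
    )
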