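"""Synthetic validation and monitoring data with known ground truth.

The generators emulate the validation design behind the uncertainty budget:
duplicate analyses of the same sediments (random-effects estimation),
spike-recovery units with a known number of added particles (systematic
effects, modelled as binomial thinning: each particle independently survives
sample preparation with probability R), and monitoring samples whose true
contamination is recorded in a separate truth table for coverage scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import DuplicateSet, SpikeSet
from .gravimetry import BalanceSpec, DryWeightRecord, PortionMass
from .montecarlo import G_PER_KG, SampleRecord
from .poislog import PoissonLognormalSpec, lognormal_logparams, sample_lambda

__all__ = ["TruthScenario", "generate_duplicates", "generate_spikes", "generate_samples"]


@dataclass(frozen=True)
class TruthScenario:
    """Ground-truth parameters of a simulated validation + monitoring study.

    ``true_lambda`` is the mean number of particles actually present in one
    analytical portion; each survives preparation with probability
    ``recovery_rate``, so the observed count is Poisson(true_lambda * R)
    when ``lambda_heterogeneity`` is zero, and Poisson mixed over a
    lognormal portion-to-portion lambda otherwise.  The defaults mirror the
    published validation design: 12 duplicated sediments, 12 spike units of
    5 particles each, recoveries in the 0.7-0.8 range.
    """

    true_lambda: float = 10.0
    lambda_heterogeneity: float = 0.0
    recovery_rate: float = 0.8
    added_per_unit: int = 5
    n_samples: int = 12
    n_duplicates: int = 12
    n_spike_units: int = 12
    balance: BalanceSpec = field(default_factory=lambda: BalanceSpec(0.01, 0.005, 9))
    true_dry_fraction: float = 0.6
    true_portion_mass: float = 50.0
    seed: int = 0
    parameter_label: str = "T"

    def __post_init__(self) -> None:
        if self.true_lambda < 0 or self.lambda_heterogeneity < 0:
            raise ValueError("true_lambda and lambda_heterogeneity must be >= 0")
        if not (0.0 < self.recovery_rate <= 1.0):
            raise ValueError("recovery_rate must be in (0, 1]")
        if not (0.0 < self.true_dry_fraction <= 1.0):
            raise ValueError("true_dry_fraction must be in (0, 1]")
        if self.true_portion_mass <= 0:
            raise ValueError("true_portion_mass must be positive")
        if min(self.n_samples, self.n_duplicates, self.n_spike_units) < 1 or self.added_per_unit < 1:
            raise ValueError("all design sizes must be positive integers")

    @property
    def true_omega(self) -> float:
        """True contamination, particles per kg dry sediment."""
        return self.true_lambda / (self.true_portion_mass * self.true_dry_fraction / G_PER_KG)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _portion_lambdas(s: TruthScenario, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-portion particle means: lognormal around true_lambda, or constant."""
    if s.lambda_heterogeneity == 0 or s.true_lambda == 0:
        return np.full(n, s.true_lambda)
    params = lognormal_logparams(PoissonLognormalSpec(s.true_lambda, s.lambda_heterogeneity))
    return sample_lambda(params, n, rng)


def generate_duplicates(s: TruthScenario, rng: np.random.Generator | None = None) -> DuplicateSet:
    """Duplicate count pairs: both replicates share one portion lambda.

    Because the pair shares its lambda, the between-portion heterogeneity
    cancels in the difference and Var(d) = 2 * E(observed count): pure
    Poisson within-pair noise.
    """
    rng = s.rng() if rng is None else rng
    lam = _portion_lambdas(s, s.n_duplicates, rng) * s.recovery_rate
    pairs = list(zip(rng.poisson(lam), rng.poisson(lam)))
    return DuplicateSet(pairs, parameter_label=s.parameter_label)


def generate_spikes(s: TruthScenario, rng: np.random.Generator | None = None) -> SpikeSet:
    """Spike-recovery counts: recovered_i ~ Binomial(A, R) per unit.

    Theoretical n_mean = A R and correction factor F = (1 - R)/R.
    """
    rng = s.rng() if rng is None else rng
    recovered = rng.binomial(s.added_per_unit, s.recovery_rate, s.n_spike_units)
    return SpikeSet(recovered, s.added_per_unit, parameter_label=s.parameter_label)


def generate_samples(
    s: TruthScenario,
    rng: np.random.Generator | None = None,
    campaign: str = "SYN1",
    exact_counts: bool = False,
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Monitoring samples plus a truth table (kept separate by design).

    Each sample's observed count is Poisson(lambda_portion * R); the
    gravimetric readings are the true tare/gross masses perturbed by the
    balance truth (one rectangular systematic error plus one repeatability
    error per reading).  ``exact_counts=True`` replaces the Poisson draw
    with the rounded expectation, for noise-free pipeline checks.

    Returns the records and a DataFrame ``sample_id, true_omega_kg`` for
    coverage scoring; the truth is never embedded in the records themselves.
    """
    rng = s.rng() if rng is None else rng
    lam_eff = _portion_lambdas(s, s.n_samples, rng) * s.recovery_rate
    counts = np.round(lam_eff).astype(int) if exact_counts else rng.poisson(lam_eff)

    e_m, s_r, df = s.balance.max_admissible_error, s.balance.repeatability_sd, s.balance.repeatability_df

    def read_mass(true_value: np.ndarray) -> np.ndarray:
        noise = np.zeros_like(true_value)
        if e_m > 0:
            noise = noise + rng.uniform(-e_m, e_m, true_value.shape)
        if s_r > 0:
            noise = noise + s_r * rng.standard_t(df, true_value.shape)
        return true_value + noise

    m_petri_true = np.full(s.n_samples, 20.0)
    wet_true = np.full(s.n_samples, s.true_portion_mass)
    dry_true = wet_true * s.true_dry_fraction
    m_p = read_mass(m_petri_true)
    m_i = read_mass(m_petri_true + wet_true)
    m_f = read_mass(m_petri_true + dry_true)
    # nominal portion mass by difference of two more readings of the same load
    m_nom = read_mass(wet_true + m_petri_true) - read_mass(m_petri_true)

    records, truths = [], []
    for i in range(s.n_samples):
        sid = f"S{i + 1:02d}"
        records.append(
            SampleRecord(
                sample_id=sid,
                campaign=campaign,
                parameter=s.parameter_label,
                count=int(counts[i]),
                portion=PortionMass(float(m_nom[i])),
                dry_record=DryWeightRecord(float(m_p[i]), float(m_i[i]), float(m_f[i])),
            )
        )
        truths.append({"sample_id": sid, "true_omega_kg": s.true_omega})
    return records, pd.DataFrame(truths)
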