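"""Weighing uncertainty of the analytical portion and dry-weight fraction.

Every mass is determined by difference (tare and gross readings), so each
balance error source enters twice: a rectangular systematic component with
half-width E_M (the balance's maximum admissible error, standard uncertainty
u_b = E_M/sqrt(3)) and a repeatability component simulated as a scaled and
shifted Student-t with the stated degrees of freedom.  All masses are in
grams; the single g -> kg conversion happens in the Monte Carlo engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BalanceSpec",
    "DryWeightRecord",
    "PortionMass",
    "standard_uncertainty_systematic",
    "combined_mass_uncertainty",
    "simulate_mass_difference",
    "dry_weight_fraction",
    "simulate_dry_portion_mass",
]

#: Validated working range of the method for the analytical portion, in grams.
PORTION_MASS_RANGE_G = (8.0, 100.0)


@dataclass(frozen=True)
class BalanceSpec:
    """Balance performance: maximum admissible error E_M (g), repeatability s_r (g) and its df."""

    max_admissible_error: float
    repeatability_sd: float
    repeatability_df: int = 9

    def __post_init__(self) -> None:
        if not np.isfinite(self.max_admissible_error) or self.max_admissible_error < 0:
            raise ValueError("max_admissible_error must be finite and >= 0")
        if not np.isfinite(self.repeatability_sd) or self.repeatability_sd < 0:
            raise ValueError("repeatability_sd must be finite and >= 0")
        if int(self.repeatability_df) < 1:
            raise ValueError("repeatability_df must be a positive integer")


@dataclass(frozen=True)
class DryWeightRecord:
    """Petri-dish tare m_P, wet gross m_I and dry gross m_F, in grams."""

    m_petri: float
    m_initial_gross: float
    m_final_gross: float

    def __post_init__(self) -> None:
        if not (self.m_petri > 0 and self.m_initial_gross > 0 and self.m_final_gross > 0):
            raise ValueError("all masses must be positive")
        if not (self.m_petri < self.m_final_gross <= self.m_initial_gross):
            raise ValueError(
                "gravimetric invariant violated: need m_P < m_F <= m_I "
                f"(got m_P={self.m_petri}, m_F={self.m_final_gross}, m_I={self.m_initial_gross})"
            )


@dataclass(frozen=True)
class PortionMass:
    """Nominal conventional mass of the wet analytical portion, in grams."""

    nominal_mass: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.nominal_mass) and self.nominal_mass > 0):
            raise ValueError("nominal_mass must be a positive real")
        lo, hi = PORTION_MASS_RANGE_G
        if not (lo <= self.nominal_mass <= hi):
            warnings.warn(
                f"portion mass {self.nominal_mass} g is outside the validated range {lo}-{hi} g",
                stacklevel=3,
            )


def standard_uncertainty_systematic(balance: BalanceSpec) -> float:
    """u_b = E_M / sqrt(3): rectangular distribution of half-width E_M."""
    return balance.max_admissible_error / np.sqrt(3.0)


def combined_mass_uncertainty(balance: BalanceSpec) -> float:
    """u_m = sqrt(2 u_b^2 + 2 s_r^2); each component counted once per reading, twice per difference."""
    u_b = standard_uncertainty_systematic(balance)
    return float(np.sqrt(2.0 * u_b**2 + 2.0 * balance.repeatability_sd**2))


def simulate_mass_difference(
    nominal: float, balance: BalanceSpec, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate a mass determined by difference of two readings.

    Each draw is ``nominal + U1 + U2 + s_r (T1 + T2)`` with independent
    U ~ Uniform(-E_M, +E_M) and T ~ Student-t(df) per reading.  The empirical
    sd approaches u_m from the quadrature combination, inflated by
    sqrt(df/(df-2)) from the t repeatability term.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if balance.repeatability_sd > 0 and balance.repeatability_df <= 2:
        raise ValueError("repeatability_df must exceed 2: Student-t variance is infinite otherwise")
    e_m, s_r, df = balance.max_admissible_error, balance.repeatability_sd, int(balance.repeatability_df)
    out = np.full(n_draws, float(nominal))
    if e_m > 0:
        out += rng.uniform(-e_m, e_m, n_draws) + rng.uniform(-e_m, e_m, n_draws)
    if s_r > 0:
        out += s_r * (rng.standard_t(df, n_draws) + rng.standard_t(df, n_draws))
    return out


def dry_weight_fraction(rec: DryWeightRecord) -> float:
    """W_d = (m_F - m_P) / (m_I - m_P), the dry-to-wet sediment mass ratio."""
    denom = rec.m_initial_gross - rec.m_petri
    if denom <= 0:
        raise ValueError("invalid record: m_I must exceed m_P")
    return (rec.m_final_gross - rec.m_petri) / denom


def simulate_dry_portion_mass(
    portion: PortionMass,
    rec: DryWeightRecord,
    balance: BalanceSpec,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate the dry analytical-portion mass m * W_d, in grams.

    Per draw, the portion mass m and the two differences (m_F - m_P) and
    (m_I - m_P) are each simulated independently as masses-by-difference;
    the result is m* (m_F - m_P)* / (m_I - m_P)*.  Non-positive draws are
    rejected and redrawn; a warning is emitted when more than 0.1 % of the
    requested draws needed rejection.  Draw order: m, numerator, denominator.
    """
    num_nominal = rec.m_final_gross - rec.m_petri
    den_nominal = rec.m_initial_gross - rec.m_petri

    def one_round(n: int) -> np.ndarray:
        m = simulate_mass_difference(portion.nominal_mass, balance, n, rng)
        num = simulate_mass_difference(num_nominal, balance, n, rng)
        den = simulate_mass_difference(den_nominal, balance, n, rng)
        return m * num / den

    out = one_round(n_draws)
    n_rejected = 0
    bad = ~(out > 0)
    while np.any(bad):
        n_rejected += int(bad.sum())
        out[bad] = one_round(int(bad.sum()))
        bad = ~(out > 0)
    if n_rejected > 0.001 * n_draws:
        warnings.warn(
            f"{n_rejected} of {n_draws} dry-mass draws were non-positive and redrawn "
            "(> 0.1 %); the balance uncertainty is large relative to the masses",
            stacklevel=2,
        )
    return out
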