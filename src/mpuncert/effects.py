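"""Estimators for random and systematic counting effects.

Random effects (replicate-to-replicate count scatter) are estimated from
duplicate analyses: Var(lambda_r) = Var(d(C)) / 2, half the variance of the
count differences, because the difference of two Poisson counts has twice
the per-count variance.

Systematic effects (particle losses during sample preparation) are estimated
from spike-recovery experiments: A particles are added per spike unit, n are
recovered, and the relative correction factor F = (A - n_mean)/n_mean turns
an observed count C into the loss-corrected count C_C = C (1 + F) = C A / n_mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .poislog import PoissonLognormalSpec

__all__ = [
    "DuplicateSet",
    "RandomEffects",
    "SpikeSet",
    "SystematicEffects",
    "estimate_random_effects",
    "estimate_systematic_effects",
    "systematic_lambda_spec",
]


def _check_natural(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr != np.floor(arr))):
        raise ValueError(f"{what} must be nonnegative integers")
    return arr.astype(np.int64)


@dataclass(frozen=True)
class DuplicateSet:
    """Count pairs from duplicate analyses of the same samples."""

    pairs: tuple
    parameter_label: str = ""

    def __init__(self, pairs: Sequence, parameter_label: str = ""):
        pairs = tuple((int(a), int(b)) for a, b in pairs)
        flat = [x for p in pairs for x in p]
        _check_natural(flat, "duplicate counts")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "parameter_label", parameter_label)

    @property
    def differences(self) -> np.ndarray:
        """Signed differences, first minus second replicate."""
        return np.array([a - b for a, b in self.pairs], dtype=float)


@dataclass(frozen=True)
class RandomEffects:
    """Pooled random-effects variance Var(lambda_r), in counts squared."""

    var_lambda_r: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.var_lambda_r) or self.var_lambda_r < 0:
            raise ValueError(f"var_lambda_r must be finite and >= 0, got {self.var_lambda_r}")


@dataclass(frozen=True)
class SpikeSet:
    """Recovered counts from spike units, each fortified with ``added_per_unit`` particles."""

    recovered: tuple
    added_per_unit: int
    parameter_label: str = ""

    def __init__(self, recovered: Sequence[int], added_per_unit: int, parameter_label: str = ""):
        rec = tuple(int(n) for n in recovered)
        _check_natural(rec, "recovered counts")
        a = int(added_per_unit)
        if a < 1:
            raise ValueError("added_per_unit must be a positive integer")
        if any(n > a for n in rec):
            raise ValueError(f"invalid spike: recovered count exceeds the {a} particles added per unit")
        if len(rec) < 2:
            raise ValueError("at least 2 spike units are required")
        object.__setattr__(self, "recovered", rec)
        object.__setattr__(self, "added_per_unit", a)
        object.__setattr__(self, "parameter_label", parameter_label)


@dataclass(frozen=True)
class SystematicEffects:
    """Spike-derived recovery statistics and correction factor F = (A - n_mean)/n_mean."""

    mean_recovered: float
    var_recovered: float
    var_mean_recovered: float
    correction_factor: float
    added_per_unit: int

    def __post_init__(self) -> None:
        if self.mean_recovered <= 0:
            raise ValueError("mean_recovered must be positive (no-recovery data cannot define a correction)")
        if self.var_recovered < 0 or self.var_mean_recovered < 0:
            raise ValueError("variances must be nonnegative")


def estimate_random_effects(duplicates: DuplicateSet, center: str = "mean") -> RandomEffects:
    """Estimate Var(lambda_r) as half the variance of duplicate differences.

    Parameters
    ----------
    duplicates
        At least two count pairs.
    center
        ``"mean"`` (default) uses the mean-subtracted sample variance of the
        differences with a (k-1) denominator.  ``"zero"`` uses the classical
        zero-mean duplicate formula sum(d^2)/k for Var(d), i.e.
        Var(lambda_r) = sum(d^2)/(2k); this variant is invariant to swapping
        the two replicate columns globally.
    """
    d = duplicates.differences
    if d.size < 2:
        raise ValueError("insufficient replication: at least 2 duplicate pairs are required")
    if center == "mean":
        var_d = float(np.var(d, ddof=1))
    elif center == "zero":
        var_d = float(np.mean(d * d))
    else:
        raise ValueError(f"center must be 'mean' or 'zero', got {center!r}")
    return RandomEffects(var_lambda_r=var_d / 2.0)


def estimate_systematic_effects(spikes: SpikeSet) -> SystematicEffects:
    """Estimate the recovery correction factor and its uncertainty from spikes.

    n_mean = mean(recovered); Var(n) is the (M-1)-denominator sample
    variance; Var(n_mean) = Var(n)/M; F = (A - n_mean)/n_mean so that the
    corrected count C (1 + F) = C A / n_mean applies the inverse of the mean
    recovery.
    """
    rec = np.asarray(spikes.recovered, dtype=float)
    m = rec.size
    n_bar = float(np.mean(rec))
    if n_bar == 0:
        raise ValueError("no particles recovered in any spike unit: correction factor undefined")
    var_n = float(np.var(rec, ddof=1))
    a = spikes.added_per_unit
    f = (a - n_bar) / n_bar
    if f < 0:
        warnings.warn(
            f"mean recovery {n_bar:.3g} exceeds the {a} particles added "
            "(analytical contamination?); correction factor is negative and not truncated",
            stacklevel=2,
        )
    return SystematicEffects(
        mean_recovered=n_bar,
        var_recovered=var_n,
        var_mean_recovered=var_n / m,
        correction_factor=f,
        added_per_unit=a,
    )


def systematic_lambda_spec(count: int, eff: SystematicEffects) -> PoissonLognormalSpec:
    """Expected value and variance of the systematic count correction lambda_s.

    E(lambda_s) = C F.  Var(lambda_s) follows from the first-order law of
    propagation of uncertainty applied to C F = C (A/n_mean - 1) with C and
    A exact constants:

        Var(lambda_s) = C^2 (A / n_mean^2)^2 Var(n_mean)

    A zero observed count gives the degenerate (0, 0) spec: no correction.
    """
    c = int(count)
    if c < 0:
        raise ValueError("count must be a nonnegative integer")
    if c == 0:
        return PoissonLognormalSpec(0.0, 0.0)
    a, n_bar = eff.added_per_unit, eff.mean_recovered
    expected = c * eff.correction_factor
    variance = (c * a / (n_bar * n_bar)) ** 2 * eff.var_mean_recovered
    return PoissonLognormalSpec(float(expected), float(variance))
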