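"""Moments and MGF of sums of independent negative-binomial counts.

A bulk transcriptome's count for one gene is the sum of contributions from
many cell populations; if each contribution is negative binomial with mean
mu_c and over-dispersion phi_c (variance mu + mu^2 phi), the sum is a
compound distribution whose moment-matched NB approximation has

    mu  = sum_c mu_c
    phi = sum_c (mu_c / mu)^2 phi_c

For N components of similar mean, phi is ~N times smaller than the mean
component over-dispersion, so the compound distribution approaches a
Poisson as populations accumulate — the analytic justification for the
Poisson likelihood used by the exposure fit. phi_c = 0 denotes the Poisson
limit of a component and is handled analytically throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class NBComponentSet:
    """Means and over-dispersions of the NB components being summed."""

    means: np.ndarray
    overdispersions: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.atleast_1d(np.asarray(self.means, float))
        self.overdispersions = np.atleast_1d(np.asarray(self.overdispersions, float))
        if self.means.shape != self.overdispersions.shape:
            raise ValueError("means and overdispersions must have the same length")
        if self.means.size < 1:
            raise ValueError("need at least one component")
        if np.any(self.means <= 0):
            raise ValueError("all means must be positive")
        if np.any(self.overdispersions < 0):
            raise ValueError("over-dispersions must be >= 0 (0 = Poisson limit)")

    @property
    def n_components(self) -> int:
        return self.means.size


@dataclass
class MatchedNB:
    """Moment-matched NB approximation to the compound distribution."""

    mean: float
    overdispersion: float

    @property
    def variance(self) -> float:
        return self.mean + self.mean**2 * self.overdispersion


def compound_mean(components: NBComponentSet) -> float:
    """Mean of the compound distribution: the sum of component means."""
    return float(components.means.sum())


def compound_variance(components: NBComponentSet) -> float:
    """Variance of the sum: sum of component variances (independence)."""
    mu, phi = components.means, components.overdispersions
    return float(np.sum(mu + mu**2 * phi))


def matched_overdispersion(components: NBComponentSet) -> float:
    """Moment-matched over-dispersion: sum_c (mu_c/mu)^2 phi_c.

    For N components with equal mean and over-dispersion phi0 this is
    exactly phi0 / N; it is 0 when every component is Poisson.
    """
    mu = compound_mean(components)
    w = components.means / mu
    return float(np.sum(w**2 * components.overdispersions))


def matched_nb(components: NBComponentSet) -> MatchedNB:
    """NB approximation matching the compound mean and variance exactly."""
    return MatchedNB(
        mean=compound_mean(components),
        overdispersion=matched_overdispersion(components),
    )


def compound_mgf(components: NBComponentSet, t: float) -> float:
    """MGF of the summed components at t: product of component MGFs.

    NB components contribute (1 + mu_c phi_c (1 - e^t))^(-1/phi_c); Poisson
    components (phi_c = 0) contribute exp(mu_c (e^t - 1)). Valid only where
    every NB factor's base is positive.
    """
    et = np.exp(float(t))
    log_m = 0.0
    for i, (mu, phi) in enumerate(zip(components.means, components.overdispersions)):
        if phi == 0:
            log_m += mu * (et - 1)
        else:
            base = 1 + mu * phi * (1 - et)
            if base <= 0:
                raise ValueError(
                    f"t={t} outside the MGF convergence domain of component {i} "
                    f"(mu={mu}, phi={phi})"
                )
            log_m += -np.log(base) / phi
    return float(np.exp(log_m))


def sample_compound(
    components: NBComponentSet, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw sums of independent NB/Poisson components (for validation)."""
    total = np.zeros(size)
    for mu, phi in zip(components.means, components.overdispersions):
        if phi == 0:
            total += rng.poisson(mu, size)
        else:
            r = 1.0 / phi
            total += rng.negative_binomial(r, r / (r + mu), size)
    return total
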