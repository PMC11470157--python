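"""Nest survival model: exposure-interval likelihood on daily survival.

The fate of nest *i,j* over exposure interval *h* of length l days is
Bernoulli with success probability phi_ij^l, where phi_ij is the daily
survival probability::

    y_ijh       ~ Bernoulli(phi_ij ^ l_ijh)
    logit(phi)  = pi_j + gamma_d * d_ij + gamma_f * f_{i,j-1}
                  + gamma_dxf * d_ij * f_{i,j-1} + eps_ind_i
    pi_j        ~ normal(delta, sigma_yr^2)        (random year intercepts)
    eps_ind_i   ~ normal(0, sigma_ind^2)

Dispersal distance d enters in raw meters (the per-meter coefficients are
printed at ~1e-4 magnitude). Nest survival over the full exposure period
is phi^28. Missing previous fates share the fidelity model's
beta-prior-based Bernoulli submodel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data_model import ExposureInterval
from .fidelity import DailySurvivalPrior, missing_fate_prob

__all__ = [
    "SurvivalParams",
    "daily_survival",
    "survival_loglik",
    "nest_survival_28",
    "resolve_missing_fates_survival",
    "log1m_phi_pow",
]


@dataclass
class SurvivalParams:
    """Full parameter vector of the nest survival model.

    ``delta`` is mean daily survival across years on the logit scale for
    previously successful birds; ``pi_yr`` are the year intercepts drawn
    around it.
    """

    delta: float = 0.0
    gamma_d: float = 0.0
    gamma_f: float = 0.0
    gamma_dxf: float = 0.0
    sigma_yr: float = 0.0
    sigma_ind: float = 0.0
    pi_yr: dict[int, float] = field(default_factory=dict)
    eps_ind: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.sigma_yr < 0 or self.sigma_ind < 0:
            raise ValueError("random-effect SDs must be >= 0")


def _inv_logit(x):
    return expit(x)


def daily_survival(
    d: float,
    f: int,
    params: SurvivalParams,
    year: int,
    individual: str | None = None,
) -> float:
    """Daily nest survival probability for one nest.

    The year intercept defaults to ``delta`` when the year has no fitted
    ``pi_yr`` entry (prediction for an average year).
    """
    if d < 0:
        raise ValueError("dispersal distance must be >= 0")
    if f not in (0, 1):
        raise ValueError("previous fate must be resolved to 0 or 1")
    pi_j = params.pi_yr.get(year, params.delta)
    eps_i = params.eps_ind.get(individual, 0.0) if individual else 0.0
    x = pi_j + params.gamma_d * d + params.gamma_f * f + params.gamma_dxf * d * f + eps_i
    if not np.isfinite(x):
        raise ValueError("non-finite linear predictor")
    return float(_inv_logit(x))


def log1m_phi_pow(log_phi, l):
    """log(1 - phi^l) computed as log1p(-exp(l*log(phi))).

    Stable for phi near 1, where 1 - phi^l underflows in direct form.
    """
    return np.log1p(-np.exp(np.asarray(l, dtype=float) * log_phi))


def survival_loglik(
    intervals: list[ExposureInterval],
    params: SurvivalParams,
    fates: np.ndarray,
    dispersal_by_nest: dict[str, float],
) -> float:
    """Log likelihood of the exposure-interval model.

    ``fates`` is the resolved previous-fate vector aligned with
    ``intervals``; ``dispersal_by_nest`` maps nest_id to dispersal
    distance in meters.
    """
    params.validate()
    fates = np.asarray(fates, dtype=int)
    if len(fates) != len(intervals):
        raise ValueError("fates length mismatch")
    total = 0.0
    for iv, f in zip(intervals, fates):
        d = dispersal_by_nest[iv.nest_id]
        phi = daily_survival(d, int(f), params, iv.year, iv.individual_id)
        log_phi = np.log(phi)
        if iv.outcome == 1:
            term = iv.length_days * log_phi
        else:
            if phi >= 1.0:
                raise ValueError(
                    f"nest {iv.nest_id}: failure observed but daily survival "
                    "is exactly 1 (data/parameter conflict)"
                )
            term = float(log1m_phi_pow(log_phi, iv.length_days))
        if not np.isfinite(term):
            raise ValueError(f"non-finite likelihood term for nest {iv.nest_id}")
        total += term
    return total


def nest_survival_28(phi: float) -> float:
    """Nest survival over the 28-day average exposure period: phi**28."""
    phi = float(phi)
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must be in [0, 1]")
    return phi**28


def resolve_missing_fates_survival(
    last_check_age: int, phi: np.ndarray
) -> float:
    """Prior failure probability for a nest with unknown previous fate.

    Shares the fidelity model's submodel exactly (single implementation),
    so identical inputs give bit-identical results across both models.
    """
    return missing_fate_prob(last_check_age, phi)


def sample_prior_fail_probs(
    last_check_ages: np.ndarray,
    years_prev: np.ndarray,
    prior: DailySurvivalPrior,
    rng: np.random.Generator,
) -> np.ndarray:
    """One joint draw of prior failure probabilities for many records.

    Draws a single (28, n_years) daily-survival matrix from the beta
    priors, then applies the remaining-exposure product per record (ages
    ``m..28`` in the record's previous year).
    """
    phi = prior.sample_phi(rng)
    out = np.empty(len(last_check_ages))
    for i, (m, yr) in enumerate(zip(last_check_ages, years_prev)):
        col = prior.column(int(yr))
        out[i] = missing_fate_prob(int(m), phi[int(m) - 1 :, col])
    return out
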