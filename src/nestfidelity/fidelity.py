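"""Nest-site fidelity model: dispersal distance on the log scale.

Log dispersal distance of individual *i* in year *j* follows a
location-scale Student-t whose scale and degrees of freedom differ by
previous nest fate k (0 success, 1 fail)::

    log d_ij ~ t(g_ij, sigma_k^2, kappa_k)
    g_ij     = alpha_j + beta_f * f_{i,j-1}
               + beta_fxw * f_{i,j-1} * w_{j-1} + eps_ind_i
    alpha_j  = mu + eta_s * s_j + eta_w * w_{j-1} + eps_yr_j

with normal random effects for individual and year. Missing previous
fates are latent Bernoulli variables whose prior failure probability is
one minus the product of age- and year-specific daily nest survival
probabilities from the age at last check through 28 days; those daily
survival probabilities carry informative beta priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .data_model import MAX_NEST_AGE, EncounterPair

__all__ = [
    "FidelityParams",
    "DailySurvivalPrior",
    "linear_predictor_g",
    "t_log_density",
    "fidelity_loglik",
    "missing_fate_prob",
    "beta_prior_from_moments",
    "expected_dispersal",
]


@dataclass
class FidelityParams:
    """Full parameter vector of the fidelity model.

    Coefficients are on the log-meter scale; ``sigma_resid`` and ``kappa``
    are two-vectors indexed by previous fate (0 success, 1 fail).
    """

    mu: float = np.log(125.5)
    beta_f: float = 0.0
    beta_fxw: float = 0.0
    eta_s: float = 0.0
    eta_w: float = 0.0
    sigma_ind: float = 0.0
    sigma_yr: float = 0.0
    sigma_resid: tuple[float, float] = (1.0, 1.0)
    kappa: tuple[float, float] = (30.0, 30.0)
    eps_ind: dict[str, float] = field(default_factory=dict)
    eps_yr: dict[int, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.sigma_ind < 0 or self.sigma_yr < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if any(s <= 0 for s in self.sigma_resid):
            raise ValueError("residual scales sigma_k must be > 0")
        if any(k <= 0 for k in self.kappa):
            raise ValueError("degrees of freedom kappa_k must be > 0")


@dataclass
class DailySurvivalPrior:
    """Beta priors for age- and year-specific daily nest survival.

    ``alpha``/``beta`` have shape (28, n_years): element (a-1, j) is the
    beta prior for the probability a nest of age *a* survives day *a* in
    year *j*. Feeds the missing-previous-fate submodel of both models.
    """

    alpha: np.ndarray
    beta: np.ndarray
    years: list[int]

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha/beta shape mismatch")
        if self.alpha.shape[0] != MAX_NEST_AGE:
            raise ValueError(f"need {MAX_NEST_AGE} age rows")
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("beta parameters must be > 0")
        self._year_col = {y: k for k, y in enumerate(self.years)}

    @classmethod
    def neutral(
        cls,
        years: list[int],
        mean: float = 0.99,
        sd: float = 0.005,
    ) -> "DailySurvivalPrior":
        """Constant moment-matched prior for all ages and years.

        The default (mean 0.99, sd 0.005 daily survival) is a neutral
        stand-in for study-area-specific published estimates; supply a
        CSV of (age, year, mean, sd) via :meth:`from_table` to use real
        informative priors.
        """
        a, b = beta_prior_from_moments(mean, sd)
        shape = (MAX_NEST_AGE, len(years))
        return cls(np.full(shape, a), np.full(shape, b), list(years))

    @classmethod
    def from_table(cls, df, years: list[int]) -> "DailySurvivalPrior":
        """Build from a tidy table with columns age, year, mean, sd.

        Years absent from the table fall back to the across-year mean of
        the age-specific moments (the convention used when a year lacks
        published estimates).
        """
        alpha = np.empty((MAX_NEST_AGE, len(years)))
        beta = np.empty((MAX_NEST_AGE, len(years)))
        mean_by_age = df.groupby("age")[["mean", "sd"]].mean()
        for k, yr in enumerate(years):
            sub = df[df["year"] == yr].set_index("age")
            for a in range(1, MAX_NEST_AGE + 1):
                if a in sub.index:
                    m, s = float(sub.loc[a, "mean"]), float(sub.loc[a, "sd"])
                elif a in mean_by_age.index:
                    m, s = (
                        float(mean_by_age.loc[a, "mean"]),
                        float(mean_by_age.loc[a, "sd"]),
                    )
                else:
                    raise ValueError(f"no prior information for nest age {a}")
                alpha[a - 1, k], beta[a - 1, k] = beta_prior_from_moments(m, s)
        return cls(alpha, beta, list(years))

    def column(self, year: int) -> int:
        """Column index of ``year``; unknown years use the first column
        (neutral priors are year-constant, so this only matters for
        table-built priors)."""
        return self._year_col.get(year, 0)

    def sample_phi(self, rng: np.random.Generator) -> np.ndarray:
        """One draw of the full (28, n_years) daily-survival matrix."""
        return rng.beta(self.alpha, self.beta)


# ---------------------------------------------------------------------------
# Likelihood pieces
# ---------------------------------------------------------------------------


def linear_predictor_g(pair: EncounterPair, params: FidelityParams) -> float:
    """Expected log dispersal distance g_ij for one encounter pair."""
    if pair.prev_fate is None:
        raise ValueError(
            "previous fate is missing; it must be resolved (imputation "
            "happens inside the sampler)"
        )
    f = pair.prev_fate
    w = pair.flood_prev
    s = pair.spring_index
    eps_i = params.eps_ind.get(pair.individual_id, 0.0)
    eps_j = params.eps_yr.get(pair.year_j, 0.0)
    g = (
        params.mu
        + params.eta_s * s
        + params.eta_w * w
        + eps_j
        + params.beta_f * f
        + params.beta_fxw * f * w
        + eps_i
    )
    if not np.isfinite(g):
        raise ValueError("non-finite linear predictor")
    return float(g)


def t_log_density(x, loc, scale, df):
    """Log density of the location-scale Student-t distribution.

    Vectorized over any broadcastable combination of arguments.
    """
    scale = np.asarray(scale, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.any(scale <= 0):
        raise ValueError("scale must be > 0")
    if np.any(df <= 0):
        raise ValueError("df must be > 0")
    z = (np.asarray(x, dtype=float) - loc) / scale
    return (
        special.gammaln((df + 1.0) / 2.0)
        - special.gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
        - (df + 1.0) / 2.0 * np.log1p(z * z / df)
    )


def fidelity_loglik(
    pairs: list[EncounterPair],
    params: FidelityParams,
    fates: np.ndarray,
    distance_floor_m: float = 1.0,
) -> float:
    """Log likelihood of the fidelity model over ``pairs``.

    ``fates`` is the resolved previous-fate vector (0/1) aligned with
    ``pairs``; distances are floored at ``distance_floor_m`` before the
    log transform.
    """
    params.validate()
    fates = np.asarray(fates, dtype=int)
    if len(fates) != len(pairs):
        raise ValueError("fates length mismatch")
    total = 0.0
    sig = np.asarray(params.sigma_resid, dtype=float)
    kap = np.asarray(params.kappa, dtype=float)
    for pair, f in zip(pairs, fates):
        resolved = EncounterPair(
            individual_id=pair.individual_id,
            year_j=pair.year_j,
            dispersal_m=pair.dispersal_m,
            prev_fate=int(f),
            flood_prev=pair.flood_prev,
            spring_index=pair.spring_index,
            prev_last_check_age=pair.prev_last_check_age,
        )
        g = linear_predictor_g(resolved, params)
        logd = np.log(max(pair.dispersal_m, distance_floor_m))
        term = float(t_log_density(logd, g, sig[f], kap[f]))
        if not np.isfinite(term):
            raise ValueError(
                f"non-finite likelihood term for pair "
                f"{pair.individual_id}/{pair.year_j}"
            )
        total += term
    return total


def missing_fate_prob(last_check_age: int, phi: np.ndarray) -> float:
    """Prior probability that a nest of unknown fate FAILED.

    ``phi`` holds daily survival probabilities for ages ``last_check_age``
    through 28 (inclusive); the failure probability is one minus their
    product — the chance the nest did not survive the exposure remaining
    after it was last seen alive.
    """
    m = int(last_check_age)
    if m < 1:
        raise ValueError("last_check_age must be >= 1")
    if m > MAX_NEST_AGE:
        warnings.warn(
            f"last_check_age {m} > {MAX_NEST_AGE}; clamping", stacklevel=2
        )
        m = MAX_NEST_AGE
    phi = np.asarray(phi, dtype=float)
    n_needed = MAX_NEST_AGE - m + 1
    if phi.shape[-1] != n_needed:
        raise ValueError(
            f"need {n_needed} daily survival values for ages {m}..{MAX_NEST_AGE}"
        )
    if np.any(phi <= 0) or np.any(phi > 1):
        raise ValueError("daily survival probabilities must be in (0, 1]")
    return float(1.0 - np.prod(phi))


def beta_prior_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched beta parameters for a given mean and SD.

    Requires ``sd**2 < mean * (1 - mean)`` (the variance bound of any
    distribution on [0, 1] with that mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise ValueError(
            f"infeasible moments: sd^2={var:.4g} >= mean(1-mean)={bound:.4g}"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def expected_dispersal(
    posterior,
    f: int,
    w: int,
    rng: np.random.Generator | None = None,
    hpdi_mass: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Marginalized expected dispersal distance (meters) for a bird with
    previous fate ``f`` after a flood (``w=1``) or ordinary (``w=0``) year.

    For every posterior draw, computes
    ``exp(mu + eta_w*w + beta_f*f + beta_fxw*f*w + eps_yr* + eps_ind*)``
    with fresh random-effect draws ``eps* ~ N(0, sigma^2)`` so the
    prediction accounts for among-year and among-individual variation
    (spring index held at its zero mean). Returns the posterior median
    and HPDI of those draws; the median is the summary of choice because
    the mean of a log-t is undefined for small degrees of freedom.
    """
    from .inference import hpdi as _hpdi  # local import avoids a cycle

    if rng is None:
        rng = np.random.default_rng(0)
    mu = posterior.stacked("mu")
    if mu.size == 0:
        raise ValueError("empty posterior")
    eta_w = posterior.stacked("eta_w")
    beta_f = posterior.stacked("beta_f")
    beta_fxw = posterior.stacked("beta_fxw")
    sig_ind = posterior.stacked("sigma_ind")
    sig_yr = posterior.stacked("sigma_yr")
    n = mu.size
    eps_yr = rng.standard_normal(n) * sig_yr
    eps_ind = rng.standard_normal(n) * sig_ind
    log_pred = mu + eta_w * w + beta_f * f + beta_fxw * f * w + eps_yr + eps_ind
    pred = np.exp(log_pred)
    lo, hi = _hpdi(pred, hpdi_mass)
    return float(np.median(pred)), (lo, hi)
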