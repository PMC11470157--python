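"""MCMC engine and posterior summaries.

The sampler is an adaptive scalar random-walk Metropolis-within-Gibbs:

* each unbounded or interval-bounded scalar parameter gets a Gaussian
  random-walk proposal whose log step size adapts toward a 0.44
  acceptance rate (Robbins–Monro) during burn-in and is frozen after;
* zero-centered random effects use the noncentered parameterization
  ``eps = sigma * z`` with ``z ~ N(0,1)``; the ``z`` vectors are updated
  with vectorized single-site proposals, valid because observations
  partition by individual and by year so components are conditionally
  independent given everything else;
* latent missing previous fates are Gibbs-sampled each iteration from
  their exact Bernoulli full conditionals, combining the beta-prior
  failure probability with the likelihood terms that depend on the fate.

Inference runs several chains from overdispersed starts; convergence is
checked with the split-chain Gelman–Rubin statistic, and posteriors are
summarized by the median, the 95% highest posterior density interval,
and the sign probability rho (fraction of draws sharing the sign of the
posterior mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .data_model import EncounterPair, ExposureInterval, floor_distances
from .fidelity import DailySurvivalPrior
from .survival import sample_prior_fail_probs

__all__ = [
    "MCMCConfig",
    "ParamSpec",
    "Model",
    "PosteriorChains",
    "run_mcmc",
    "gelman_rubin",
    "hpdi",
    "sign_probability",
    "effective_sample_size",
    "fit_fidelity",
    "fit_survival",
    "FidelityMCMC",
    "SurvivalMCMC",
]

_ADAPT_TARGET = 0.44


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    The default run length (3 chains x 80,000 iterations, 40,000 burn-in)
    matches the full analysis; :meth:`fast` is the preset used by the
    acceptance suite (3 x 10,000 / 5,000).
    """

    n_chains: int = 3
    n_iterations: int = 80_000
    n_burnin: int = 40_000
    thin: int = 1
    seed: int = 0
    adapt_target: float = _ADAPT_TARGET
    init_jitter: float = 1.0

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for the Gelman-Rubin check")

    @classmethod
    def full_preset(cls, seed: int = 0) -> "MCMCConfig":
        return cls(seed=seed)

    @classmethod
    def fast(cls, seed: int = 0) -> "MCMCConfig":
        return cls(n_iterations=10_000, n_burnin=5_000, seed=seed)


@dataclass
class ParamSpec:
    """One sampled block: a scalar or an iid-N(0,1) latent vector."""

    name: str
    lower: float = -np.inf
    upper: float = np.inf
    step: float = 0.2
    size: int | None = None  # None -> scalar


class Model:
    """Interface the engine samples from.

    Subclasses bundle their data and expose the joint log posterior of
    the continuous parameters (given current latent fates), per-component
    conditional log posteriors for latent vectors, and a Gibbs update for
    discrete latents.
    """

    def scalar_specs(self) -> list[ParamSpec]:
        raise NotImplementedError

    def vector_specs(self) -> list[ParamSpec]:
        return []

    def init_state(self, rng: np.random.Generator, jitter: float) -> dict:
        raise NotImplementedError

    def logp(self, state: dict) -> float:
        raise NotImplementedError

    def group_logp(self, state: dict, name: str) -> np.ndarray:
        raise NotImplementedError

    def resample_latents(self, state: dict, rng: np.random.Generator) -> None:
        return None

    def aux_update(self, state: dict, rng: np.random.Generator) -> None:
        """Optional extra MH moves (e.g. likelihood-invariant
        reparameterization moves); no-op by default."""
        return None

    def tracked_latents(self) -> list[str]:
        return []


class PosteriorChains:
    """Multi-chain MCMC draws with cached posterior summaries.

    ``draws[name]`` has shape (n_chains, n_draws) for scalars or
    (n_chains, n_draws, k) for vectors.
    """

    def __init__(
        self,
        draws: dict[str, np.ndarray],
        acceptance: dict[str, float] | None = None,
    ):
        if not draws:
            raise ValueError("no draws")
        lengths = {v.shape[:2] for v in draws.values()}
        if len(lengths) != 1:
            raise ValueError("chains must have equal draw counts")
        self.draws = draws
        self.acceptance = acceptance or {}
        (self.n_chains, self.n_draws) = next(iter(lengths))
        self._summary: pd.DataFrame | None = None

    @property
    def parameter_names(self) -> list[str]:
        return list(self.draws)

    def scalar_names(self) -> list[str]:
        return [k for k, v in self.draws.items() if v.ndim == 2]

    def get(self, name: str) -> np.ndarray:
        return self.draws[name]

    def stacked(self, name: str) -> np.ndarray:
        v = self.draws[name]
        return v.reshape(-1, *v.shape[2:])

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.draws.items()})

    def summary(self, hpdi_mass: float = 0.95) -> pd.DataFrame:
        """Per-scalar-parameter median, HPDI, rho, split R-hat and ESS."""
        if self._summary is not None:
            return self._summary
        rows = []
        for name in self.scalar_names():
            v = self.draws[name]
            flat = v.reshape(-1)
            lo, hi = hpdi(flat, hpdi_mass)
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(flat)),
                    "hpdi_lo": lo,
                    "hpdi_hi": hi,
                    "rho": sign_probability(flat),
                    "rhat": gelman_rubin(v),
                    "ess": effective_sample_size(v),
                }
            )
        self._summary = pd.DataFrame(rows).set_index("parameter")
        return self._summary

    @property
    def converged(self) -> bool:
        return bool((self.summary()["rhat"] <= 1.1).all())

    def to_tidy_frame(self) -> pd.DataFrame:
        """Tidy draws: columns chain, iteration, parameter, value."""
        frames = []
        for name in self.scalar_names():
            v = self.draws[name]
            ch, it = np.meshgrid(
                np.arange(self.n_chains), np.arange(self.n_draws), indexing="ij"
            )
            frames.append(
                pd.DataFrame(
                    {
                        "chain": ch.ravel(),
                        "iteration": it.ravel(),
                        "parameter": name,
                        "value": v.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    ``chains`` has shape (n_chains, n_draws); each chain is split in half
    before the between/within variance comparison, which also flags
    non-stationarity within a single chain. Degenerate (zero-variance)
    draws return 1.0 with a warning by convention.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (n_chains>=2, n_draws) array")
    if chains.shape[1] < 10:
        raise ValueError("need >= 10 draws per chain")
    n_half = chains.shape[1] // 2
    halves = np.concatenate(
        [chains[:, :n_half], chains[:, n_half : 2 * n_half]], axis=0
    )
    w = halves.var(axis=1, ddof=1).mean()
    if w == 0.0:
        warnings.warn(
            "zero within-chain variance; R-hat degenerate, returning 1.0",
            stacklevel=2,
        )
        return 1.0
    b_over_n = halves.mean(axis=1).var(ddof=1)
    var_plus = (n_half - 1) / n_half * w + b_over_n
    return float(np.sqrt(var_plus / w))


def hpdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest posterior density interval by exhaustive window search.

    Returns the shortest interval (x[i], x[i + floor(mass*n)]) over the
    sorted samples, i.e. the narrowest window covering at least ``mass``
    of the draws (Chen–Shao algorithm).
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    offset = int(np.floor(mass * n))
    if offset < 1 or offset >= n:
        if n >= 1 and offset >= n:
            return float(x[0]), float(x[-1])
        raise ValueError(f"too few samples ({n}) for mass {mass}")
    widths = x[offset:] - x[: n - offset]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + offset])


def sign_probability(samples: np.ndarray) -> float:
    """Fraction of draws sharing the sign of the sample mean (rho).

    Zeros count as matching either sign; a mean of exactly zero is
    evaluated against the positive sign with a warning.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty samples")
    m = x.mean()
    if m == 0.0:
        warnings.warn("sample mean exactly 0; rho computed vs positive sign",
                      stacklevel=2)
        m = 1.0
    if m > 0:
        return float(np.mean(x >= 0))
    return float(np.mean(x <= 0))


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk effective sample size of one parameter's (n_chains, n_draws)
    draws, via arviz."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(np.asarray(chains, dtype=float)))


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


def run_mcmc(model: Model, cfg: MCMCConfig) -> PosteriorChains:
    """Sample ``model`` with adaptive random-walk Metropolis-within-Gibbs.

    Per iteration: latent discrete variables are Gibbs-refreshed, each
    scalar parameter takes one adaptive random-walk step against the full
    log posterior, and each latent vector takes vectorized single-site
    steps against per-component conditionals. Chains are reproducible:
    chain *c* uses ``default_rng([seed, c])``.
    """
    scalars = model.scalar_specs()
    vectors = [v for v in model.vector_specs() if v.size]
    latents = model.tracked_latents()
    target = cfg.adapt_target

    all_draws: dict[str, list[np.ndarray]] = {}
    acc_totals: dict[str, float] = {s.name: 0.0 for s in scalars}
    n_kept_total = 0

    for chain in range(cfg.n_chains):
        rng = np.random.default_rng([cfg.seed, chain])
        state = model.init_state(rng, cfg.init_jitter)
        model.resample_latents(state, rng)
        lp = model.logp(state)
        if not np.isfinite(lp):
            raise RuntimeError(
                f"non-finite initial log posterior in chain {chain}; "
                f"state: { {k: np.asarray(v).tolist() for k, v in state.items()} }"
            )
        ls_scalar = {s.name: np.log(s.step) for s in scalars}
        ls_vector = {
            v.name: np.full(v.size, np.log(v.step)) for v in vectors
        }
        records: dict[str, list] = {
            s.name: [] for s in scalars
        }
        for v in vectors:
            records[v.name] = []
        for nm in latents:
            records[nm] = []
        acc_counts = {s.name: 0 for s in scalars}
        n_kept = 0

        for it in range(cfg.n_iterations):
            model.resample_latents(state, rng)
            lp = model.logp(state)
            adapting = it < cfg.n_burnin
            gamma = (it + 1) ** -0.6

            for spec in scalars:
                nm = spec.name
                x = state[nm]
                prop = x + np.exp(ls_scalar[nm]) * rng.standard_normal()
                if spec.lower <= prop <= spec.upper:
                    state[nm] = prop
                    lp_new = model.logp(state)
                    with np.errstate(over="ignore"):
                        a = min(1.0, np.exp(lp_new - lp))
                    if rng.random() < a:
                        lp = lp_new
                        if not adapting:
                            acc_counts[nm] += 1
                    else:
                        state[nm] = x
                else:
                    a = 0.0
                if adapting:
                    ls_scalar[nm] += gamma * (a - target)

            for spec in vectors:
                nm = spec.name
                z = state[nm]
                prop = z + np.exp(ls_vector[nm]) * rng.standard_normal(spec.size)
                lp0 = model.group_logp(state, nm)
                state[nm] = prop
                lp1 = model.group_logp(state, nm)
                with np.errstate(invalid="ignore"):
                    dl = lp1 - lp0
                a = np.exp(np.minimum(0.0, dl))
                accept = rng.random(spec.size) < a
                state[nm] = np.where(accept, prop, z)
                if adapting:
                    ls_vector[nm] += gamma * (a - target)

            model.aux_update(state, rng)

            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                n_kept += 1
                for spec in scalars:
                    records[spec.name].append(state[spec.name])
                for spec in vectors:
                    records[spec.name].append(state[spec.name].copy())
                for nm in latents:
                    records[nm].append(np.asarray(state[nm], dtype=float).copy())

        for nm, vals in records.items():
            all_draws.setdefault(nm, []).append(np.asarray(vals))
        n_post = cfg.n_iterations - cfg.n_burnin
        for nm in acc_counts:
            acc_totals[nm] += acc_counts[nm] / max(1, n_post)
        n_kept_total = n_kept

    draws = {nm: np.stack(chains_) for nm, chains_ in all_draws.items()}
    acceptance = {nm: v / cfg.n_chains for nm, v in acc_totals.items()}
    return PosteriorChains(draws, acceptance)


# ---------------------------------------------------------------------------
# Fidelity model driver
# ---------------------------------------------------------------------------

_COEF_PRIOR_VAR = 100.0  # normal(0, 100) read as variance 100 (SD 10)


def _normal_lp(x: float, var: float) -> float:
    return -0.5 * x * x / var


def _logistic_lp(x: float) -> float:
    """Log density of the standard logistic distribution."""
    if x >= 0:
        return -x - 2.0 * np.log1p(np.exp(-x))
    return x - 2.0 * np.log1p(np.exp(x))


class FidelityMCMC(Model):
    """Joint log posterior of the nest-site fidelity model.

    Parameterization used by the sampler: random effects are noncentered
    (``eps = sigma * z``); the per-fate degrees of freedom are sampled on
    the log scale with the exponential(1) prior's Jacobian correction.
    """

    SCALARS = [
        "mu", "beta_f", "beta_fxw", "eta_s", "eta_w",
        "sigma_ind", "sigma_yr", "sigma_0", "sigma_1",
        "log_kappa_0", "log_kappa_1",
    ]

    def __init__(
        self,
        pairs: list[EncounterPair],
        prior: DailySurvivalPrior,
        distance_floor_m: float = 1.0,
    ):
        self.prior = prior
        d = floor_distances([p.dispersal_m for p in pairs], distance_floor_m)
        self.logd = np.log(d)
        self.w = np.array([p.flood_prev for p in pairs], dtype=float)
        self.s = np.array([p.spring_index for p in pairs], dtype=float)
        inds = sorted({p.individual_id for p in pairs})
        yrs = sorted({p.year_j for p in pairs})
        self.individuals, self.years = inds, yrs
        ind_ix = {v: k for k, v in enumerate(inds)}
        yr_ix = {v: k for k, v in enumerate(yrs)}
        self.ind = np.array([ind_ix[p.individual_id] for p in pairs], dtype=int)
        self.yr = np.array([yr_ix[p.year_j] for p in pairs], dtype=int)
        self.n_ind, self.n_yr = len(inds), len(yrs)
        self.f_obs = np.array(
            [-1 if p.prev_fate is None else p.prev_fate for p in pairs],
            dtype=int,
        )
        self.mis = np.flatnonzero(self.f_obs < 0)
        self.m_mis = np.array(
            [
                pairs[i].prev_last_check_age
                if pairs[i].prev_last_check_age is not None
                else 1
                for i in self.mis
            ],
            dtype=int,
        )
        self.yr_prev_mis = np.array(
            [pairs[i].year_j - 1 for i in self.mis], dtype=int
        )
        self.n = len(pairs)

    # -- engine interface ---------------------------------------------------

    def scalar_specs(self) -> list[ParamSpec]:
        sp = [ParamSpec(n, step=0.1) for n in
              ("mu", "beta_f", "beta_fxw", "eta_w")]
        sp.append(ParamSpec("eta_s", step=0.01))
        sp += [
            ParamSpec(n, lower=0.0, upper=3.0, step=0.1)
            for n in ("sigma_ind", "sigma_yr", "sigma_0", "sigma_1")
        ]
        sp += [ParamSpec(n, step=0.3) for n in ("log_kappa_0", "log_kappa_1")]
        return sp

    def vector_specs(self) -> list[ParamSpec]:
        return [
            ParamSpec("z_ind", step=0.5, size=self.n_ind),
            ParamSpec("z_yr", step=0.5, size=self.n_yr),
        ]

    def tracked_latents(self) -> list[str]:
        return ["f"] if self.mis.size else []

    def init_state(self, rng: np.random.Generator, jitter: float) -> dict:
        state = {
            "mu": jitter * rng.standard_normal(),
            "beta_f": jitter * rng.standard_normal(),
            "beta_fxw": jitter * rng.standard_normal(),
            "eta_s": 0.01 * jitter * rng.standard_normal(),
            "eta_w": jitter * rng.standard_normal(),
            "sigma_ind": float(np.clip(1.5 + 0.5 * jitter * rng.standard_normal(), 0.05, 2.95)),
            "sigma_yr": float(np.clip(1.5 + 0.5 * jitter * rng.standard_normal(), 0.05, 2.95)),
            "sigma_0": float(np.clip(1.5 + 0.5 * jitter * rng.standard_normal(), 0.05, 2.95)),
            "sigma_1": float(np.clip(1.5 + 0.5 * jitter * rng.standard_normal(), 0.05, 2.95)),
            "log_kappa_0": float(np.log(np.log(2.0)) + 0.3 * jitter * rng.standard_normal()),
            "log_kappa_1": float(np.log(np.log(2.0)) + 0.3 * jitter * rng.standard_normal()),
            "z_ind": 0.1 * rng.standard_normal(self.n_ind),
            "z_yr": 0.1 * rng.standard_normal(self.n_yr),
        }
        f = np.where(self.f_obs < 0, rng.integers(0, 2, self.n), self.f_obs)
        state["f"] = f.astype(float)
        return state

    # -- densities ----------------------------------------------------------

    def _g(self, state: dict, f: np.ndarray) -> np.ndarray:
        return (
            state["mu"]
            + state["eta_s"] * self.s
            + state["eta_w"] * self.w
            + state["sigma_yr"] * state["z_yr"][self.yr]
            + state["beta_f"] * f
            + state["beta_fxw"] * f * self.w
            + state["sigma_ind"] * state["z_ind"][self.ind]
        )

    def _obs_loglik(self, state: dict) -> np.ndarray:
        """Per-observation t log density at the current state."""
        f = state["f"]
        g = self._g(state, f)
        sig = np.where(f == 1, state["sigma_1"], state["sigma_0"])
        kap = np.where(
            f == 1, np.exp(state["log_kappa_1"]), np.exp(state["log_kappa_0"])
        )
        k0, k1 = np.exp(state["log_kappa_0"]), np.exp(state["log_kappa_1"])
        const = {
            0: special.gammaln((k0 + 1) / 2) - special.gammaln(k0 / 2)
            - 0.5 * np.log(k0 * np.pi) - np.log(state["sigma_0"]),
            1: special.gammaln((k1 + 1) / 2) - special.gammaln(k1 / 2)
            - 0.5 * np.log(k1 * np.pi) - np.log(state["sigma_1"]),
        }
        z = (self.logd - g) / sig
        c = np.where(f == 1, const[1], const[0])
        return c - (kap + 1.0) / 2.0 * np.log1p(z * z / kap)

    def logp(self, state: dict) -> float:
        for nm in ("sigma_0", "sigma_1"):
            if state[nm] <= 0:
                return -np.inf
        lik = float(self._obs_loglik(state).sum()) if self.n else 0.0
        lp = lik
        for nm in ("mu", "beta_f", "beta_fxw", "eta_s", "eta_w"):
            lp += _normal_lp(state[nm], _COEF_PRIOR_VAR)
        # exponential(1) prior on kappa, log-scale Jacobian
        for nm in ("log_kappa_0", "log_kappa_1"):
            lp += -np.exp(state[nm]) + state[nm]
        lp += -0.5 * float(state["z_ind"] @ state["z_ind"])
        lp += -0.5 * float(state["z_yr"] @ state["z_yr"])
        return lp

    def group_logp(self, state: dict, name: str) -> np.ndarray:
        obs = self._obs_loglik(state)
        z = state[name]
        if name == "z_ind":
            grouped = np.bincount(self.ind, weights=obs, minlength=self.n_ind)
        else:
            grouped = np.bincount(self.yr, weights=obs, minlength=self.n_yr)
        return grouped - 0.5 * z * z

    def resample_latents(self, state: dict, rng: np.random.Generator) -> None:
        if not self.mis.size:
            return
        p_fail = sample_prior_fail_probs(
            self.m_mis, self.yr_prev_mis, self.prior, rng
        )
        p_fail = np.clip(p_fail, 1e-12, 1 - 1e-12)
        f = state["f"]
        lp1 = self._loglik_at_fate(state, 1.0)
        lp0 = self._loglik_at_fate(state, 0.0)
        logit = np.log(p_fail) - np.log1p(-p_fail) + lp1 - lp0
        pr1 = 1.0 / (1.0 + np.exp(-logit))
        f[self.mis] = (rng.random(self.mis.size) < pr1).astype(float)

    def _loglik_at_fate(self, state: dict, fate: float) -> np.ndarray:
        """Per-missing-pair t log density with that pair's fate forced."""
        i = self.mis
        g = (
            state["mu"]
            + state["eta_s"] * self.s[i]
            + state["eta_w"] * self.w[i]
            + state["sigma_yr"] * state["z_yr"][self.yr[i]]
            + state["beta_f"] * fate
            + state["beta_fxw"] * fate * self.w[i]
            + state["sigma_ind"] * state["z_ind"][self.ind[i]]
        )
        k = int(fate)
        sig = state[f"sigma_{k}"]
        kap = np.exp(state[f"log_kappa_{k}"])
        const = (
            special.gammaln((kap + 1) / 2)
            - special.gammaln(kap / 2)
            - 0.5 * np.log(kap * np.pi)
            - np.log(sig)
        )
        zz = (self.logd[i] - g) / sig
        return const - (kap + 1.0) / 2.0 * np.log1p(zz * zz / kap)


# ---------------------------------------------------------------------------
# Survival model driver
# ---------------------------------------------------------------------------


class SurvivalMCMC(Model):
    """Joint log posterior of the exposure-interval nest survival model."""

    SCALARS = [
        "delta", "gamma_d", "gamma_f", "gamma_dxf", "sigma_yr", "sigma_ind",
    ]

    def __init__(
        self,
        intervals: list[ExposureInterval],
        pairs: list[EncounterPair],
        prior: DailySurvivalPrior,
    ):
        self.prior = prior
        pair_by_key = {(p.individual_id, p.year_j): p for p in pairs}
        nest_keys: list[tuple] = []
        nest_ix: dict[tuple, int] = {}
        kept: list[ExposureInterval] = []
        dropped = 0
        for iv in intervals:
            key = (iv.individual_id, iv.year)
            if key not in pair_by_key:
                dropped += 1  # no dispersal covariate for this nest
                continue
            if key not in nest_ix:
                nest_ix[key] = len(nest_keys)
                nest_keys.append(key)
            kept.append(iv)
        self.n_dropped_no_pair = dropped
        self.intervals = kept
        self.n_nests = len(nest_keys)
        self.nest = np.array(
            [nest_ix[(iv.individual_id, iv.year)] for iv in kept], dtype=int
        )
        self.l = np.array([iv.length_days for iv in kept], dtype=float)
        self.y = np.array([iv.outcome for iv in kept], dtype=float)

        nest_pairs = [pair_by_key[k] for k in nest_keys]
        self.d = np.array([p.dispersal_m for p in nest_pairs], dtype=float)
        inds = sorted({p.individual_id for p in nest_pairs})
        yrs = sorted({p.year_j for p in nest_pairs})
        self.individuals, self.years = inds, yrs
        ind_ix = {v: k for k, v in enumerate(inds)}
        yr_ix = {v: k for k, v in enumerate(yrs)}
        self.ind = np.array([ind_ix[p.individual_id] for p in nest_pairs], dtype=int)
        self.yr = np.array([yr_ix[p.year_j] for p in nest_pairs], dtype=int)
        self.n_ind, self.n_yr = len(inds), len(yrs)
        self.f_obs = np.array(
            [-1 if p.prev_fate is None else p.prev_fate for p in nest_pairs],
            dtype=int,
        )
        self.mis = np.flatnonzero(self.f_obs < 0)
        self.m_mis = np.array(
            [
                nest_pairs[i].prev_last_check_age
                if nest_pairs[i].prev_last_check_age is not None
                else 1
                for i in self.mis
            ],
            dtype=int,
        )
        self.yr_prev_mis = np.array(
            [nest_pairs[i].year_j - 1 for i in self.mis], dtype=int
        )

    def scalar_specs(self) -> list[ParamSpec]:
        return [
            ParamSpec("delta", step=0.2),
            ParamSpec("gamma_d", step=1e-3),
            ParamSpec("gamma_f", step=0.3),
            ParamSpec("gamma_dxf", step=1e-3),
            ParamSpec("sigma_yr", lower=0.0, upper=3.0, step=0.2),
            ParamSpec("sigma_ind", lower=0.0, upper=3.0, step=0.2),
        ]

    def vector_specs(self) -> list[ParamSpec]:
        return [
            ParamSpec("z_yr", step=0.5, size=self.n_yr),
            ParamSpec("z_ind", step=0.5, size=self.n_ind),
        ]

    def tracked_latents(self) -> list[str]:
        return ["f"] if self.mis.size else []

    def init_state(self, rng: np.random.Generator, jitter: float) -> dict:
        state = {
            "delta": jitter * rng.standard_normal(),
            "gamma_d": 1e-3 * jitter * rng.standard_normal(),
            "gamma_f": jitter * rng.standard_normal(),
            "gamma_dxf": 1e-3 * jitter * rng.standard_normal(),
            "sigma_yr": float(np.clip(1.5 + 0.5 * jitter * rng.standard_normal(), 0.05, 2.95)),
            "sigma_ind": float(np.clip(1.5 + 0.5 * jitter * rng.standard_normal(), 0.05, 2.95)),
            "z_yr": 0.1 * rng.standard_normal(self.n_yr),
            "z_ind": 0.1 * rng.standard_normal(self.n_ind),
        }
        f = np.where(
            self.f_obs < 0, rng.integers(0, 2, self.n_nests), self.f_obs
        )
        state["f"] = f.astype(float)
        return state

    def _log_phi_nest(self, state: dict, f: np.ndarray) -> np.ndarray:
        x = (
            state["delta"]
            + state["sigma_yr"] * state["z_yr"][self.yr]
            + state["gamma_d"] * self.d
            + state["gamma_f"] * f
            + state["gamma_dxf"] * self.d * f
            + state["sigma_ind"] * state["z_ind"][self.ind]
        )
        return -np.logaddexp(0.0, -x)  # log inverse-logit, stable

    def _interval_loglik(self, state: dict, log_phi: np.ndarray) -> np.ndarray:
        lp_iv = self.l * log_phi[self.nest]
        fail = self.y == 0
        if fail.any():
            with np.errstate(divide="ignore"):
                lp_iv = np.where(fail, np.log1p(-np.exp(lp_iv)), lp_iv)
        return lp_iv

    def logp(self, state: dict) -> float:
        log_phi = self._log_phi_nest(state, state["f"])
        lik = float(self._interval_loglik(state, log_phi).sum()) if len(
            self.intervals
        ) else 0.0
        if not np.isfinite(lik):
            return -np.inf
        lp = lik
        lp += _logistic_lp(state["delta"])  # logistic(0, 1) prior
        for nm in ("gamma_d", "gamma_f", "gamma_dxf"):
            lp += _normal_lp(state[nm], _COEF_PRIOR_VAR)
        lp += -0.5 * float(state["z_yr"] @ state["z_yr"])
        lp += -0.5 * float(state["z_ind"] @ state["z_ind"])
        return lp

    def group_logp(self, state: dict, name: str) -> np.ndarray:
        log_phi = self._log_phi_nest(state, state["f"])
        lp_iv = self._interval_loglik(state, log_phi)
        lp_iv = np.nan_to_num(lp_iv, nan=-np.inf)
        idx = self.yr if name == "z_yr" else self.ind
        size = self.n_yr if name == "z_yr" else self.n_ind
        grouped = np.bincount(idx[self.nest], weights=lp_iv, minlength=size)
        z = state[name]
        return grouped - 0.5 * z * z

    def aux_update(self, state: dict, rng: np.random.Generator) -> None:
        """Reparameterization moves along the noncentered ridge.

        The year intercepts pi_j = delta + sigma_yr * z_j leave the
        likelihood unchanged under (a) a shear delta -> delta + e,
        z -> z - e/sigma_yr, and (b) a joint rescale sigma_yr -> sigma_yr
        e^u, z -> z e^-u; both are accepted on prior ratios alone and
        decorrelate delta and sigma_yr from the year effects.
        """
        sig = state["sigma_yr"]
        z = state["z_yr"]
        if sig > 1e-8 and z.size:
            e = 0.3 * rng.standard_normal()
            z_new = z - e / sig
            d0, d1 = state["delta"], state["delta"] + e
            la = (
                _logistic_lp(d1)
                - _logistic_lp(d0)
                - 0.5 * float(z_new @ z_new)
                + 0.5 * float(z @ z)
            )
            if np.log(rng.random()) < la:
                state["delta"] = d1
                state["z_yr"] = z_new
        sig = state["sigma_yr"]
        z = state["z_yr"]
        if sig > 1e-8 and z.size:
            u = 0.3 * rng.standard_normal()
            sig_new = sig * np.exp(u)
            if 0.0 < sig_new < 3.0:
                z_new = z * np.exp(-u)
                # |det| of (sigma, z) -> (sigma e^u, z e^-u) is e^{(1-n)u}
                la = (
                    -0.5 * float(z_new @ z_new)
                    + 0.5 * float(z @ z)
                    + (1 - z.size) * u
                )
                if np.log(rng.random()) < la:
                    state["sigma_yr"] = sig_new
                    state["z_yr"] = z_new

    def resample_latents(self, state: dict, rng: np.random.Generator) -> None:
        if not self.mis.size:
            return
        p_fail = sample_prior_fail_probs(
            self.m_mis, self.yr_prev_mis, self.prior, rng
        )
        p_fail = np.clip(p_fail, 1e-12, 1 - 1e-12)
        f = state["f"]
        lp_nest = {}
        for fate in (0.0, 1.0):
            f_try = f.copy()
            f_try[self.mis] = fate
            log_phi = self._log_phi_nest(state, f_try)
            lp_iv = self._interval_loglik(state, log_phi)
            lp_nest[fate] = np.bincount(
                self.nest, weights=lp_iv, minlength=self.n_nests
            )[self.mis]
        logit = (
            np.log(p_fail) - np.log1p(-p_fail) + lp_nest[1.0] - lp_nest[0.0]
        )
        pr1 = 1.0 / (1.0 + np.exp(-logit))
        f[self.mis] = (rng.random(self.mis.size) < pr1).astype(float)


# ---------------------------------------------------------------------------
# Fit entry points
# ---------------------------------------------------------------------------


def fit_fidelity(
    pairs: list[EncounterPair],
    prior: DailySurvivalPrior,
    cfg: MCMCConfig,
    distance_floor_m: float = 1.0,
) -> PosteriorChains:
    """Fit the nest-site fidelity model; returns posterior chains with
    summaries attached (medians, 95% HPDI, rho, split R-hat, ESS)."""
    model = FidelityMCMC(pairs, prior, distance_floor_m)
    post = run_mcmc(model, cfg)
    post.model = model
    if not post.converged:
        warnings.warn("fidelity fit flagged non-converged (some R-hat > 1.1)")
    return post


def fit_survival(
    intervals: list[ExposureInterval],
    pairs: list[EncounterPair],
    prior: DailySurvivalPrior,
    cfg: MCMCConfig,
) -> PosteriorChains:
    """Fit the nest survival model; same summary contract as
    :func:`fit_fidelity`."""
    model = SurvivalMCMC(intervals, pairs, prior)
    post = run_mcmc(model, cfg)
    post.model = model
    if not post.converged:
        warnings.warn("survival fit flagged non-converged (some R-hat > 1.1)")
    return post
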