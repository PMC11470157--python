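"""Posterior predictive checks and report generation.

For each retained posterior draw a full replicate dataset is simulated
from the fitted model — using that draw's coefficients, random effects
and imputed fates — and a discrepancy statistic is compared with the
observed value. The Bayesian p-value is the fraction of replicated
statistics at or above the observed one; values outside (.10, .90) are
flagged as lack of fit. Fidelity-model statistics (median and SD) are
computed on the log-distance scale, the scale the model is specified on;
the survival-model statistic is the mean interval outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fidelity import expected_dispersal
from .inference import PosteriorChains, hpdi

__all__ = [
    "PPCResult",
    "posterior_predictive_replicates",
    "bayesian_pvalue",
    "report",
    "expected_dispersal_table",
    "survival_curve_table",
]

_LACK_OF_FIT_LO = 0.10
_LACK_OF_FIT_HI = 0.90


@dataclass
class PPCResult:
    """One discrepancy statistic's posterior predictive check."""

    statistic: str
    observed: float
    replicated: np.ndarray
    bayesian_p: float

    @property
    def lack_of_fit(self) -> bool:
        return not (_LACK_OF_FIT_LO < self.bayesian_p < _LACK_OF_FIT_HI)


def bayesian_pvalue(observed: float, replicated: np.ndarray) -> float:
    """Fraction of replicated statistics >= the observed statistic."""
    replicated = np.asarray(replicated, dtype=float)
    if replicated.size == 0:
        raise ValueError("need at least one replicate")
    return float(np.mean(replicated >= observed))


def _draw_indices(posterior: PosteriorChains, n_reps: int) -> np.ndarray:
    total = posterior.n_chains * posterior.n_draws
    if n_reps > total:
        raise ValueError(f"n_reps={n_reps} exceeds available draws ({total})")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return np.linspace(0, total - 1, n_reps).astype(int)


def posterior_predictive_replicates(
    posterior: PosteriorChains,
    model_id: str,
    n_reps: int = 500,
    rng: np.random.Generator | None = None,
) -> list[PPCResult]:
    """Simulate replicate datasets from the fitted model and compute the
    discrepancy statistics: median and SD of log dispersal distance for
    the fidelity model (``model_id='fidelity'``), mean interval outcome
    for the survival model (``model_id='survival'``)."""
    if rng is None:
        rng = np.random.default_rng(0)
    model = getattr(posterior, "model", None)
    if model is None:
        raise ValueError("posterior has no attached model/data")
    idx = _draw_indices(posterior, n_reps)

    def flat(name):
        return posterior.stacked(name)

    if model_id == "fidelity":
        obs_stats = {
            "median": float(np.median(model.logd)),
            "sd": float(np.std(model.logd, ddof=1)),
        }
        reps = {k: np.empty(n_reps) for k in obs_stats}
        have_f = "f" in posterior.draws
        for r, i in enumerate(idx):
            state = {
                nm: flat(nm)[i]
                for nm in (
                    "mu", "beta_f", "beta_fxw", "eta_s", "eta_w",
                    "sigma_ind", "sigma_yr", "sigma_0", "sigma_1",
                    "log_kappa_0", "log_kappa_1",
                )
            }
            state["z_ind"] = flat("z_ind")[i]
            state["z_yr"] = flat("z_yr")[i]
            if have_f:
                f = flat("f")[i]
            else:
                f = model.f_obs.astype(float)
            g = model._g(state, f)
            sig = np.where(f == 1, state["sigma_1"], state["sigma_0"])
            kap = np.where(
                f == 1,
                np.exp(state["log_kappa_1"]),
                np.exp(state["log_kappa_0"]),
            )
            rep = g + sig * rng.standard_t(kap)
            reps["median"][r] = np.median(rep)
            reps["sd"][r] = np.std(rep, ddof=1)
    elif model_id == "survival":
        obs_stats = {"mean": float(np.mean(model.y))}
        reps = {"mean": np.empty(n_reps)}
        have_f = "f" in posterior.draws
        for r, i in enumerate(idx):
            state = {
                nm: flat(nm)[i]
                for nm in (
                    "delta", "gamma_d", "gamma_f", "gamma_dxf",
                    "sigma_yr", "sigma_ind",
                )
            }
            state["z_yr"] = flat("z_yr")[i]
            state["z_ind"] = flat("z_ind")[i]
            f = flat("f")[i] if have_f else model.f_obs.astype(float)
            log_phi = model._log_phi_nest(state, f)
            p_surv = np.exp(model.l * log_phi[model.nest])
            y_rep = rng.random(model.l.size) < p_surv
            reps["mean"][r] = float(np.mean(y_rep))
    else:
        raise ValueError(f"unknown model_id {model_id!r}")

    return [
        PPCResult(
            statistic=name,
            observed=obs_stats[name],
            replicated=reps[name],
            bayesian_p=bayesian_pvalue(obs_stats[name], reps[name]),
        )
        for name in obs_stats
    ]


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def expected_dispersal_table(
    posterior: PosteriorChains, seed: int = 0
) -> pd.DataFrame:
    """Marginalized expected dispersal distance (m) by previous fate and
    flood status — the fate-by-flood prediction grid."""
    rows = []
    for f in (0, 1):
        for w in (0, 1):
            rng = np.random.default_rng([seed, f, w])
            med, (lo, hi) = expected_dispersal(posterior, f=f, w=w, rng=rng)
            rows.append(
                {
                    "prev_fate": f,
                    "flood_prev": w,
                    "median_m": med,
                    "hpdi_lo": lo,
                    "hpdi_hi": hi,
                }
            )
    return pd.DataFrame(rows)


def survival_curve_table(
    posterior: PosteriorChains,
    d_grid: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """28-day nest survival across a dispersal-distance grid by previous
    fate, marginalized over among-year and among-individual variation
    with fresh random-effect draws per posterior draw."""
    if d_grid is None:
        d_grid = np.linspace(0.0, 1000.0, 21)
    delta = posterior.stacked("delta")
    gam_d = posterior.stacked("gamma_d")
    gam_f = posterior.stacked("gamma_f")
    gam_df = posterior.stacked("gamma_dxf")
    sig_yr = posterior.stacked("sigma_yr")
    sig_ind = posterior.stacked("sigma_ind")
    rng = np.random.default_rng([seed, 7])
    eps = sig_yr * rng.standard_normal(delta.size) + sig_ind * rng.standard_normal(
        delta.size
    )
    rows = []
    for f in (0, 1):
        for d in d_grid:
            x = delta + gam_d * d + gam_f * f + gam_df * d * f + eps
            phi = 1.0 / (1.0 + np.exp(-x))
            s28 = phi**28
            lo, hi = hpdi(s28, 0.95)
            rows.append(
                {
                    "prev_fate": f,
                    "dispersal_m": float(d),
                    "nest_survival_28": float(np.median(s28)),
                    "hpdi_lo": lo,
                    "hpdi_hi": hi,
                }
            )
    return pd.DataFrame(rows)


def report(
    posteriors: dict[str, PosteriorChains],
    ppc_results: dict[str, list[PPCResult]],
    out_dir: str | Path,
    seed: int = 0,
    make_plots: bool = False,
) -> dict[str, pd.DataFrame]:
    """Render the full report bundle.

    ``posteriors`` maps model id ('fidelity', 'survival') to fitted
    chains. Writes summary.csv, ppc.csv, expected_dispersal.csv and
    survival_curves.csv plus a machine-readable report.json (and PNG
    plots on request); returns the tables.
    """
    missing = [k for k in ("fidelity", "survival") if k not in posteriors]
    if missing:
        raise ValueError(f"missing fitted posteriors: {missing}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summaries = []
    for mid, post in posteriors.items():
        s = post.summary().reset_index()
        s.insert(0, "model", mid)
        summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)

    ppc_rows = []
    for mid, results in ppc_results.items():
        for r in results:
            ppc_rows.append(
                {
                    "model": mid,
                    "statistic": r.statistic,
                    "observed": r.observed,
                    "bayesian_p": r.bayesian_p,
                    "lack_of_fit": r.lack_of_fit,
                }
            )
    ppc_df = pd.DataFrame(ppc_rows)

    disp = expected_dispersal_table(posteriors["fidelity"], seed=seed)
    curves = survival_curve_table(posteriors["survival"], seed=seed)

    tables = {
        "summary": summary,
        "ppc": ppc_df,
        "expected_dispersal": disp,
        "survival_curves": curves,
    }
    summary.to_csv(out / "summary.csv", index=False)
    ppc_df.to_csv(out / "ppc.csv", index=False)
    disp.to_csv(out / "expected_dispersal.csv", index=False)
    curves.to_csv(out / "survival_curves.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(
            {
                name: df.to_dict(orient="records")
                for name, df in tables.items()
            },
            indent=2,
            default=float,
        )
    )
    if make_plots:
        _plots(disp, curves, out)
    return tables


def _plots(disp: pd.DataFrame, curves: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for f, color in ((0, "tab:blue"), (1, "tab:red")):
        sub = disp[disp.prev_fate == f]
        ax.errorbar(
            sub.flood_prev + 0.05 * f,
            sub.median_m,
            yerr=[sub.median_m - sub.hpdi_lo, sub.hpdi_hi - sub.median_m],
            fmt="o",
            color=color,
            label=f"previous fate {'fail' if f else 'success'}",
        )
    ax.set_xlabel("flood in previous year")
    ax.set_ylabel("expected dispersal (m)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "expected_dispersal.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for f, color in ((0, "tab:blue"), (1, "tab:red")):
        sub = curves[curves.prev_fate == f]
        ax.plot(sub.dispersal_m, sub.nest_survival_28, color=color,
                label=f"previous fate {'fail' if f else 'success'}")
        ax.fill_between(sub.dispersal_m, sub.hpdi_lo, sub.hpdi_hi,
                        color=color, alpha=0.2)
    ax.set_xlabel("dispersal distance (m)")
    ax.set_ylabel("28-day nest survival")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "survival_curves.png", dpi=120)
    plt.close(fig)
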