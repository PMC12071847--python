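"""Fitting the hierarchical RBC-lifespan model and summarizing posteriors.

``fit`` runs NUTS chains over the unconstrained posterior of
:class:`~rbclifespan.model.HierarchicalRbcModel`, then assembles an
``arviz.InferenceData`` with natural-scale population parameters, generated
quantities (mean lifespan, pre/post contrasts, derived hemoglobin) and the
per-blood-draw pointwise log likelihood needed for PSIS-LOO.  All contrasts
are computed per posterior draw, never from summary statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .model import STATE_NAMES, HierarchicalRbcModel, PriorConfig, records_from_timelines
from .nuts import ChainResult, NutsConfig, sample_nuts

log = logging.getLogger(__name__)

__all__ = ["FitConfig", "FitResult", "build_model", "fit", "summarize", "REPORT_ROWS"]

#: population-level quantities reported by :func:`summarize`
REPORT_ROWS = [
    "mcv_pre", "mcv_post", "mcv_delta",
    "mchc_pre", "mchc_post", "mchc_delta",
    "rbc_pre", "rbc_post", "rbc_delta_decrease",
    "hgb_pre", "hgb_post", "hgb_delta",
    "lifespan_days",
]


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings (reference analysis: 4 chains, 2000+2000 draws)."""

    n_chains: int = 4
    n_warmup: int = 2000
    n_sampling: int = 2000
    seed: int = 0
    target_acceptance: float = 0.9
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (convergence diagnostics need comparison)")
        if self.n_sampling < 100 or self.n_warmup < 100:
            raise ValueError("warmup and sampling draws must each be >= 100")


@dataclass
class FitResult:
    """Posterior draws plus convergence bookkeeping for one model fit."""

    idata: az.InferenceData
    model: HierarchicalRbcModel
    config: FitConfig
    raw_draws: np.ndarray        # (chain, draw, dim) unconstrained
    n_divergences: int
    step_sizes: list[float] = field(default_factory=list)

    @property
    def summaries(self) -> pd.DataFrame:
        return summarize(self)

    def diagnostics(self, rhat_limit: float = 1.01, ess_limit: float = 400.0) -> dict:
        """Convergence acceptance: 0 divergences, split-R̂ < 1.01 and
        bulk-ESS > 400 on every population-level parameter."""
        sub = self.idata.posterior[_POP_VARS]
        rhat = az.rhat(sub).to_array().values
        ess = az.ess(sub).to_array().values
        return {
            "divergences": int(self.n_divergences),
            "max_rhat": float(np.nanmax(rhat)),
            "min_bulk_ess": float(np.nanmin(ess)),
            "converged": bool(self.n_divergences == 0
                              and np.nanmax(rhat) < rhat_limit
                              and np.nanmin(ess) > ess_limit),
        }


_POP_VARS = ["mu_survival", "sigma_survival", "lifespan_days",
             "mu_pop", "sigma_pop", "sigma_obs", "nu"]


def build_model(records_or_timelines, patient_index=None,
                priors: PriorConfig = PriorConfig()) -> HierarchicalRbcModel:
    """Build the model from a record table or a list of eligible timelines."""
    if isinstance(records_or_timelines, pd.DataFrame):
        return HierarchicalRbcModel(records_or_timelines, patient_index, priors)
    records, pidx = records_from_timelines(records_or_timelines)
    return HierarchicalRbcModel(records, pidx, priors)


def _generated_quantities(model: HierarchicalRbcModel, draws: np.ndarray) -> dict:
    """Natural-scale parameters + derived quantities, shape (chain, draw, ...)."""
    p = model.unpack(draws)
    mu = p["mu_pop"]
    out = {
        "mu_survival": p["mu_s"],
        "sigma_survival": p["sigma_s"],
        "lifespan_days": np.exp(p["mu_s"] + p["sigma_s"] ** 2 / 2.0),
        "mu_pop": mu,
        "sigma_pop": p["sigma_pop"],
        "sigma_obs": p["sigma_obs"],
        "nu": p["nu"],
        "patient_values": model.patient_values(p),
        "rbc_pre": mu[..., 0], "rbc_post": mu[..., 1],
        "mcv_pre": mu[..., 2], "mcv_post": mu[..., 3],
        "mchc_pre": mu[..., 4], "mchc_post": mu[..., 5],
    }
    out["mcv_delta"] = out["mcv_post"] - out["mcv_pre"]
    out["mchc_delta"] = out["mchc_post"] - out["mchc_pre"]
    out["rbc_delta_decrease"] = out["rbc_pre"] - out["rbc_post"]
    # hemoglobin identity Hgb = RBC * MCV * MCHC / 1000, evaluated per draw
    out["hgb_pre"] = out["rbc_pre"] * out["mcv_pre"] * out["mchc_pre"] / 1000.0
    out["hgb_post"] = out["rbc_post"] * out["mcv_post"] * out["mchc_post"] / 1000.0
    out["hgb_delta"] = out["hgb_post"] - out["hgb_pre"]
    return out


def fit(model: HierarchicalRbcModel, config: FitConfig = FitConfig()) -> FitResult:
    """Run NUTS chains and assemble the posterior.

    Chains are seeded from independent streams spawned off ``config.seed``;
    identical (model, config, library versions) reproduce identical draws.
    A chain whose initialization fails is retried from a fresh jittered
    start before aborting.
    """
    nuts_cfg = NutsConfig(n_warmup=config.n_warmup, n_draws=config.n_sampling,
                          target_accept=config.target_acceptance,
                          max_treedepth=config.max_treedepth)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains: list[ChainResult] = []
    for c, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        last_err = None
        for attempt in range(5):
            try:
                x0 = model.initial_value(rng)
                res = sample_nuts(model.logp_grad, x0, nuts_cfg, rng)
                break
            except RuntimeError as err:     # bad initialization point
                last_err = err
        else:
            raise RuntimeError(
                f"chain {c} failed to initialize after 5 attempts: {last_err}")
        log.info("chain %d done: step_size=%.3g divergences=%d",
                 c, res.step_size, int(res.diverging.sum()))
        chains.append(res)

    raw = np.stack([ch.draws for ch in chains])           # (C, D, dim)
    n_div = int(sum(ch.diverging.sum() for ch in chains))
    gq = _generated_quantities(model, raw)

    coords = {
        "state": list(STATE_NAMES),
        "observable": ["n_rbc", "mcv", "mchc"],
        "patient": list(model.patient_index),
        "record": np.arange(model.n_records),
    }
    dims = {
        "mu_pop": ["state"], "sigma_pop": ["state"],
        "sigma_obs": ["observable"], "nu": ["observable"],
        "patient_values": ["patient", "state"],
        "cbc": ["record"],
    }
    loglik = model.pointwise_loglik(raw.reshape(-1, model.dim)).reshape(
        raw.shape[0], raw.shape[1], model.n_records)
    idata = az.from_dict(
        posterior=gq,
        sample_stats={
            "diverging": np.stack([ch.diverging for ch in chains]),
            "energy": np.stack([ch.energy for ch in chains]),
            "tree_depth": np.stack([ch.treedepth for ch in chains]),
            "acceptance_rate": np.stack([ch.accept_stat for ch in chains]),
            "lp": np.stack([ch.logp for ch in chains]),
        },
        log_likelihood={"cbc": loglik},
        coords=coords,
        dims=dims,
    )
    return FitResult(idata=idata, model=model, config=config, raw_draws=raw,
                     n_divergences=n_div,
                     step_sizes=[ch.step_size for ch in chains])


def summarize(result: FitResult) -> pd.DataFrame:
    """Medians and central 95% credible intervals for the reported
    population-level quantities (contrasts computed per draw)."""
    post = result.idata.posterior
    rows = []
    for name in REPORT_ROWS:
        pooled = post[name].values.ravel()
        lo, med, hi = np.percentile(pooled, [2.5, 50.0, 97.5])
        rows.append({"quantity": name, "median": med, "ci_2.5%": lo, "ci_97.5%": hi})
    return pd.DataFrame(rows).set_index("quantity")
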