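"""Model-criticism battery: rank uniformity, posterior predictive checks,
PSIS-LOO with Pareto-k̂ outlier counts.

The pointwise unit for LOO is one blood draw — the three observables' log
likelihoods summed — so a k̂ value flags an entire laboratory measurement;
points with k̂ > 0.7 are influential and k̂ > 1 are severe outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2, gaussian_kde, rankdata

__all__ = ["RankResult", "PpcResult", "LooResult",
           "rank_statistics", "posterior_predictive", "loo_khat",
           "in_sample_lpd", "convergence_verdict"]

_OBS_INDEX = {"n_rbc": 0, "mcv": 1, "mchc": 2}


@dataclass
class RankResult:
    """Per-chain histogram of pooled posterior-draw ranks for one parameter."""

    counts: np.ndarray      # (n_chains, n_bins)
    statistic: np.ndarray   # chi-square uniformity score per chain
    pvalue: np.ndarray
    n_bins: int

    def uniform(self, alpha: float = 0.01) -> bool:
        """True when no chain's rank histogram rejects uniformity."""
        return bool(np.all(self.pvalue > alpha))


@dataclass
class PpcResult:
    grid: np.ndarray
    observed_density: np.ndarray
    replicate_densities: np.ndarray   # (S, grid)
    mean_density: np.ndarray

    def envelope_coverage(self, lo: float = 2.5, hi: float = 97.5) -> float:
        """Fraction of the grid where the observed curve lies inside the
        pointwise replicate envelope."""
        if self.replicate_densities.shape[0] < 2:
            return float("nan")
        lo_c, hi_c = np.percentile(self.replicate_densities, [lo, hi], axis=0)
        inside = (self.observed_density >= lo_c) & (self.observed_density <= hi_c)
        return float(inside.mean())


@dataclass
class LooResult:
    """PSIS-LOO summary with severe-outlier counts (k̂ > 0.7 influential,
    k̂ > 1 severe)."""

    pointwise_khat: np.ndarray
    elpd_estimate: float
    elpd_se: float
    p_loo: float
    n_khat_gt_07: int
    n_khat_gt_10: int

    @property
    def counts(self) -> dict:
        return {"khat_gt_0.7": self.n_khat_gt_07, "khat_gt_1.0": self.n_khat_gt_10}


def rank_statistics(fit, parameter: str, n_bins: int = 20) -> RankResult:
    """Rank-plot statistics: pooled-rank histogram per chain plus a
    chi-square uniformity score (uniform counts indicate good mixing)."""
    da = fit.idata.posterior[parameter]
    if da.sizes["chain"] < 2:
        raise ValueError("rank statistics require at least two chains")
    values = da.values
    if values.ndim != 2:
        raise ValueError(f"parameter {parameter!r} is not scalar; select a component")
    n_chains, n_draws = values.shape
    ranks = rankdata(values.ravel(), method="average").reshape(n_chains, n_draws)
    edges = np.linspace(0.5, n_chains * n_draws + 0.5, n_bins + 1)
    counts = np.stack([np.histogram(r, bins=edges)[0] for r in ranks])
    expected = n_draws / n_bins
    stat = ((counts - expected) ** 2 / expected).sum(axis=1)
    pval = chi2.sf(stat, df=n_bins - 1)
    return RankResult(counts=counts, statistic=stat, pvalue=pval, n_bins=n_bins)


def posterior_predictive(fit, observable: str, n_rep: int = 100,
                         seed: int = 0, n_grid: int = 200) -> PpcResult:
    """Replicate-vs-observed density comparison for one observable.

    Draws ``n_rep`` replicate datasets from the full generative model
    (posterior patient values, old-cell fractions at the observed times,
    Student-T noise) and summarizes each by a kernel density estimate; the
    bandwidth is the rule-of-thumb bandwidth of the observed data, shared
    across replicates for comparability.
    """
    if observable not in _OBS_INDEX:
        raise ValueError(f"unknown observable {observable!r}; valid: {sorted(_OBS_INDEX)}")
    k = _OBS_INDEX[observable]
    model = fit.model
    rng = np.random.default_rng(seed)
    flat = fit.raw_draws.reshape(-1, model.dim)
    idx = rng.choice(flat.shape[0], size=min(n_rep, flat.shape[0]), replace=False)
    p = model.unpack(flat[idx])
    values = model.patient_values(p)
    w = model.w_old_batch(p["mu_s"], p["sigma_s"])
    loc = w * values[:, model.pidx, 2 * k] + (1.0 - w) * values[:, model.pidx, 2 * k + 1]
    noise = rng.standard_t(p["nu"][:, k, None], size=loc.shape)
    reps = loc + p["sigma_obs"][:, k, None] * noise

    observed = model.y[:, k]
    obs_kde = gaussian_kde(observed)
    bw = obs_kde.factor
    span = observed.max() - observed.min()
    grid = np.linspace(observed.min() - 0.15 * span, observed.max() + 0.15 * span, n_grid)
    obs_density = obs_kde(grid)
    rep_density = np.stack([gaussian_kde(r, bw_method=bw)(grid) for r in reps])
    return PpcResult(grid=grid, observed_density=obs_density,
                     replicate_densities=rep_density,
                     mean_density=rep_density.mean(axis=0))


def loo_khat(fit, unit: str = "blood_draw") -> LooResult:
    """Pareto-smoothed importance-sampling LOO.

    ``unit='blood_draw'`` (default) treats one laboratory measurement —
    MCV, RBC count and MCHC combined — as one point; ``unit='observable'``
    treats each (measurement, observable) pair separately.
    """
    if "log_likelihood" not in fit.idata.groups():
        raise ValueError("fit has no stored pointwise log likelihood; refit with storage enabled")
    if unit == "blood_draw":
        idata = fit.idata
    elif unit == "observable":
        model = fit.model
        ll = model.pointwise_loglik(fit.raw_draws.reshape(-1, model.dim), per_observable=True)
        C, D = fit.raw_draws.shape[:2]
        tmp = az.from_dict(log_likelihood={
            "cbc_obs": ll.reshape(C, D, model.n_records * 3)})
        # posterior group carried over so arviz can estimate relative ESS
        idata = az.InferenceData(posterior=fit.idata.posterior,
                                 log_likelihood=tmp.log_likelihood)
    else:
        raise ValueError("unit must be 'blood_draw' or 'observable'")
    res = az.loo(idata, pointwise=True)
    khat = np.asarray(res.pareto_k)
    return LooResult(pointwise_khat=khat,
                     elpd_estimate=float(res.elpd_loo),
                     elpd_se=float(res.se),
                     p_loo=float(res.p_loo),
                     n_khat_gt_07=int((khat > 0.7).sum()),
                     n_khat_gt_10=int((khat > 1.0).sum()))


def in_sample_lpd(fit) -> float:
    """In-sample log pointwise predictive density (LOO must not exceed it)."""
    ll = fit.idata.log_likelihood["cbc"].values
    C, D, N = ll.shape
    flat = ll.reshape(C * D, N)
    return float(np.sum(logsumexp(flat, axis=0) - np.log(C * D)))


def convergence_verdict(fit, loo: LooResult | None = None) -> str:
    """Plain-text pass/fail of the convergence acceptance rules."""
    d = fit.diagnostics()
    lines = [
        f"divergences: {d['divergences']} (require 0): "
        + ("PASS" if d["divergences"] == 0 else "FAIL"),
        f"max split-R-hat: {d['max_rhat']:.4f} (require < 1.01): "
        + ("PASS" if d["max_rhat"] < 1.01 else "FAIL"),
        f"min bulk-ESS: {d['min_bulk_ess']:.0f} (require > 400): "
        + ("PASS" if d["min_bulk_ess"] > 400 else "FAIL"),
    ]
    if loo is not None:
        lines.append(
            f"PSIS-LOO severe outliers (k-hat > 1.0): {loo.n_khat_gt_10} "
            f"(influential k-hat > 0.7: {loo.n_khat_gt_07})")
    verdict = "CONVERGED" if d["converged"] else "NOT CONVERGED"
    return "\n".join(lines + [f"verdict: {verdict}"])
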