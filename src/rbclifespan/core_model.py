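"""Deterministic kinetics of red-blood-cell (RBC) replacement.

RBCs created before the start of CDK4/6-inhibitor treatment ("old" cells,
small, low MCV) are progressively replaced by cells created under treatment
("new" cells, large, high MCV).  The residual lifetime of an old cell is
modelled as LogNormal on the day scale, so the fraction of old cells still
circulating ``t`` days after the first dose is the LogNormal survival
function.  Any population-average RBC index (MCV, MCHC, RBC count) is then a
mixture mean between the old-cell and new-cell values, weighted by that
fraction.

Units are fixed throughout the package: time in days (``t = 0`` at first
dose, pre-treatment times negative), RBC count in 10^12 cells/L, MCV in fL,
MCHC in g/dL, hemoglobin in g/dL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "SurvivalParams",
    "RbcIndices",
    "residual_survival",
    "old_fraction",
    "mean_lifespan",
    "mixture_mean",
    "derived_hemoglobin",
]


@dataclass(frozen=True)
class SurvivalParams:
    """Location/scale of the LogNormal residual-survival law (log-days scale).

    The implied mean lifespan is ``exp(mu_survival + sigma_survival**2 / 2)``
    days; the healthy-adult reference is about 118 days.
    """

    mu_survival: float
    sigma_survival: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu_survival", float(self.mu_survival))
        object.__setattr__(self, "sigma_survival", float(self.sigma_survival))
        if not self.sigma_survival >= 0:
            raise ValueError(f"sigma_survival must be >= 0, got {self.sigma_survival}")
        if not np.isfinite(self.mu_survival):
            raise ValueError("mu_survival must be finite")

    @classmethod
    def from_mean_lifespan(cls, lifespan_days: float, sigma_survival: float) -> "SurvivalParams":
        """Build params whose LogNormal mean equals ``lifespan_days``."""
        return cls(np.log(lifespan_days) - sigma_survival**2 / 2.0, sigma_survival)


@dataclass(frozen=True)
class RbcIndices:
    """One set of RBC indices: count (10^12/L), MCV (fL), MCHC (g/dL)."""

    n_rbc: float
    mcv: float
    mchc: float

    def __post_init__(self) -> None:
        if not (self.n_rbc >= 0 and self.mcv >= 0 and self.mchc >= 0):
            raise ValueError("RBC indices must be non-negative")


def residual_survival(t, params: SurvivalParams):
    """Fraction of pre-treatment RBCs still alive ``t`` days after first dose.

    ``S(t) = 1 - Phi((log t - mu_survival) / sigma_survival)`` with ``Phi``
    the standard normal CDF — i.e. the LogNormal survival function whose mean
    is the RBC lifespan.  Strictly decreasing, S(median) = 1/2.

    Parameters
    ----------
    t : float or array-like
        Days since treatment start, must be > 0 (route t <= 0 through
        :func:`old_fraction`).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("residual_survival requires t > 0; use old_fraction for t <= 0")
    z = (np.log(t) - params.mu_survival) / params.sigma_survival
    out = norm.sf(z)
    return out if out.ndim else float(out)


def old_fraction(t, params: SurvivalParams):
    """Proportion of circulating RBCs created before treatment start.

    Equal to 1 for ``t <= 0`` (all cells are old before the first dose) and
    to :func:`residual_survival` afterwards; continuous at ``t = 0`` because
    the LogNormal survival tends to 1 as ``t → 0+``.
    """
    t = np.asarray(t, dtype=float)
    out = np.ones(t.shape)
    pos = t > 0
    if np.any(pos):
        out[pos] = residual_survival(t[pos], params)
    return out if out.ndim else float(out)


def mean_lifespan(params: SurvivalParams) -> float:
    """Mean of the LogNormal residual-survival law, in days."""
    return float(np.exp(params.mu_survival + params.sigma_survival**2 / 2.0))


def mixture_mean(w_old, value_old, value_new):
    """Population-average index as an old/new weighted arithmetic mean.

    ``w_old * value_old + (1 - w_old) * value_new``; always lies between the
    two endpoint values.
    """
    w_old = np.asarray(w_old, dtype=float)
    if np.any(w_old < 0) or np.any(w_old > 1):
        raise ValueError("w_old must lie in [0, 1]")
    out = w_old * np.asarray(value_old, dtype=float) + (1.0 - w_old) * np.asarray(value_new, dtype=float)
    return out if out.ndim else float(out)


def derived_hemoglobin(indices: RbcIndices) -> float:
    """Hemoglobin concentration (g/dL) implied by the RBC indices.

    Standard hematology identity ``Hgb = RBC x MCV x MCHC / 1000`` with RBC
    in 10^12/L, MCV in fL, MCHC in g/dL.  Hemoglobin is a derived quantity
    here, not an independently modelled observable.
    """
    return indices.n_rbc * indices.mcv * indices.mchc / 1000.0
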