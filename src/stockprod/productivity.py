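"""Stock productivity proxy: surplus production per unit biomass.

Observed surplus production is SP_t = B_{t+1} - B_t + C_t and the
productivity proxy P_t = SP_t / B_t.  Hindcast uncertainty is carried by
an ensemble of candidate productivity series, one per retained posterior
draw of the surplus-production fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ProductivityEnsemble",
    "TrendClass",
    "observed_surplus_production",
    "productivity_series",
    "build_ensemble",
    "classify_linear_trend",
]


@dataclass
class ProductivityEnsemble:
    """Candidate productivity series for one stock (year x member)."""

    stock_id: str
    years: np.ndarray  # year t of each P_t (one shorter than the biomass series)
    members: np.ndarray  # (n_years, n_members)
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    @property
    def n_members(self) -> int:
        return self.members.shape[1]


@dataclass(frozen=True)
class TrendClass:
    """OLS slope of productivity on year with its 95% CI and label."""

    slope: float
    ci: tuple
    label: str  # negative | neutral | positive


def observed_surplus_production(biomass, catch) -> np.ndarray:
    """SP_t = B_{t+1} - B_t + C_t (length n-1 for n biomass years)."""
    B = np.asarray(biomass, dtype=float)
    C = np.asarray(catch, dtype=float)
    if B.ndim != 1 or B.size < 2:
        raise ValueError("biomass must be 1-d with length >= 2")
    if C.size != B.size:
        raise ValueError(
            f"misaligned series: {B.size} biomass years vs {C.size} catch years"
        )
    return B[1:] - B[:-1] + C[:-1]


def productivity_series(sp, biomass) -> np.ndarray:
    """P_t = SP_t / B_t; ``biomass`` holds B_t for each SP_t."""
    sp = np.asarray(sp, dtype=float)
    B = np.asarray(biomass, dtype=float)[: sp.size]
    if np.any(B <= 0):
        raise ValueError("biomass must be strictly positive")
    return sp / B


def build_ensemble(
    posterior, catch, n_members: int = 1000, seed: int = 0
) -> ProductivityEnsemble:
    """Productivity candidates from posterior biomass trajectories.

    Samples ``n_members`` retained draws without replacement; each
    member's P series uses that draw's biomass trajectory with the
    observed catch.
    """
    states = posterior.states
    if states.shape[0] < n_members:
        raise ValueError(
            f"posterior holds {states.shape[0]} draws < {n_members} members"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(states.shape[0], size=n_members, replace=False)
    C = np.asarray(catch, dtype=float)
    members = np.empty((states.shape[1] - 1, n_members))
    for j, ix in enumerate(pick):
        B = states[ix]
        members[:, j] = (B[1:] - B[:-1] + C[:-1]) / B[:-1]
    mean = members.mean(axis=1)
    lo, hi = np.percentile(members, [2.5, 97.5], axis=1)
    return ProductivityEnsemble(
        stock_id=getattr(posterior, "stock_id", "stock"),
        years=np.asarray(posterior.years)[:-1],
        members=members,
        mean=mean,
        ci_lower=np.minimum(lo, mean),
        ci_upper=np.maximum(hi, mean),
    )


def classify_linear_trend(P, years, window: tuple = (1981, 2022)) -> TrendClass:
    """Classify the long-term linear pattern of a productivity series.

    OLS of P on year restricted to ``window``; the label is positive /
    negative iff the 95% CI of the slope (t distribution) excludes zero.
    Zero-variance series classify as neutral.
    """
    P = np.asarray(P, dtype=float)
    years = np.asarray(years)
    keep = (years >= window[0]) & (years <= window[1]) & np.isfinite(P)
    if keep.sum() < 3:
        raise ValueError("need >= 3 in-window years for a trend")
    y, x = P[keep], years[keep].astype(float)
    if np.ptp(y) == 0.0:
        return TrendClass(0.0, (0.0, 0.0), "neutral")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, x.size - 2)
    lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
    if lo > 0:
        label = "positive"
    elif hi < 0:
        label = "negative"
    else:
        label = "neutral"
    return TrendClass(float(res.slope), (float(lo), float(hi)), label)
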