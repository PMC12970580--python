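"""Lognormal prior elicitation for surplus-production model parameters.

Priors for the intrinsic growth rate ``r``, carrying capacity ``K`` and
initial depletion ``psi`` are built from qualitative stock information:
``r`` from a resilience category, ``K`` from empirical multiples of the
(smoothed) maximum catch, and ``psi`` from a qualitative stock-size
category derived — in order of preference — from B/B_MSY, an abundance
index, or the catch history itself.

Every prior is specified by its 95% limits ``(lower, upper)`` and
converted to log-scale parameters by the symmetric-on-log-scale rule::

    log_mean = (ln lower + ln upper) / 2
    log_sd   = ln(upper / lower) / (2 * 1.96)

so that ``exp(log_mean +- 1.96 * log_sd)`` reproduces the limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LognormalPrior",
    "StockSizeCategory",
    "R_PRIOR_LIMITS",
    "PSI_PRIOR_LIMITS",
    "STOCK_SIZE_LABELS",
    "r_prior_from_resilience",
    "moving_average3",
    "biomass_level_end",
    "k_prior",
    "qualitative_stock_size",
    "psi_prior",
]

_Z95 = 1.96

#: 95% prior limits for r by resilience category.
R_PRIOR_LIMITS = {
    "Very low": (0.015, 0.10),
    "Low": (0.05, 0.50),
    "Medium": (0.20, 0.80),
    "High": (0.60, 1.50),
}

#: 95% prior limits for initial depletion psi by qualitative stock size.
PSI_PRIOR_LIMITS = {
    "Very small": (0.01, 0.20),
    "Small": (0.15, 0.40),
    "About half": (0.35, 0.65),
    "More than half": (0.50, 0.85),
    "Close to unexploited": (0.75, 1.00),
}

#: Stock-size labels ordered from most depleted to least depleted.
STOCK_SIZE_LABELS = (
    "Very small",
    "Small",
    "About half",
    "More than half",
    "Close to unexploited",
)


@dataclass(frozen=True)
class LognormalPrior:
    """A lognormal prior specified by its 95% limits.

    Attributes
    ----------
    lower, upper
        95% interval limits on the natural scale (0 < lower < upper).
    log_mean, log_sd
        Mean and standard deviation of ``log(X)``.
    mean, cv
        Natural-scale mean and coefficient of variation.
    """

    lower: float
    upper: float
    log_mean: float = field(init=False)
    log_sd: float = field(init=False)
    mean: float = field(init=False)
    cv: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError(
                f"require 0 < lower < upper, got ({self.lower}, {self.upper})"
            )
        log_mean = 0.5 * (np.log(self.lower) + np.log(self.upper))
        log_sd = np.log(self.upper / self.lower) / (2.0 * _Z95)
        object.__setattr__(self, "log_mean", float(log_mean))
        object.__setattr__(self, "log_sd", float(log_sd))
        object.__setattr__(self, "mean", float(np.exp(log_mean + 0.5 * log_sd**2)))
        object.__setattr__(self, "cv", float(np.sqrt(np.expm1(log_sd**2))))

    @property
    def variance(self) -> float:
        """Natural-scale variance of the lognormal."""
        return (self.mean * self.cv) ** 2

    @property
    def median(self) -> float:
        return float(np.exp(self.log_mean))

    def logpdf(self, x):
        return stats.lognorm.logpdf(x, s=self.log_sd, scale=np.exp(self.log_mean))

    def sample(self, size, rng: np.random.Generator):
        return rng.lognormal(self.log_mean, self.log_sd, size=size)


@dataclass(frozen=True)
class StockSizeCategory:
    """Qualitative stock size with the method that produced it."""

    label: str
    method: str  # "bbmsy" | "abundance" | "catch"

    def __post_init__(self) -> None:
        if self.label not in STOCK_SIZE_LABELS:
            raise ValueError(f"unknown stock-size label {self.label!r}")
        if self.method not in ("bbmsy", "abundance", "catch"):
            raise ValueError(f"unknown method {self.method!r}")


def r_prior_from_resilience(resilience: str) -> LognormalPrior:
    """Prior for the intrinsic growth rate from a resilience category."""
    try:
        lo, hi = R_PRIOR_LIMITS[resilience]
    except KeyError:
        raise ValueError(
            f"unknown resilience category {resilience!r}; "
            f"valid: {sorted(R_PRIOR_LIMITS)}"
        ) from None
    return LognormalPrior(lo, hi)


def moving_average3(series) -> np.ndarray:
    """Centred 3-year moving average; endpoints use the 2-point window."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1-d with length >= 3")
    out = np.empty_like(x)
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = 0.5 * (x[0] + x[1])
    out[-1] = 0.5 * (x[-2] + x[-1])
    return out


def _last3_mean(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    return float(np.mean(x[-3:]))


def biomass_level_end(record) -> str:
    """Classify the stock's terminal biomass level as ``"High"`` or ``"Low"``.

    Uses the mean B/B_MSY of the last 3 years against 1.0 when available;
    otherwise, for each abundance index, the ratio of the last-3-year mean
    to the historical maximum against 0.5, combined by majority rule (ties
    resolve to the precautionary ``"Low"``).
    """
    b = getattr(record, "b_over_bmsy", None)
    if b is not None:
        b = np.asarray(b, dtype=float)
        if np.sum(~np.isnan(b)) >= 3:
            return "High" if _last3_mean(b) > 1.0 else "Low"
    indices = getattr(record, "indices", None)
    if indices is not None:
        votes = []
        for row in np.atleast_2d(np.asarray(indices, dtype=float)):
            obs = row[~np.isnan(row)]
            if obs.size < 3 or np.max(obs) <= 0:
                continue
            votes.append(np.mean(obs[-3:]) / np.max(obs) > 0.5)
        if votes:
            n_high = sum(votes)
            return "High" if n_high > len(votes) - n_high else "Low"
    raise ValueError("no usable B/B_MSY or abundance series (need >= 3 years)")


def k_prior(catch, r_prior: LognormalPrior, level: str) -> LognormalPrior:
    """Prior for carrying capacity from smoothed maximum catch and the r prior.

    ``level`` is the terminal biomass level from :func:`biomass_level_end`:
    High -> limits (2 maxC / r_upper, 12 maxC / r_lower);
    Low  -> limits (maxC / r_upper, 4 maxC / r_lower),
    with maxC the maximum of the 3-year-smoothed catch.
    """
    c = np.asarray(catch, dtype=float)
    if np.nanmax(c) <= 0:
        raise ValueError("catch series is all zero; cannot scale a K prior")
    max_c = float(np.nanmax(moving_average3(c)))
    if level == "High":
        lo, hi = 2.0 * max_c / r_prior.upper, 12.0 * max_c / r_prior.lower
    elif level == "Low":
        lo, hi = max_c / r_prior.upper, 4.0 * max_c / r_prior.lower
    else:
        raise ValueError(f"level must be 'High' or 'Low', got {level!r}")
    return LognormalPrior(lo, hi)


def _classify_bbmsy(v: float) -> str:
    if v >= 1.75:
        return "Close to unexploited"
    if v > 1.25:
        return "More than half"
    if v > 0.75:
        return "About half"
    if v > 0.25:
        return "Small"
    return "Very small"


def _classify_abundance(v: float) -> str:
    if v >= 0.80:
        return "Close to unexploited"
    if v > 0.60:
        return "More than half"
    if v > 0.40:
        return "About half"
    if v > 0.20:
        return "Small"
    return "Very small"


def _classify_catch(v: float) -> str:
    # Inverted ordering: a large early catch fraction implies a small stock.
    if v >= 0.80:
        return "Very small"
    if v > 0.60:
        return "Small"
    if v > 0.40:
        return "About half"
    if v > 0.20:
        return "More than half"
    return "Close to unexploited"


def _first3_mean(x: np.ndarray):
    """Mean of the first 3 observed values iff the series starts observed."""
    if np.isnan(x[0]) or np.sum(~np.isnan(x[:3])) < 3:
        return None
    return float(np.mean(x[:3]))


def qualitative_stock_size(record) -> StockSizeCategory:
    """Qualitative stock size at the start of the catch series.

    Tries, in order: mean B/B_MSY of the initial 3 years; the ratio of the
    initial-3-year mean of each abundance index to its historical maximum
    (A/A_MAX, majority vote across indices, ties to the smaller category);
    and finally the initial-3-year mean catch over the maximum catch
    (C/C_MAX, inverted ordering). A series only qualifies if it is aligned
    with the catch start (first value observed).
    """
    b = getattr(record, "b_over_bmsy", None)
    if b is not None:
        v = _first3_mean(np.asarray(b, dtype=float))
        if v is not None:
            return StockSizeCategory(_classify_bbmsy(v), "bbmsy")
    indices = getattr(record, "indices", None)
    if indices is not None:
        labels = []
        for row in np.atleast_2d(np.asarray(indices, dtype=float)):
            v = _first3_mean(row)
            obs = row[~np.isnan(row)]
            if v is None or obs.size == 0 or np.max(obs) <= 0:
                continue
            labels.append(_classify_abundance(v / float(np.max(obs))))
        if labels:
            ranks = sorted(STOCK_SIZE_LABELS.index(l) for l in labels)
            # majority by median rank; even ties resolve toward depletion
            return StockSizeCategory(
                STOCK_SIZE_LABELS[ranks[(len(ranks) - 1) // 2]], "abundance"
            )
    catch = getattr(record, "catch", None)
    if catch is not None:
        c = np.asarray(catch, dtype=float)
        v = _first3_mean(c)
        if v is not None and np.nanmax(c) > 0:
            return StockSizeCategory(_classify_catch(v / float(np.nanmax(c))), "catch")
    raise ValueError("no series usable for qualitative stock size")


def psi_prior(category: StockSizeCategory | str) -> LognormalPrior:
    """Prior for initial depletion psi from the qualitative stock size."""
    label = category.label if isinstance(category, StockSizeCategory) else category
    if label not in PSI_PRIOR_LIMITS:
        raise ValueError(
            f"unknown stock-size label {label!r}; valid: {list(PSI_PRIOR_LIMITS)}"
        )
    lo, hi = PSI_PRIOR_LIMITS[label]
    return LognormalPrior(lo, hi)
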