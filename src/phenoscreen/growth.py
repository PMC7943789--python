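"""Net growth rates, DIP-normalized rates, and log2 count changes.

The growth-rate-inhibition readout of the pipeline.  A population growing
exponentially from ``N_t1`` to ``N_t2`` has net growth rate

    mu = ln(N_t2 / N_t1) / (t2 - t1)        [day^-1]

and the average net growth rate of a treatment condition is the mean of
the per-interval rates over consecutive observed timepoints.  Drug
sensitivity is compared across cell lines through the drug-induced
proliferation (DIP) rate, the treated rate normalized to the matched
vehicle (DMSO) rate:

    DIP = mu_drug / mu_DMSO

DIP < 0 indicates net cell loss (cytotoxicity), DIP = 0 a constant viable
cell number (cytostasis), and DIP = 1 growth at the control rate (no drug
effect).  Rates are computed per replicate and then averaged across
replicates, never by pooling counts first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    InsufficientDataError,
    MissingControlError,
    NonNormalizableError,
)

__all__ = [
    "GrowthRateEstimate",
    "NormalizedGrowthRate",
    "net_growth_rate",
    "average_growth_rate",
    "normalized_growth_rate",
    "log2_count_change",
    "growth_rate_table",
    "dip_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrowthRateEstimate:
    """A net growth rate (day^-1) over an interval; ``mu`` equals the
    arithmetic mean of the per-interval rates in ``interval_rates``."""

    mu: float
    interval: tuple[float, float]
    interval_rates: tuple[float, ...] = ()


@dataclass(frozen=True)
class NormalizedGrowthRate:
    """DIP rate: treated over control net growth rate (dimensionless)."""

    dip: float
    mu_drug: float
    mu_dmso: float


def _series_arrays(tc: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(tc["time_days"], dtype=float)
    n = np.asarray(tc["live_count"], dtype=float)
    order = np.argsort(t, kind="stable")
    t, n = t[order], n[order]
    if np.any(np.diff(t) <= 0):
        raise DomainError("timepoints must be strictly increasing within a series")
    if np.any(n <= 0):
        raise DomainError("live counts must be positive")
    return t, n


def net_growth_rate(
    tc: pd.DataFrame, interval: tuple[float, float]
) -> GrowthRateEstimate:
    """Net growth rate over one interval of a single count series.

    ``tc`` is one replicate's time course (columns ``time_days``,
    ``live_count``); both interval endpoints must be observed timepoints.
    """
    t, n = _series_arrays(tc)
    t1, t2 = float(interval[0]), float(interval[1])
    if t2 == t1:
        raise DomainError("interval endpoints coincide; rate undefined")
    lookup = {tp: cnt for tp, cnt in zip(t, n)}
    if t1 not in lookup or t2 not in lookup:
        raise DomainError(f"interval ({t1}, {t2}) not present in the series")
    mu = float(np.log(lookup[t2] / lookup[t1]) / (t2 - t1))
    return GrowthRateEstimate(mu=mu, interval=(t1, t2), interval_rates=(mu,))


def average_growth_rate(tc: pd.DataFrame) -> GrowthRateEstimate:
    """Mean of the net growth rates over consecutive observed intervals.

    Intervals are formed only between consecutive observed timepoints
    (no interpolation), and each interval contributes equally to the
    mean regardless of its duration.
    """
    t, n = _series_arrays(tc)
    if t.size < 2:
        raise InsufficientDataError("need >= 2 timepoints for a growth rate")
    rates = np.diff(np.log(n)) / np.diff(t)
    return GrowthRateEstimate(
        mu=float(rates.mean()),
        interval=(float(t[0]), float(t[-1])),
        interval_rates=tuple(float(r) for r in rates),
    )


def normalized_growth_rate(mu_drug: float, mu_dmso: float) -> NormalizedGrowthRate:
    """DIP rate mu_drug / mu_dmso; requires a growing control."""
    if not np.isfinite(mu_drug) or not np.isfinite(mu_dmso):
        raise DomainError("growth rates must be finite")
    if mu_dmso <= 0:
        raise NonNormalizableError(
            f"control growth rate {mu_dmso} <= 0; DIP normalization undefined"
        )
    return NormalizedGrowthRate(
        dip=float(mu_drug) / float(mu_dmso),
        mu_drug=float(mu_drug),
        mu_dmso=float(mu_dmso),
    )


def log2_count_change(tc: pd.DataFrame, t_ref: float) -> pd.Series:
    """log2(N_t / N_ref) at every observed timepoint of one series."""
    t, n = _series_arrays(tc)
    t_ref = float(t_ref)
    where = np.flatnonzero(t == t_ref)
    if where.size == 0:
        raise DomainError(f"reference timepoint {t_ref} not present")
    return pd.Series(np.log2(n / n[where[0]]), index=pd.Index(t, name="time_days"))


def growth_rate_table(
    timecourses: pd.DataFrame,
    *,
    by: Sequence[str] = ("condition_id",),
) -> pd.DataFrame:
    """Average net growth rate per condition, replicate-first.

    Rates are computed per replicate series with
    :func:`average_growth_rate` and then averaged across replicates.
    Returns one row per ``by`` group with columns ``mu`` (mean across
    replicates), ``mu_sd`` and ``n_replicates``.
    """
    by = list(by)
    per_rep = (
        timecourses.groupby(by + ["replicate"], sort=True, observed=True)
        .apply(lambda g: average_growth_rate(g).mu, include_groups=False)
        .rename("mu_rep")
        .reset_index()
    )
    out = (
        per_rep.groupby(by, sort=True, observed=True)["mu_rep"]
        .agg(mu="mean", mu_sd="std", n_replicates="count")
        .reset_index()
    )
    return out


def dip_table(
    rates: pd.DataFrame,
    *,
    control_mask: pd.Series,
    by: Sequence[str] = ("cell_line",),
) -> pd.DataFrame:
    """Attach DIP values to a per-condition rate table.

    ``rates`` has one row per condition with a ``mu`` column;
    ``control_mask`` marks the vehicle rows.  Each group defined by
    ``by`` must contain exactly one control row; its ``mu`` is the
    denominator for every row of the group.  Groups whose control rate
    is <= 0 are excluded with a logged warning (the normalization
    presumes growing controls).
    """
    by = list(by)
    out = []
    for key, grp in rates.groupby(by, sort=True, observed=True):
        ctrl = grp.loc[control_mask.reindex(grp.index).fillna(False).astype(bool)]
        if len(ctrl) == 0:
            raise MissingControlError(f"no vehicle control row for group {key!r}")
        if len(ctrl) > 1:
            raise DomainError(
                f"group {key!r} has {len(ctrl)} control rows, expected exactly 1"
            )
        mu_dmso = float(ctrl["mu"].iloc[0])
        if mu_dmso <= 0:
            logger.warning(
                "group %r excluded: control growth rate %.4g <= 0 is not "
                "DIP-normalizable",
                key,
                mu_dmso,
            )
            continue
        g = grp.copy()
        g["mu_dmso"] = mu_dmso
        g["dip"] = g["mu"] / mu_dmso
        out.append(g)
    if not out:
        return rates.iloc[0:0].assign(mu_dmso=[], dip=[])
    return pd.concat(out).sort_index()
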