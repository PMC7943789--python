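"""Deviation-from-Bliss-independence scoring of drug combinations.

DIP rates are unbounded (a strongly cytotoxic treatment has DIP < 0), so
before applying the Bliss independence model each DIP is mapped to a
fraction affected

    fa = (1 - DIP) / (1 - min(DIP))

where min(DIP) is the minimum DIP observed across all cell lines and
treatment conditions of the analysis dataset: the most effective
treatment anywhere defines fa = 1 and an ineffective treatment
(DIP = 1) defines fa = 0.  A pair of drugs A and B acting independently
is expected to affect the fraction fa(A) + fa(B) - fa(A) fa(B); the
deviation from Bliss independence is the ratio of that expectation to the
observed combination effect,

    DBI = (fa(A) + fa(B) - fa(A) fa(B)) / fa(A+B)

so DBI = 1 means an additive (independent) combination, DBI < 1 a
stronger-than-expected one (synergy), DBI > 1 a weaker-than-expected one
(antagonism).  Values of fa outside [0, 1] (DIP > 1, i.e. faster than
control growth) are propagated with a warning rather than clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDatasetError, DomainError, UndefinedScoreError

__all__ = [
    "BlissScore",
    "global_min_dip",
    "fraction_affected",
    "deviation_from_bliss",
    "score_combination_table",
    "DEFAULT_ADDITIVITY_TOL",
]

#: Half-width of the band |DBI - 1| <= tol labelled "additive".  The DBI
#: definition itself carries no band; this default is this package's own
#: reporting choice and is configurable everywhere it is used.
DEFAULT_ADDITIVITY_TOL = 0.05


@dataclass(frozen=True)
class BlissScore:
    """Fractions affected of the single agents and the combination, the
    DBI value, and the categorical call."""

    fa_a: float
    fa_b: float
    fa_ab: float
    dbi: float
    call: str  # {"synergy", "additive", "antagonism"}


def global_min_dip(dips) -> float:
    """Dataset-wide min(DIP) reference for the fraction-affected map.

    Computed once per analysis dataset over every cell line and
    treatment condition, and recorded in the run manifest.
    """
    arr = np.asarray(list(dips), dtype=float)
    if arr.size == 0:
        raise DomainError("empty DIP collection")
    if not np.all(np.isfinite(arr)):
        raise DomainError("DIP values must be finite")
    m = float(arr.min())
    if m >= 1:
        raise DegenerateDatasetError(
            f"min(DIP) = {m} >= 1: no treatment had any effect; "
            "fraction affected is not well posed"
        )
    return m


def fraction_affected(dip, min_dip: float):
    """fa = (1 - DIP) / (1 - min(DIP)); affine and order-reversing in DIP.

    Accepts scalars or arrays.  fa > 1 cannot occur by construction of
    min_dip on the same dataset; fa < 0 (DIP > 1) is permitted but
    flagged with a warning, since the map is defined for unbounded drug
    effects.
    """
    if min_dip >= 1:
        raise DomainError(f"min_dip = {min_dip} >= 1; map undefined")
    fa = (1.0 - np.asarray(dip, dtype=float)) / (1.0 - min_dip)
    if np.any(fa < 0) or np.any(fa > 1):
        warnings.warn(
            "fraction affected outside [0, 1] (DIP beyond the dataset range); "
            "propagating unclipped",
            stacklevel=2,
        )
    if np.ndim(dip) == 0:
        return float(fa)
    return fa


def _call(dbi: float, additivity_tol: float) -> str:
    if abs(dbi - 1.0) <= additivity_tol:
        return "additive"
    return "synergy" if dbi < 1.0 else "antagonism"


def deviation_from_bliss(
    fa_a: float,
    fa_b: float,
    fa_ab: float,
    *,
    additivity_tol: float = DEFAULT_ADDITIVITY_TOL,
) -> BlissScore:
    """DBI of one drug pair from its three fractions affected."""
    if fa_ab == 0:
        raise UndefinedScoreError(
            "combination fraction affected is 0; DBI undefined "
            "(combination had no effect)"
        )
    expected = fa_a + fa_b - fa_a * fa_b
    dbi = expected / fa_ab
    return BlissScore(
        fa_a=float(fa_a),
        fa_b=float(fa_b),
        fa_ab=float(fa_ab),
        dbi=float(dbi),
        call=_call(float(dbi), additivity_tol),
    )


def score_combination_table(
    table: pd.DataFrame,
    *,
    min_dip: float | None = None,
    additivity_tol: float = DEFAULT_ADDITIVITY_TOL,
) -> pd.DataFrame:
    """Score a tidy table of combinations.

    ``table`` needs columns ``dip_a``, ``dip_b``, ``dip_ab`` (single
    agents and combination); any identifier columns are carried through.
    ``min_dip`` defaults to the minimum over all three DIP columns of
    the table — pass the dataset-wide value explicitly when the table is
    a subset of the analysis dataset.  Rows with fa_ab = 0 are excluded
    with a warning and an ``undefined`` flag in the returned frame.
    """
    dip_cols = ["dip_a", "dip_b", "dip_ab"]
    if min_dip is None:
        min_dip = global_min_dip(table[dip_cols].to_numpy().ravel())
    out = table.copy()
    for c in dip_cols:
        out["fa" + c[3:]] = fraction_affected(out[c].to_numpy(), min_dip)
    undefined = out["fa_ab"] == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} combination(s) with fa_ab = 0 flagged as "
            "undefined and excluded from DBI",
            stacklevel=2,
        )
    expected = out["fa_a"] + out["fa_b"] - out["fa_a"] * out["fa_b"]
    out["dbi"] = np.where(undefined, np.nan, expected / out["fa_ab"].replace(0, np.nan))
    out["undefined"] = undefined
    out["call"] = [
        "undefined" if u else _call(d, additivity_tol)
        for u, d in zip(undefined, out["dbi"].fillna(np.inf))
    ]
    out.attrs["min_dip"] = min_dip
    return out
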