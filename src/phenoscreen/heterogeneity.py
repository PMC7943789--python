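"""Single-cell heterogeneity statistics and High/Low marker gating.

Three per-population summaries of cell-to-cell variability:

* **Fano factor** (index of dispersion): variance-to-mean ratio of the
  raw marker intensities of a population.  Equals 1 for a Poisson
  distributed measurement; scales linearly under intensity rescaling.
  Computed on the raw (non-log) scale, where variance-to-mean is a
  meaningful dispersion index.
* **Mean pairwise distance**: the mean Euclidean distance over all
  n(n-1)/2 unordered cell pairs in z-scored marker space, a joint
  heterogeneity measure across markers.  Exact up to ``max_cells``
  cells, seeded subsampling above.
* **Binary gating**: each marker's pooled log-intensity distribution is
  split into X^High / X^Low classes, by default at the equal-posterior
  boundary of a two-component Gaussian mixture (a computational stand-in
  for gates drawn by inspecting histograms); a manual threshold override
  is always available.  Per-condition High fractions are the gated
  readout.

Preprocessing for distance/embedding analyses is natural-log transform
followed by per-marker z-scoring across the pooled cell set (sample
standard deviation, ddof=1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import pdist
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .errors import DomainError, GateFitError, InsufficientDataError

__all__ = [
    "GateSpec",
    "MixtureGate",
    "log_zscore",
    "subsample_cells",
    "fano_factor",
    "mean_pairwise_distance",
    "fit_gate",
    "apply_gate",
    "heterogeneity_table",
]

DEFAULT_CONDITION_COLS = ("cell_line", "treatment", "timepoint")


@dataclass(frozen=True)
class GateSpec:
    """A binary gate: ln-intensity threshold for one marker."""

    marker: str
    threshold: float  # on the natural-log intensity scale
    provenance: str  # {"auto", "manual"}


def log_zscore(
    table: pd.DataFrame,
    markers: Sequence[str],
    *,
    ddof: int = 1,
) -> pd.DataFrame:
    """ln-transform then z-score each marker across all pooled cells.

    Degenerate (constant) markers z-score to all zeros with a warning
    instead of dividing by zero.  Uses the sample standard deviation
    (ddof=1) — negligibly different from the population convention at
    realistic cell numbers, but fixed for reproducibility.
    """
    out = table.copy()
    for m in markers:
        vals = np.asarray(out[m], dtype=float)
        if np.any(vals <= 0):
            raise DomainError(f"marker {m!r} has nonpositive intensities")
        logged = np.log(vals)
        sd = logged.std(ddof=ddof) if logged.size > ddof else 0.0
        if sd == 0:
            warnings.warn(
                f"marker {m!r} is constant; z-scores set to 0", stacklevel=2
            )
            out[m] = 0.0
        else:
            out[m] = (logged - logged.mean()) / sd
    return out


def subsample_cells(
    table: pd.DataFrame,
    per_condition: int,
    seed: int,
    *,
    condition_cols: Sequence[str] = DEFAULT_CONDITION_COLS,
) -> pd.DataFrame:
    """Uniform without-replacement subsample of up to ``per_condition``
    cells from every condition; smaller conditions contribute all their
    cells.  Deterministic for a fixed seed."""
    if per_condition < 1:
        raise DomainError("per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    picked = []
    for _, grp in table.groupby(list(condition_cols), sort=True, observed=True):
        if len(grp) <= per_condition:
            picked.append(grp)
        else:
            idx = rng.choice(len(grp), size=per_condition, replace=False)
            picked.append(grp.iloc[np.sort(idx)])
    return pd.concat(picked).reset_index(drop=True)


def fano_factor(values) -> float:
    """Variance-to-mean ratio of raw intensities (1 for Poisson)."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean <= 0:
        raise DomainError(f"mean {mean} <= 0; Fano factor undefined")
    var = arr.var(ddof=1) if arr.size > 1 else 0.0
    return float(var / mean)


def mean_pairwise_distance(
    X,
    *,
    max_cells: int = 5000,
    seed: int = 0,
) -> float:
    """Mean Euclidean distance over all unordered cell pairs.

    ``X`` is cells x markers (z-scored).  Exact O(n^2) computation up to
    ``max_cells`` rows; larger populations are subsampled with the given
    seed before the exact computation.
    """
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < 2:
        raise InsufficientDataError("need >= 2 cells for a pairwise distance")
    if arr.shape[0] > max_cells:
        rng = np.random.default_rng(seed)
        arr = arr[rng.choice(arr.shape[0], size=max_cells, replace=False)]
    return float(pdist(arr, metric="euclidean").mean())


class MixtureGate(BaseEstimator):
    """Binary High/Low gate from a two-component Gaussian mixture.

    Fit on pooled ln-intensities spanning conditions (including
    controls); the threshold is the equal-posterior boundary between the
    two component means.  ``threshold`` may be supplied to bypass the
    mixture fit entirely (manual gate).

    Parameters
    ----------
    threshold : float or None
        Manual ln-intensity threshold; ``None`` fits the mixture.
    min_separation : float
        Minimum distance between fitted component means (in pooled-sd
        units) below which the fit is declared degenerate.
    random_state : int
        Seed of the mixture EM initialization.

    Attributes
    ----------
    threshold_ : float
        The fitted (or manual) gate on the ln scale.
    provenance_ : str
        ``"auto"`` or ``"manual"``.
    """

    def __init__(
        self,
        threshold: float | None = None,
        min_separation: float = 0.5,
        random_state: int = 0,
    ):
        self.threshold = threshold
        self.min_separation = min_separation
        self.random_state = random_state

    def fit(self, X, y=None):
        vals = np.asarray(X, dtype=float).ravel()
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
            self.provenance_ = "manual"
            return self
        if np.any(vals <= 0):
            raise DomainError("intensities must be positive before the log")
        logged = np.log(vals)
        gm = GaussianMixture(
            n_components=2, random_state=self.random_state, n_init=3
        ).fit(logged[:, None])
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        weights = gm.weights_.ravel()
        lo, hi = np.sort(means)
        pooled_sd = logged.std(ddof=1)
        if pooled_sd == 0 or (hi - lo) < self.min_separation * pooled_sd:
            raise GateFitError(
                "mixture components are not separated; supply a manual threshold"
            )

        order = np.argsort(means)
        w, m, s = weights[order], means[order], sds[order]

        def posterior_diff(x: float) -> float:
            return w[0] * norm.pdf(x, m[0], s[0]) - w[1] * norm.pdf(x, m[1], s[1])

        try:
            self.threshold_ = float(brentq(posterior_diff, m[0], m[1]))
        except ValueError as exc:  # no sign change between the means
            raise GateFitError(
                "no equal-posterior boundary between the component means; "
                "supply a manual threshold"
            ) from exc
        self.provenance_ = "auto"
        return self

    def predict(self, X) -> np.ndarray:
        """True where a cell is High (ln intensity above the gate)."""
        check_is_fitted(self, "threshold_")
        vals = np.asarray(X, dtype=float).ravel()
        if np.any(vals <= 0):
            raise DomainError("intensities must be positive before the log")
        return np.log(vals) > self.threshold_

    def high_fraction(self, X) -> float:
        return float(self.predict(X).mean())


def fit_gate(
    values,
    *,
    marker: str,
    threshold: float | None = None,
    random_state: int = 0,
) -> GateSpec:
    """Fit (or accept) a binary gate for one marker's raw intensities."""
    gate = MixtureGate(threshold=threshold, random_state=random_state).fit(values)
    return GateSpec(
        marker=marker, threshold=gate.threshold_, provenance=gate.provenance_
    )


def apply_gate(
    table: pd.DataFrame,
    gates: Mapping[str, GateSpec] | Sequence[GateSpec],
    *,
    condition_cols: Sequence[str] = DEFAULT_CONDITION_COLS,
) -> pd.DataFrame:
    """Per-condition fraction of X^High cells for every gated marker.

    Returns one row per condition with a ``{marker}_high_fraction``
    column per gate.
    """
    if not isinstance(gates, Mapping):
        gates = {g.marker: g for g in gates}
    rows = []
    for key, grp in table.groupby(list(condition_cols), sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(condition_cols, key))
        row["n_cells"] = len(grp)
        for marker, gate in gates.items():
            vals = np.asarray(grp[marker], dtype=float)
            if np.any(vals <= 0):
                raise DomainError(f"marker {marker!r} has nonpositive intensities")
            row[f"{marker}_high_fraction"] = float(
                (np.log(vals) > gate.threshold).mean()
            )
        rows.append(row)
    return pd.DataFrame(rows)


def heterogeneity_table(
    table: pd.DataFrame,
    markers: Sequence[str],
    *,
    condition_cols: Sequence[str] = DEFAULT_CONDITION_COLS,
    max_cells: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-condition Fano factors (raw scale) and mean pairwise distance
    (z-scored marker space, z-scoring pooled across all cells)."""
    zscored = log_zscore(table, markers)
    rows = []
    keys = list(condition_cols)
    for (key, grp_raw), (_, grp_z) in zip(
        table.groupby(keys, sort=True, observed=True),
        zscored.groupby(keys, sort=True, observed=True),
    ):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        row["n_cells"] = len(grp_raw)
        for m in markers:
            row[f"fano_{m}"] = fano_factor(grp_raw[m])
        if len(grp_z) >= 2:
            row["mean_pairwise_distance"] = mean_pairwise_distance(
                grp_z[list(markers)].to_numpy(), max_cells=max_cells, seed=seed
            )
        else:
            row["mean_pairwise_distance"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
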