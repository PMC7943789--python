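"""Screen hit calling and mechanism clustering of the response matrix.

A compound condition is a (compound, dose, cell line, MAPK condition,
timepoint) cell of the screen.  Its effect is the difference between the
net growth rate of the compound-treated wells and the mean rate of the
matched no-compound control pool (same cell line, MAPK condition and
timepoint).  A compound is a **hit** when, in at least one of its tested
conditions, the decrease passes both filters:

* statistical: two-sample t-test of the compound replicates against the
  pooled controls, significant at the Dunn-Sidak-corrected per-test
  level ``1 - (1 - alpha)^(1/m)``, where m counts every comparison of
  the run (recorded in the output so the family is auditable).  The
  pooled-variance test is the default: with only two compound
  replicates, a separate-variance (Welch) test has ~1 denominator
  degree of freedom and is strongly anticonservative at the deep tail
  probabilities the multiplicity correction requires, whereas the
  pooled test borrows the large control pool's variance and is exactly
  calibrated when well-to-well variability is shared — which the
  constant-CV count-noise model guarantees.  ``variance="welch"``
  restores the separate-variance test;
* effect size: the growth-rate decrease is at least ``effect_threshold``
  (default 0.5 day^-1, applied to the net-rate delta; a config switch
  allows the dimensionless normalized-rate reading instead).

For mechanism inference, per-compound changes in growth rate and in
log-intensity of co-stained readouts (p-Erk, p-Rb, Mitf) are averaged
across timepoints and doses into a response matrix (rows = compounds,
columns = readout x cell line x MAPK condition) and clustered with the
correlation distance and complete linkage.  Rows are pre-sorted
lexicographically by compound label so tied merges are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from scipy.stats import ttest_ind

from .errors import DomainError, MissingControlError

__all__ = [
    "well_growth_rates",
    "normalize_to_control",
    "dunn_sidak_alpha",
    "call_hits",
    "compound_hits",
    "build_response_matrix",
    "hierarchical_cluster",
    "ClusterResult",
]

WELL_KEYS = ["cell_line", "mapk_condition", "compound", "dose", "replicate"]
CONDITION_KEYS = ["compound", "dose", "cell_line", "mapk_condition", "timepoint"]
CONTROL_KEYS = ["cell_line", "mapk_condition", "timepoint"]


def well_growth_rates(screen_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-well net growth rates from t0 to each later timepoint.

    One output row per well and post-baseline timepoint, with ``mu``
    the net rate over (t0, t); matches reading out the screen after
    each exposure duration.
    """
    t0 = screen_counts["time_days"].min()
    base = (
        screen_counts[screen_counts["time_days"] == t0]
        .set_index(WELL_KEYS)["live_count"]
    )
    later = screen_counts[screen_counts["time_days"] > t0].copy()
    n0 = base.reindex(pd.MultiIndex.from_frame(later[WELL_KEYS])).to_numpy()
    if np.any(~np.isfinite(n0)):
        raise DomainError("wells missing a baseline (t0) count")
    later["mu"] = np.log(later["live_count"].to_numpy() / n0) / (
        later["time_days"].to_numpy() - t0
    )
    later = later.rename(columns={"time_days": "timepoint"})
    return later[WELL_KEYS + ["timepoint", "mu"]]


def normalize_to_control(
    data: pd.DataFrame,
    *,
    value_col: str = "mu",
    control_label: str = "DMSO",
    group_cols: Sequence[str] = CONTROL_KEYS,
) -> pd.DataFrame:
    """Delta of ``value_col`` vs the matched no-compound control mean.

    Controls are the rows whose ``compound`` equals ``control_label``;
    within each ``group_cols`` group (cell line, MAPK condition,
    timepoint by default, plus ``readout`` for protein tables) every row
    gets ``delta = value - mean(control values)``.  A group with treated
    rows but no control raises :class:`MissingControlError` naming the
    orphan condition.  Growth deltas are rate differences in day^-1;
    protein deltas are differences of log-transformed intensities.
    """
    group_cols = list(group_cols)
    is_ctrl = data["compound"] == control_label
    ctrl_mean = (
        data[is_ctrl].groupby(group_cols, sort=False, observed=True)[value_col].mean()
    )
    keys = pd.MultiIndex.from_frame(data[group_cols])
    ref = ctrl_mean.reindex(keys).to_numpy()
    orphan = ~np.isfinite(ref)
    if orphan.any():
        missing = data.loc[orphan, group_cols].drop_duplicates()
        raise MissingControlError(
            "no matched control for condition(s): "
            + "; ".join(str(tuple(r)) for r in missing.itertuples(index=False))
        )
    out = data.copy()
    out["control_mean"] = ref
    out["delta"] = out[value_col].to_numpy() - ref
    return out


def dunn_sidak_alpha(alpha: float, m: int) -> float:
    """Per-test threshold 1 - (1 - alpha)^(1/m) controlling the
    family-wise error over m independent comparisons."""
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    if m < 1:
        raise DomainError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def call_hits(
    rates: pd.DataFrame,
    *,
    alpha: float = 0.05,
    effect_threshold: float = 0.5,
    control_label: str = "DMSO",
    effect_on: str = "net",
    variance: str = "pooled",
) -> pd.DataFrame:
    """Per-condition hit calls from well-level growth rates.

    ``rates`` is the output of :func:`well_growth_rates`.  Each compound
    condition's replicates are tested against the pooled matched
    controls with a two-sample t-test (``variance``: "pooled" for the
    equal-variance test, "welch" for separate variances — see the
    module docstring for why pooled is the default at n=2 replicates).
    ``effect_on`` selects the scale of the effect filter: ``"net"``
    applies ``delta_mu <= -effect_threshold`` in day^-1; ``"normalized"``
    divides the delta by the control mean rate first.

    Returns one row per condition with ``delta_mu``, ``t_stat``,
    ``p_raw`` and ``significant``; the family size ``m``, ``alpha`` and
    the corrected per-test level are stored in ``.attrs``.  Conditions
    with zero variance in both groups are skipped with a warning.
    """
    if effect_on not in ("net", "normalized"):
        raise DomainError("effect_on must be 'net' or 'normalized'")
    if variance not in ("pooled", "welch"):
        raise DomainError("variance must be 'pooled' or 'welch'")
    treated = rates[rates["compound"] != control_label]
    controls = rates[rates["compound"] == control_label]
    ctrl_groups = {
        key: grp["mu"].to_numpy()
        for key, grp in controls.groupby(CONTROL_KEYS, sort=False, observed=True)
    }
    rows = []
    skipped = 0
    for key, grp in treated.groupby(CONDITION_KEYS, sort=True, observed=True):
        compound, dose, line, mapk, tp = key
        ctrl = ctrl_groups.get((line, mapk, tp))
        if ctrl is None:
            raise MissingControlError(
                f"no control pool for {(line, mapk, tp)!r}"
            )
        mus = grp["mu"].to_numpy()
        if mus.size < 2:
            raise DomainError(
                f"condition {key!r} has {mus.size} replicate(s); need >= 2"
            )
        if np.ptp(mus) == 0 and np.ptp(ctrl) == 0:
            skipped += 1
            continue
        t_stat, p_raw = ttest_ind(mus, ctrl, equal_var=(variance == "pooled"))
        delta = float(mus.mean() - ctrl.mean())
        effect = delta if effect_on == "net" else delta / float(ctrl.mean())
        rows.append(
            {
                "compound": compound,
                "dose": dose,
                "cell_line": line,
                "mapk_condition": mapk,
                "timepoint": tp,
                "delta_mu": delta,
                "effect": float(effect),
                "t_stat": float(t_stat),
                "p_raw": float(p_raw),
            }
        )
    if skipped:
        warnings.warn(
            f"{skipped} condition(s) skipped: zero variance in both groups",
            stacklevel=2,
        )
    calls = pd.DataFrame(rows)
    m = len(calls)
    p_threshold = dunn_sidak_alpha(alpha, m) if m else np.nan
    if m:
        calls["significant"] = (calls["p_raw"] < p_threshold) & (
            calls["effect"] <= -effect_threshold
        )
    calls.attrs.update(
        {
            "m": m,
            "alpha": alpha,
            "p_threshold": p_threshold,
            "effect_threshold": effect_threshold,
            "effect_on": effect_on,
        }
    )
    return calls


def compound_hits(calls: pd.DataFrame) -> pd.Series:
    """Compound-level flag: significant in at least one tested condition."""
    return calls.groupby("compound", sort=True)["significant"].any()


def build_response_matrix(
    normalized: pd.DataFrame,
    *,
    average_over: Sequence[str] = ("timepoint", "dose"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Compound x (readout, cell line, MAPK condition) response matrix.

    ``normalized`` is long-format with columns ``compound, readout,
    cell_line, mapk_condition, dose, timepoint, delta`` (growth deltas
    and protein log-intensity deltas stacked); each matrix cell is the
    mean delta over ``average_over`` (and replicates).  Returns the
    matrix and a boolean Series flagging compounds with missing cells
    (incomplete rows are kept but flagged).
    """
    required = {"compound", "readout", "cell_line", "mapk_condition", "delta"}
    missing = required - set(normalized.columns)
    if missing:
        raise DomainError(f"normalized table missing columns: {sorted(missing)}")
    cell = (
        normalized.groupby(
            ["compound", "readout", "cell_line", "mapk_condition"],
            sort=True,
            observed=True,
        )["delta"]
        .mean()
        .rename("delta")
        .reset_index()
    )
    matrix = cell.pivot_table(
        index="compound",
        columns=["readout", "cell_line", "mapk_condition"],
        values="delta",
    ).sort_index()
    incomplete = matrix.isna().any(axis=1)
    return matrix, incomplete


@dataclass
class ClusterResult:
    """Complete-linkage dendrogram over response-matrix rows."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]  # row labels in the (lexicographic) input order
    leaf_order: list[str]  # labels in dendrogram leaf order
    newick: str


def _newick(node, labels: list[str], parent_height: float) -> str:
    length = parent_height - node.dist
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _newick(node.left, labels, node.dist)
    right = _newick(node.right, labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def hierarchical_cluster(
    matrix: pd.DataFrame,
    *,
    metric: str = "correlation",
    method: str = "complete",
) -> ClusterResult:
    """Cluster response-matrix rows (correlation distance, complete
    linkage).  Zero-variance rows (correlation undefined) are excluded
    with a warning; rows are sorted lexicographically by label first so
    tie-breaking is reproducible."""
    mat = matrix.sort_index()
    if mat.isna().any().any():
        raise DomainError("response matrix has missing cells; drop or impute first")
    variances = mat.var(axis=1, ddof=0)
    degenerate = variances == 0
    if metric == "correlation" and degenerate.any():
        warnings.warn(
            f"excluding zero-variance row(s): {list(mat.index[degenerate])}",
            stacklevel=2,
        )
        mat = mat.loc[~degenerate]
    if len(mat) < 2:
        raise DomainError("need >= 2 complete rows to cluster")
    dists = pdist(mat.to_numpy(float), metric=metric)
    Z = linkage(dists, method=method)
    tree = to_tree(Z)
    labels = list(mat.index)
    leaf_order = [labels[i] for i in tree.pre_order(lambda n: n.id)]
    newick = f"({_newick(tree.left, labels, tree.dist)},{_newick(tree.right, labels, tree.dist)});"
    return ClusterResult(
        linkage=Z, labels=labels, leaf_order=leaf_order, newick=newick
    )
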