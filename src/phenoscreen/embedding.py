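"""z-score -> PCA -> t-SNE embedding of pooled single-cell data.

The pooled, log-transformed and z-scored marker matrix is reduced by PCA
and the scores of the first two principal components are embedded in 2-D
with Barnes-Hut t-SNE.  t-SNE defaults match a high-cell-count setting
(learning rate 1000, 2000 optimization iterations, perplexity 480,
early exaggeration 4); the perplexity is reduced automatically (with a
warning) when the population is too small for it.  The t-SNE stage is a
delegated standard algorithm: its contract is seed-reproducibility and
preservation of cluster structure, not specific coordinates.

Per-cell-line "projections" reproduce the overlay view: the full map in
gray with one condition's cells masked in and colored by a z-scored
marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .errors import DomainError
from .heterogeneity import log_zscore

__all__ = ["EmbeddingResult", "pca_embed", "tsne_embed", "embed_single_cells",
           "project_condition"]

DEFAULT_TSNE_PARAMS = {
    "algorithm": "barnes_hut",
    "learning_rate": 1000.0,
    "max_iter": 2000,
    "perplexity": 480.0,
    "exaggeration": 4.0,
}


@dataclass
class EmbeddingResult:
    """PCA scores/variance fractions and the 2-D t-SNE coordinates."""

    pc_scores: pd.DataFrame
    variance_explained: np.ndarray
    tsne_xy: pd.DataFrame
    tsne_params: Mapping[str, object]
    seed: int
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)


def pca_embed(
    X: pd.DataFrame | np.ndarray,
    *,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Full (or truncated) PCA of a z-scored cells x markers matrix.

    Returns (scores, variance_explained fractions, loadings).  For
    reproducibility the sign of each component is fixed so that its
    largest-magnitude loading is positive.  Rank-deficient inputs simply
    yield trailing zero-variance components.
    """
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise DomainError("PCA needs a 2-D matrix with >= 2 markers")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(arr)
    loadings = pca.components_
    flip = np.sign(loadings[np.arange(loadings.shape[0]),
                            np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    loadings = loadings * flip[:, None]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    index = X.index if isinstance(X, pd.DataFrame) else None
    return (
        pd.DataFrame(scores, columns=cols, index=index),
        pca.explained_variance_ratio_.copy(),
        loadings,
    )


def tsne_embed(
    pc_scores: pd.DataFrame | np.ndarray,
    *,
    perplexity: float = DEFAULT_TSNE_PARAMS["perplexity"],
    learning_rate: float = DEFAULT_TSNE_PARAMS["learning_rate"],
    max_iter: int = DEFAULT_TSNE_PARAMS["max_iter"],
    exaggeration: float = DEFAULT_TSNE_PARAMS["exaggeration"],
    seed: int = 0,
) -> pd.DataFrame:
    """Barnes-Hut t-SNE of PCA scores (typically the first two PCs).

    ``perplexity`` must satisfy perplexity < n/3; larger requests are
    reduced to (n - 1) / 3 with a warning.  Deterministic for a fixed
    seed on fixed input.
    """
    arr = np.asarray(pc_scores, dtype=float)
    n = arr.shape[0]
    if n <= 3 * perplexity:
        adjusted = max((n - 1) / 3.0, 2.0)
        warnings.warn(
            f"perplexity {perplexity} >= n/3 for n={n}; reduced to {adjusted:.1f}",
            stacklevel=2,
        )
        perplexity = adjusted
    tsne = TSNE(
        n_components=2,
        method="barnes_hut",
        perplexity=perplexity,
        learning_rate=learning_rate,
        max_iter=max_iter,
        early_exaggeration=exaggeration,
        init="pca",
        random_state=seed,
    )
    xy = tsne.fit_transform(arr)
    index = pc_scores.index if isinstance(pc_scores, pd.DataFrame) else None
    return pd.DataFrame(xy, columns=["tSNE1", "tSNE2"], index=index)


def embed_single_cells(
    table: pd.DataFrame,
    markers: Sequence[str],
    *,
    n_pcs_for_tsne: int = 2,
    seed: int = 0,
    **tsne_kwargs,
) -> EmbeddingResult:
    """Full z-score -> PCA -> t-SNE pipeline on a pooled cell table."""
    zscored = log_zscore(table, markers)
    scores, var_ratio, _ = pca_embed(zscored[list(markers)])
    xy = tsne_embed(scores.iloc[:, :n_pcs_for_tsne], seed=seed, **tsne_kwargs)
    params = dict(DEFAULT_TSNE_PARAMS)
    params.update(tsne_kwargs)
    meta_cols = [c for c in table.columns if c not in markers]
    return EmbeddingResult(
        pc_scores=scores,
        variance_explained=var_ratio,
        tsne_xy=xy,
        tsne_params=params,
        seed=seed,
        metadata=table[meta_cols].reset_index(drop=True),
    )


def project_condition(
    result: EmbeddingResult,
    condition: Mapping[str, object],
    *,
    color_marker: str | None = None,
    zscored_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Overlay data for one condition on the shared t-SNE map.

    ``condition`` maps metadata columns to required values (e.g.
    ``{"cell_line": "COLO858"}``).  Returns the t-SNE coordinates plus an
    ``in_condition`` mask (cells outside it are drawn in gray) and, when
    ``color_marker`` is given, that marker's z-scored values as
    ``color``.  Unknown conditions raise ``LookupError``.
    """
    meta = result.metadata
    mask = np.ones(len(meta), dtype=bool)
    for col, val in condition.items():
        if col not in meta.columns:
            raise LookupError(f"unknown metadata column {col!r}")
        mask &= (meta[col] == val).to_numpy()
    if not mask.any():
        raise LookupError(f"no cells match condition {dict(condition)!r}")
    out = result.tsne_xy.reset_index(drop=True).copy()
    out["in_condition"] = mask
    if color_marker is not None:
        if zscored_table is None:
            raise DomainError("zscored_table required when color_marker is set")
        out["color"] = np.asarray(zscored_table[color_marker], dtype=float)
    return out
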