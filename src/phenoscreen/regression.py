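"""PLSR with LOOCV/VIP and MLR with a sorted 2:1 train/validation split.

Both regressions link per-condition protein measurements (inputs) to
drug-induced normalized growth rates (responses) across cell lines.

**PLSR** (partial least squares regression, single-response PLS1) handles
many correlated predictors and few samples by regressing on latent
components.  Goodness of fit is R^2; predictive power is Q^2 from
leave-one-out cross-validation,

    Q^2 = 1 - PRESS / TSS,   PRESS = sum (y_i - yhat_(-i))^2,

together with the Pearson correlation between measured and LOO-predicted
responses.  Predictor importance is the variable importance in the
projection,

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),

over components a with explained response variance SSY_a and weight
vectors w_a; sum_j VIP_j^2 = p identically.  A sign is attached from the
Pearson correlation of the raw predictor with the raw response, so a
negative VIP marks a predictor whose increase tracks a decreased
response.

**MLR** is ordinary least squares with intercept, evaluated on a held-out
validation set chosen by the sorted 2:1 rule: sort samples by response,
then walking down the list assign two to training and one to validation,
repeating (21 samples -> 14 train / 7 validation; trailing samples of a
partial group go to training).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr as _pivoted_qr
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_is_fitted

from .errors import DomainError, InsufficientDataError

__all__ = [
    "PLSRegressionVIP",
    "MultiLinearRegression",
    "select_significant_vips",
    "split_train_validation",
    "fit_mlr",
    "predict_mlr",
    "rank_marker_correlations",
]


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DomainError("X must be 2-D with one row per response value")
    return X, y


class PLSRegressionVIP(BaseEstimator, RegressorMixin):
    """PLS1 regression with LOOCV Q^2 and signed VIP scores.

    Predictors and response are centered internally; inputs are expected
    already z-scored across conditions (the pipeline's convention), in
    which case centering is a no-op.  The latent decomposition is
    delegated to scikit-learn's NIPALS ``PLSRegression`` (for a single
    response NIPALS and SIMPLS coincide up to normalization).

    Parameters
    ----------
    n_components : int or None
        Number of latent components; ``None`` picks the value in
        ``1..min(n_samples - 2, n_features)`` maximizing LOOCV Q^2.
    scale : bool
        Also divide columns by their sd inside the PLS core (default
        False: the pipeline z-scores once, globally).

    Attributes
    ----------
    n_components_ : chosen number of components.
    r2_ : goodness of fit on the training data.
    q2_ : leave-one-out cross-validated predictive fraction.
    loocv_predictions_ : per-left-out-sample predictions.
    loocv_r_, loocv_p_ : Pearson correlation (and p) of measured vs
        LOO-predicted responses.
    vip_ : signed VIP score per predictor.
    coef_ : regression coefficients of the final model.
    """

    def __init__(self, n_components: int | None = None, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    # -- internals -----------------------------------------------------
    def _fit_core(self, X: np.ndarray, y: np.ndarray, a: int) -> PLSRegression:
        return PLSRegression(n_components=a, scale=self.scale).fit(X, y)

    def _loocv(self, X: np.ndarray, y: np.ndarray, a: int) -> np.ndarray:
        n = len(y)
        preds = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            model = self._fit_core(X[mask], y[mask], a)
            preds[i] = model.predict(X[[i]]).ravel()[0]
        return preds

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y):
        X, y = _as_xy(X, y)
        n, p = X.shape
        if n < 3:
            raise InsufficientDataError("PLSR with LOOCV needs >= 3 samples")
        if np.ptp(y) == 0:
            raise DomainError("constant response; PLSR fit rejected")
        a_max = min(n - 2, p)
        if self.n_components is None:
            best_a, best_q2 = 1, -np.inf
            for a in range(1, a_max + 1):
                preds = self._loocv(X, y, a)
                q2 = 1.0 - np.sum((y - preds) ** 2) / np.sum((y - y.mean()) ** 2)
                if q2 > best_q2:
                    best_a, best_q2 = a, q2
            a = best_a
        else:
            a = int(self.n_components)
            if a > a_max:
                warnings.warn(
                    f"n_components {a} too large for n={n}; reduced to {a_max}",
                    stacklevel=2,
                )
                a = a_max
        self.n_components_ = a
        self._pls = self._fit_core(X, y, a)
        fitted = self._pls.predict(X).ravel()
        tss = np.sum((y - y.mean()) ** 2)
        self.r2_ = float(1.0 - np.sum((y - fitted) ** 2) / tss)
        self.fitted_ = fitted

        self.loocv_predictions_ = self._loocv(X, y, a)
        press = np.sum((y - self.loocv_predictions_) ** 2)
        self.q2_ = float(1.0 - press / tss)
        r, pval = pearsonr(y, self.loocv_predictions_)
        self.loocv_r_, self.loocv_p_ = float(r), float(pval)

        self.vip_ = self._signed_vip(X, y)
        self.coef_ = self._pls.coef_.ravel().copy()
        self._X_fit, self._y_fit = X, y
        return self

    def predict(self, X):
        check_is_fitted(self, "n_components_")
        return self._pls.predict(np.asarray(X, dtype=float)).ravel()

    # -- VIP -----------------------------------------------------------
    def _signed_vip(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        W = self._pls.x_weights_  # p x A
        T = self._pls.x_scores_  # n x A
        q = self._pls.y_loadings_.ravel()  # A
        ssy = (T**2).sum(axis=0) * q**2  # response variance per component
        total = ssy.sum()
        if total <= 0:
            raise DomainError("model explains no response variance; VIP undefined")
        p = W.shape[0]
        wnorm2 = (W**2).sum(axis=0)
        wnorm2[wnorm2 == 0] = np.inf
        vip = np.sqrt(p * ((W**2 / wnorm2) @ ssy) / total)
        signs = np.array(
            [
                np.sign(np.corrcoef(X[:, j], y)[0, 1]) if np.ptp(X[:, j]) > 0 else 1.0
                for j in range(p)
            ]
        )
        signs[signs == 0] = 1.0
        return vip * signs


def select_significant_vips(
    vips: pd.Series | np.ndarray,
    p_values: pd.Series | np.ndarray,
    *,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
) -> np.ndarray:
    """Predictors with |VIP| strictly above 1 and a significant Pearson
    correlation with the response (p < 0.05): the highlighted marker set."""
    v = np.asarray(vips, dtype=float)
    p = np.asarray(p_values, dtype=float)
    mask = (np.abs(v) > vip_threshold) & (p < alpha)
    if isinstance(vips, pd.Series):
        return vips.index.to_numpy()[mask]
    return np.flatnonzero(mask)


def split_train_validation(
    sample_ids: Sequence,
    responses: Sequence[float],
) -> tuple[list, list]:
    """Sorted 2:1 split: order samples by response (ties broken by a
    stable sort on the given order), then repeatedly assign two to
    training and one to validation; trailing samples of an incomplete
    group go to training.  21 samples -> 14 train / 7 validation."""
    ids = list(sample_ids)
    y = np.asarray(responses, dtype=float)
    if len(ids) != len(y):
        raise DomainError("sample_ids and responses differ in length")
    if len(ids) < 3:
        raise InsufficientDataError("need >= 3 samples for a 2:1 split")
    order = np.argsort(y, kind="stable")
    train, val = [], []
    for pos, idx in enumerate(order):
        (val if pos % 3 == 2 else train).append(ids[idx])
    return train, val


class MultiLinearRegression(BaseEstimator, RegressorMixin):
    """Ordinary least squares with intercept (the MLR stage).

    Attributes: ``coef_``, ``intercept_``, ``r2_``.  A rank-deficient
    design raises with the names of the collinear columns.
    """

    def fit(self, X, y):
        X, y = _as_xy(X, y)
        n, p = X.shape
        if n <= p + 1:
            raise InsufficientDataError(
                f"need more samples ({n}) than features + 1 ({p + 1})"
            )
        design = np.column_stack([np.ones(n), X])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # name the offending columns via QR pivoting on the design
            _, _, piv = _pivoted_qr(design, pivoting=True)
            dependent = sorted(piv[rank:].tolist())
            names = ["intercept"] + [f"x{j}" for j in range(p)]
            raise DomainError(
                "singular design; collinear columns: "
                + ", ".join(names[j] for j in dependent)
            )
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        fitted = design @ beta
        tss = np.sum((y - y.mean()) ** 2)
        self.r2_ = float(1.0 - np.sum((y - fitted) ** 2) / tss) if tss > 0 else np.nan
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def validate(self, X_val, y_val) -> tuple[float, float]:
        """Pearson r (and p) of predicted vs measured validation responses."""
        preds = self.predict(X_val)
        r, p = pearsonr(np.asarray(y_val, dtype=float).ravel(), preds)
        return float(r), float(p)


def fit_mlr(X_train, y_train) -> MultiLinearRegression:
    return MultiLinearRegression().fit(X_train, y_train)


def predict_mlr(model: MultiLinearRegression, X_val) -> np.ndarray:
    return model.predict(X_val)


def rank_marker_correlations(
    proteins: pd.DataFrame,
    marker_a: str,
    marker_b: str,
    *,
    named: Sequence[str] = (),
) -> pd.DataFrame:
    """Correlation ranking of every protein against a marker difference.

    ``proteins`` is samples x proteins, z-scored across samples; the
    target is ``proteins[marker_a] - proteins[marker_b]``.  Each other
    protein's Pearson r and p against the target is computed; the
    ``percentile`` column places each r within the empirical distribution
    of all tested proteins (100 = most positively correlated).  Constant
    columns are excluded with a warning; ``named`` proteins are flagged
    in a ``named`` column for easy lookup.
    """
    for m in (marker_a, marker_b):
        if m not in proteins.columns:
            raise DomainError(f"marker {m!r} not in the protein matrix")
    target = proteins[marker_a].to_numpy(float) - proteins[marker_b].to_numpy(float)
    if np.ptp(target) == 0:
        raise DomainError("marker difference is constant; ranking undefined")
    rows = []
    for col in proteins.columns:
        if col in (marker_a, marker_b):
            continue
        vals = proteins[col].to_numpy(float)
        if np.ptp(vals) == 0:
            warnings.warn(f"constant protein {col!r} excluded", stacklevel=2)
            continue
        r, p = pearsonr(vals, target)
        rows.append({"protein": col, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    if out.empty:
        raise DomainError("no non-constant proteins to rank")
    ranks = out["r"].rank(method="average")
    out["percentile"] = 100.0 * (ranks - 1) / max(len(out) - 1, 1)
    out["named"] = out["protein"].isin(list(named))
    return out.sort_values("r", ascending=False).reset_index(drop=True)
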