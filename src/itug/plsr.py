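"""Single-response partial least squares regression (PLS1), from scratch.

The NIPALS deflation scheme for one response: predictors are z-scored and
the response centred; each component extracts the unit weight vector
``w_a`` proportional to ``X_a' y_a`` (the covariance direction), scores
``t_a = X_a w_a``, loadings ``p_a = X_a' t_a / t_a't_a`` and
``q_a = y_a' t_a / t_a't_a``, then deflates ``X`` and ``y``.  Scores of
different components are exactly orthogonal; regression coefficients on
the original scale are recoverable for every component count.

Also provided: per-component explained response variation (the quantity
tabulated per component in validation reports), RMSEP, variable
importance in projection (VIP, whose squares average to 1 across
features) and the conventional 0.83 / 1 / 1.21 VIP banding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PreprocessingError, SchemaError

#: Conventional VIP interpretation cut-offs (lower / middle / upper).
VIP_CUTOFFS = (0.83, 1.0, 1.21)
VIP_BANDS = ("below 0.83", "0.83-1", "1-1.21", "above 1.21")


@dataclass
class FeatureTable:
    """An n x m predictor matrix with named columns and a response vector."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self):
        if not isinstance(self.X, pd.DataFrame):
            self.X = pd.DataFrame(self.X)
        if not isinstance(self.y, pd.Series):
            self.y = pd.Series(np.asarray(self.y, dtype=float), index=self.X.index)
        if len(self.X) != len(self.y):
            raise SchemaError("X and y have different numbers of rows")
        if self.X.columns.duplicated().any():
            raise SchemaError("feature names must be unique")
        if self.X.isna().any().any() or self.y.isna().any():
            raise PreprocessingError("missing values must be imputed upstream")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def subset(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(self.X[list(names)], self.y)

    def rows(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X.iloc[idx], self.y.iloc[idx])


@dataclass
class PlsModel:
    """A fitted PLS1 model.

    Holds the z-scoring constants, per-component weights ``W`` (columns of
    unit norm), X-loadings ``P``, response loadings ``q``, scores ``T``,
    per-component explained response sum of squares ``ssy`` and the total
    centred response sum of squares ``ss_total``.
    """

    feature_names: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    W: np.ndarray  # (m, A)
    P: np.ndarray  # (m, A)
    q: np.ndarray  # (A,)
    T: np.ndarray  # (n, A)
    ssy: np.ndarray  # (A,)
    ss_total: float
    coef_std: np.ndarray = field(init=False)  # (m, A), standardized scale

    def __post_init__(self):
        # b_a = W (P'W)^-1 q for each truncation a, built incrementally.
        m, A = self.W.shape
        self.coef_std = np.zeros((m, A))
        for a in range(1, A + 1):
            Wa, Pa, qa = self.W[:, :a], self.P[:, :a], self.q[:a]
            self.coef_std[:, a - 1] = Wa @ np.linalg.solve(Pa.T @ Wa, qa)

    @property
    def a_max(self) -> int:
        return self.W.shape[1]

    def coefficients(self, a: int) -> tuple[np.ndarray, float]:
        """Original-scale regression coefficients and intercept for ``a``."""
        if not 1 <= a <= self.a_max:
            raise ValueError(f"component count {a} outside 1..{self.a_max}")
        b = self.coef_std[:, a - 1] / self.x_std
        return b, float(self.y_mean - self.x_mean @ b)


def fit_pls1(table: FeatureTable, a_max: int) -> PlsModel:
    """Fit a PLS1 model with up to ``a_max`` components.

    Extraction stops early when the residual covariance vanishes (rank
    exhausted); zero-variance predictor columns are rejected by name.
    """
    X = table.X.to_numpy(dtype=float)
    y = table.y.to_numpy(dtype=float)
    n, m = X.shape
    if a_max < 1:
        raise ValueError("a_max must be at least 1")
    if a_max > min(n - 1, m):
        raise ValueError(f"a_max={a_max} exceeds min(n-1, m)={min(n - 1, m)}")
    x_std = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(x_std <= 0)
    if dead.size:
        names = [table.X.columns[j] for j in dead[:5]]
        raise PreprocessingError(f"zero-variance predictor column(s): {names}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xa = (X - x_mean) / x_std
    ya = y - y_mean
    ss_total = float(ya @ ya)

    W, P, Q, T, SSY = [], [], [], [], []
    for _ in range(a_max):
        cov = Xa.T @ ya
        norm = np.linalg.norm(cov)
        if norm <= 1e-12 * max(1.0, ss_total):
            break
        w = cov / norm
        t = Xa @ w
        tt = float(t @ t)
        if tt <= 1e-12:
            break
        p = Xa.T @ t / tt
        qa = float(ya @ t / tt)
        Xa = Xa - np.outer(t, p)
        ya = ya - qa * t
        W.append(w)
        P.append(p)
        Q.append(qa)
        T.append(t)
        SSY.append(qa * qa * tt)
    if not W:
        raise PreprocessingError("response has no covariance with the predictors")
    return PlsModel(
        feature_names=list(table.X.columns),
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        W=np.column_stack(W),
        P=np.column_stack(P),
        q=np.asarray(Q),
        T=np.column_stack(T),
        ssy=np.asarray(SSY),
        ss_total=ss_total,
    )


def predict(model: PlsModel, X_new, a: int) -> np.ndarray:
    """Predict the response with ``a`` components (0 = the training mean).

    Training z-scoring constants are applied to ``X_new``; nothing is
    re-estimated from the new data.
    """
    if isinstance(X_new, pd.DataFrame):
        if list(X_new.columns) != model.feature_names:
            raise SchemaError("prediction columns do not match the fitted features")
        X_new = X_new.to_numpy(dtype=float)
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.feature_names):
        raise SchemaError(
            f"expected {len(model.feature_names)} columns, got {X_new.shape[1]}"
        )
    if a == 0:
        return np.full(len(X_new), model.y_mean)
    if not 1 <= a <= model.a_max:
        raise ValueError(f"component count {a} outside 0..{model.a_max}")
    Xs = (X_new - model.x_mean) / model.x_std
    return model.y_mean + Xs @ model.coef_std[:, a - 1]


def explained_variation(model: PlsModel) -> np.ndarray:
    """Per-component fraction of the centred response sum of squares."""
    if model.ss_total <= 0:
        return np.zeros(model.a_max)
    return model.ssy / model.ss_total


def rmsep(y_true, y_pred) -> float:
    """Root mean square error of prediction."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("inputs must be equal-length non-empty vectors")
    d = y_true - y_pred
    return float(np.sqrt(np.mean(d * d)))


def vip(model: PlsModel, a: int) -> np.ndarray:
    """Variable importance in projection over the first ``a`` components.

    VIP_j = sqrt(m * sum_b ssy_b w_jb^2 / sum_b ssy_b); the mean squared
    VIP across features is exactly 1.
    """
    if not 1 <= a <= model.a_max:
        raise ValueError(f"component count {a} outside 1..{model.a_max}")
    ssy = model.ssy[:a]
    W2 = model.W[:, :a] ** 2
    m = len(model.feature_names)
    return np.sqrt(m * (W2 @ ssy) / ssy.sum())


def classify_vip(vips) -> list[str]:
    """Band VIP values by the 0.83 / 1 / 1.21 cut-offs (ties go up)."""
    lo, mid, hi = VIP_CUTOFFS
    out = []
    for v in np.asarray(vips, dtype=float):
        if v < lo:
            out.append(VIP_BANDS[0])
        elif v < mid:
            out.append(VIP_BANDS[1])
        elif v < hi:
            out.append(VIP_BANDS[2])
        else:
            out.append(VIP_BANDS[3])
    return out
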