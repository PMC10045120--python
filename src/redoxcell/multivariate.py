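"""Partial least squares regression with VIP scores.

PLSR relates the per-cell model protein concentrations (X) to an endpoint
redox readout (Y, typically the 2 h NADPH:NADP+ ratio) through a small
number of latent components.  Data are log10-transformed and autoscaled
(zero mean, unit variance per column) before fitting.  The decomposition is
the classical NIPALS algorithm: each component's X-weight vector is the
unit-norm direction maximizing covariance with the current Y residual,
followed by deflation of X and Y.  Model quality is summarized by cumulative
R2Y (explained Y variance) and cross-validated Q2 (1 - PRESS/SS, K-fold with
preprocessing refit inside each training fold), and per-variable importance
by VIP scores, normalized so that the mean squared VIP equals one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Preprocessing",
    "PLSRFit",
    "preprocess",
    "fit_plsr",
    "predict",
    "q2_crossval",
    "vip_scores",
    "select_components",
    "plsr_analysis",
    "plsr_by_class",
]

_MAX_NIPALS_ITER = 500
_NIPALS_TOL = 1e-12


@dataclass(frozen=True)
class Preprocessing:
    """Log10 + autoscaling record; stores what is needed to re-apply or
    invert the transform."""

    x_offset: np.ndarray  # per-column additive offset before log10 (0 where unused)
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_offset: float
    y_mean: float
    y_sd: float
    x_names: tuple[str, ...] = ()

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (np.log10(X + self.x_offset) - self.x_mean) / self.x_sd

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.log10(y + self.y_offset) - self.y_mean) / self.y_sd

    def inverse_y_log(self, y_std: np.ndarray) -> np.ndarray:
        """Back to the log10 scale (not the original linear scale)."""
        return y_std * self.y_sd + self.y_mean


def _auto_offset(col: np.ndarray, name: str) -> float:
    """Half the smallest positive value when zeros are present, else 0."""
    if np.any(col < 0):
        raise ValueError(f"column {name!r} has negative values; cannot log-transform")
    if np.all(col > 0):
        return 0.0
    positive = col[col > 0]
    if positive.size == 0:
        raise ValueError(f"column {name!r} is all zeros")
    return 0.5 * float(positive.min())


def preprocess(
    X, y, log_offset: float | None = None
) -> tuple[np.ndarray, np.ndarray, Preprocessing]:
    """Log10-transform then autoscale X (columns) and y.

    ``log_offset=None`` picks, per column, half the smallest positive value
    when zeros are present (dropout guard) and no offset otherwise.  A
    zero-variance column after transformation is an error naming the
    variable.
    """
    X_df = pd.DataFrame(X)
    names = tuple(str(c) for c in X_df.columns)
    Xv = X_df.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(Xv)) and np.all(np.isfinite(yv))):
        raise ValueError("X and y must be finite")

    if log_offset is None:
        x_off = np.array([_auto_offset(Xv[:, j], names[j]) for j in range(Xv.shape[1])])
        y_off = _auto_offset(yv, "y")
    else:
        x_off = np.full(Xv.shape[1], float(log_offset))
        y_off = float(log_offset)

    Xl = np.log10(Xv + x_off)
    yl = np.log10(yv + y_off)
    x_mean, x_sd = Xl.mean(axis=0), Xl.std(axis=0, ddof=1)
    zero = np.flatnonzero(x_sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance column {names[int(zero[0])]!r}")
    y_mean, y_sd = float(yl.mean()), float(yl.std(ddof=1))
    if y_sd == 0:
        raise ValueError("response has zero variance")

    record = Preprocessing(
        x_offset=x_off, x_mean=x_mean, x_sd=x_sd,
        y_offset=y_off, y_mean=y_mean, y_sd=y_sd, x_names=names,
    )
    return record.transform_x(Xv), record.transform_y(yv), record


@dataclass
class PLSRFit:
    """A fitted PLS regression: per-component weights/loadings/scores,
    cumulative R2Y, VIP scores and (optionally) cross-validated Q2."""

    weights: np.ndarray      # (p, A) unit-norm X-weights
    x_loadings: np.ndarray   # (p, A)
    y_loadings: np.ndarray   # (A,)
    scores: np.ndarray       # (n, A)
    r2y: np.ndarray          # cumulative, length A
    ssy_explained: np.ndarray  # per-component explained Y sum of squares
    coefficients: np.ndarray   # (p,) regression vector in standardized space
    x_names: tuple[str, ...] = ()
    preprocessing: Preprocessing | None = None
    q2: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def vip(self) -> pd.Series:
        return vip_scores(self)


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRFit:
    """NIPALS PLS regression of a single response on standardized data.

    ``X`` (n x p) and ``y`` (n,) are assumed already centered/scaled (see
    :func:`preprocess`).  Raises on rank-deficient requests (A > rank) via a
    vanishing-weight check, and on non-convergence of the NIPALS iteration.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")

    Xr, yr = X.copy(), y.copy()
    ss_tot = float((y**2).sum())
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    r2y = np.zeros(n_components)
    ssy = np.zeros(n_components)

    for a in range(n_components):
        # single-response NIPALS: the inner iteration is exact after one
        # pass, w = X'y / ||X'y||
        w = Xr.T @ yr[:, 0]
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise ValueError(
                f"component {a + 1}: X residual orthogonal to y (rank exhausted)"
            )
        w /= norm
        t = Xr @ w
        tt = float(t @ t)
        if tt < 1e-14:
            raise ValueError(f"component {a + 1}: degenerate score vector")
        p_a = Xr.T @ t / tt
        qa = float(yr[:, 0] @ t / tt)
        Xr = Xr - np.outer(t, p_a)
        yr = yr - (t * qa)[:, None]
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, qa, t
        ssy[a] = qa**2 * tt
        r2y[a] = 1.0 - float((yr**2).sum()) / ss_tot

    # regression vector in the standardized space: B = W (P'W)^-1 q
    B = W @ np.linalg.solve(P.T @ W, q)
    return PLSRFit(
        weights=W, x_loadings=P, y_loadings=q, scores=T,
        r2y=r2y, ssy_explained=ssy, coefficients=B,
    )


def predict(fit: PLSRFit, X: np.ndarray) -> np.ndarray:
    """Predicted response (standardized space) for standardized X."""
    return np.asarray(X, dtype=float) @ fit.coefficients


def vip_scores(fit: PLSRFit) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ) with unit-norm
    weights; the mean squared VIP is identically 1.
    """
    p = fit.weights.shape[0]
    ssy = fit.ssy_explained
    v = np.sqrt(p * (fit.weights**2 @ ssy) / ssy.sum())
    index = list(fit.x_names) if fit.x_names else list(range(p))
    return pd.Series(v, index=index, name="VIP").sort_values(ascending=False)


def q2_crossval(
    X,
    y,
    n_components: int,
    folds: int = 7,
    seed: int = 0,
    log_offset: float | None = None,
) -> np.ndarray:
    """Cross-validated Q2 per cumulative component count.

    Samples are shuffled with the seeded generator and split into
    ``folds`` contiguous blocks; the log/autoscale preprocessing is refit on
    each training fold.  Q2(a) = 1 - PRESS(a)/SS_tot, with PRESS and SS_tot
    accumulated on the log10 response scale.
    """
    X_df = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = len(yv)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("need at least one sample per fold")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    blocks = np.array_split(order, folds)

    press = np.zeros(n_components)
    ss_tot = 0.0
    for test_idx in blocks:
        train_idx = np.setdiff1d(order, test_idx, assume_unique=False)
        Xs, ys, rec = preprocess(
            X_df.iloc[train_idx], yv[train_idx], log_offset=log_offset
        )
        y_test_log = np.log10(yv[test_idx] + rec.y_offset)
        X_test = rec.transform_x(X_df.iloc[test_idx].to_numpy(dtype=float))
        ss_tot += float(((y_test_log - rec.y_mean) ** 2).sum())
        for a in range(1, n_components + 1):
            fit = fit_plsr(Xs, ys, a)
            y_hat_log = rec.inverse_y_log(predict(fit, X_test))
            press[a - 1] += float(((y_test_log - y_hat_log) ** 2).sum())
    return 1.0 - press / ss_tot


def select_components(q2: np.ndarray, gain: float = 0.01) -> int:
    """Smallest component count whose next increment of Q2 is below ``gain``."""
    for a in range(len(q2) - 1):
        if q2[a + 1] - q2[a] < gain:
            return a + 1
    return len(q2)


def plsr_analysis(
    X,
    y,
    n_components: int | None = None,
    max_components: int = 6,
    folds: int = 7,
    seed: int = 0,
    log_offset: float | None = None,
) -> PLSRFit:
    """Preprocess, cross-validate, pick the component count (unless given)
    and fit the final model on all samples."""
    X_df = pd.DataFrame(X)
    max_a = min(max_components, X_df.shape[1], X_df.shape[0] - 1)
    q2 = q2_crossval(X_df, y, max_a, folds=folds, seed=seed, log_offset=log_offset)
    A = n_components if n_components is not None else select_components(q2)
    Xs, ys, record = preprocess(X_df, y, log_offset=log_offset)
    fit = fit_plsr(Xs, ys, A)
    fit.x_names = tuple(str(c) for c in X_df.columns)
    fit.preprocessing = record
    fit.q2 = q2[:A]
    return fit


def plsr_by_class(
    X,
    y,
    classes: Sequence,
    n_components: Mapping | None = None,
    **kwargs,
) -> dict:
    """Separate PLSR fits per class label (e.g. malignant / non-malignant).

    ``n_components`` may map class label -> fixed component count; labels not
    present use cross-validated selection.
    """
    X_df = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float).ravel()
    labels = pd.Series(list(classes))
    fits = {}
    for label in labels.unique():
        mask = (labels == label).to_numpy()
        A = (n_components or {}).get(label)
        fits[label] = plsr_analysis(X_df.loc[mask], yv[mask], n_components=A, **kwargs)
    return fits
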