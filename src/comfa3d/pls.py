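"""Partial least squares (PLS1) with leave-one-out cross-validation.

PLS extracts latent components by NIPALS-style sequential deflation:

    w_a = X'y / |X'y|        (weight)
    t_a = X w_a              (score)
    p_a = X't_a / t_a't_a    (loading)
    q_a = y't_a / t_a't_a    (y loading)
    X <- X - t_a p_a',  y <- y - q_a t_a

after mean-centering X and y. Regression coefficients in the original
descriptor space are B = W (P'W)^-1 q, so the latent-path prediction and
``X B + intercept`` agree to numerical precision.

Model quality statistics follow the 3D-QSAR conventions: q² and SEP from
leave-one-out refits (PRESS_cv = sum (y_i - yhat_(-i))², q² = 1 -
PRESS_cv / SS_total, SEP = sqrt(PRESS_cv / (n - N - 1))), and on the fitted
model r², SEE = sqrt(RSS / (n - N - 1)) and the F statistic
(r²/N) / ((1-r²)/(n-N-1)). A q² above 0.5 is the conventional bar for a
predictive model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .fields import FieldMatrix

__all__ = [
    "PLSModel",
    "PLSSummary",
    "fit_pls",
    "loo_cv",
    "scan_components",
    "select_components",
    "final_stats",
    "field_contributions",
]

_RANK_TOL = 1e-12


class PLSError(ValueError):
    pass


@dataclass
class PLSModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray   # (p, N)
    loadings: np.ndarray  # (p, N)
    scores: np.ndarray    # (n, N)
    y_loadings: np.ndarray  # (N,)
    coefficients: np.ndarray  # (p,)

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coefficients)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return X @ self.coefficients + self.intercept

    def predict_path(self, X: np.ndarray) -> np.ndarray:
        """Predictions for every nested sub-model N = 1..n_components.

        NIPALS components are extracted sequentially, so truncating the
        component list gives exactly the model that would have been fit
        with fewer components. Returns shape (n_samples, n_components).
        """
        X = np.atleast_2d(np.asarray(X, float))
        Xc = X - self.x_mean
        out = np.empty((X.shape[0], self.n_components))
        acc = np.full(X.shape[0], self.y_mean)
        for a in range(self.n_components):
            t = Xc @ self.weights[:, a]
            acc = acc + self.y_loadings[a] * t
            Xc = Xc - np.outer(t, self.loadings[:, a])
            out[:, a] = acc
        return out


@dataclass
class PLSSummary:
    """All fit/CV statistics for one model (layout mirrors a QSAR report)."""

    n_components: int
    q2: float
    sep: float
    r2: float
    see: float
    f_stat: float
    contributions: tuple[float, float] | None = None
    component_scan: list[tuple[int, float, float]] | None = None  # (N, sep, q2)


def _validate_xy(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise PLSError(f"shape mismatch: X {X.shape}, y {y.shape}")
    if n_components < 1:
        raise PLSError("n_components must be >= 1")
    if np.ptp(y) == 0:
        raise PLSError("y has zero variance")
    return X, y


def _fit_upto(X: np.ndarray, y: np.ndarray, n_max: int) -> PLSModel:
    """NIPALS extraction of up to ``n_max`` components, stopping early when
    the centered matrix runs out of rank. Returns the achieved model."""
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    x_scale = float(np.abs(Xc).max()) or 1.0

    W = np.zeros((p, n_max))
    P = np.zeros((p, n_max))
    T = np.zeros((n, n_max))
    q = np.zeros(n_max)
    achieved = 0
    for a in range(n_max):
        w = Xc.T @ yc
        wnorm = np.linalg.norm(w)
        if wnorm <= _RANK_TOL * x_scale * max(np.abs(yc).max(), 1.0):
            break
        w /= wnorm
        t = Xc @ w
        tt = float(t @ t)
        if tt <= (_RANK_TOL * x_scale) ** 2 * n:
            break
        pvec = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pvec)
        yc = yc - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
        achieved = a + 1
    if achieved == 0:
        raise PLSError("X carries no covariance with y; no component extractable")
    W, P, T, q = W[:, :achieved], P[:, :achieved], T[:, :achieved], q[:achieved]
    # B = W (P'W)^{-1} q
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_components=achieved,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=q,
        coefficients=coef,
    )


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent components.

    Raises PLSError when the requested number of components exceeds the
    rank of the centered descriptor matrix (the message names the
    achievable rank).
    """
    X, y = _validate_xy(X, y, n_components)
    model = _fit_upto(X, y, n_components)
    if model.n_components < n_components:
        raise PLSError(
            f"requested {n_components} components but rank supports only "
            f"{model.n_components}"
        )
    return model


def loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    dof: Literal["n-N-1", "n-N"] = "n-N-1",
) -> tuple[float, float, float]:
    """Leave-one-out cross-validation: returns (q2, sep, press_cv).

    Each sample is predicted by a model refit on the remaining n-1
    samples. SEP uses n - N - 1 degrees of freedom by default.
    """
    X, y = _validate_xy(X, y, n_components)
    n = X.shape[0]
    if n < 3:
        raise PLSError("need at least 3 samples for LOO")
    denom = _dof(n, n_components, dof)
    press = 0.0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = fit_pls(X[mask], y[mask], n_components)
        press += float(y[i] - model.predict(X[i][None, :])[0]) ** 2
        mask[i] = True
    ss_total = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss_total
    sep = float(np.sqrt(press / denom))
    return q2, sep, press


def _dof(n: int, n_components: int, rule: str) -> int:
    d = n - n_components - (1 if rule == "n-N-1" else 0)
    if d <= 0:
        raise PLSError(f"non-positive degrees of freedom (n={n}, N={n_components})")
    return d


def scan_components(
    X: np.ndarray,
    y: np.ndarray,
    n_max: int = 15,
    rule: str | tuple = "max_q2",
) -> tuple[list[tuple[int, float, float]], int]:
    """LOO statistics for N = 1..n_max; returns (scan, selected N).

    ``scan`` rows are (N, SEP, q²); infeasible N (rank or degrees of
    freedom) are skipped. Selection is delegated to
    :func:`select_components`.
    """
    if n_max < 1:
        raise PLSError("n_max must be >= 1")
    X, y = _validate_xy(X, y, 1)
    n = X.shape[0]
    if n < 3:
        raise PLSError("need at least 3 samples for LOO")
    # one LOO pass at the deepest model; nested NIPALS sub-models give the
    # held-out prediction for every smaller N (equals refitting, see loo_cv)
    preds = np.full((n, n_max), np.nan)
    achieved_min = n_max
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = _fit_upto(X[mask], y[mask], n_max)
        path = model.predict_path(X[i][None, :])[0]
        preds[i, : model.n_components] = path
        achieved_min = min(achieved_min, model.n_components)
        mask[i] = True
    ss_total = float(np.sum((y - y.mean()) ** 2))
    scan: list[tuple[int, float, float]] = []
    for n_comp in range(1, achieved_min + 1):
        if n - n_comp - 1 <= 0:
            break
        press = float(np.sum((y - preds[:, n_comp - 1]) ** 2))
        q2 = 1.0 - press / ss_total
        sep = float(np.sqrt(press / (n - n_comp - 1)))
        scan.append((n_comp, sep, q2))
    if not scan:
        raise PLSError("no feasible component count in scan")
    return scan, select_components(scan, rule)


def select_components(
    scan: Sequence[tuple[int, float, float]], rule: str | tuple = "max_q2"
) -> int:
    """Pick N from a (N, SEP, q²) scan.

    Rules: ``"max_q2"`` (default) takes the argmax of q², first occurrence
    on ties; ``("first_within", tol)`` takes the smallest N whose q² is
    within tol of the scan maximum; ``("override", N)`` returns N as given
    (how runs that fix the component count by hand are reproduced).
    """
    if isinstance(rule, tuple):
        kind, value = rule
        if kind == "override":
            return int(value)
        if kind == "first_within":
            best = max(q2 for _, _, q2 in scan)
            for n_comp, _, q2 in scan:
                if q2 >= best - value:
                    return n_comp
        raise PLSError(f"unknown selection rule {rule!r}")
    if rule == "max_q2":
        best = max(scan, key=lambda row: row[2])
        return best[0]
    raise PLSError(f"unknown selection rule {rule!r}")


def final_stats(
    model: PLSModel,
    X: np.ndarray,
    y: np.ndarray,
    dof: Literal["n-N-1", "n-N"] = "n-N-1",
) -> tuple[float, float, float]:
    """Non-cross-validated statistics: (r², SEE, F)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = y.size
    N = model.n_components
    denom = _dof(n, N, dof)
    resid = y - model.predict(X)
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise PLSError("y has zero variance")
    r2 = 1.0 - rss / tss
    see = float(np.sqrt(rss / denom))
    f_stat = (r2 / N) / ((1.0 - r2) / denom) if r2 < 1.0 else float("inf")
    return r2, see, f_stat


def field_contributions(
    model: PLSModel, fields: FieldMatrix
) -> tuple[float, float]:
    """Percent (steric, electrostatic) contributions of a fitted model.

    Per-column contribution is |coefficient| × column standard deviation in
    the descriptor space the model was fit on; block percentages are the
    block sums normalized to 100.
    """
    sigma = fields.column_stdevs()
    beta = np.abs(model.coefficients)
    if beta.size != sigma.size:
        raise PLSError(
            f"model has {beta.size} coefficients but field matrix retains "
            f"{sigma.size} columns"
        )
    contrib = beta * sigma
    total = contrib.sum()
    if total == 0:
        raise PLSError("all coefficients are zero; contributions undefined")
    block = fields.block_of_column()
    steric = float(contrib[block == 0].sum() / total * 100.0)
    return steric, 100.0 - steric
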