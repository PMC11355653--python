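"""PLS1 regression (NIPALS), explained variance and VIP scores.

Partial least squares builds orthogonal score components t_a = X_a w_a whose
weight vectors maximize covariance with the response; for a single response
the NIPALS weight has the closed form w_a = X_a' y_a / ||X_a' y_a||, so the
fit is deterministic.  Variable importance in projection (VIP) summarizes a
predictor's contribution across components,

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ),   SSY_a = q_a^2 t_a' t_a,

with unit-norm weights, so that mean(VIP^2) = 1 and VIP > 1 flags variables
contributing more than average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import VariableKey
from .preprocess import DesignMatrix

logger = logging.getLogger(__name__)

_DEGENERATE_TOL = 1e-12


@dataclass
class PLSModel:
    """A fitted PLS1 model on the normalized predictor scale."""

    A: int
    W: np.ndarray  # p x A, unit-norm weight columns
    P: np.ndarray  # p x A X-loadings
    T: np.ndarray  # n x A orthogonal scores
    q: np.ndarray  # A y-loadings
    b_coef: np.ndarray  # p regression coefficients, normalized scale
    intercept: float
    explvar_X: np.ndarray  # per-component fraction of X sum of squares
    explvar_Y: np.ndarray  # per-component fraction of y sum of squares
    column_keys: list[VariableKey]
    x_center: np.ndarray = field(repr=False, default=None)


@dataclass
class VIPResult:
    """Per-variable VIP scores with descending ranking and threshold counts."""

    scores: dict[VariableKey, float]
    model_A: int
    ranking: list[VariableKey]
    n_above_1: int
    n_above_1_5: int
    n_above_2: int


def fit_pls(design: DesignMatrix, A: int) -> PLSModel:
    """Fit a PLS1 model with ``A`` components by NIPALS deflation.

    X and y are centred internally (the design matrix is already z-scored,
    but imputation and fold subsetting can leave small column means), so the
    model carries an explicit intercept.  If the deflated residual becomes
    orthogonal to y before ``A`` components, the fit truncates with a
    warning.

    Raises
    ------
    ValueError
        If A is out of [1, min(n-1, p)] or y holds a single class.
    """
    X, y = np.asarray(design.X, dtype=float), np.asarray(design.y, dtype=float)
    n, p = X.shape
    A_max = min(n - 1, p)
    if not 1 <= A <= A_max:
        raise ValueError(f"A must be in [1, {A_max}] for n={n}, p={p}; got {A}")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate response: only one class present")

    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    Xa = X - x_center
    ya = y - y_center
    ssx_total = float((Xa**2).sum())
    ssy_total = float((ya**2).sum())

    Ws, Ps, Ts, qs, evx, evy = [], [], [], [], [], []
    for a in range(A):
        w = Xa.T @ ya
        w_norm = float(np.linalg.norm(w))
        if w_norm < _DEGENERATE_TOL * max(1.0, np.abs(Xa).max(initial=0.0)):
            logger.warning(
                "PLS residual orthogonal to response after %d components "
                "(requested %d); truncating", a, A,
            )
            break
        w = w / w_norm
        t = Xa @ w
        tt = float(t @ t)
        if tt < _DEGENERATE_TOL:
            logger.warning("degenerate score at component %d; truncating", a + 1)
            break
        p_load = Xa.T @ t / tt
        q_load = float(ya @ t) / tt
        Xa = Xa - np.outer(t, p_load)
        ya = ya - q_load * t
        Ws.append(w)
        Ps.append(p_load)
        Ts.append(t)
        qs.append(q_load)
        evx.append(tt * float(p_load @ p_load) / ssx_total if ssx_total > 0 else 0.0)
        evy.append(q_load**2 * tt / ssy_total)

    if not Ws:
        raise ValueError("degenerate predictors: no PLS component could be extracted")
    A_eff = len(Ws)
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    T = np.column_stack(Ts)
    q = np.array(qs)

    # b = W (P'W)^{-1} q maps centred X to centred predictions.
    b = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_center - float(x_center @ b)
    return PLSModel(
        A=A_eff,
        W=W,
        P=P,
        T=T,
        q=q,
        b_coef=b,
        intercept=intercept,
        explvar_X=np.array(evx),
        explvar_Y=np.array(evy),
        column_keys=list(design.column_keys),
        x_center=x_center,
    )


def predict(model: PLSModel, Xnew: np.ndarray) -> np.ndarray:
    """Continuous responses for rows of ``Xnew`` on the model's normalized scale."""
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != len(model.b_coef):
        raise ValueError(
            f"Xnew has {Xnew.shape[1]} columns, model expects {len(model.b_coef)}"
        )
    return Xnew @ model.b_coef + model.intercept


def cumulative_explained_variance(model: PLSModel) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative fractions of X and y sum-of-squares explained per component."""
    return np.cumsum(model.explvar_X), np.cumsum(model.explvar_Y)


def vip_scores(model: PLSModel) -> VIPResult:
    """Wold VIP scores for every predictor of a fitted model.

    Ranking is by descending score with ties broken by canonical key order,
    so reports are deterministic.
    """
    p = model.W.shape[0]
    ssy = model.q**2 * np.einsum("ia,ia->a", model.T, model.T)
    total = ssy.sum()
    if total <= 0:
        vip = np.zeros(p)
    else:
        vip = np.sqrt(p * (model.W**2) @ ssy / total)
    scores = {key: float(v) for key, v in zip(model.column_keys, vip)}
    ranking = sorted(model.column_keys, key=lambda k: (-scores[k], k.sort_index()))
    return VIPResult(
        scores=scores,
        model_A=model.A,
        ranking=ranking,
        n_above_1=int((vip > 1).sum()),
        n_above_1_5=int((vip > 1.5).sum()),
        n_above_2=int((vip > 2).sum()),
    )


def auto_components(
    design: DesignMatrix, target_y_fraction: float = 0.9, cap: int | None = None
) -> int:
    """Smallest component count whose cumulative y explained variance reaches
    ``target_y_fraction``, capped at min(n-1, p) (and at ``cap`` if given)."""
    A_max = min(design.n - 1, design.p)
    if cap is not None:
        A_max = min(A_max, cap)
    full = fit_pls(design, A_max)
    _, cum_y = cumulative_explained_variance(full)
    reached = np.nonzero(cum_y >= target_y_fraction)[0]
    return int(reached[0]) + 1 if reached.size else full.A
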